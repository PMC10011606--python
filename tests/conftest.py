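"""Shared fixtures: small synthetic genomes and random graph builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hicphase.graph_io import SequenceGraph
from hicphase.pipeline import RunConfig, run_all
from hicphase.simulate import (SimConfig, build_truth_graph, simulate_diploid,
                               simulate_hic)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def random_bidirected_graph(rng: np.random.Generator,
                            n_nodes: int) -> SequenceGraph:
    """A random DAG-like bidirected component with random orientations.

    Nodes are ordered; edges go forward in that order (acyclic in the
    walk direction) with random per-node orientation flips, which
    exercises the mirror/orientation handling of bubble detection.
    """
    g = SequenceGraph()
    names = [f"n{i:02d}" for i in range(n_nodes)]
    flips = rng.integers(0, 2, n_nodes)
    for name in names:
        g.add_node(name, random_dna(rng, 20))
    for j in range(1, n_nodes):
        # every node gets at least one parent: graph stays connected
        n_par = 1 + (rng.random() < 0.35)
        parents = rng.choice(j, size=min(n_par, j), replace=False)
        for i in parents:
            oa = "+" if flips[i] == 0 else "-"
            ob = "+" if flips[j] == 0 else "-"
            g.add_edge(names[i], oa, names[j], ob, 0)
    g.label_components()
    return g


SMALL_SIM = dict(n_chromosomes=2, chrom_length=120_000, snp_rate=0.001,
                 n_insertions=1, n_deletions=1, n_inversions=1, depth=30,
                 node_split=12_000, n_breaks=2, k=21)


@pytest.fixture(scope="session")
def small_sim():
    """One small two-chromosome simulation shared across tests."""
    cfg = SimConfig(seed=11, **SMALL_SIM)
    truth = simulate_diploid(cfg)
    graph, gt = build_truth_graph(truth, cfg)
    sim = simulate_hic(truth, cfg)
    return cfg, truth, graph, gt, sim


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Full pipeline result on the shared small simulation."""
    cfg, truth, graph, gt, sim = small_sim
    rc = RunConfig(k=cfg.k, long_threshold=40_000)
    phased, scaf = run_all(graph, (sim.seq1, sim.seq2), rc)
    return cfg, truth, graph, gt, sim, phased, scaf
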