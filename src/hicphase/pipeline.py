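"""End-to-end drivers wiring the stages together.

These functions are the library-level equivalents of the CLI
subcommands: graph -> bubbles -> Hi-C mapping -> phasing -> scaffolding.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .bubbles import Bubble, BubbleChain, chain_bubbles, find_bubbles
from .graph_io import SequenceGraph
from .hic_map import AlleleKmerIndex, LinkCounts, build_index, count_links
from .phase import PhasedContigPair, phase_all
from .scaffold import (ScaffoldGraph, ScaffoldSet, build_scaffold_graph,
                       greedy_partition, order_and_orient, spell_scaffolds)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunables of the whole workflow, defaulting to the printed constants:
    k=31, support strictly >5 read pairs, 10 Mb long-contig threshold,
    p=3 neighbouring contigs, 100 N gaps."""

    k: int = 31
    min_support: int = 5
    max_alleles: int = 16
    long_threshold: int = 10_000_000
    p: int = 3
    conf_floor: float = 0.2
    head_frac: float = 0.2
    gap_len: int = 100
    genome_size: Optional[int] = None


@dataclass
class PhaseResult:
    bubbles: List[Bubble]
    chains: List[BubbleChain]
    index: AlleleKmerIndex
    links: LinkCounts
    pairs: List[PhasedContigPair]

    def contig_seqs(self) -> Dict[Tuple[int, int], str]:
        return {(p.component_id, h): (p.hap1_seq if h == 0 else p.hap2_seq)
                for p in self.pairs for h in (0, 1)}

    def contig_fasta(self) -> Dict[str, str]:
        out = {}
        for p in self.pairs:
            out[f"c{p.component_id}_h1"] = p.hap1_seq
            out[f"c{p.component_id}_h2"] = p.hap2_seq
        return out


@dataclass
class ScaffoldResult:
    graph: ScaffoldGraph
    scaffolds: ScaffoldSet
    seqs: Dict[str, str] = field(default_factory=dict)


def run_phase(graph: SequenceGraph, read_seqs, cfg: RunConfig = RunConfig()
              ) -> PhaseResult:
    """Detect and chain bubbles, map Hi-C pairs, phase every component."""
    t0 = time.perf_counter()
    bubbles = find_bubbles(graph, max_alleles=cfg.max_alleles)
    chains = chain_bubbles(graph, bubbles)
    t1 = time.perf_counter()
    index = build_index(graph, bubbles, k=cfg.k)
    links = count_links(read_seqs, index)
    t2 = time.perf_counter()
    pairs = phase_all(graph, chains, links, min_support=cfg.min_support)
    t3 = time.perf_counter()
    logger.info(
        "phase: %d bubbles in %d chains (%.1fs); %d/%d pairs informative "
        "(%.1fs); %d contig pairs phased (%.1fs)",
        len(bubbles), len(chains), t1 - t0, links.n_pairs_counted,
        links.n_pairs, t2 - t1, len(pairs), t3 - t2)
    return PhaseResult(bubbles, chains, index, links, pairs)


def run_scaffold(phased: PhaseResult, cfg: RunConfig = RunConfig()
                 ) -> ScaffoldResult:
    """Build the phased scaffold graph, partition, order, and spell."""
    sg = build_scaffold_graph(phased.pairs, phased.links,
                              head_frac=cfg.head_frac)
    ss = greedy_partition(sg, long_threshold=cfg.long_threshold, p=cfg.p,
                          conf_floor=cfg.conf_floor,
                          min_support=cfg.min_support)
    for part in ss.partitions:
        order_and_orient(part, sg)
    ss.gap_len = cfg.gap_len
    seqs = spell_scaffolds(ss, phased.contig_seqs())
    logger.info("scaffold: %d partitions from %d contigs",
                len(ss.partitions), len(phased.pairs))
    return ScaffoldResult(graph=sg, scaffolds=ss, seqs=seqs)


def run_all(graph: SequenceGraph, read_seqs, cfg: RunConfig = RunConfig()
            ) -> Tuple[PhaseResult, ScaffoldResult]:
    phased = run_phase(graph, read_seqs, cfg)
    return phased, run_scaffold(phased, cfg)
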