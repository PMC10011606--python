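"""Scaffold graph, confidence, partitioning, ordering, spelling."""

import itertools

import numpy as np
import pytest

from hicphase.evaluate import ng50
from hicphase.scaffold import (Partition, ScaffoldGraph, ScaffoldSet,
                               edge_confidence, greedy_partition,
                               order_and_orient, spell_scaffolds)

from _oracles import brute_force_partition


def make_sg(lengths, edges):
    """edges: {(ci, cj): weight} entered as straight allele-allele counts."""
    sg = ScaffoldGraph(list(lengths), lengths)
    for (ci, cj), w in edges.items():
        rec = sg.record(ci, cj)
        rec.aa[0][0] += w - w // 2
        rec.aa[1][1] += w // 2
    return sg


class TestEdgeConfidence:
    @pytest.mark.parametrize("e,i,j,expected", [
        (4, 2, 2, 1.0),
        (3, 6, 6, 0.25),
        (7, 0, 0, 1.0),  # isolated pair: defined maximum
        (0, 5, 5, 0.0),
    ])
    def test_printed_formula(self, e, i, j, expected):
        assert edge_confidence(e, i, j) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            edge_confidence(-1, 0, 0)
        with pytest.raises(ValueError):
            edge_confidence(1, -2, 0)


class TestGraphAccounting:
    def test_single_edge_pair(self):
        sg = make_sg({1: 1000, 2: 1000}, {(1, 2): 12})
        he = sg.hap_edges()
        assert sum(he.values()) == 12
        assert sg.weight(1, 2) == 12
        assert sg.confidence(1, 2) == 1.0  # no adjacent edges

    def test_haplotype_split_links_stay_on_their_edge(self):
        sg = ScaffoldGraph([1, 2], {1: 100, 2: 100})
        rec = sg.record(1, 2)
        rec.aa[0][0] = 9   # h1-h1 links only
        he = sg.hap_edges()
        assert he == {((1, 0), (2, 0)): 9}

    def test_shared_links_half_weight_rounded_down(self):
        sg = ScaffoldGraph([1, 2], {1: 100, 2: 100})
        rec = sg.record(1, 2)
        rec.shared = 7
        he = sg.hap_edges()
        assert he[((1, 0), (2, 0))] == 3
        assert he[((1, 1), (2, 1))] == 3


class TestGreedyPartition:
    def test_three_long_contigs_chain(self):
        lengths = {1: 20_000_000, 2: 20_000_000, 3: 20_000_000}
        sg = make_sg(lengths, {(1, 2): 500, (2, 3): 480, (1, 3): 40})
        ss = greedy_partition(sg)
        assert [p.contigs for p in ss.partitions] == [[1, 2, 3]]

    def test_short_contig_with_agreeing_neighbours_joins(self):
        lengths = {1: 20_000_000, 2: 20_000_000, 3: 20_000_000, 4: 50_000}
        sg = make_sg(lengths, {(1, 2): 500, (2, 3): 480,
                               (1, 4): 30, (2, 4): 60, (3, 4): 25})
        ss = greedy_partition(sg)
        assert [p.contigs for p in ss.partitions] == [[1, 2, 3, 4]]

    def test_short_contig_with_split_evidence_stays_singleton(self):
        lengths = {1: 20_000_000, 2: 20_000_000,
                   3: 20_000_000, 4: 20_000_000, 5: 50_000}
        sg = make_sg(lengths, {(1, 2): 500, (3, 4): 500,
                               (1, 5): 40, (2, 5): 35, (3, 5): 30})
        ss = greedy_partition(sg)
        parts = sorted(p.contigs for p in ss.partitions)
        assert [5] in parts  # 2/1 split across partitions: unattached

    def test_matches_exhaustive_partition_oracle(self):
        """On small instances with well-separated intra/inter supports
        (>2x margin) the greedy equals the exhaustive set-partition
        optimum of total intra-partition support."""
        rng = np.random.default_rng(31)
        for _ in range(25):
            n = int(rng.integers(4, 7))
            contigs = list(range(n))
            split = int(rng.integers(2, n))
            groups = [contigs[:split], contigs[split:]]
            lengths = {c: 20_000_000 for c in contigs}
            edges = {}
            for grp in groups:
                for a, b in zip(grp, grp[1:]):
                    edges[(a, b)] = int(rng.integers(200, 400))
                # weaker non-adjacent support inside the group
                for a, b in itertools.combinations(grp, 2):
                    if (a, b) not in edges and rng.random() < 0.6:
                        edges[(a, b)] = int(rng.integers(20, 90))
            sg = make_sg(lengths, edges)
            ss = greedy_partition(sg)
            got = sorted(tuple(sorted(p.contigs)) for p in ss.partitions)
            weight = {k: sg.weight(*k) for k in edges}
            _, best = brute_force_partition(contigs, weight)
            assert got == sorted(best)

    def test_mirror_partitions_by_relabelling(self):
        """h2 scaffolds mirror h1's: same partition, flipped haplotypes."""
        lengths = {1: 20_000_000, 2: 20_000_000}
        sg = ScaffoldGraph([1, 2], lengths)
        rec = sg.record(1, 2)
        rec.aa[0][1] = 400  # cross pairing: c1-h1 goes with c2-h2
        ss = greedy_partition(sg)
        assert len(ss.partitions) == 1
        rel = dict(ss.partitions[0].members)
        assert rel[1] != rel[2]  # cross parity propagated


class TestOrderOrient:
    def _chain_sg(self, n=3, L=1_000_000):
        lengths = {i: L for i in range(n)}
        sg = ScaffoldGraph(list(range(n)), lengths)
        for i in range(n - 1):
            rec = sg.record(i, i + 1)
            rec.aa[0][0] = 200
            rec.ends[("T", "H")] = 120
            rec.ends[("M", "M")] = 80
        return sg

    def test_chain_recovered_all_forward(self):
        sg = self._chain_sg()
        part = Partition(members=[(0, 0), (1, 0), (2, 0)])
        assert order_and_orient(part, sg) == [(0, "+"), (1, "+"), (2, "+")]

    def test_flipped_middle_contig_detected(self):
        sg = self._chain_sg()
        # contig 1's end support inverted: its head faces contig 0's tail
        sg.records[(0, 1)].ends = {("T", "T"): 120}
        sg.records[(1, 2)].ends = {("H", "H"): 120}
        part = Partition(members=[(0, 0), (1, 0), (2, 0)])
        assert order_and_orient(part, sg) == [(0, "+"), (1, "-"), (2, "+")]

    def test_disconnected_partition_ordered_per_piece(self, caplog):
        lengths = {i: 1_000_000 - i for i in range(4)}
        sg = ScaffoldGraph(list(range(4)), lengths)
        sg.record(0, 1).aa[0][0] = 100
        sg.record(2, 3).aa[0][0] = 100
        part = Partition(members=[(i, 0) for i in range(4)])
        order = order_and_orient(part, sg)
        assert [c for c, _ in order] == [0, 1, 2, 3]


class TestSpelling:
    def test_gap_joined_lengths(self):
        ss = ScaffoldSet(partitions=[
            Partition(members=[(1, 0), (2, 0)], order=[(1, "+"), (2, "+")])])
        seqs = spell_scaffolds(ss, {(1, 0): "A" * 1000, (1, 1): "C" * 1000,
                                    (2, 0): "G" * 2000, (2, 1): "T" * 2000})
        assert len(seqs["scaffold_1_h1"]) == 3100
        assert seqs["scaffold_1_h1"].count("N") == 100
        assert seqs["scaffold_1_h2"] == "C" * 1000 + "N" * 100 + "T" * 2000

    def test_singleton_partition_no_gap(self):
        ss = ScaffoldSet(partitions=[
            Partition(members=[(1, 0)], order=[(1, "+")])])
        seqs = spell_scaffolds(ss, {(1, 0): "ACGT", (1, 1): "AGGT"})
        assert seqs["scaffold_1_h1"] == "ACGT"
        assert "N" not in seqs["scaffold_1_h1"]

    def test_conservation_identity_on_simulation(self, small_run):
        """Sum of scaffold lengths minus gaps equals sum of contig
        lengths, for both haplotypes."""
        cfg, truth, graph, gt, sim, phased, scaf = small_run
        for h, key in ((1, 0), (2, 1)):
            total_scaffold = sum(len(s) for n, s in scaf.seqs.items()
                                 if n.endswith(f"_h{h}"))
            n_joins = sum(len(p.order or p.contigs) - 1
                          for p in scaf.scaffolds.partitions)
            total_contig = sum(len(p.hap1_seq if h == 1 else p.hap2_seq)
                               for p in phased.pairs)
            assert total_scaffold - 100 * n_joins == total_contig

    def test_ng50_of_scaffolds_not_below_contigs(self, small_run):
        cfg, truth, graph, gt, sim, phased, scaf = small_run
        G = sum(len(s) for s in truth.hap1.values())
        contig_ng = ng50([p.length for p in phased.pairs], G)
        scaf_ng = ng50([len(s) for n, s in scaf.seqs.items()
                        if n.endswith("_h1")], G)
        assert scaf_ng >= contig_ng

    def test_fixed_seed_byte_identical_output(self, small_sim):
        from hicphase.pipeline import RunConfig, run_all
        cfg, truth, graph, gt, sim = small_sim
        rc = RunConfig(k=cfg.k, long_threshold=40_000)
        _, s1 = run_all(graph, (sim.seq1, sim.seq2), rc)
        _, s2 = run_all(graph, (sim.seq1, sim.seq2), rc)
        assert s1.seqs == s2.seqs
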