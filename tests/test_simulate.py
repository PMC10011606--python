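"""Simulator: truth invariants, graph topology, Hi-C contact model."""

import numpy as np
import pytest
from scipy import stats

from hicphase.bubbles import find_bubbles
from hicphase.simulate import (SimConfig, apply_variants, build_truth_graph,
                               simulate_diploid, simulate_hic)

BASE = dict(n_chromosomes=1, chrom_length=80_000, snp_rate=0.0005,
            n_insertions=1, n_deletions=1, n_inversions=1,
            node_split=15_000, n_breaks=0, k=21)


class TestDiploid:
    def test_no_variants_identical_haplotypes(self):
        cfg = SimConfig(seed=1, **{**BASE, "snp_rate": 0.0, "n_insertions": 0,
                                   "n_deletions": 0, "n_inversions": 0})
        truth = simulate_diploid(cfg)
        assert truth.hap1 == truth.hap2
        assert truth.variants.empty

    def test_variant_table_recreates_hap2(self):
        cfg = SimConfig(seed=2, **BASE)
        truth = simulate_diploid(cfg)
        for chrom in truth.hap1:
            vs = truth.variants[truth.variants.chrom == chrom]
            assert apply_variants(truth.hap1[chrom], vs) == truth.hap2[chrom]

    def test_exact_snp_count_and_types(self):
        cfg = SimConfig(seed=3, **BASE)
        truth = simulate_diploid(cfg)
        counts = truth.variants.type.value_counts().to_dict()
        assert counts["snp"] == round(cfg.snp_rate * cfg.chrom_length)
        assert counts["ins"] == 1 and counts["del"] == 1 \
            and counts["inv"] == 1

    def test_snp_positions_differ_exactly(self):
        cfg = SimConfig(seed=4, **{**BASE, "n_insertions": 0,
                                   "n_deletions": 0, "n_inversions": 0})
        truth = simulate_diploid(cfg)
        h1, h2 = truth.hap1["chr1"], truth.hap2["chr1"]
        assert len(h1) == len(h2)
        diff = [i for i, (a, b) in enumerate(zip(h1, h2)) if a != b]
        assert diff == sorted(truth.variants.pos)

    def test_same_seed_identical_truth(self):
        cfg = SimConfig(seed=5, **BASE)
        t1 = simulate_diploid(cfg)
        t2 = simulate_diploid(SimConfig(seed=5, **BASE))
        assert t1.hap1 == t2.hap1 and t1.hap2 == t2.hap2
        assert t1.variants.equals(t2.variants)

    def test_overdense_variants_rejected(self):
        cfg = SimConfig(seed=6, **{**BASE, "chrom_length": 2_000,
                                   "snp_rate": 0.5})
        with pytest.raises(ValueError, match="rate too high"):
            simulate_diploid(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, trans_noise=1.5, **BASE).validate()


class TestTruthGraph:
    def test_single_snp_minimal_bubble(self):
        cfg = SimConfig(seed=7, n_chromosomes=1, chrom_length=30_000,
                        snp_rate=0.0, n_insertions=0, n_deletions=0,
                        n_inversions=0, node_split=100_000, n_breaks=0, k=21)
        truth = simulate_diploid(cfg)
        # plant one SNP manually through the variant channel
        import pandas as pd
        pos = 15_000
        ref = truth.hap1["chr1"]
        alt = "A" if ref[pos] != "A" else "C"
        truth.variants = pd.DataFrame(
            [{"chrom": "chr1", "pos": pos, "type": "snp",
              "ref": ref[pos], "alt": alt}])
        truth.hap2["chr1"] = apply_variants(ref, truth.variants)
        graph, gt = build_truth_graph(truth, cfg)
        homo = [n for n in graph.nodes if "_s" in n]
        alleles = [n for n in graph.nodes if "_v" in n]
        assert len(homo) == 2 and len(alleles) == 2
        assert len(graph.edges) == 4
        assert len(find_bubbles(graph)) == 1

    def test_no_variants_single_linear_component(self):
        cfg = SimConfig(seed=8, **{**BASE, "snp_rate": 0.0, "n_insertions": 0,
                                   "n_deletions": 0, "n_inversions": 0})
        truth = simulate_diploid(cfg)
        graph, gt = build_truth_graph(truth, cfg)
        assert len(set(graph.component_id.values())) == 1
        assert find_bubbles(graph) == []

    def test_detected_bubbles_equal_truth_bubbles(self):
        """find_bubbles on the generated graph recovers exactly the truth
        allele-node pairs."""
        cfg = SimConfig(seed=9, **BASE)
        truth = simulate_diploid(cfg)
        graph, gt = build_truth_graph(truth, cfg)
        bubbles = find_bubbles(graph)
        got = sorted(frozenset(n for p in b.alleles for n, _ in p)
                     for b in bubbles)
        expected = sorted(frozenset((a, b))
                          for _, a, b in gt.bubble_nodes)
        assert got == expected

    def test_breaks_create_components(self):
        cfg = SimConfig(seed=10, **{**BASE, "n_breaks": 3})
        truth = simulate_diploid(cfg)
        graph, gt = build_truth_graph(truth, cfg)
        assert len(set(graph.component_id.values())) == 4
        assert sum(len(v) for v in gt.chrom_contigs.values()) == 4

    def test_variant_spacing_supports_disjoint_bubbles(self):
        cfg = SimConfig(seed=11, **BASE)
        truth = simulate_diploid(cfg)
        vs = truth.variants
        gaps = (vs.pos.values[1:]
                - (vs.pos.values[:-1]
                   + vs.ref.str.len().values[:-1]))
        assert (gaps >= 2 * cfg.k).all()


class TestHic:
    def test_pair_count_formula(self):
        cfg = SimConfig(seed=12, n_chromosomes=1, chrom_length=1_000_000,
                        snp_rate=0.0001, n_insertions=0, n_deletions=0,
                        n_inversions=0, depth=30.0, read_length=150,
                        node_split=100_000, n_breaks=0, k=21)
        truth = simulate_diploid(cfg)
        sim = simulate_hic(truth, cfg)
        assert sim.n_pairs() == 100_000  # 30 * 1e6 / (2 * 150)

    def test_noise_free_pairs_share_haplotype(self):
        cfg = SimConfig(seed=13, **BASE)
        truth = simulate_diploid(cfg)
        sim = simulate_hic(truth, cfg)
        assert (sim.truth.hap1_copy == sim.truth.hap2_copy).all()

    def test_trans_noise_fraction(self):
        cfg = SimConfig(seed=14, **{**BASE, "trans_noise": 0.2})
        truth = simulate_diploid(cfg)
        sim = simulate_hic(truth, cfg)
        frac = float((sim.truth.hap1_copy != sim.truth.hap2_copy).mean())
        assert frac == pytest.approx(0.2, abs=0.03)

    def test_reads_match_their_source_positions(self):
        cfg = SimConfig(seed=15, **BASE)
        truth = simulate_diploid(cfg)
        sim = simulate_hic(truth, cfg)
        from hicphase._kmers import revcomp
        rows = sim.truth.head(50)
        for i, row in rows.iterrows():
            src1 = (truth.hap1 if row.hap1_copy == 0 else truth.hap2)[row.chrom]
            src2 = (truth.hap1 if row.hap2_copy == 0 else truth.hap2)[row.chrom]
            assert sim.seq1[i] == src1[row.pos1:row.pos1 + cfg.read_length]
            assert sim.seq2[i] == revcomp(
                src2[row.pos2:row.pos2 + cfg.read_length])

    def test_distance_distribution_matches_inverse_power_law(self):
        """Empirical contact distances follow the truncated d^-1 density,
        corrected for chromosome-boundary rejection, by a KS test."""
        cfg = SimConfig(seed=16, n_chromosomes=1, chrom_length=2_000_000,
                        snp_rate=0.0, n_insertions=0, n_deletions=0,
                        n_inversions=0, depth=15.0, node_split=1_000_000,
                        n_breaks=0, k=21)
        truth = simulate_diploid(cfg)
        sim = simulate_hic(truth, cfg)
        d = np.abs(sim.truth.pos2.values - sim.truth.pos1.values).astype(float)
        # chromosome-boundary rejection thins large distances by the
        # fraction of valid start positions: density ~ d^-1 * (L' - d)
        dmin = float(cfg.min_distance)
        L = float(cfg.chrom_length - cfg.read_length)

        def cdf(x):
            num = L * np.log(x / dmin) - (x - dmin)
            den = L * np.log(L / dmin) - (L - dmin)
            return num / den

        stat, pval = stats.kstest(d, cdf)
        assert pval > 1e-3, f"KS stat {stat:.4f}"

    def test_same_seed_identical_reads(self):
        cfg = SimConfig(seed=17, **BASE)
        truth = simulate_diploid(cfg)
        s1 = simulate_hic(truth, cfg)
        s2 = simulate_hic(truth, cfg)
        assert s1.seq1 == s2.seq1 and s1.seq2 == s2.seq2


class TestNoiseMonotonicity:
    def test_trans_noise_never_improves_hamming(self):
        """Raising the cross-haplotype noise fraction never improves the
        median truth hamming rate over seeds."""
        from hicphase import pipeline as pl
        from hicphase.simulate import (truth_bubble_labels,
                                       truth_switch_hamming)

        def median_hamming(noise):
            rates = []
            for seed in (21, 22, 23):
                cfg = SimConfig(seed=seed, n_chromosomes=1,
                                chrom_length=150_000, snp_rate=0.001,
                                n_insertions=1, n_deletions=1,
                                n_inversions=0, depth=30,
                                node_split=25_000, n_breaks=2, k=21,
                                trans_noise=noise)
                truth = simulate_diploid(cfg)
                graph, gt = build_truth_graph(truth, cfg)
                sim = simulate_hic(truth, cfg)
                phased, scaf = pl.run_all(
                    graph, (sim.seq1, sim.seq2),
                    pl.RunConfig(k=21, long_threshold=60_000))
                labels = truth_bubble_labels(phased.pairs, phased.bubbles,
                                             gt)
                _, hmr, _ = truth_switch_hamming(scaf.scaffolds, labels)
                rates.append(hmr)
            return float(np.median(rates))

        h = [median_hamming(n) for n in (0.0, 0.25, 0.45)]
        assert h == sorted(h), f"medians not monotone: {h}"
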