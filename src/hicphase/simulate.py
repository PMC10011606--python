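"""Synthetic diploid genomes, their bubble-bearing sequence graphs, and
Hi-C read pairs with truth labels.

The generator stands in for the upstream HiFi assembly and the Hi-C
library: it draws a random reference per chromosome, plants heterozygous
SNPs and structural variants (insertions, deletions, inversions of
50 bp - 10 kb) on the second haplotype, builds the corresponding sequence
graph -- shared nodes for homozygous stretches, two-branch bubbles at
every variant -- and samples Hi-C read pairs whose two ends come from the
same haplotype copy with a heavy-tailed genomic-distance distribution
(density proportional to d^-alpha, the standard Hi-C contact decay with
alpha = 1 by default).  Every random choice is driven by the mandatory
seed; the truth channel records haplotype sequences, the variant table,
per-bubble phase labels, and the chromosomal order of graph components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._kmers import revcomp
from .graph_io import FWD, SequenceGraph
from .scaffold import ScaffoldSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic diploid experiment.

    Defaults describe a 5 Mb, two-chromosome genome with a 0.1% het SNP
    rate and 20 structural variants, read at 30x with 150 bp noise-free
    Hi-C pairs -- a desk-scale analogue of a human phasing benchmark.
    """

    seed: int
    n_chromosomes: int = 2
    chrom_length: int = 2_500_000
    snp_rate: float = 0.001          # het SNPs per bp
    n_insertions: int = 7
    n_deletions: int = 7
    n_inversions: int = 6
    sv_min: int = 50                 # SV size floor, bp
    sv_max: int = 10_000
    depth: float = 30.0              # Hi-C fold coverage
    read_length: int = 150
    alpha: float = 1.0               # contact-distance decay exponent
    min_distance: int = 1_000        # contact distance truncation, bp
    trans_noise: float = 0.0         # fraction of cross-haplotype pairs
    error_rate: float = 0.0          # per-base substitution rate in reads
    node_split: int = 50_000         # homozygous node split length, bp
    n_breaks: int = 3                # components created per chromosome
    k: int = 31                      # flank size for allele branches
    bubble_span: int = 4_000         # variants closer than this share a bubble

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("snp_rate", "trans_noise", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chromosomes", "chrom_length", "read_length",
                     "node_split", "sv_min", "sv_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sv_min > self.sv_max:
            raise ValueError("sv_min > sv_max")


@dataclass
class Truth:
    """Ground truth channel of one simulated diploid genome."""

    hap1: Dict[str, str]
    hap2: Dict[str, str]
    variants: pd.DataFrame   # chrom, pos, type, ref, alt (0-based, on hap1)
    cfg: SimConfig


@dataclass
class GraphTruth:
    """Truth facts about the generated sequence graph."""

    node_hap: Dict[str, int]                     # allele node -> 0 (hap1) / 1
    node_nvars: Dict[str, int]                   # allele node -> #variants inside
    bubble_nodes: List[Tuple[str, str, str]]     # (chrom, hap1 node, hap2 node)
    chrom_contigs: Dict[str, List[frozenset]]    # node sets in chromosome order


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def simulate_diploid(cfg: SimConfig) -> Truth:
    """Draw the reference and plant het variants on the second haplotype.

    Variant starts keep at least 2k bp of homozygous sequence between
    consecutive variant extents so every variant forms its own disjoint
    bubble in the graph; a configuration too dense to honour that spacing
    is rejected.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed % (2 ** 31), 0])
    hap1: Dict[str, str] = {}
    hap2: Dict[str, str] = {}
    rows = []
    gap = 2 * cfg.k
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = cfg.chrom_length
        ref = _random_seq(rng, L)
        n_snp = int(round(cfg.snp_rate * L))
        types = (["snp"] * n_snp + ["ins"] * cfg.n_insertions
                 + ["del"] * cfg.n_deletions + ["inv"] * cfg.n_inversions)
        rng.shuffle(types)
        extents = np.array([1 if t == "snp" else 0 if t == "ins"
                            else int(rng.integers(cfg.sv_min, cfg.sv_max + 1))
                            for t in types], np.int64)
        n = len(types)
        min_span = int(extents.sum()) + (n + 1) * gap
        slack = L - min_span
        if slack <= 0:
            raise ValueError(
                f"variant rate too high for {L} bp chromosome with >= "
                f"{gap} bp spacing (need {min_span} bp)")
        offsets = np.sort(rng.integers(0, slack, n))
        positions = offsets + gap + np.concatenate(
            [[0], np.cumsum(extents[:-1] + gap)])

        pieces = []
        cursor = 0
        for t, pos, ext in zip(types, positions, extents):
            pos = int(pos)
            ext = int(ext)
            seg = ref[pos:pos + ext]
            if t == "snp":
                alt = "ACGT"[(("ACGT".index(seg)) + int(rng.integers(1, 4))) % 4]
            elif t == "ins":
                alt = _random_seq(rng, int(rng.integers(cfg.sv_min,
                                                        cfg.sv_max + 1)))
            elif t == "del":
                alt = ""
            else:
                alt = revcomp(seg)
            rows.append({"chrom": chrom, "pos": pos, "type": t,
                         "ref": seg, "alt": alt})
            pieces.append(ref[cursor:pos])
            pieces.append(alt)
            cursor = pos + ext
        pieces.append(ref[cursor:])
        hap1[chrom] = ref
        hap2[chrom] = "".join(pieces)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "type", "ref", "alt"])
    variants = variants.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return Truth(hap1=hap1, hap2=hap2, variants=variants, cfg=cfg)


def apply_variants(ref: str, variants: pd.DataFrame) -> str:
    """Re-apply a chromosome's variant table to hap1 (truth invariant)."""
    pieces = []
    cursor = 0
    for _, v in variants.sort_values("pos").iterrows():
        pieces.append(ref[cursor:v.pos])
        pieces.append(v.alt)
        cursor = v.pos + len(v.ref)
    pieces.append(ref[cursor:])
    return "".join(pieces)


def build_truth_graph(truth: Truth,
                      cfg: Optional[SimConfig] = None
                      ) -> Tuple[SequenceGraph, GraphTruth]:
    """Build the bubble-bearing sequence graph the assembler would emit.

    Variants whose gaps are below ``bubble_span`` merge into one
    haplotype-block bubble: a two-branch site whose allele nodes carry
    each haplotype's sequence over the block plus k-1 bp of shared flank,
    the way a HiFi assembler's unitig branches span whole haplotype
    blocks rather than single variants.  An isolated variant yields the
    minimal bubble (two homozygous neighbours, two allele nodes).
    Which truth haplotype receives the lexicographically smaller allele
    node name is randomized per bubble, so downstream evaluations cannot
    lean on naming conventions.

    Homozygous stretches between blocks become shared nodes (split at
    ``node_split``).  Per chromosome, ``n_breaks`` homozygous stretches
    (drawn among the longer ones) are cut in half with the joining edge
    omitted, so the graph falls apart into ``n_breaks + 1`` components
    and exercises the scaffolder.
    """
    cfg = cfg or truth.cfg
    rng = np.random.default_rng([cfg.seed % (2 ** 31), 1])
    f = cfg.k - 1
    graph = SequenceGraph()
    gt = GraphTruth(node_hap={}, node_nvars={}, bubble_nodes=[],
                    chrom_contigs={})

    for chrom in sorted(truth.hap1):
        ref = truth.hap1[chrom]
        vs = truth.variants[truth.variants.chrom == chrom]

        # cluster variants into haplotype blocks by gap
        clusters: List[List[Tuple[int, int, str]]] = []  # (pos, ext, alt)
        for _, v in vs.iterrows():
            pos, ext = int(v.pos), len(v.ref)
            if (clusters and pos - (clusters[-1][-1][0] + clusters[-1][-1][1])
                    <= cfg.bubble_span):
                clusters[-1].append((pos, ext, v.alt))
            else:
                clusters.append([(pos, ext, v.alt)])

        # first pass: homozygous segments and allele branches along hap1
        items: List[Tuple[str, object]] = []  # ("homo", seq) / ("bub", ...)
        cursor = 0
        for bi, cl in enumerate(clusters):
            start = cl[0][0] - f
            end = cl[-1][0] + cl[-1][1] + f
            if start > cursor:
                items.append(("homo", ref[cursor:start]))
            hap1_seq = ref[start:end]
            pieces = []
            cur = start
            for pos, ext, alt in cl:
                pieces.append(ref[cur:pos])
                pieces.append(alt)
                cur = pos + ext
            pieces.append(ref[cur:end])
            hap2_seq = "".join(pieces)
            items.append(("bub", (bi, hap1_seq, hap2_seq, len(cl))))
            cursor = end
        if cursor < len(ref):
            items.append(("homo", ref[cursor:]))

        # choose homozygous segments to cut: long enough to anchor reads
        # on both sides, and spread out so no degenerate mini-contig forms
        homo_idx = [i for i, (kind, _) in enumerate(items) if kind == "homo"]
        breakable = [i for i in homo_idx
                     if len(items[i][1]) >= max(4 * cfg.k, 2 * cfg.read_length)]
        if not breakable:
            breakable = [i for i in homo_idx if len(items[i][1]) >= 2]
        break_at: set = set()
        if breakable and cfg.n_breaks > 0:
            min_sep = max(1, len(items) // (2 * (cfg.n_breaks + 1)))
            for i in rng.permutation(np.array(breakable)).tolist():
                # keep cuts apart from each other and from chromosome ends,
                # so every component stays large enough to carry Hi-C signal
                if (i >= min_sep and i <= len(items) - 1 - min_sep
                        and all(abs(i - j) >= min_sep for j in break_at)):
                    break_at.add(i)
                    if len(break_at) >= cfg.n_breaks:
                        break

        # second pass: materialize nodes/edges; an ended contig starts anew
        n_homo = 0
        contigs: List[List[str]] = [[]]
        tails: List[str] = []  # open right ends of the previous item

        def add_homo_piece(seq: str) -> None:
            nonlocal n_homo, tails
            n_parts = max(1, -(-len(seq) // cfg.node_split))
            step = -(-len(seq) // n_parts)
            for i in range(0, len(seq), step):
                name = f"{chrom}_s{n_homo:05d}"
                n_homo += 1
                graph.add_node(name, seq[i:i + step])
                for t in tails:
                    graph.add_edge(t, FWD, name, FWD, 0)
                tails = [name]
                contigs[-1].append(name)

        for idx, (kind, payload) in enumerate(items):
            if kind == "homo":
                seq = payload
                if idx in break_at:
                    half = len(seq) // 2
                    add_homo_piece(seq[:half])
                    tails = []
                    contigs.append([])
                    add_homo_piece(seq[half:])
                else:
                    add_homo_piece(seq)
            else:
                bi, hap1_seq, hap2_seq, n_vars = payload
                a_name = f"{chrom}_v{bi:04d}a"
                b_name = f"{chrom}_v{bi:04d}b"
                if rng.random() < 0.5:  # naming carries no haplotype signal
                    hap1_node, hap2_node = a_name, b_name
                else:
                    hap1_node, hap2_node = b_name, a_name
                graph.add_node(hap1_node, hap1_seq)
                graph.add_node(hap2_node, hap2_seq)
                gt.node_hap[hap1_node] = 0
                gt.node_hap[hap2_node] = 1
                gt.node_nvars[hap1_node] = gt.node_nvars[hap2_node] = n_vars
                gt.bubble_nodes.append((chrom, hap1_node, hap2_node))
                for t in tails:
                    graph.add_edge(t, FWD, a_name, FWD, 0)
                    graph.add_edge(t, FWD, b_name, FWD, 0)
                tails = [a_name, b_name]
                contigs[-1].extend([a_name, b_name])
        gt.chrom_contigs[chrom] = [frozenset(c) for c in contigs if c]
    graph.label_components()
    return graph, gt


# ---------------------------------------------------------------------------
# Hi-C read simulation


@dataclass
class HicSim:
    """Simulated Hi-C pairs plus their truth labels."""

    seq1: List[str]
    seq2: List[str]
    truth: pd.DataFrame  # chrom, hap1_copy, hap2_copy, pos1, pos2

    def n_pairs(self) -> int:
        return len(self.seq1)


def _sample_distances(rng: np.random.Generator, n: int, dmin: float,
                      dmax: float, alpha: float) -> np.ndarray:
    """Inverse-CDF samples from density ~ d^-alpha on [dmin, dmax]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        d = dmin * (dmax / dmin) ** u
    else:
        a, b = dmin ** (1.0 - alpha), dmax ** (1.0 - alpha)
        d = (a + u * (b - a)) ** (1.0 / (1.0 - alpha))
    return d.astype(np.int64)


def simulate_hic(truth: Truth, cfg: Optional[SimConfig] = None) -> HicSim:
    """Sample depth x G / (2 x read length) intra-chromosomal read pairs.

    Both ends of a pair come from the same haplotype copy (probability
    1 - trans_noise) at a genomic distance drawn from the truncated
    d^-alpha contact decay; the second end is reverse-complemented as in
    real Hi-C libraries.  Cross-haplotype noise pairs place their second
    end uniformly on the homologous chromosome copy.
    """
    cfg = cfg or truth.cfg
    cfg.validate()
    rng = np.random.default_rng([cfg.seed % (2 ** 31), 2])
    rl = cfg.read_length
    chroms = sorted(truth.hap1)
    G = sum(len(truth.hap1[c]) for c in chroms)
    n_pairs = int(round(cfg.depth * G / (2.0 * rl)))

    lens = {(c, h): len((truth.hap1 if h == 0 else truth.hap2)[c])
            for c in chroms for h in (0, 1)}
    probs = np.array([len(truth.hap1[c]) for c in chroms], float)
    probs /= probs.sum()
    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=probs)
    hap1_copy = rng.integers(0, 2, n_pairs)
    trans = rng.random(n_pairs) < cfg.trans_noise
    hap2_copy = np.where(trans, 1 - hap1_copy, hap1_copy)

    pos1 = np.empty(n_pairs, np.int64)
    pos2 = np.empty(n_pairs, np.int64)
    for ci, chrom in enumerate(chroms):
        for h in (0, 1):
            sel = np.nonzero((chrom_idx == ci) & (hap1_copy == h))[0]
            if sel.size == 0:
                continue
            L1 = lens[(chrom, h)]
            dmax = max(L1 - rl, cfg.min_distance + 1)
            todo = sel
            while todo.size:
                p1 = rng.integers(0, max(L1 - rl, 1), todo.size)
                d = _sample_distances(rng, todo.size, cfg.min_distance,
                                      dmax, cfg.alpha)
                sign = np.where(rng.random(todo.size) < 0.5, 1, -1)
                p2 = p1 + sign * d
                ok = (p2 >= 0) & (p2 <= L1 - rl)
                pos1[todo[ok]] = p1[ok]
                pos2[todo[ok]] = p2[ok]
                todo = todo[~ok]
            # cross-haplotype ends: re-place uniformly on the other copy
            tsel = np.nonzero((chrom_idx == ci) & (hap1_copy == h)
                              & trans)[0]
            if tsel.size:
                L2 = lens[(chrom, 1 - h)]
                pos2[tsel] = rng.integers(0, max(L2 - rl, 1), tsel.size)

    seq1: List[str] = []
    seq2: List[str] = []
    for i in range(n_pairs):
        chrom = chroms[chrom_idx[i]]
        s1 = (truth.hap1 if hap1_copy[i] == 0 else truth.hap2)[chrom]
        s2 = (truth.hap1 if hap2_copy[i] == 0 else truth.hap2)[chrom]
        seq1.append(s1[pos1[i]:pos1[i] + rl])
        seq2.append(revcomp(s2[pos2[i]:pos2[i] + rl]))

    if cfg.error_rate > 0:
        seq1 = _add_errors(rng, seq1, cfg.error_rate)
        seq2 = _add_errors(rng, seq2, cfg.error_rate)

    tdf = pd.DataFrame({"chrom": [chroms[i] for i in chrom_idx],
                        "hap1_copy": hap1_copy, "hap2_copy": hap2_copy,
                        "pos1": pos1, "pos2": pos2})
    return HicSim(seq1=seq1, seq2=seq2, truth=tdf)


def _add_errors(rng: np.random.Generator, seqs: List[str],
                rate: float) -> List[str]:
    out = []
    for s in seqs:
        arr = np.frombuffer(s.encode(), np.uint8).copy()
        hit = np.nonzero(rng.random(arr.size) < rate)[0]
        if hit.size:
            arr[hit] = _BASES[(np.searchsorted(_BASES, 0) +
                               rng.integers(0, 4, hit.size))]
        out.append(arr.tobytes().decode())
    return out


def write_hic_fastq(sim: HicSim, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, (s1, s2) in enumerate(zip(sim.seq1, sim.seq2)):
            f1.write(f"@pair{i}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@pair{i}/2\n{s2}\n+\n{'I' * len(s2)}\n")


# ---------------------------------------------------------------------------
# Truth-based metrics (for validating the pipeline on simulations)


def truth_bubble_labels(pairs, bubbles, gt: GraphTruth) -> Dict[int, List[int]]:
    """Per contig: truth haplotype labels along its het sites.

    Each phased bubble contributes one label (0 when the contig's hap1
    path took the truth-hap1 branch) repeated once per variant the
    branch carries, so downstream rates are per heterozygous site.
    Bubbles unknown to the truth channel (complex, demoted) are skipped.
    """
    allele_nodes = {}
    for b in bubbles:
        for ai, path in enumerate(b.alleles):
            if len(path) == 1:
                allele_nodes[(b.bubble_id, ai)] = path[0][0]
    out: Dict[int, List[int]] = {}
    for p in pairs:
        labels = []
        for bid in p.bubble_order:
            for ai in range(4):
                if p.allele_hap.get((bid, ai)) == 0:
                    node = allele_nodes.get((bid, ai))
                    if node is not None and node in gt.node_hap:
                        labels.extend([gt.node_hap[node]]
                                      * gt.node_nvars.get(node, 1))
                    break
        out[p.component_id] = labels
    return out


def truth_switch_hamming(ss: ScaffoldSet, contig_labels: Dict[int, List[int]]
                         ) -> Tuple[float, float, int]:
    """Truth switch/hamming rates of a scaffold set.

    Concatenates per-contig bubble labels in scaffold order (respecting
    orientation and the member's haplotype parity), counts adjacent label
    flips as switches and minority labels as hamming errors.
    """
    tot_sites = tot_sw = tot_ham = 0
    for part in ss.partitions:
        rel = dict(part.members)
        ordered = part.order or [(c, "+") for c in part.contigs]
        labels: List[int] = []
        for c, orient in ordered:
            ls = [l ^ rel[c] for l in contig_labels.get(c, [])]
            if orient == "-":
                ls = ls[::-1]
            labels.extend(ls)
        if not labels:
            continue
        arr = np.array(labels)
        tot_sites += arr.size
        tot_sw += int(np.sum(arr[1:] != arr[:-1]))
        tot_ham += int(min(arr.sum(), arr.size - arr.sum()))
    if tot_sites == 0:
        return 0.0, 0.0, 0
    return tot_sw / tot_sites, tot_ham / tot_sites, tot_sites


def truth_order_recovered(ss: ScaffoldSet, gt: GraphTruth,
                          graph: SequenceGraph) -> bool:
    """Did scaffolding recover each chromosome's contig order/orientation?

    A chromosome counts as recovered when one partition contains exactly
    its contigs, ordered as in truth (forward or reversed), with
    consistent orientations.
    """
    contig_of = {}
    for node, comp in graph.component_id.items():
        contig_of[node] = comp
    truth_orders = []
    for chrom in sorted(gt.chrom_contigs):
        order = []
        for nodes in gt.chrom_contigs[chrom]:
            comps = {contig_of[n] for n in nodes}
            if len(comps) != 1:
                return False
            order.append(comps.pop())
        truth_orders.append(order)
    if len(ss.partitions) != len(truth_orders):
        return False
    for order in truth_orders:
        hit = None
        for part in ss.partitions:
            if sorted(part.contigs) == sorted(order):
                hit = part
                break
        if hit is None:
            return False
        ordered = hit.order or [(c, "+") for c in hit.contigs]
        seq = [c for c, _ in ordered]
        ors = [o for _, o in ordered]
        if seq == order and all(o == "+" for o in ors):
            continue
        if seq == order[::-1] and all(o == "-" for o in ors):
            continue
        if len(order) == 1:
            continue
        return False
    return True
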