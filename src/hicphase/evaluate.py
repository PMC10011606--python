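"""Reference-free phasing evaluation and assembly statistics.

Switch and hamming error rates are estimated directly from Hi-C reads,
with no truth assembly: heterozygous k-mers (31-mers present in exactly
one haplotype of a phased assembly pair) are collapsed into heterozygous
sites, Hi-C read pairs are mapped to those k-mers by exact canonical
match, and every consecutive site pair is tallied for same-haplotype
versus cross-haplotype support.  A junction with cross support strictly
above the threshold (default >5 read pairs) and exceeding its same
support is a haplotype switch.  The switch error rate is the number of
switches divided by the number of heterozygous sites; the hamming error
rate propagates the switch flips along each scaffold and counts the
sites assigned to the wrong haplotype (minimized over the two global
labellings, since haplotype naming is arbitrary) -- long switches are
thereby penalized in proportion to their extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import _kmers
from .graph_io import ReadPair

DEFAULT_K = 31


@dataclass
class HetSite:
    """A maximal run of overlapping het k-mers, paired across haplotypes."""

    pos1: int
    pos2: int
    codes1: np.ndarray
    codes2: np.ndarray


def _unique_runs(codes: np.ndarray, valid: np.ndarray, het: np.ndarray,
                 k: int) -> List[Tuple[int, np.ndarray]]:
    """Group het window positions into maximal overlapping runs."""
    pos = np.nonzero(valid)[0]
    hp = pos[het]
    if hp.size == 0:
        return []
    splits = np.nonzero(np.diff(hp) > k - 1)[0] + 1
    return [(int(g[0]), codes[g]) for g in np.split(hp, splits)]


def find_het_sites(hap1: str, hap2: str, k: int = DEFAULT_K) -> List[HetSite]:
    """Het k-mer sites of one scaffold pair, ordered along hap1.

    A k-mer is heterozygous when its canonical form occurs exactly once
    across the two haplotypes together.  A single variant produces up to
    k overlapping het k-mers; they collapse into one site.  Sites are
    paired across haplotypes by co-linear order.
    """
    _kmers.check_k(k)
    b1, b2 = _kmers.encode(hap1), _kmers.encode(hap2)
    c1, v1 = _kmers.canonical_codes(b1, k)
    c2, v2 = _kmers.canonical_codes(b2, k)
    a1, a2 = c1[v1], c2[v2]
    allc = np.concatenate([a1, a2])
    uniq, counts = np.unique(allc, return_counts=True)
    singletons = uniq[counts == 1]
    het1 = np.isin(a1, singletons)
    het2 = np.isin(a2, singletons)
    runs1 = _unique_runs(c1, v1, het1, k)
    runs2 = _unique_runs(c2, v2, het2, k)
    n = min(len(runs1), len(runs2))
    return [HetSite(runs1[i][0], runs2[i][0], runs1[i][1], runs2[i][1])
            for i in range(n)]


def find_het_kmers(hap1: str, hap2: str, k: int = DEFAULT_K
                   ) -> List[Tuple[int, str, str]]:
    """(position-on-hap1, het k-mer of hap1, het k-mer of hap2) per site.

    The reported k-mers are the canonical representatives of each site's
    first window.
    """
    return [(s.pos1, _kmers.decode_code(int(s.codes1[0]), k),
             _kmers.decode_code(int(s.codes2[0]), k))
            for s in find_het_sites(hap1, hap2, k)]


@dataclass
class PhasingReport:
    """Switch/hamming summary; rates are fractions (None = not evaluable)."""

    n_sites: int
    n_switches: int
    n_hamming: int
    switch_rate: Optional[float]
    hamming_rate: Optional[float]
    evaluable: bool
    n_informative_pairs: int
    per_scaffold: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("scaffold\tn_het_sites\tn_switches\thamming_sites\t"
                     "switch_rate_pct\thamming_rate_pct\n")
            for _, row in self.per_scaffold.iterrows():
                fh.write(f"{row['scaffold']}\t{row['n_sites']}\t"
                         f"{row['n_switches']}\t{row['n_hamming']}\t"
                         f"{_pct(row['switch_rate'])}\t"
                         f"{_pct(row['hamming_rate'])}\n")
            fh.write(f"TOTAL\t{self.n_sites}\t{self.n_switches}\t"
                     f"{self.n_hamming}\t{_pct(self.switch_rate)}\t"
                     f"{_pct(self.hamming_rate)}\n")


def _pct(x: Optional[float]) -> str:
    return "NA" if x is None else f"{100.0 * x:.4f}"


PairInput = Union[Iterable[ReadPair], Tuple[Sequence[str], Sequence[str]]]


def _pair_seqs(pairs: PairInput) -> Tuple[Sequence[str], Sequence[str]]:
    if isinstance(pairs, tuple) and len(pairs) == 2:
        return pairs
    s1, s2 = [], []
    for p in pairs:
        s1.append(p.seq1)
        s2.append(p.seq2)
    return s1, s2


def phasing_error(hap1: Union[str, Dict[str, str]],
                  hap2: Union[str, Dict[str, str]],
                  pairs: PairInput, k: int = DEFAULT_K,
                  min_support: int = 5) -> PhasingReport:
    """Hi-C based switch/hamming evaluation of a phased assembly pair.

    ``hap1`` and ``hap2`` are either single scaffold sequences or
    name-matched dicts of scaffolds (the two FASTA files of a phased
    assembly).  Read ends mapping to het k-mers of more than one site,
    haplotype, or scaffold are discarded.
    """
    if isinstance(hap1, str):
        hap1, hap2 = {"seq": hap1}, {"seq": hap2}
    names = sorted(hap1)
    if sorted(hap2) != names:
        raise ValueError("hap1 and hap2 scaffold names do not match")

    sites_by_scaf = {name: find_het_sites(hap1[name], hap2[name], k)
                     for name in names}

    # global table: code -> (scaffold, site, haplotype); k-mers colliding
    # across scaffolds are not usable barcodes and are dropped
    codes, meta = [], []
    for si, name in enumerate(names):
        for ti, site in enumerate(sites_by_scaf[name]):
            for hap, cs in ((0, site.codes1), (1, site.codes2)):
                codes.append(cs)
                meta.append(np.tile([si, ti, hap], (len(cs), 1)))
    if codes:
        codes = np.concatenate(codes)
        meta = np.concatenate(meta)
        uniq, first, counts = np.unique(codes, return_index=True,
                                        return_counts=True)
        keep = counts == 1
        table_codes = uniq[keep]
        table_meta = meta[first[keep]]
    else:
        table_codes = np.empty(0, np.uint64)
        table_meta = np.empty((0, 3), np.int64)

    def end_sites(seqs, chunk: int = 100_000) -> np.ndarray:
        """(scaffold, site, hap) or -1 row for each end."""
        if len(seqs) > chunk:
            return np.concatenate([end_sites(seqs[i:i + chunk])
                                   for i in range(0, len(seqs), chunk)])
        out = np.full((len(seqs), 3), -1, np.int64)
        if len(seqs) == 0 or table_codes.size == 0:
            return out
        cc, owner, _ = _kmers.batch_canonical(seqs, k)
        idx = np.searchsorted(table_codes, cc)
        idx_c = np.minimum(idx, table_codes.size - 1)
        hit = table_codes[idx_c] == cc
        owner, idx_c = owner[hit], idx_c[hit]
        rows = table_meta[idx_c]
        # consistency: all hits of a read must agree on one (scaf, site, hap)
        flat = (rows[:, 0] * (2 ** 40) + rows[:, 1] * 4 + rows[:, 2])
        lo = np.full(len(seqs), np.iinfo(np.int64).max, np.int64)
        hi = np.full(len(seqs), -1, np.int64)
        np.minimum.at(lo, owner, flat)
        np.maximum.at(hi, owner, flat)
        ok = (hi >= 0) & (lo == hi)
        out[ok, 2] = hi[ok] & 3
        out[ok, 1] = (hi[ok] >> 2) & (2 ** 38 - 1)
        out[ok, 0] = hi[ok] >> 40
        return out

    s1, s2 = _pair_seqs(pairs)
    e1 = end_sites(s1)
    e2 = end_sites(s2)
    both = (e1[:, 0] >= 0) & (e2[:, 0] >= 0) & (e1[:, 0] == e2[:, 0])
    n_informative = int(both.sum())

    # junction tallies per scaffold: same/cross support between
    # consecutive het sites
    same: Dict[int, np.ndarray] = {}
    cross: Dict[int, np.ndarray] = {}
    for si, name in enumerate(names):
        nj = max(len(sites_by_scaf[name]) - 1, 0)
        same[si] = np.zeros(nj, np.int64)
        cross[si] = np.zeros(nj, np.int64)
    sel = np.nonzero(both)[0]
    for i in sel:
        si = int(e1[i, 0])
        t1, t2 = int(e1[i, 1]), int(e2[i, 1])
        if abs(t1 - t2) != 1:
            continue
        j = min(t1, t2)
        if e1[i, 2] == e2[i, 2]:
            same[si][j] += 1
        else:
            cross[si][j] += 1

    rows = []
    tot_sites = tot_switches = tot_ham = 0
    any_evidence = False
    for si, name in enumerate(names):
        n_sites = len(sites_by_scaf[name])
        sw = (cross[si] > min_support) & (cross[si] > same[si])
        if (same[si].sum() + cross[si].sum()) > 0:
            any_evidence = True
        n_sw = int(sw.sum())
        labels = np.zeros(n_sites, np.int64)
        if n_sites:
            labels[1:] = np.cumsum(sw) % 2
        n_ham = int(min(labels.sum(), n_sites - labels.sum())) if n_sites else 0
        rows.append({"scaffold": name, "n_sites": n_sites,
                     "n_switches": n_sw, "n_hamming": n_ham,
                     "switch_rate": n_sw / n_sites if n_sites else None,
                     "hamming_rate": n_ham / n_sites if n_sites else None})
        tot_sites += n_sites
        tot_switches += n_sw
        tot_ham += n_ham

    evaluable = any_evidence and tot_sites > 0
    return PhasingReport(
        n_sites=tot_sites, n_switches=tot_switches, n_hamming=tot_ham,
        switch_rate=tot_switches / tot_sites if evaluable else None,
        hamming_rate=tot_ham / tot_sites if evaluable else None,
        evaluable=evaluable, n_informative_pairs=n_informative,
        per_scaffold=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Assembly statistics


def ng50(lengths: Sequence[int], genome_size: int) -> int:
    """Shortest sequence among those covering half the assumed genome size.

    Returns 0 when the summed lengths never reach G/2.
    """
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    total = 0
    for length in sorted(lengths, reverse=True):
        total += length
        if 2 * total >= genome_size:
            return length
    return 0


@dataclass
class AssemblyStats:
    total_size: int
    ng50: int
    lengths: List[int]


def assembly_stats(seqs: Dict[str, str], genome_size: int) -> AssemblyStats:
    lengths = sorted((len(s) for s in seqs.values()), reverse=True)
    return AssemblyStats(total_size=sum(lengths),
                         ng50=ng50(lengths, genome_size),
                         lengths=lengths)
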