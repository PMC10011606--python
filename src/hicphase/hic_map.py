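"""Distinct-k-mer indexing of the graph and Hi-C read-pair assignment.

A k-mer is *distinct* when its canonical form occurs at exactly one
location in the whole graph (node-internal windows only; windows never
span edges).  Global uniqueness -- not merely uniqueness between the two
alleles of a bubble -- is required, so repeats elsewhere in the genome
cannot attract reads.  Distinct k-mers found inside a (non-complex)
bubble allele barcode that allele; distinct k-mers of any other node
barcode the node itself.

Read ends are assigned by exact canonical k-mer match with heterozygous
priority: an end whose hits name exactly one bubble allele is assigned
to that allele, even when it also overlaps distinct k-mers of adjacent
homozygous nodes -- allele branches are narrow, so reads covering a
variant routinely extend into the flanking shared sequence, and
discarding them would lose most of the het signal.  Ends hitting two or
more alleles are ambiguous; ends with no allele hits map to a single
homozygous node or are ambiguous across several.  Ambiguous ends are
discarded whole -- counts feed hard support thresholds downstream, so no
fractional assignment is ever made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np

from . import _kmers
from .bubbles import Bubble
from .graph_io import ReadPair, SequenceGraph

# endpoint encodings: ("a", bubble_id, allele_idx) or ("n", node_id)
Endpoint = Tuple
UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"


@dataclass
class AlleleKmerIndex:
    """Sorted-array index of globally unique canonical k-mers.

    ``locations[i]`` is the endpoint barcoded by ``sorted_codes`` values
    mapping to location id ``i``.
    """

    k: int
    sorted_codes: np.ndarray          # uint64, ascending
    loc_of_code: np.ndarray           # int32, parallel to sorted_codes
    locations: List[Endpoint]         # allele endpoints first (sorted)
    node_of_code: np.ndarray = None   # int32 into node_names
    pos_of_code: np.ndarray = None    # int32 window start within node
    node_names: List[str] = None
    n_allele_locs: int = 0

    @property
    def allele_kmers(self) -> Dict[int, Endpoint]:
        """Map canonical code -> (bubble_id, allele_idx). Materialized lazily."""
        return {int(c): (self.locations[l][1], self.locations[l][2])
                for c, l in zip(self.sorted_codes, self.loc_of_code)
                if self.locations[l][0] == "a"}

    @property
    def homo_kmers(self) -> Dict[int, str]:
        """Map canonical code -> node id for non-bubble nodes."""
        return {int(c): self.locations[l][1]
                for c, l in zip(self.sorted_codes, self.loc_of_code)
                if self.locations[l][0] == "n"}

    def lookup_codes(self, codes: np.ndarray) -> np.ndarray:
        """Location ids for an array of canonical codes (-1 when absent)."""
        kidx = _lookup_indices(self, codes)
        out = np.full(codes.shape, -1, np.int64)
        hit = kidx >= 0
        out[hit] = self.loc_of_code[kidx[hit]]
        return out


_PREFILTER_BITS = 24
_PREFILTER_MASK = np.uint64((1 << _PREFILTER_BITS) - 1)


def _lookup_indices(index: "AlleleKmerIndex", codes: np.ndarray) -> np.ndarray:
    """Index into the sorted k-mer arrays per code (-1 when absent).

    Most query k-mers are not in the index (only globally unique graph
    k-mers are), so a low-bits membership table screens out the bulk of
    the queries before the binary search.
    """
    if len(index.sorted_codes) == 0:
        return np.full(codes.shape, -1, np.int64)
    filt = getattr(index, "_prefilter", None)
    if filt is None:
        filt = np.zeros(1 << _PREFILTER_BITS, bool)
        filt[(index.sorted_codes & _PREFILTER_MASK).astype(np.int64)] = True
        index._prefilter = filt
    out = np.full(codes.shape, -1, np.int64)
    cand = filt[(codes & _PREFILTER_MASK).astype(np.int64)]
    sub = codes[cand]
    idx = np.searchsorted(index.sorted_codes, sub)
    idx_c = np.minimum(idx, len(index.sorted_codes) - 1)
    hit = index.sorted_codes[idx_c] == sub
    out[cand] = np.where(hit, idx_c, -1)
    return out


def build_index(graph: SequenceGraph, bubbles: Sequence[Bubble],
                k: int = 31) -> AlleleKmerIndex:
    """Census every node-internal canonical k-mer and keep the unique ones."""
    _kmers.check_k(k)

    node_loc: Dict[str, Endpoint] = {}
    for b in bubbles:
        if b.is_complex:
            continue  # complex bubbles are carried as homozygous-like nodes
        for ai, path in enumerate(b.alleles):
            for n, _ in path:
                node_loc[n] = ("a", b.bubble_id, ai)

    names = sorted(graph.nodes)
    codes, owner, wpos = _kmers.batch_canonical(
        [graph.nodes[n] for n in names], k)
    uniq, first, counts = np.unique(codes, return_index=True, return_counts=True)
    keep = counts == 1
    uniq = uniq[keep]
    owners = owner[first[keep]]
    positions = wpos[first[keep]].astype(np.int32)

    loc_index: Dict[Endpoint, int] = {}
    locations: List[Endpoint] = []
    loc_ids = np.empty(len(uniq), np.int32)
    for i, ow in enumerate(owners):
        name = names[ow]
        ep = node_loc.get(name, ("n", name))
        j = loc_index.get(ep)
        if j is None:
            j = loc_index[ep] = len(locations)
            locations.append(ep)
        loc_ids[i] = j
    # reorder so allele locations get the smallest ids: the batch assigner
    # relies on this to give heterozygous hits priority cheaply
    order = sorted(range(len(locations)), key=lambda j: locations[j])
    remap = np.empty(len(locations), np.int32)
    for new, old in enumerate(order):
        remap[old] = new
    idx = AlleleKmerIndex(k=k, sorted_codes=uniq,
                          loc_of_code=remap[loc_ids] if len(locations)
                          else loc_ids,
                          locations=[locations[j] for j in order],
                          node_of_code=owners.astype(np.int32),
                          pos_of_code=positions,
                          node_names=names)
    idx.n_allele_locs = sum(1 for ep in idx.locations if ep[0] == "a")
    return idx


def _assign_batch(seqs: Sequence, index: AlleleKmerIndex,
                  want_pos: bool = False):
    """Location id per sequence; -1 unassigned, -2 ambiguous.

    Heterozygous priority: allele locations occupy the low id range, so a
    read's allele hits are exactly its hits below ``n_allele_locs``.  One
    distinct allele -> that allele (homozygous context ignored); two or
    more alleles -> ambiguous; no allele -> one node or ambiguous.

    With ``want_pos`` also returns, per assigned read, a representative
    hit coordinate (node index, window position) -- the smallest hit
    consistent with the assignment -- for contig-end bookkeeping.
    """
    n = len(seqs)
    out = np.full(n, -1, np.int64)
    rep = np.full(n, -1, np.int64)
    if n == 0:
        return (out, rep) if want_pos else out
    codes, owner, _ = _kmers.batch_canonical(seqs, index.k)
    kidx = _lookup_indices(index, codes)
    m = kidx >= 0
    owner, kidx = owner[m], kidx[m]
    if owner.size == 0:
        return (out, rep) if want_pos else out
    locs = index.loc_of_code[kidx].astype(np.int64)
    big = np.iinfo(np.int64).max
    na = index.n_allele_locs

    def _minmax(ow, lc):
        lo = np.full(n, big, np.int64)
        hi = np.full(n, -1, np.int64)
        np.minimum.at(lo, ow, lc)
        np.maximum.at(hi, ow, lc)
        return lo, hi

    is_allele = locs < na
    alo, ahi = _minmax(owner[is_allele], locs[is_allele])
    hlo, hhi = _minmax(owner[~is_allele], locs[~is_allele])
    has_a = ahi >= 0
    has_h = hhi >= 0
    out[has_a & (alo == ahi)] = ahi[has_a & (alo == ahi)]
    out[has_a & (alo != ahi)] = -2
    only_h = ~has_a & has_h
    out[only_h & (hlo == hhi)] = hhi[only_h & (hlo == hhi)]
    out[only_h & (hlo != hhi)] = -2
    if not want_pos:
        return out
    if index.node_of_code is not None:
        combo = (index.node_of_code[kidx].astype(np.int64) << np.int64(32))             | index.pos_of_code[kidx].astype(np.int64)
        match = locs == out[owner]
        rmin = np.full(n, big, np.int64)
        np.minimum.at(rmin, owner[match], combo[match])
        rep[rmin < big] = rmin[rmin < big]
    return out, rep


def assign_end(sequence: str, index: AlleleKmerIndex):
    """Assign one read end: (bubble, allele), node id, or a sentinel string."""
    if len(sequence) < index.k:
        return UNASSIGNED
    code = _assign_batch([sequence], index)[0]
    if code == -1:
        return UNASSIGNED
    if code == -2:
        return AMBIGUOUS
    ep = index.locations[code]
    return (ep[1], ep[2]) if ep[0] == "a" else ep[1]


@dataclass
class LinkCounts:
    """Read-pair support counts between allele/node endpoints, plus stats.

    ``rows`` optionally keeps one record per counted pair with the
    representative hit coordinates of both ends -- (location id, node
    name, offset within node) -- which the scaffolder turns into
    contig-end evidence.
    """

    counts: Dict[Tuple[Endpoint, Endpoint], int] = field(default_factory=dict)
    rows: List[Tuple[Endpoint, str, int, Endpoint, str, int]] = None
    n_pairs: int = 0
    n_pairs_counted: int = 0
    ends_allele: int = 0
    ends_homo: int = 0
    ends_ambiguous: int = 0
    ends_unassigned: int = 0

    def _submap(self, kinds) -> Dict[Tuple[Endpoint, Endpoint], int]:
        return {k: v for k, v in self.counts.items()
                if tuple(sorted((k[0][0], k[1][0]))) == kinds}

    @property
    def allele_allele(self):
        return self._submap(("a", "a"))

    @property
    def allele_node(self):
        return self._submap(("a", "n"))

    @property
    def node_node(self):
        return self._submap(("n", "n"))

    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, other: "LinkCounts") -> None:
        for key, v in other.counts.items():
            self.counts[key] = self.counts.get(key, 0) + v
        for f in ("n_pairs", "n_pairs_counted", "ends_allele", "ends_homo",
                  "ends_ambiguous", "ends_unassigned"):
            setattr(self, f, getattr(self, f) + getattr(other, f))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("endpoint1\tendpoint2\tcount\n")
            for (e1, e2) in sorted(self.counts):
                fh.write(f"{_ep_str(e1)}\t{_ep_str(e2)}\t"
                         f"{self.counts[(e1, e2)]}\n")


def _ep_str(ep: Endpoint) -> str:
    return (f"bubble{ep[1]}:allele{ep[2]}" if ep[0] == "a"
            else f"node:{ep[1]}")


PairInput = Union[Iterable[ReadPair], Tuple[Sequence[str], Sequence[str]]]


def count_links(pairs: PairInput, index: AlleleKmerIndex,
                chunk: int = 100_000) -> LinkCounts:
    """Count unordered endpoint pairs over all read pairs.

    Accepts either a stream of ReadPair or a (seqs1, seqs2) tuple of
    parallel sequence lists.  The result is independent of input order.
    """
    out = LinkCounts()
    if isinstance(pairs, tuple) and len(pairs) == 2:
        s1, s2 = pairs
        for i in range(0, len(s1), chunk):
            _count_chunk(s1[i:i + chunk], s2[i:i + chunk], index, out)
        return out
    buf1: List[str] = []
    buf2: List[str] = []
    for p in pairs:
        buf1.append(p.seq1)
        buf2.append(p.seq2)
        if len(buf1) >= chunk:
            _count_chunk(buf1, buf2, index, out)
            buf1, buf2 = [], []
    if buf1:
        _count_chunk(buf1, buf2, index, out)
    return out


def _count_chunk(seqs1, seqs2, index: AlleleKmerIndex, out: LinkCounts) -> None:
    both_ends, reps = _assign_batch(list(seqs1) + list(seqs2), index,
                                    want_pos=True)
    a1, a2 = both_ends[:len(seqs1)], both_ends[len(seqs1):]
    r1, r2 = reps[:len(seqs1)], reps[len(seqs1):]
    out.n_pairs += len(seqs1)
    is_allele = np.array([loc[0] == "a" for loc in index.locations], bool)
    for a in (a1, a2):
        out.ends_unassigned += int(np.sum(a == -1))
        out.ends_ambiguous += int(np.sum(a == -2))
        assigned = a[a >= 0]
        if assigned.size:
            n_all = int(is_allele[assigned].sum())
            out.ends_allele += n_all
            out.ends_homo += assigned.size - n_all
    both = (a1 >= 0) & (a2 >= 0)
    out.n_pairs_counted += int(both.sum())
    lo = np.minimum(a1[both], a2[both])
    hi = np.maximum(a1[both], a2[both])
    combo, cnt = np.unique(lo * np.int64(len(index.locations)) + hi,
                           return_counts=True)
    for c, n in zip(combo, cnt):
        e1 = index.locations[int(c) // len(index.locations)]
        e2 = index.locations[int(c) % len(index.locations)]
        key = tuple(sorted((e1, e2)))
        out.counts[key] = out.counts.get(key, 0) + int(n)
    if out.rows is None:
        out.rows = []
    names = index.node_names
    for i in np.nonzero(both)[0]:
        e1 = index.locations[a1[i]]
        e2 = index.locations[a2[i]]
        n1, p1 = names[int(r1[i]) >> 32], int(r1[i]) & 0xFFFFFFFF
        n2, p2 = names[int(r2[i]) >> 32], int(r2[i]) & 0xFFFFFFFF
        out.rows.append((e1, n1, p1, e2, n2, p2))
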