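"""Phased scaffolding: connect phased contigs across graph components.

Hi-C links are re-aggregated from bubble alleles and homozygous nodes
onto the contigs containing them.  Allele-resolved links carry haplotype
identity and decide how the two haplotypes of one contig pair up with the
two haplotypes of another; homozygous-node links cannot discriminate
haplotypes and are shared between both at half weight (they still inform
adjacency).  The resulting phased scaffold graph has one node per
oriented haplotype contig and a confidence score e/(i+j) per edge, where
e is the edge's Hi-C coverage and i, j the summed coverages of the other
edges at its two endpoints.

Partitioning the graph into 2 x #chromosomes scaffold classes is a
k-partite matching problem, solved greedily: long contigs first, taking
edges in descending confidence while each contig keeps at most two
joined neighbours; remaining short contigs are attached only where their
p best-supported neighbours agree on one partition.  Haplotype identity
is propagated through every join with union-find parity, so the second
haplotype's scaffolds are always the exact mirror of the first's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ._kmers import revcomp
from .hic_map import LinkCounts
from .phase import PhasedContigPair, _ParityUnionFind

logger = logging.getLogger(__name__)

HEAD, MID, TAIL = "H", "M", "T"


def edge_confidence(e: float, i: float, j: float) -> float:
    """Confidence e/(i+j); an isolated pair (i+j == 0) scores the maximum 1.0."""
    if e < 0 or i < 0 or j < 0:
        raise ValueError("edge confidence arguments must be non-negative")
    if i + j == 0:
        return 1.0
    return e / (i + j)


@dataclass
class _PairRecord:
    """Aggregated Hi-C evidence between two contigs (ci < cj)."""

    aa: List[List[int]] = field(default_factory=lambda: [[0, 0], [0, 0]])
    shared: int = 0                      # haplotype-uninformative links
    ends: Dict[Tuple[str, str], int] = field(default_factory=dict)

    @property
    def straight(self) -> int:
        return self.aa[0][0] + self.aa[1][1]

    @property
    def cross(self) -> int:
        return self.aa[0][1] + self.aa[1][0]

    @property
    def weight(self) -> int:
        """Haplotype-summed coverage used for adjacency decisions."""
        return self.straight + self.cross + 2 * (self.shared // 2)

    @property
    def parity(self) -> int:
        """0: h1-h1/h2-h2 pairing; 1: h1-h2/h2-h1 pairing."""
        return 0 if self.straight >= self.cross else 1


class ScaffoldGraph:
    """Oriented phased contigs plus confidence-scored Hi-C edges."""

    def __init__(self, contigs: Sequence[int], lengths: Dict[int, int]):
        self.contigs = sorted(contigs)
        self.lengths = dict(lengths)
        self.records: Dict[Tuple[int, int], _PairRecord] = {}
        self._wsum = None

    def record(self, ci: int, cj: int) -> _PairRecord:
        key = (ci, cj) if ci < cj else (cj, ci)
        rec = self.records.get(key)
        if rec is None:
            rec = self.records[key] = _PairRecord()
        return rec

    def weight(self, ci: int, cj: int) -> int:
        key = (ci, cj) if ci < cj else (cj, ci)
        rec = self.records.get(key)
        return rec.weight if rec else 0

    def nweight(self, ci: int, cj: int) -> float:
        """Hi-C coverage: pair count per bp of the smaller contig.

        Normalizing by the smaller contig's length removes the bulk
        advantage of long contigs -- raw counts between two long contigs
        separated by a short one can exceed the short contig's own
        counts, whereas its per-bp coverage always peaks at its true
        neighbours.
        """
        w = self.weight(ci, cj)
        return w / max(min(self.lengths.get(ci, 1),
                           self.lengths.get(cj, 1)), 1)

    def neighbors(self, ci: int) -> List[Tuple[int, int]]:
        """(weight, other) for every contig linked to ci, heaviest first."""
        out = []
        for (a, b), rec in self.records.items():
            if rec.weight <= 0:
                continue
            if a == ci:
                out.append((rec.weight, b))
            elif b == ci:
                out.append((rec.weight, a))
        out.sort(key=lambda t: (-t[0], t[1]))
        return out

    def _weight_sums(self, normalize: bool) -> Dict[int, float]:
        if self._wsum is None or self._wsum[0] is not normalize:
            ws = {c: 0.0 for c in self.contigs}
            for (a, b), rec in self.records.items():
                w = self.nweight(a, b) if normalize else rec.weight
                ws[a] += w
                ws[b] += w
            self._wsum = (normalize, ws)
        return self._wsum[1]

    def confidence(self, ci: int, cj: int, normalize: bool = False) -> float:
        """Neighbourhood confidence e/(i+j) of the contig-pair edge.

        Raw pair counts by default; with ``normalize=True`` e and the
        neighbourhood sums are per-bp coverages (see ``nweight``).
        """
        w = self.nweight(ci, cj) if normalize else self.weight(ci, cj)
        ws = self._weight_sums(normalize)
        return edge_confidence(w, ws[ci] - w, ws[cj] - w)

    def end_count(self, ci: int, ei: str, cj: int, ej: str) -> int:
        key = (ci, cj) if ci < cj else (cj, ci)
        rec = self.records.get(key)
        if rec is None:
            return 0
        pair = (ei, ej) if ci < cj else (ej, ei)
        return rec.ends.get(pair, 0)

    def hap_edges(self) -> Dict[Tuple[Tuple[int, int], Tuple[int, int]], int]:
        """Per-haplotype edge coverages e, keyed ((ci, hi), (cj, hj)).

        Only the two edges of the preferred pairing are reported; shared
        (homozygous) links contribute half weight, rounded down, to each.
        """
        out = {}
        for (ci, cj), rec in self.records.items():
            p = rec.parity
            half = rec.shared // 2
            e0 = rec.aa[0][p] + half
            e1 = rec.aa[1][1 - p] + half
            if e0:
                out[((ci, 0), (cj, p))] = e0
            if e1:
                out[((ci, 1), (cj, 1 - p))] = e1
        return out


def _end_of(pos: int, length: int, head_frac: float) -> str:
    if length <= 0:
        return MID
    f = pos / length
    if f < head_frac:
        return HEAD
    if f > 1.0 - head_frac:
        return TAIL
    return MID


def build_scaffold_graph(pairs: Sequence[PhasedContigPair], links: LinkCounts,
                         head_frac: float = 0.2) -> ScaffoldGraph:
    """Aggregate link counts onto contigs, split by haplotype membership."""
    lengths = {p.component_id: p.length for p in pairs}
    sg = ScaffoldGraph([p.component_id for p in pairs], lengths)

    node_contig: Dict[str, Tuple[int, int]] = {}
    bubble_contig: Dict[int, int] = {}
    by_id = {p.component_id: p for p in pairs}
    for p in pairs:
        for n, pos in p.node_pos.items():
            node_contig[n] = (p.component_id, pos)
        for bid in p.bubble_pos:
            bubble_contig[bid] = p.component_id

    def resolve(ep, node=None, off=0) -> Optional[Tuple[int, Optional[int], int]]:
        """Endpoint (plus optional hit coordinate) -> (contig, hap, pos)."""
        if ep[0] == "a":
            ci = bubble_contig.get(ep[1])
            if ci is None:
                return None
            hap = by_id[ci].allele_hap.get((ep[1], ep[2]))
            base = by_id[ci].bubble_pos.get(ep[1], 0)
        else:
            hit = node_contig.get(ep[1])
            if hit is None:
                return None
            ci, base = hit
        if node is not None:
            start = by_id[ci].node_pos.get(node)
            if start is not None:
                base = start + off
        return ci, (hap if ep[0] == "a" else None), base

    if links.rows is not None:
        entries = [((e1, n1, p1), (e2, n2, p2), 1)
                   for (e1, n1, p1, e2, n2, p2) in links.rows]
    else:
        entries = [((e1, None, 0), (e2, None, 0), c)
                   for (e1, e2), c in links.counts.items()]
    for (e1, n1, o1), (e2, n2, o2), c in entries:
        r1, r2 = resolve(e1, n1, o1), resolve(e2, n2, o2)
        if r1 is None or r2 is None:
            continue
        (c1, h1, p1), (c2, h2, p2) = r1, r2
        if c1 == c2:
            continue  # intra-contig evidence already consumed by phasing
        if c1 > c2:
            (c1, h1, p1), (c2, h2, p2) = (c2, h2, p2), (c1, h1, p1)
        rec = sg.record(c1, c2)
        if h1 is not None and h2 is not None:
            rec.aa[h1][h2] += c
        else:
            rec.shared += c
        ends = (_end_of(p1, sg.lengths[c1], head_frac),
                _end_of(p2, sg.lengths[c2], head_frac))
        rec.ends[ends] = rec.ends.get(ends, 0) + c
    return sg


@dataclass
class Partition:
    """One scaffold class: members carry a relative haplotype parity.

    A member (contig, rel) contributes its hap1 sequence to the scaffold's
    first haplotype when rel == 0, its hap2 sequence when rel == 1.  The
    mirror scaffold flips every rel -- it is derived by relabelling, never
    re-partitioned.
    """

    members: List[Tuple[int, int]] = field(default_factory=list)
    order: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def contigs(self) -> List[int]:
        return [c for c, _ in self.members]


@dataclass
class ScaffoldSet:
    partitions: List[Partition] = field(default_factory=list)
    gap_len: int = 100


def greedy_partition(sg: ScaffoldGraph, long_threshold: int = 10_000_000,
                     p: int = 3, conf_floor: float = 0.2,
                     min_support: int = 5, normalize: bool = False,
                     lengths: Optional[Dict[int, int]] = None) -> ScaffoldSet:
    """Greedy k-partite partitioning of the phased scaffold graph."""
    lengths = lengths or sg.lengths
    uf = _ParityUnionFind(sg.contigs)
    degree = {c: 0 for c in sg.contigs}
    size = {c: 1 for c in sg.contigs}  # partition sizes, by current root

    # phase 1: long contigs, highest-confidence edges first
    long_set = {c for c in sg.contigs if lengths.get(c, 0) > long_threshold}
    cand = []
    for (ci, cj), rec in sg.records.items():
        if ci in long_set and cj in long_set and rec.weight > 0:
            cand.append((sg.confidence(ci, cj, normalize), rec.weight, ci, cj))
    cand.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    for conf, w, ci, cj in cand:
        if conf < conf_floor:
            break
        if degree[ci] >= 2 or degree[cj] >= 2:
            continue
        ri, _ = uf.find(ci)
        rj, _ = uf.find(cj)
        if ri == rj:
            continue
        uf.union(ci, cj, sg.record(ci, cj).parity)
        size[uf.find(ci)[0]] = size[ri] + size[rj]
        degree[ci] += 1
        degree[cj] += 1

    # phase 2: attach remaining contigs where their p best-supported
    # neighbours agree.  Longest first; neighbours still sitting in
    # singleton partitions cast no veto (they will be attached later),
    # but two disagreeing multi-contig partitions do.  When every top
    # neighbour is a singleton the contig pairs up with its best one,
    # seeding a new partition.
    remaining = sorted(sg.contigs, key=lambda c: (-lengths.get(c, 0), c))
    changed = True
    passes = 0
    while changed and passes <= len(sg.contigs):
        changed = False
        passes += 1
        for c in remaining:
            rc, _ = uf.find(c)
            if size[rc] > 1:
                continue
            nbrs = [(w, o) for w, o in sg.neighbors(c) if w > min_support]
            top = nbrs[:p]
            if not top:
                continue
            multi_roots = {uf.find(o)[0] for _, o in top
                           if size[uf.find(o)[0]] > 1}
            if len(multi_roots) > 1:
                continue  # conflicting evidence: stay singleton
            if multi_roots:
                target = next(o for _, o in top
                              if uf.find(o)[0] in multi_roots)
            else:
                target = top[0][1]
            # parity vote: each neighbour of the target's partition implies
            # a haplotype pairing for c
            troot = uf.find(target)[0]
            vote = [0, 0]
            for w, o in top:
                if uf.find(o)[0] != troot:
                    continue
                rel = sg.record(c, o).parity ^ uf.find(o)[1]
                vote[rel] += w
            best = 0 if vote[0] >= vote[1] else 1
            old_size = size[troot]
            _, po = uf.find(target)
            uf.union(c, target, best ^ po)
            size[uf.find(c)[0]] = old_size + 1
            changed = True

    groups: Dict[object, Partition] = {}
    for c in sg.contigs:
        root, par = uf.find(c)
        groups.setdefault(root, Partition()).members.append((c, par))
    parts = list(groups.values())
    for part in parts:
        part.members.sort()
    parts.sort(key=lambda pt: (-sum(lengths.get(c, 0) for c in pt.contigs),
                               pt.contigs[0]))
    return ScaffoldSet(partitions=parts)


def _corner_score(sg: ScaffoldGraph, a: int, b: int,
                  head_frac: float = 0.2) -> float:
    """Adjacency-normalized head/tail-corner support between two contigs.

    Links whose both representative positions fall in terminal windows
    are the adjacency signal: corners of truly neighbouring contigs face
    each other across a short gap, while corners of contigs separated by
    another contig sit a whole contig length apart and decay away.  The
    observed corner count is divided by its expectation under the
    adjacency hypothesis with 1/d contact decay,

        E(wa, wb) ~ (wa+wb) ln(wa+wb) - wa ln wa - wb ln wb,

    (the double integral of 1/(x+y) over the two windows), which rises
    roughly linearly in the smaller window: raw counts would let wide
    windows of long contigs outvote a short true neighbour, while a
    plain per-area density over-rewards tiny contigs whose handful of
    stray long-range corners sits in a minuscule denominator.  Bulk
    (mid-body) counts are excluded.
    """
    key = (a, b) if a < b else (b, a)
    rec = sg.records.get(key)
    if rec is None:
        return 0.0
    n = sum(c for (e1, e2), c in rec.ends.items()
            if e1 != MID and e2 != MID)
    if n == 0:
        return 0.0
    from math import log
    wa = max(head_frac * sg.lengths.get(a, 1), 2.0)
    wb = max(head_frac * sg.lengths.get(b, 1), 2.0)
    s = wa + wb
    expect = s * log(s) - wa * log(wa) - wb * log(wb)
    return n / max(expect, 1e-9)


def _junction_score(sg: ScaffoldGraph, a: int, oa: str, b: int, ob: str) -> int:
    """Support for placing oriented contig b directly after oriented a."""
    ea = TAIL if oa == "+" else HEAD
    eb = HEAD if ob == "+" else TAIL
    return sg.end_count(a, ea, b, eb)


def order_and_orient(partition: Partition, sg: ScaffoldGraph,
                     lengths: Optional[Dict[int, int]] = None) -> List[Tuple[int, str]]:
    """Order and orient a partition's contigs along the chromosome.

    Greedy longest-edge path insertion, then one correction sweep that
    flips contigs with inverted end support and swaps adjacent contigs
    when that strictly increases the summed adjacent corner support.

    Adjacency is judged on head/tail-corner support (see
    ``_corner_score``), with per-bp coverage as the tie-breaker.
    """
    lengths = lengths or sg.lengths
    contigs = partition.contigs
    if len(contigs) <= 1:
        partition.order = [(c, "+") for c in contigs]
        return partition.order

    cset = set(contigs)
    edges = []
    for (ci, cj), rec in sg.records.items():
        if ci in cset and cj in cset and rec.weight > 0:
            edges.append(((_corner_score(sg, ci, cj), sg.nweight(ci, cj)),
                          ci, cj))
    edges.sort(key=lambda t: (-t[0][0], -t[0][1], t[1], t[2]))

    adj: Dict[int, List[int]] = {c: [] for c in contigs}
    uf = _ParityUnionFind(contigs)
    for w, ci, cj in edges:
        if len(adj[ci]) >= 2 or len(adj[cj]) >= 2:
            continue
        if uf.find(ci)[0] == uf.find(cj)[0]:
            continue
        uf.union(ci, cj, 0)
        adj[ci].append(cj)
        adj[cj].append(ci)

    # walk each path fragment from its smaller endpoint
    frags: List[List[int]] = []
    seen = set()
    for c in contigs:
        if c in seen or len(adj[c]) > 1:
            continue
        frag = [c]
        seen.add(c)
        while True:
            nxt = [x for x in adj[frag[-1]] if x not in seen]
            if not nxt:
                break
            frag.append(nxt[0])
            seen.add(nxt[0])
        frags.append(frag)
    for c in contigs:  # isolated cycles cannot appear; safety for leftovers
        if c not in seen:
            frags.append([c])
            seen.add(c)
    if len(frags) > 1:
        logger.info("partition %s: support graph disconnected into %d pieces",
                    contigs, len(frags))
    frags.sort(key=lambda f: (-sum(lengths.get(c, 0) for c in f), f[0]))
    order = [c for f in frags for c in f]

    # orient greedily along the path
    orients: List[str] = []
    for i, c in enumerate(order):
        if i == 0:
            if len(order) > 1:
                best = max(
                    ((o1, o2) for o1 in "+-" for o2 in "+-"),
                    key=lambda oo: (_junction_score(sg, c, oo[0],
                                                    order[1], oo[1]),
                                    oo == ("+", "+"), oo[0] == "+"))
                orients.append(best[0])
            else:
                orients.append("+")
        else:
            prev = order[i - 1]
            best = max("+-", key=lambda o: (_junction_score(
                sg, prev, orients[i - 1], c, o), o == "+"))
            orients.append(best)

    # correction sweep 1: flip inverted contigs
    def flank_score(i: int, orient: str) -> int:
        s = 0
        if i > 0:
            s += _junction_score(sg, order[i - 1], orients[i - 1],
                                 order[i], orient)
        if i < len(order) - 1:
            s += _junction_score(sg, order[i], orient,
                                 order[i + 1], orients[i + 1])
        return s

    for i in range(len(order)):
        cur = orients[i]
        alt = "-" if cur == "+" else "+"
        if flank_score(i, alt) > flank_score(i, cur):
            orients[i] = alt

    # correction sweep 2: swap adjacent contigs on strictly better support
    for i in range(len(order) - 1):
        a, b = order[i], order[i + 1]
        before = after = 0.0
        if i > 0:
            before += _corner_score(sg, order[i - 1], a)
            after += _corner_score(sg, order[i - 1], b)
        if i < len(order) - 2:
            before += _corner_score(sg, b, order[i + 2])
            after += _corner_score(sg, a, order[i + 2])
        if after > before:
            order[i], order[i + 1] = b, a
            orients[i], orients[i + 1] = orients[i + 1], orients[i]

    if order[0] > order[-1]:
        order.reverse()
        orients = ["+" if o == "-" else "-" for o in reversed(orients)]

    partition.order = list(zip(order, orients))
    return partition.order


def spell_scaffolds(ss: ScaffoldSet,
                    hap_seqs: Dict[Tuple[int, int], str]) -> Dict[str, str]:
    """Spell scaffold FASTA sequences, joining contigs with 100-N gaps.

    ``hap_seqs`` maps (contig_id, 0|1) to the two haplotype sequences of
    each phased contig.  Output names are scaffold_<i>_h1 / _h2; the h2
    scaffold mirrors h1's order and orientation with complementary
    haplotype choices.
    """
    rel = {}
    out: Dict[str, str] = {}
    for idx, part in enumerate(ss.partitions, 1):
        rel = dict(part.members)
        ordered = part.order or [(c, "+") for c in part.contigs]
        for hap_label in (1, 2):
            pieces = []
            for c, orient in ordered:
                h = rel[c] if hap_label == 1 else 1 - rel[c]
                seq = hap_seqs[(c, h)]
                pieces.append(revcomp(seq) if orient == "-" else seq)
            out[f"scaffold_{idx}_h{hap_label}"] = ("N" * ss.gap_len).join(pieces)
    return out


def scaffold_table(ss: ScaffoldSet) -> List[Tuple[str, int, int, str, int]]:
    """AGP-like rows: (scaffold, ordinal, contig, orientation, gap_after)."""
    rows = []
    for idx, part in enumerate(ss.partitions, 1):
        ordered = part.order or [(c, "+") for c in part.contigs]
        for j, (c, o) in enumerate(ordered):
            gap = ss.gap_len if j < len(ordered) - 1 else 0
            rows.append((f"scaffold_{idx}", j + 1, c, o, gap))
    return rows
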