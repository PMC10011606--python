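"""Greedy phasing of bubble chains into two haplotype paths per component.

For every pair of biallelic bubbles in a chain that shares Hi-C link
evidence, the two consistent allele pairings are scored: the better one
(cis) against the other (trans).  Pairs are processed greedily in
descending margin |cis - trans|; a pair joins the two bubbles' phase
groups -- via union-find with relative-phase parity -- only when
max(cis, trans) exceeds the support threshold strictly (default >5
read pairs).  An earlier join is never overturned: conflicting evidence
is skipped and counted.  Hi-C is long-range, so links between *all*
bubble pairs of a chain contribute, not only adjacent ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ._kmers import revcomp
from .bubbles import BubbleChain, ChainBubble
from .graph_io import OrientedNode, REV, SequenceGraph
from .hic_map import LinkCounts

logger = logging.getLogger(__name__)


class SpellingError(ValueError):
    """Raised when an edge overlap is inconsistent with node lengths."""


@dataclass
class PhasedContigPair:
    """The two haplotype paths (and sequences) of one graph component."""

    component_id: int
    hap1_path: List[OrientedNode] = field(default_factory=list)
    hap2_path: List[OrientedNode] = field(default_factory=list)
    hap1_seq: str = ""
    hap2_seq: str = ""
    phase_blocks: List[List[int]] = field(default_factory=list)
    bubble_order: List[int] = field(default_factory=list)
    allele_hap: Dict[Tuple[int, int], Optional[int]] = field(default_factory=dict)
    n_conflicts: int = 0
    node_pos: Dict[str, int] = field(default_factory=dict)
    bubble_pos: Dict[int, int] = field(default_factory=dict)
    length: int = 0


class _ParityUnionFind:
    """Union-find that tracks each element's phase parity to its root."""

    def __init__(self, elems):
        self.parent = {e: e for e in elems}
        self.parity = {e: 0 for e in elems}
        self.rank = {e: 0 for e in elems}

    def find(self, x) -> Tuple[object, int]:
        if self.parent[x] == x:
            return x, 0
        root, par = self.find(self.parent[x])
        self.parent[x] = root
        self.parity[x] ^= par
        return root, self.parity[x]

    def union(self, x, y, rel: int) -> bool:
        """Join with parity(x) xor parity(y) == rel; False on conflict."""
        rx, px = self.find(x)
        ry, py = self.find(y)
        if rx == ry:
            return (px ^ py) == rel
        if self.rank[rx] < self.rank[ry]:
            rx, ry, px, py = ry, rx, py, px
        self.parent[ry] = rx
        self.parity[ry] = px ^ py ^ rel
        if self.rank[rx] == self.rank[ry]:
            self.rank[rx] += 1
        return True


def _select_biallelic(cb: ChainBubble, allele_support: Dict[Tuple[int, int], int]
                      ) -> Optional[Tuple[int, int]]:
    """Indices of the two alleles to phase, or None for complex bubbles.

    Multi-allelic bubbles keep their two best-supported alleles; the rest
    are demoted to unphased.
    """
    if cb.is_complex or len(cb.alleles) < 2:
        return None
    if len(cb.alleles) == 2:
        return 0, 1
    ranked = sorted(range(len(cb.alleles)),
                    key=lambda ai: (-allele_support.get((cb.bubble_id, ai), 0), ai))
    pair = sorted(ranked[:2])
    return pair[0], pair[1]


def phase_chain(chain: BubbleChain, links: LinkCounts,
                min_support: int = 5) -> PhasedContigPair:
    """Phase one bubble chain into a pair of haplotype paths."""
    allele_support: Dict[Tuple[int, int], int] = {}
    for (e1, e2), c in links.counts.items():
        for e in (e1, e2):
            if e[0] == "a":
                key = (e[1], e[2])
                allele_support[key] = allele_support.get(key, 0) + c

    selected: Dict[int, Tuple[int, int]] = {}
    for cb in chain.bubbles:
        sel = _select_biallelic(cb, allele_support)
        if sel is not None:
            selected[cb.bubble_id] = sel

    # aggregate cis/trans support per bubble pair of this chain
    sel_pos: Dict[Tuple[int, int], int] = {}
    for bid, (a0, a1) in selected.items():
        sel_pos[(bid, a0)] = 0
        sel_pos[(bid, a1)] = 1
    pair_cfg: Dict[Tuple[int, int], List[int]] = {}
    for (e1, e2), c in links.counts.items():
        if e1[0] != "a" or e2[0] != "a":
            continue
        k1, k2 = (e1[1], e1[2]), (e2[1], e2[2])
        if k1 not in sel_pos or k2 not in sel_pos or e1[1] == e2[1]:
            continue
        (bi, si), (bj, sj) = sorted(((e1[1], sel_pos[k1]), (e2[1], sel_pos[k2])))
        cfg = pair_cfg.setdefault((bi, bj), [0, 0, 0, 0])
        cfg[2 * si + sj] += c

    records = []
    for (bi, bj), cfg in pair_cfg.items():
        same = cfg[0] + cfg[3]
        cross = cfg[1] + cfg[2]
        records.append((abs(same - cross), bi, bj, same, cross))
    records.sort(key=lambda r: (-r[0], r[1], r[2]))

    uf = _ParityUnionFind(selected)
    n_conflicts = 0
    for margin, bi, bj, same, cross in records:
        if margin == 0 or max(same, cross) <= min_support:
            continue  # threshold is strictly >min_support
        rel = 0 if same > cross else 1
        if not uf.union(bi, bj, rel):
            n_conflicts += 1

    chain_order = [cb.bubble_id for cb in chain.bubbles
                   if cb.bubble_id in selected]
    blocks: Dict[object, List[int]] = {}
    for bid in chain_order:
        root, _ = uf.find(bid)
        blocks.setdefault(root, []).append(bid)
    phase_blocks = sorted(blocks.values(), key=lambda blk: chain_order.index(blk[0]))

    # per-bubble label: which selected allele goes to hap1
    label: Dict[int, int] = {}
    for blk in phase_blocks:
        leader = blk[0]
        _, lead_par = uf.find(leader)
        for bid in blk:
            _, par = uf.find(bid)
            label[bid] = par ^ lead_par

    pair = PhasedContigPair(component_id=chain.component_id,
                            n_conflicts=n_conflicts,
                            phase_blocks=phase_blocks,
                            bubble_order=chain_order)
    for bid, (a0, a1) in selected.items():
        sel = (a0, a1)
        lab = label[bid]
        pair.allele_hap[(bid, sel[lab])] = 0
        pair.allele_hap[(bid, sel[1 - lab])] = 1

    # build haplotype paths: shared linking segments + chosen alleles
    h1: List[OrientedNode] = list(chain.linking[0])
    h2: List[OrientedNode] = list(chain.linking[0])
    for i, cb in enumerate(chain.bubbles):
        if cb.bubble_id in selected:
            a0, a1 = selected[cb.bubble_id]
            lab = label[cb.bubble_id]
            first, second = (a0, a1) if lab == 0 else (a1, a0)
            h1.extend(cb.alleles[first])
            h2.extend(cb.alleles[second])
        else:
            stand_in = max(cb.alleles, key=lambda p: (len(p), p)) \
                if cb.alleles else ()
            h1.extend(stand_in)
            h2.extend(stand_in)
        h1.extend(chain.linking[i + 1])
        h2.extend(chain.linking[i + 1])
    pair.hap1_path, pair.hap2_path = h1, h2
    return pair


def _spell_path(path: Sequence[OrientedNode], graph: SequenceGraph
                ) -> Tuple[str, Dict[str, int]]:
    parts: List[str] = []
    pos: Dict[str, int] = {}
    cur = 0
    prev: Optional[OrientedNode] = None
    for (n, o) in path:
        seq = graph.nodes[n]
        if o == REV:
            seq = revcomp(seq)
        ov = 0
        if prev is not None:
            try:
                ov = graph.overlap(prev[0], prev[1], n, o)
            except KeyError:
                raise SpellingError(
                    f"no edge between consecutive path nodes {prev} and "
                    f"{(n, o)}") from None
            if ov > len(seq):
                raise SpellingError(
                    f"overlap {ov} longer than node {n} ({len(seq)} bp)")
        pos.setdefault(n, cur - ov)  # node start on the spelled contig
        parts.append(seq[ov:])
        cur += len(seq) - ov
        prev = (n, o)
    return "".join(parts), pos


def spell_contigs(pair: PhasedContigPair, graph: SequenceGraph) -> Tuple[str, str]:
    """Spell both haplotype paths, trimming edge overlaps.

    Records node offsets (hap1 coordinates; hap2-only allele nodes get
    their hap2 offsets, which are comparable at contig scale) and per
    bubble the offset of its source node -- the scaffolder uses these to
    decide which contig end a Hi-C link lands in.
    """
    pair.hap1_seq, pos1 = _spell_path(pair.hap1_path, graph)
    pair.hap2_seq, pos2 = _spell_path(pair.hap2_path, graph)
    pair.node_pos = dict(pos2)
    pair.node_pos.update(pos1)
    pair.length = len(pair.hap1_seq)
    return pair.hap1_seq, pair.hap2_seq


def phase_all(graph: SequenceGraph, chains: Sequence[BubbleChain],
              links: LinkCounts, min_support: int = 5) -> List[PhasedContigPair]:
    """Phase and spell every component's chain."""
    pairs = []
    for chain in chains:
        pair = phase_chain(chain, links, min_support=min_support)
        spell_contigs(pair, graph)
        for cb in chain.bubbles:
            pair.bubble_pos[cb.bubble_id] = pair.node_pos.get(cb.source[0], 0)
        pairs.append(pair)
    return pairs
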