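"""Superbubble detection and bubble-chain construction.

Heterozygous variants appear in a diploid assembly graph as bubbles: a
source/sink pair of oriented nodes whose interior is entered only through
the source, left only through the sink, and is acyclic in the walk
direction.  The distinct source-to-sink interior paths are the alleles.

Detection runs on the doubled directed view of the bidirected graph with
an Onodera-style single-source expansion: from every oriented node with
out-degree >= 2 the walk advances a frontier, admitting a vertex only
once all of its parents have been visited, and reports the first moment
the frontier collapses to a single exit vertex.  Candidates are then
deduplicated against their reverse-complement mirrors and filtered to the
innermost set, so returned bubble interiors are pairwise disjoint.

Bubbles whose alleles are not vertex-disjoint paths, or which have more
than ``max_alleles`` interior paths, are flagged complex: they stay in
the graph (their longest allele stands in during spelling) but are not
phased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .graph_io import FWD, OrientedNode, SequenceGraph, flip

logger = logging.getLogger(__name__)

AllelePath = Tuple[OrientedNode, ...]


@dataclass
class Bubble:
    """A source/sink pair with its allele paths (oriented canonically)."""

    bubble_id: int
    source: OrientedNode
    sink: OrientedNode
    alleles: List[AllelePath]
    interior: FrozenSet[str]
    is_complex: bool = False

    def mirror(self) -> Tuple[OrientedNode, OrientedNode]:
        """Source/sink of the reverse-complement traversal."""
        return ((self.sink[0], flip(self.sink[1])),
                (self.source[0], flip(self.source[1])))


def _flip_path(path: AllelePath) -> AllelePath:
    return tuple((n, flip(o)) for n, o in reversed(path))


def _walk_superbubble(s: OrientedNode, adj, radj) -> Optional[Tuple[OrientedNode, Set[OrientedNode]]]:
    """Find the minimal superbubble exit for source s, or None.

    Frontier expansion that admits a vertex only when all of its parents
    are visited; stalls (cycles), tips, escapes to the source's node, or a
    node seen in both orientations abort the walk.
    """
    seen: Set[OrientedNode] = set()
    visited: Set[OrientedNode] = set()
    stack = [s]
    orient_of = {s[0]: s[1]}
    while stack:
        v = stack.pop()
        visited.add(v)
        seen.discard(v)
        children = adj[v]
        if not children:
            return None  # tip: interior leaks out
        for u in children:
            if u[0] == s[0]:
                return None  # cycle back into the source node
            prev = orient_of.get(u[0])
            if prev is not None and prev != u[1]:
                return None  # inverted repeat: both orientations inside
            orient_of[u[0]] = u[1]
            if u in visited:
                return None  # back edge: cyclic interior
            seen.add(u)
            if all(p in visited for p in radj[u]):
                stack.append(u)
        if len(stack) == 1 and seen == {stack[0]}:
            t = stack[0]
            if s in adj[t]:
                return None  # edge sink -> source closes a cycle
            if visited == {s}:
                return None  # no interior at all
            return t, visited | {t}
    return None  # stalled: cyclic or externally entered interior


def _enumerate_alleles(s: OrientedNode, t: OrientedNode, nodes: Set[OrientedNode],
                       adj, cap: int) -> Tuple[List[AllelePath], bool]:
    """Interior s->t paths and a flag telling whether enumeration finished.

    Enumeration stops early once more than ``cap`` paths are found (the
    bubble is then complex and the partial list is only used to pick a
    stand-in allele).
    """
    paths: List[AllelePath] = []
    path: List[OrientedNode] = []
    on_path: Set[OrientedNode] = set()

    def dfs(v: OrientedNode) -> bool:
        for u in adj[v]:
            if u == t:
                paths.append(tuple(path))
                if len(paths) > cap:
                    return False
            elif u in nodes and u not in on_path:
                path.append(u)
                on_path.add(u)
                ok = dfs(u)
                path.pop()
                on_path.discard(u)
                if not ok:
                    return False
        return True

    complete = dfs(s)
    return paths, complete


def find_bubbles(graph: SequenceGraph, max_alleles: int = 16) -> List[Bubble]:
    """Detect all minimal bubbles of the graph (per component).

    Returns bubbles sorted by (source, sink), with ids assigned in that
    order.  Interiors of the returned bubbles are pairwise disjoint.
    """
    adj = graph.directed_adjacency()
    radj: Dict[OrientedNode, List[OrientedNode]] = {v: [] for v in adj}
    for v, children in adj.items():
        for u in children:
            radj[u].append(v)

    candidates: Dict[Tuple[OrientedNode, OrientedNode], Set[OrientedNode]] = {}
    for s in sorted(adj):
        if len(adj[s]) < 2:
            continue
        hit = _walk_superbubble(s, adj, radj)
        if hit is None:
            continue
        t, nodes = hit
        mirror_key = ((t[0], flip(t[1])), (s[0], flip(s[1])))
        if (s, t) <= mirror_key:
            candidates.setdefault((s, t), nodes)
        else:
            flipped = {(n, flip(o)) for n, o in nodes}
            candidates.setdefault(mirror_key, flipped)

    # innermost filter: smallest first; interiors must stay disjoint from
    # everything already accepted (including accepted endpoints).
    accepted: List[Tuple[OrientedNode, OrientedNode, Set[OrientedNode]]] = []
    used_interior: Set[str] = set()
    used_endpoints: Set[str] = set()
    for key in sorted(candidates, key=lambda k: (len(candidates[k]), k)):
        s, t = key
        nodes = candidates[key]
        interior = {n for n, _ in nodes} - {s[0], t[0]}
        if interior & used_interior or interior & used_endpoints:
            continue
        if s[0] in used_interior or t[0] in used_interior:
            continue
        accepted.append((s, t, nodes))
        used_interior |= interior
        used_endpoints |= {s[0], t[0]}

    bubbles: List[Bubble] = []
    for s, t, nodes in sorted(accepted, key=lambda c: (c[0], c[1])):
        interior_nodes = nodes - {s, t}
        alleles, complete = _enumerate_alleles(s, t, interior_nodes, adj,
                                               max_alleles)
        interior = frozenset(n for n, _ in interior_nodes)
        alleles.sort(key=lambda p: (len(p), p))
        if not complete:
            is_complex = True
            alleles = alleles[-1:]  # longest found path stands in
        else:
            covered: Set[OrientedNode] = set()
            disjoint = True
            for p in alleles:
                if covered & set(p):
                    disjoint = False
                covered |= set(p)
            is_complex = (not disjoint or covered != interior_nodes
                          or len(alleles) < 2)
        bubbles.append(Bubble(len(bubbles), s, t, alleles, interior, is_complex))
    return bubbles


# ---------------------------------------------------------------------------
# Bubble chains


@dataclass
class ChainBubble:
    """A bubble as traversed by its chain (possibly mirror-flipped)."""

    bubble_id: int
    source: OrientedNode
    sink: OrientedNode
    alleles: List[AllelePath]
    is_complex: bool


@dataclass
class BubbleChain:
    """Ordered bubbles of one component plus homozygous linking segments.

    ``linking`` always has ``len(bubbles) + 1`` entries: the oriented node
    path before the first bubble, between consecutive bubbles, and after
    the last one.  A bubble-free component yields zero bubbles and one
    linking segment covering the whole path.
    """

    component_id: int
    bubbles: List[ChainBubble] = field(default_factory=list)
    linking: List[List[OrientedNode]] = field(default_factory=list)
    truncated: bool = False

    @property
    def ordered_bubbles(self) -> List[int]:
        return [b.bubble_id for b in self.bubbles]


def _chain_one_component(comp_id: int, comp_nodes: List[str],
                         graph: SequenceGraph,
                         comp_bubbles: List[Bubble]) -> BubbleChain:
    interior: Set[str] = set()
    for b in comp_bubbles:
        interior |= b.interior

    # incident structure over backbone nodes: real edges avoiding bubble
    # interiors, plus one virtual edge per bubble (source node <-> sink node)
    incident: Dict[str, List[Tuple[str, object]]] = {
        n: [] for n in comp_nodes if n not in interior}
    for ek in sorted(graph.edges):
        a, _, b, _ = ek
        if a not in incident or b not in incident:
            continue
        incident[a].append(("e", ek))
        if b != a:
            incident[b].append(("e", ek))
    for bub in comp_bubbles:
        incident[bub.source[0]].append(("b", bub))
        if bub.sink[0] != bub.source[0]:
            incident[bub.sink[0]].append(("b", bub))

    chain = BubbleChain(component_id=comp_id)
    if not incident:
        chain.linking.append([])
        return chain

    endpoints = sorted(n for n, items in incident.items() if len(items) <= 1)
    start = endpoints[0] if endpoints else min(incident)

    def item_key(item):
        kind, obj = item
        return (kind, obj.bubble_id) if kind == "b" else (kind, obj)

    # initial orientation: whatever lets the first incident item be traversed
    def start_orientation(n: str) -> str:
        items = sorted(incident[n], key=item_key)
        if not items:
            return FWD
        kind, obj = items[0]
        if kind == "b":
            if obj.source[0] == n:
                return obj.source[1]
            return flip(obj.sink[1])
        a, oa, b, ob = obj
        return oa if a == n else flip(ob)

    cur: OrientedNode = (start, start_orientation(start))
    seg: List[OrientedNode] = [cur]
    visited_items: Set[Tuple] = set()

    while True:
        n, o = cur
        if len(incident[n]) > 2:
            logger.warning(
                "component %d: branch at node %s that is not a bubble; "
                "chain truncated", comp_id, n)
            chain.truncated = True
            break
        nxt = [it for it in incident[n] if item_key(it) not in visited_items]
        if not nxt:
            break
        kind, obj = sorted(nxt, key=item_key)[0]
        visited_items.add(item_key((kind, obj)))
        if kind == "b":
            if cur == obj.source:
                cb = ChainBubble(obj.bubble_id, obj.source, obj.sink,
                                 list(obj.alleles), obj.is_complex)
            elif cur == (obj.sink[0], flip(obj.sink[1])):
                src, snk = obj.mirror()
                cb = ChainBubble(obj.bubble_id, src, snk,
                                 [_flip_path(p) for p in obj.alleles],
                                 obj.is_complex)
            else:
                logger.warning(
                    "component %d: bubble %d attaches to node %s in an "
                    "incompatible orientation; chain truncated",
                    comp_id, obj.bubble_id, n)
                chain.truncated = True
                break
            chain.linking.append(seg)
            chain.bubbles.append(cb)
            cur = cb.sink
            seg = [cur]
        else:
            a, oa, b, ob = obj
            if (a, oa) == cur:
                cur = (b, ob)
            elif (b, flip(ob)) == cur:
                cur = (a, flip(oa))
            else:
                logger.warning(
                    "component %d: edge %s leaves node %s against the walk "
                    "orientation; chain truncated", comp_id, obj, n)
                chain.truncated = True
                break
            seg.append(cur)
    chain.linking.append(seg)
    return chain


def chain_bubbles(graph: SequenceGraph, bubbles: Sequence[Bubble]) -> List[BubbleChain]:
    """Order each component's bubbles into a chain by walking its backbone.

    The chain starts at the lexicographically smallest backbone endpoint,
    which fixes the traversal direction deterministically.
    """
    if not graph.component_id and graph.nodes:
        graph.label_components()
    by_comp: Dict[int, List[Bubble]] = {}
    for b in bubbles:
        by_comp.setdefault(graph.component_id[b.source[0]], []).append(b)
    comp_nodes: Dict[int, List[str]] = {}
    for n, c in graph.component_id.items():
        comp_nodes.setdefault(c, []).append(n)
    chains = []
    for comp in sorted(comp_nodes):
        chains.append(_chain_one_component(
            comp, sorted(comp_nodes[comp]), graph,
            sorted(by_comp.get(comp, []), key=lambda b: b.bubble_id)))
    return chains
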