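"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from its definition by exhaustive
enumeration, deliberately sharing no code with the implementation paths
it checks.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Set, Tuple

from hicphase.graph_io import SequenceGraph, flip

Oriented = Tuple[str, str]


def _directed_view(graph: SequenceGraph):
    adj: Dict[Oriented, Set[Oriented]] = {(n, o): set() for n in graph.nodes
                                          for o in "+-"}
    for (a, oa, b, ob) in graph.edges:
        adj[(a, oa)].add((b, ob))
        adj[(b, flip(ob))].add((a, flip(oa)))
    radj: Dict[Oriented, Set[Oriented]] = {v: set() for v in adj}
    for v, cs in adj.items():
        for u in cs:
            radj[u].add(v)
    return adj, radj


def _reach(start: Oriented, stop: Oriented, adj) -> Set[Oriented]:
    """Vertices reachable from start without expanding stop."""
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        if v == stop:
            continue
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return seen


def _is_acyclic(nodes: Set[Oriented], adj, s: Oriented, t: Oriented) -> bool:
    sub = {v: [u for u in adj[v] if u in nodes and u != s] for v in nodes}
    sub[t] = []
    color: Dict[Oriented, int] = {}

    def dfs(v) -> bool:
        color[v] = 1
        for u in sub[v]:
            c = color.get(u, 0)
            if c == 1:
                return False
            if c == 0 and not dfs(u):
                return False
        color[v] = 2
        return True

    return all(color.get(v, 0) or dfs(v) for v in nodes)


def _interior_paths(s: Oriented, t: Oriented, interior: Set[Oriented],
                    adj, cap: int = 64) -> List[Tuple[Oriented, ...]]:
    paths: List[Tuple[Oriented, ...]] = []

    def walk(v, acc):
        if len(paths) > cap:
            return
        for u in sorted(adj[v]):
            if u == t:
                paths.append(tuple(acc))
            elif u in interior and u not in acc:
                walk(u, acc + [u])

    walk(s, [])
    return paths


def brute_force_bubbles(graph: SequenceGraph
                        ) -> List[Tuple[Oriented, Oriented, frozenset]]:
    """All minimal innermost bubbles by testing every oriented pair.

    Checks the superbubble definition by exhaustive reachability:
    reachable-set matching, interior acyclicity, no sink-to-source edge,
    no node in both orientations, at least two source-to-sink paths.
    Minimality is enforced per source (smallest vertex set), mirror
    duplicates are collapsed, and only innermost candidates (pairwise
    disjoint interiors) survive -- the same conventions the detector
    documents.
    """
    adj, radj = _directed_view(graph)
    verts = sorted(adj)
    per_source: Dict[Oriented, Tuple[int, Oriented, Set[Oriented]]] = {}
    for s in verts:
        for t in verts:
            if s == t or s[0] == t[0]:
                continue
            fwd = _reach(s, t, adj)
            if t not in fwd:
                continue
            bwd = _reach(t, s, radj)
            if s not in bwd or fwd != bwd:
                continue
            names = [v[0] for v in fwd]
            if len(names) != len(set(names)):
                continue  # a node in both orientations
            if s in adj[t]:
                continue
            if len(fwd) < 3:
                continue  # no interior
            if not _is_acyclic(fwd, adj, s, t):
                continue
            interior = fwd - {s, t}
            if len(_interior_paths(s, t, interior, adj, cap=4)) < 2:
                continue
            cur = per_source.get(s)
            cand = (len(fwd), t, fwd)
            if cur is None or cand[:2] < cur[:2]:
                per_source[s] = cand
    # mirror dedup
    cands: Dict[Tuple[Oriented, Oriented], Set[Oriented]] = {}
    for s, (_, t, fwd) in per_source.items():
        mirror = ((t[0], flip(t[1])), (s[0], flip(s[1])))
        if (s, t) <= mirror:
            cands.setdefault((s, t), fwd)
        else:
            cands.setdefault(mirror, {(n, flip(o)) for n, o in fwd})
    # innermost filter
    out = []
    used_interior: Set[str] = set()
    used_ends: Set[str] = set()
    for key in sorted(cands, key=lambda k: (len(cands[k]), k)):
        s, t = key
        interior = {n for n, _ in cands[key]} - {s[0], t[0]}
        if interior & used_interior or interior & used_ends:
            continue
        if s[0] in used_interior or t[0] in used_interior:
            continue
        out.append((s, t, frozenset(interior)))
        used_interior |= interior
        used_ends |= {s[0], t[0]}
    return sorted(out)


def brute_force_components(graph: SequenceGraph) -> Dict[str, int]:
    """Union-find over edge endpoints, labels ordered by smallest member."""
    parent = {n: n for n in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, _, b, _) in graph.edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: Dict[str, List[str]] = {}
    for n in graph.nodes:
        groups.setdefault(find(n), []).append(n)
    ordered = sorted(groups.values(), key=min)
    return {n: i for i, grp in enumerate(ordered) for n in grp}


def brute_force_phase(chain_bubbles_ids: List[int],
                      cfg_counts: Dict[Tuple[Tuple[int, int], Tuple[int, int]], int]
                      ) -> Tuple[int, Tuple[int, ...]]:
    """Maximum total satisfied link support over all 2^n allele assignments.

    ``cfg_counts`` maps ((bubble_i, allele_i), (bubble_j, allele_j)) to a
    read count; an assignment x (allele chosen for haplotype 1 at each
    bubble) satisfies the count when the pairing is consistent with it.
    """
    n = len(chain_bubbles_ids)
    pos = {b: i for i, b in enumerate(chain_bubbles_ids)}
    best, best_x = -1, None
    for bits in itertools.product((0, 1), repeat=n):
        score = 0
        for ((bi, ai), (bj, aj)), c in cfg_counts.items():
            same = (ai == bits[pos[bi]]) == (aj == bits[pos[bj]])
            if same:
                score += c
        if score > best:
            best, best_x = score, bits
    return best, best_x


def _has_spanning_path(members: Tuple[int, ...],
                       weight: Dict[Tuple[int, int], int]) -> bool:
    if len(members) <= 1:
        return True
    for perm in itertools.permutations(members):
        if perm[0] > perm[-1]:
            continue
        if all(weight.get((min(a, b), max(a, b)), 0) > 0
               for a, b in zip(perm, perm[1:])):
            return True
    return False


def brute_force_partition(contigs: List[int],
                          weight: Dict[Tuple[int, int], int]
                          ) -> Tuple[int, List[Tuple[int, ...]]]:
    """Exhaustive set-partition optimum of total intra-partition support.

    Only partitions whose every class admits a spanning path through
    positive-support edges (the neighbour-degree constraint of the
    greedy) are feasible.
    """
    n = len(contigs)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for sub in partitions(rest):
            for i in range(len(sub)):
                yield sub[:i] + [sub[i] + (first,)] + sub[i + 1:]
            yield sub + [(first,)]

    best, best_parts = -1, None
    for parts in partitions(list(contigs)):
        if not all(_has_spanning_path(cls, weight) for cls in parts):
            continue
        score = 0
        for cls in parts:
            for a, b in itertools.combinations(sorted(cls), 2):
                score += weight.get((a, b), 0)
        if score > best:
            best, best_parts = score, [tuple(sorted(c)) for c in parts]
    return best, sorted(best_parts)


def brute_force_ng50(lengths: List[int], G: int) -> int:
    """NG50 from the definition: largest L with >= G/2 covered by >= L."""
    best = 0
    for L in sorted(set(lengths)):
        covered = sum(x for x in lengths if x >= L)
        if 2 * covered >= G:
            best = max(best, L)
    return best
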