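"""Core assembly-graph data model and readers/writers for GFA1, FASTA, FASTQ.

The graph is bidirected: every node (contig/unitig sequence) can be walked
in forward (+) or reverse-complement (-) orientation, and an edge
``(a, +, b, +)`` is the same object as its mirror ``(b, -, a, -)``.  Only
the GFA1 dialect that HiFi assemblers emit is supported: S and L records,
overlaps written as ``<n>M``.  Coordinates are 0-based half-open
throughout; conversion happens only at format boundaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Tuple

import networkx as nx
from Bio import SeqIO

FWD = "+"
REV = "-"

OrientedNode = Tuple[str, str]
EdgeKey = Tuple[str, str, str, str]


class FormatError(ValueError):
    """Raised for malformed GFA/FASTA/FASTQ input."""


def flip(orient: str) -> str:
    return REV if orient == FWD else FWD


def canonical_edge(a: str, oa: str, b: str, ob: str) -> EdgeKey:
    """Canonical representative of a bidirected edge and its mirror."""
    e = (a, oa, b, ob)
    m = (b, flip(ob), a, flip(oa))
    return e if e <= m else m


_VALID_BASES = frozenset("ACGTN")


@dataclass
class SequenceGraph:
    """Bidirected assembly graph: node sequences plus oriented overlaps."""

    nodes: Dict[str, str] = field(default_factory=dict)
    edges: Dict[EdgeKey, int] = field(default_factory=dict)
    component_id: Dict[str, int] = field(default_factory=dict)

    def add_node(self, name: str, seq: str) -> None:
        if name in self.nodes:
            raise FormatError(f"duplicate segment name {name!r}")
        seq = seq.upper()
        if not seq:
            raise FormatError(f"segment {name!r} has an empty sequence")
        if not _VALID_BASES.issuperset(seq):
            bad = sorted(set(seq) - _VALID_BASES)
            raise FormatError(f"segment {name!r} contains invalid characters {bad}")
        self.nodes[name] = seq

    def add_edge(self, a: str, oa: str, b: str, ob: str, overlap: int = 0) -> None:
        for n in (a, b):
            if n not in self.nodes:
                raise FormatError(f"link references unknown segment {n!r}")
        if oa not in (FWD, REV) or ob not in (FWD, REV):
            raise FormatError(f"bad orientation in link {a} {oa} {b} {ob}")
        if overlap < 0:
            raise FormatError("negative overlap")
        self.edges[canonical_edge(a, oa, b, ob)] = overlap

    def has_edge(self, a: str, oa: str, b: str, ob: str) -> bool:
        return canonical_edge(a, oa, b, ob) in self.edges

    def overlap(self, a: str, oa: str, b: str, ob: str) -> int:
        return self.edges[canonical_edge(a, oa, b, ob)]

    def label_components(self) -> None:
        """Label connected components 0..n-1, ordered by smallest node id."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e[0], e[2]) for e in self.edges)
        comps = sorted((sorted(c) for c in nx.connected_components(g)),
                       key=lambda c: c[0])
        self.component_id = {n: i for i, c in enumerate(comps) for n in c}

    def directed_adjacency(self) -> Dict[OrientedNode, List[OrientedNode]]:
        """Doubled directed view over oriented nodes.

        Each bidirected edge contributes the directed arc (a,oa)->(b,ob)
        and its mirror (b,~ob)->(a,~oa); self-mirror edges contribute once.
        """
        adj: Dict[OrientedNode, List[OrientedNode]] = {
            (n, o): [] for n in self.nodes for o in (FWD, REV)
        }
        for (a, oa, b, ob) in self.edges:
            adj[(a, oa)].append((b, ob))
            if (b, flip(ob)) != (a, oa) or (a, flip(oa)) != (b, ob):
                adj[(b, flip(ob))].append((a, flip(oa)))
        for v in adj.values():
            v.sort()
        return adj


@dataclass
class ReadPair:
    """One Hi-C read pair; qualities are irrelevant to k-mer matching."""

    pair_id: str
    seq1: str
    seq2: str


# ---------------------------------------------------------------------------
# GFA1


def read_gfa(path) -> SequenceGraph:
    """Read a GFA1 graph (S and L records; other record types are ignored)."""
    graph = SequenceGraph()
    links: List[Tuple[int, str, str, str, str, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] not in "SL":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3 or not fields[2] or fields[2] == "*":
                    raise FormatError(f"line {ln}: S record without a sequence")
                try:
                    graph.add_node(fields[1], fields[2])
                except FormatError as exc:
                    raise FormatError(f"line {ln}: {exc}") from None
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise FormatError(f"line {ln}: truncated L record")
                cigar = fields[5]
                if cigar in ("*", "0M"):
                    ov = 0
                elif cigar.endswith("M") and cigar[:-1].isdigit():
                    ov = int(cigar[:-1])
                else:
                    raise FormatError(
                        f"line {ln}: unsupported overlap {cigar!r} (only <n>M)")
                links.append((ln, fields[1], fields[2], fields[3], fields[4], ov))
    for ln, a, oa, b, ob, ov in links:
        try:
            graph.add_edge(a, oa, b, ob, ov)
        except FormatError as exc:
            raise FormatError(f"line {ln}: {exc}") from None
    graph.label_components()
    return graph


def write_gfa(graph: SequenceGraph, path) -> None:
    """Write S/L records with deterministic (lexicographic) ordering."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for name in sorted(graph.nodes):
            fh.write(f"S\t{name}\t{graph.nodes[name]}\n")
        for (a, oa, b, ob) in sorted(graph.edges):
            ov = graph.edges[(a, oa, b, ob)]
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t{ov}M\n")


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def _norm_read_id(rid: str) -> str:
    rid = rid.split()[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Stream synchronized R1/R2 FASTQ files as ReadPairs, in file order."""
    with open(path1) as fh1, open(path2) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        try:
            for r1, r2 in itertools.zip_longest(it1, it2):
                if r1 is None or r2 is None:
                    raise FormatError(
                        f"desynchronized FASTQ pair: {path1} and {path2} "
                        "have different record counts")
                id1, id2 = _norm_read_id(r1.id), _norm_read_id(r2.id)
                if id1 != id2:
                    raise FormatError(
                        f"desynchronized FASTQ pair: {r1.id!r} vs {r2.id!r}")
                s1, s2 = str(r1.seq).upper(), str(r2.seq).upper()
                if not s1 or not s2:
                    raise FormatError(f"empty read in pair {id1!r}")
                yield ReadPair(id1, s1, s2)
        except ValueError as exc:  # Biopython: truncated/corrupt record
            if isinstance(exc, FormatError):
                raise
            raise FormatError(str(exc)) from None


def write_fastq_pairs(pairs, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = "I" * len(p.seq1)
            q2 = "I" * len(p.seq2)
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{q2}\n")


def read_fasta(path) -> Dict[str, str]:
    """Read FASTA into name -> uppercase sequence; duplicate names error."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise FormatError(f"duplicate FASTA record name {rec.id!r}")
            out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")
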