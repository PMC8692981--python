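"""Scaffold-junction graph from long reads spanning terminal anchors.

A fixed-length window at each scaffold end (default 500 bp) is the terminal
anchor. Long reads are aligned to the anchors; a read whose consecutive
anchor hits leave one scaffold and enter another with a small gap evidences
that junction, and junctions are aggregated into a weighted graph whose edge
support is the set of spanning-read ids.

Orientation convention: each scaffold end is (id, 'head'|'tail'); a junction
is an unordered pair of ends. A traversal entering the head exits the tail
(forward) and vice versa — the standard bidirected assembly-graph encoding,
which keeps inverted-repeat flip-flop representable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median

from .align import SeedIndex, kmer_seed_index, local_align
from .sequtil import Scaffold, round_half_up

__all__ = [
    "Anchor",
    "AnchorHit",
    "JunctionObservation",
    "JunctionGraph",
    "extract_anchors",
    "map_reads_to_anchors",
    "call_spanning",
    "build_graph",
    "flag_repeat_nodes",
]

End = tuple[str, str]


@dataclass
class Anchor:
    """A terminal window of one scaffold."""

    scaffold_id: str
    side: str  # 'head' | 'tail'
    interval: tuple[int, int]  # on the scaffold, 0-based half-open
    sequence: str
    short: bool = False  # scaffold shorter than two full anchors

    @property
    def key(self) -> str:
        return f"{self.scaffold_id}|{self.side}"


def _as_scaffold_dict(scaffolds) -> dict[str, str]:
    if isinstance(scaffolds, dict):
        return {
            k: (v.seq if isinstance(v, Scaffold) else v) for k, v in scaffolds.items()
        }
    return {s.id: s.seq for s in scaffolds}


def extract_anchors(scaffolds, anchor_len: int = 500) -> list[Anchor]:
    """Two anchors per scaffold: head [0, La) and tail [L-La, L).

    Scaffolds shorter than two anchor lengths yield overlapping anchors
    flagged ``short``; scaffolds shorter than one anchor use the whole
    sequence for both.
    """
    if anchor_len < 50:
        raise ValueError(f"anchor_len must be >= 50, got {anchor_len}")
    seqs = _as_scaffold_dict(scaffolds)
    if not seqs:
        raise ValueError("no scaffolds given")
    anchors = []
    for sid, seq in seqs.items():
        L = len(seq)
        la = min(anchor_len, L)
        short = L < 2 * anchor_len
        anchors.append(Anchor(sid, "head", (0, la), seq[:la], short))
        anchors.append(Anchor(sid, "tail", (L - la, L), seq[L - la :], short))
    return anchors


@dataclass
class AnchorHit:
    """One anchor alignment on a read, with the scaffold-terminus position.

    ``terminus_pos`` extrapolates the read coordinate of the scaffold end the
    anchor represents (head: anchor coordinate 0; tail: anchor length), which
    is where a junction with the neighboring scaffold sits on the read.
    """

    scaffold_id: str
    side: str
    strand: str
    read_interval: tuple[int, int]
    identity: float
    terminus_pos: int

    @property
    def end(self) -> End:
        return (self.scaffold_id, self.side)

    @property
    def can_exit(self) -> bool:
        """Read leaves the scaffold right after this hit."""
        return (self.strand == "+") == (self.side == "tail")

    @property
    def can_enter(self) -> bool:
        """Read enters the scaffold at this hit."""
        return (self.strand == "+") == (self.side == "head")


def map_reads_to_anchors(
    long_reads,
    anchors: list[Anchor],
    min_identity: float = 80.0,
    k: int = 13,
    index: SeedIndex | None = None,
) -> dict[str, list[AnchorHit]]:
    """Per-read anchor hit chains, ordered by read coordinate.

    Hits below ``min_identity`` or shorter than half the anchor length are
    discarded. Returns only reads with at least one retained hit.
    """
    by_key = {a.key: a for a in anchors}
    if index is None:
        index = kmer_seed_index({a.key: a.sequence for a in anchors}, k)
    reads = long_reads if isinstance(long_reads, dict) else dict(long_reads)
    chains: dict[str, list[AnchorHit]] = {}
    for rid, seq in reads.items():
        hits = []
        alns = local_align(
            (rid, seq), index=index, min_identity=min_identity, min_length=50
        )
        for a in alns:
            anchor = by_key[a.target_id]
            la = len(anchor.sequence)
            if a.target_span < 0.5 * la:
                continue
            qs, qe = a.query_interval
            ts, te = a.target_interval
            if anchor.side == "tail":
                # read coordinate of anchor coordinate La
                term = qe + (la - te) if a.strand == "+" else qs - (la - te)
            else:
                # read coordinate of anchor coordinate 0
                term = qs - ts if a.strand == "+" else qe + ts
            hits.append(
                AnchorHit(
                    anchor.scaffold_id,
                    anchor.side,
                    a.strand,
                    (qs, qe),
                    a.identity,
                    term,
                )
            )
        if hits:
            hits.sort(key=lambda h: h.read_interval)
            chains[rid] = hits
    return chains


@dataclass
class JunctionObservation:
    """One read spanning the junction between two scaffold ends."""

    read_id: str
    left: End
    right: End
    gap_estimate: int  # bp between the two termini; negative = overlap


def call_spanning(
    hit_chains: dict[str, list[AnchorHit]], max_gap: int = 500
) -> list[JunctionObservation]:
    """Junction observations from consecutive anchor hits on each read.

    A pair qualifies when the first hit exits its scaffold, the second enters
    its scaffold, and the extrapolated termini are within ``max_gap`` bp.
    The within-scaffold head->tail continuation of a fully traversed scaffold
    is not a junction.
    """
    obs = []
    for rid, chain in hit_chains.items():
        for h1, h2 in zip(chain, chain[1:]):
            if h1.scaffold_id == h2.scaffold_id and h1.strand == h2.strand:
                inner = (h1.side, h2.side) == (
                    ("head", "tail") if h1.strand == "+" else ("tail", "head")
                )
                if inner:
                    continue
            if not (h1.can_exit and h2.can_enter):
                continue
            gap = h2.terminus_pos - h1.terminus_pos
            if abs(gap) > max_gap:
                continue
            obs.append(JunctionObservation(rid, h1.end, h2.end, gap))
    return obs


@dataclass
class JunctionGraph:
    """Weighted scaffold-end adjacency graph.

    ``nodes`` maps scaffold id -> copy number (1 until depth evidence raises
    it); ``edges`` maps an unordered end pair (frozenset of (id, side)) to
    the set of supporting read ids.
    """

    nodes: dict[str, int] = field(default_factory=dict)
    edges: dict[frozenset, set[str]] = field(default_factory=dict)
    repeat_flags: set[str] = field(default_factory=set)

    def count(self, end1: End, end2: End) -> int:
        return len(self.edges.get(frozenset((end1, end2)), ()))

    def neighbors(self, end: End) -> set[End]:
        out = set()
        for e in self.edges:
            ends = tuple(e)
            if len(ends) == 1 and ends[0] == end:
                out.add(end)
            elif end in ends:
                out.add(ends[0] if ends[1] == end else ends[1])
        return out

    def to_edge_rows(self) -> list[tuple]:
        rows = []
        for e, ids in sorted(self.edges.items(), key=lambda kv: sorted(kv[0])):
            ends = sorted(e)
            a = ends[0]
            b = ends[-1]
            rows.append((a[0], a[1], b[0], b[1], len(ids), ",".join(sorted(ids))))
        return rows

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("end1_scaffold\tend1_side\tend2_scaffold\tend2_side"
                     "\tcount\tread_ids\n")
            for row in self.to_edge_rows():
                fh.write("\t".join(str(x) for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "JunctionGraph":
        g = cls()
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("end1_scaffold")
            for line in fh:
                s1, d1, s2, d2, _count, ids = line.rstrip("\n").split("\t")
                key = frozenset(((s1, d1), (s2, d2)))
                g.edges[key] = set(ids.split(",")) if ids else set()
                g.nodes.setdefault(s1, 1)
                g.nodes.setdefault(s2, 1)
        return g

    def to_gfa(self, path, scaffold_seqs: dict[str, str] | None = None) -> None:
        """GFA1 segment/link text for external viewers."""
        with open(path, "w") as fh:
            fh.write("H\tVN:Z:1.0\n")
            for sid in sorted(self.nodes):
                seq = scaffold_seqs.get(sid, "*") if scaffold_seqs else "*"
                fh.write(f"S\t{sid}\t{seq}\tDP:i:{self.nodes[sid]}\n")
            for e, ids in sorted(self.edges.items(), key=lambda kv: sorted(kv[0])):
                ends = sorted(e)
                (s1, d1), (s2, d2) = ends[0], ends[-1]
                o1 = "+" if d1 == "tail" else "-"
                o2 = "+" if d2 == "head" else "-"
                fh.write(f"L\t{s1}\t{o1}\t{s2}\t{o2}\t0M\tRC:i:{len(ids)}\n")


def build_graph(
    observations: list[JunctionObservation],
    scaffolds=None,
    min_support: int = 2,
) -> JunctionGraph:
    """Aggregate observations into a graph; edges with fewer than
    ``min_support`` distinct supporting reads are dropped (a single chimeric
    long read must not create an edge)."""
    agg: dict[frozenset, set[str]] = defaultdict(set)
    nodes: dict[str, int] = {}
    if scaffolds is not None:
        for sid in _as_scaffold_dict(scaffolds):
            nodes[sid] = 1
    for o in observations:
        agg[frozenset((o.left, o.right))].add(o.read_id)
        nodes.setdefault(o.left[0], 1)
        nodes.setdefault(o.right[0], 1)
    edges = {e: ids for e, ids in agg.items() if len(ids) >= min_support}
    return JunctionGraph(nodes=nodes, edges=edges)


def flag_repeat_nodes(graph: JunctionGraph, depth_table) -> JunctionGraph:
    """Set copy numbers from depth ratios and flag two-copy repeat scaffolds.

    Copy number is the rounded ratio of a scaffold's median depth to the
    single-copy baseline (floor 1). A scaffold is flagged repeat when its
    rounded ratio reaches 2, or when the ratio is >= 1.5 and one of its ends
    shows two or more distinct neighbor contexts (the signature of a repeat
    used in two genomic places).
    """
    depths = _depths_of(depth_table)
    for sid in graph.nodes:
        if sid not in depths:
            raise KeyError(f"no depth entry for scaffold {sid!r}")
    baseline = _baseline_of(depth_table, depths)
    out = JunctionGraph(dict(graph.nodes), dict(graph.edges), set(graph.repeat_flags))
    for sid in out.nodes:
        ratio = depths[sid] / baseline if baseline > 0 else 1.0
        copy = max(1, int(round_half_up(ratio, 0)))
        multi_context = any(
            len(out.neighbors((sid, side))) >= 2 for side in ("head", "tail")
        )
        if copy >= 2 or (ratio >= 1.5 and multi_context):
            out.nodes[sid] = max(copy, 2)
            out.repeat_flags.add(sid)
        else:
            out.nodes[sid] = 1
    return out


def _depths_of(depth_table) -> dict[str, float]:
    if isinstance(depth_table, dict):
        return depth_table
    return {sid: row.median for sid, row in depth_table.per_scaffold.items()}


def _baseline_of(depth_table, depths: dict[str, float]) -> float:
    if hasattr(depth_table, "baseline"):
        return depth_table.baseline
    vals = sorted(depths.values())
    base0 = median(vals)
    single = [v for v in vals if base0 == 0 or v / base0 < 1.5]
    return median(single) if single else base0
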