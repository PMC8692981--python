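"""Circular conformations of a multipartite mitogenome and their algebra.

A plant mitochondrial genome with long (>1 kb) two-copy repeats does not have
a single structure: homologous recombination across a *direct* repeat pair
fuses two circles into one (or splits one into two, the reverse), and
recombination across an *inverted* pair reverse-complements the segment
between the copies ("flip-flop"), leaving circle count and length unchanged.
The set of conformations reachable from a base arrangement is the closure of
the base under these events; total genome length is invariant across it.

This module provides:

* ``CircularMolecule`` / ``ConformationSet`` with a rotation- and
  strand-invariant canonical form for deduplicating circular isomorphs;
* ``apply_recombination`` / ``conformation_space`` — the event algebra;
* ``decompose_circles`` — exhaustive enumeration of circular decompositions
  of a junction graph under per-scaffold copy-number capacities;
* ``estimate_mixture`` — conformation mixture frequencies from junction-
  spanning read counts;
* ``check_component_separation`` — verifies that molecule groups sharing no
  repeat stay unconnected (the paper-scale genomes split into independent
  "master ring" components).

Unit strands are +1/-1; a traversal entering a scaffold's head end exits its
tail (+1) and vice versa (-1).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from math import gcd

__all__ = [
    "CircularMolecule",
    "ConformationSet",
    "RecombinationEvent",
    "RepeatUnit",
    "MixtureEstimate",
    "SeparationReport",
    "apply_recombination",
    "conformation_space",
    "decompose_circles",
    "estimate_mixture",
    "molecule_length",
    "check_component_separation",
]

SignedUnit = tuple[str, int]
End = tuple[str, str]  # (scaffold id, 'head'|'tail')


def exit_end(unit: str, sign: int) -> End:
    return (unit, "tail" if sign > 0 else "head")


def entry_end(unit: str, sign: int) -> End:
    return (unit, "head" if sign > 0 else "tail")


@dataclass(frozen=True)
class RepeatUnit:
    """A >1 kb two-copy segment, the recombination substrate.

    ``kind`` is 'direct' when the copies lie in the same orientation along
    their host circle(s), 'inverted' otherwise. ``copy_locations`` holds two
    (molecule, (start, end), strand) entries when known.
    """

    id: str
    length: int
    kind: str  # 'direct' | 'inverted'
    copy_locations: tuple = ()

    def __post_init__(self):
        if self.kind not in ("direct", "inverted"):
            raise ValueError(f"repeat kind must be direct|inverted, got {self.kind!r}")


@dataclass(frozen=True)
class CircularMolecule:
    """A circular, signed ordering of scaffold units."""

    units: tuple[SignedUnit, ...]

    def __post_init__(self):
        if not self.units:
            raise ValueError("a circular molecule must contain at least one unit")

    def canonical(self) -> tuple[SignedUnit, ...]:
        """Lexicographically smallest rotation over both strand readings."""
        readings = [self.units, tuple((u, -s) for u, s in reversed(self.units))]
        best = None
        for r in readings:
            n = len(r)
            for i in range(n):
                cand = r[i:] + r[:i]
                if best is None or cand < best:
                    best = cand
        return best

    def length(self, unit_lengths: dict[str, int]) -> int:
        return molecule_length(self, unit_lengths)

    def occurrences(self, unit: str) -> list[tuple[int, int]]:
        """(position, sign) of every traversal of ``unit``."""
        return [(i, s) for i, (u, s) in enumerate(self.units) if u == unit]


def molecule_length(molecule: CircularMolecule, unit_lengths: dict[str, int]) -> int:
    """Sum of constituent unit lengths, repeats counted per traversal."""
    total = 0
    for u, _ in molecule.units:
        if u not in unit_lengths:
            raise KeyError(f"unknown unit {u!r} in molecule")
        total += unit_lengths[u]
    return total


@dataclass
class ConformationSet:
    """One genome-wide set of circular molecules."""

    molecules: list[CircularMolecule]
    provenance: list["RecombinationEvent"] = field(default_factory=list)

    def signature(self) -> tuple:
        return tuple(sorted(m.canonical() for m in self.molecules))

    def total_length(self, unit_lengths: dict[str, int]) -> int:
        return sum(m.length(unit_lengths) for m in self.molecules)

    def unit_copy_counts(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for m in self.molecules:
            for u, _ in m.units:
                counts[u] += 1
        return dict(counts)

    def adjacency_edges(self) -> set[frozenset]:
        """Unordered scaffold-end pairs realized by this conformation."""
        edges = set()
        for m in self.molecules:
            n = len(m.units)
            for i in range(n):
                u, s = m.units[i]
                v, t = m.units[(i + 1) % n]
                edges.add(frozenset((exit_end(u, s), entry_end(v, t))))
        return edges

    def through_pairs(self, unit: str) -> frozenset:
        """For a two-copy unit: which entry edge pairs with which exit edge.

        Direct-repeat fused and split states realize the *same* junction edge
        set and differ only in these pairings, so they are the discriminating
        feature for mixture estimation.
        """
        pairs = set()
        for m in self.molecules:
            n = len(m.units)
            for i, s in m.occurrences(unit):
                pu, ps = m.units[(i - 1) % n]
                nu, ns = m.units[(i + 1) % n]
                e_in = frozenset((exit_end(pu, ps), entry_end(unit, s)))
                e_out = frozenset((exit_end(unit, s), entry_end(nu, ns)))
                pairs.add(frozenset((e_in, e_out)))
        return frozenset(pairs)


@dataclass(frozen=True)
class RecombinationEvent:
    """One homologous-recombination event on a two-copy repeat."""

    repeat_id: str
    mechanism: str  # 'fusion' | 'fission' | 'inversion'

    def __post_init__(self):
        if self.mechanism not in ("fusion", "fission", "inversion"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


def _rotate_to_plus(mol: CircularMolecule, unit: str) -> tuple[SignedUnit, ...]:
    """Rotation starting at a +1 traversal of ``unit`` (flip strand if needed)."""
    for i, s in mol.occurrences(unit):
        if s > 0:
            return mol.units[i:] + mol.units[:i]
    flipped = tuple((u, -s) for u, s in reversed(mol.units))
    for i, (u, s) in enumerate(flipped):
        if u == unit and s > 0:
            return flipped[i:] + flipped[:i]
    raise ValueError(f"unit {unit!r} not found in molecule")


def apply_recombination(
    state: ConformationSet, event: RecombinationEvent, repeat: RepeatUnit | None = None
) -> ConformationSet:
    """Apply one event; returns a new conformation (the input is not mutated).

    fusion: two circles each holding one copy of a direct repeat merge into
    one circle holding both copies; fission is the exact inverse; inversion
    (inverted repeats only) reverse-complements the arc strictly between the
    two copies of one circle, preserving circle count and length.
    """
    r = event.repeat_id
    if repeat is not None:
        want = {"fusion": "direct", "fission": "direct", "inversion": "inverted"}
        if repeat.kind != want[event.mechanism]:
            raise ValueError(
                f"{event.mechanism} requires a {want[event.mechanism]} repeat; "
                f"{r} is {repeat.kind}"
            )
    holders = [
        (mi, m.occurrences(r)) for mi, m in enumerate(state.molecules)
        if m.occurrences(r)
    ]
    occ_total = sum(len(o) for _, o in holders)
    if occ_total != 2:
        raise ValueError(f"repeat {r!r} must have exactly 2 copies, found {occ_total}")

    mols = list(state.molecules)
    if event.mechanism == "fusion":
        if len(holders) != 2:
            raise ValueError(f"fusion requires copies of {r!r} on two molecules")
        (ia, _), (ib, _) = holders
        ra = _rotate_to_plus(mols[ia], r)
        rb = _rotate_to_plus(mols[ib], r)
        fused = CircularMolecule(ra + rb)
        new = [m for i, m in enumerate(mols) if i not in (ia, ib)] + [fused]
    elif event.mechanism == "fission":
        if len(holders) != 1:
            raise ValueError(f"fission requires both copies of {r!r} on one molecule")
        mi = holders[0][0]
        units = _rotate_to_plus(mols[mi], r)
        second = [i for i, (u, s) in enumerate(units) if u == r and i > 0]
        if not second or units[second[0]][1] < 0:
            raise ValueError(
                f"fission on {r!r} requires same-orientation copies on the circle"
            )
        p = second[0]
        new = [m for i, m in enumerate(mols) if i != mi]
        new += [CircularMolecule(units[:p]), CircularMolecule(units[p:])]
    else:  # inversion
        if len(holders) != 1:
            raise ValueError(f"inversion requires both copies of {r!r} on one molecule")
        mi = holders[0][0]
        units = _rotate_to_plus(mols[mi], r)
        second = [i for i, (u, s) in enumerate(units) if u == r and i > 0]
        if not second or units[second[0]][1] > 0:
            raise ValueError(
                f"inversion on {r!r} requires opposite-orientation copies"
            )
        p = second[0]
        arc = tuple((u, -s) for u, s in reversed(units[1:p]))
        new = [m for i, m in enumerate(mols) if i != mi]
        new.append(CircularMolecule(units[:1] + arc + units[p:]))
    return ConformationSet(new, provenance=state.provenance + [event])


def _valid_events(
    state: ConformationSet, repeats: list[RepeatUnit]
) -> list[RecombinationEvent]:
    events = []
    for rep in repeats:
        holders = [m for m in state.molecules if m.occurrences(rep.id)]
        occs = [s for m in holders for _, s in m.occurrences(rep.id)]
        if len(occs) != 2:
            continue
        if rep.kind == "direct":
            if len(holders) == 2:
                events.append(RecombinationEvent(rep.id, "fusion"))
            elif _same_orientation(holders[0], rep.id):
                events.append(RecombinationEvent(rep.id, "fission"))
        else:
            if len(holders) == 1 and not _same_orientation(holders[0], rep.id):
                events.append(RecombinationEvent(rep.id, "inversion"))
    return events


def _same_orientation(mol: CircularMolecule, unit: str) -> bool:
    signs = [s for _, s in mol.occurrences(unit)]
    return signs[0] == signs[1]


def conformation_space(
    base: ConformationSet, repeats: list[RepeatUnit]
) -> list[ConformationSet]:
    """Closure of ``base`` under all single recombination events (BFS).

    States are deduplicated by canonical form; the base state comes first and
    each state's provenance records one shortest event path from the base.
    """
    rep_by_id = {r.id: r for r in repeats}
    seen = {base.signature()}
    out = [base]
    frontier = [base]
    while frontier:
        nxt = []
        for state in frontier:
            for ev in _valid_events(state, repeats):
                new = apply_recombination(state, ev, rep_by_id[ev.repeat_id])
                sig = new.signature()
                if sig not in seen:
                    seen.add(sig)
                    out.append(new)
                    nxt.append(new)
        frontier = nxt
    return out


# ---------------------------------------------------------------------------
# Circular decomposition of a junction graph
# ---------------------------------------------------------------------------


class GraphStructureError(ValueError):
    """A scaffold end cannot participate in any circular traversal."""


def _graph_parts(graph):
    """Duck-typed access: copy-number dict and edge set of end pairs."""
    nodes = dict(graph.nodes)
    edges = set(graph.edges) if not isinstance(graph.edges, (set, frozenset)) else set(
        graph.edges
    )
    return nodes, edges


def decompose_circles(graph, max_results: int = 100000) -> list[ConformationSet]:
    """All decompositions of a junction graph into circular molecules.

    Every scaffold is traversed exactly copy-number times (single-copy once,
    repeats twice), every traversal enters one end and exits the other, and
    consecutive traversals must be linked by an observed junction edge.
    Exhaustive backtracking with canonical start pruning; results are
    deduplicated by canonical form. Returns [] when no decomposition exists.
    """
    nodes, edges = _graph_parts(graph)
    if not nodes:
        return []
    adj: dict[End, list[End]] = defaultdict(list)
    for e in edges:
        ends = tuple(e)
        a, b = (ends[0], ends[0]) if len(ends) == 1 else ends
        adj[a].append(b)
        if a != b:
            adj[b].append(a)
    for s in nodes:
        for side in ("head", "tail"):
            if (s, side) not in adj:
                raise GraphStructureError(
                    f"scaffold {s!r} end {side!r} has no incident junction edge"
                )
    for ends_list in adj.values():
        ends_list.sort()

    cap = {(s, side): nodes[s] for s in nodes for side in ("head", "tail")}
    used: dict[End, int] = defaultdict(int)
    rem = dict(nodes)
    order = sorted(nodes)
    results: dict[tuple, ConformationSet] = {}
    circles: list[list[SignedUnit]] = []

    def can_use(a: End, b: End) -> bool:
        if a == b:
            return used[a] + 2 <= cap[a]
        return used[a] < cap[a] and used[b] < cap[b]

    def consume(a: End, b: End, d: int) -> None:
        used[a] += d
        used[b] += d

    def start_circle() -> None:
        if len(results) >= max_results:
            return
        s = next((x for x in order if rem[x] > 0), None)
        if s is None:
            state = ConformationSet(
                [CircularMolecule(tuple(c)) for c in circles]
            )
            results.setdefault(state.signature(), state)
            return
        rem[s] -= 1
        circles.append([(s, 1)])
        extend((s, "head"), (s, "tail"))
        circles.pop()
        rem[s] += 1

    def extend(entry: End, cur: End) -> None:
        close = frozenset((cur, entry))
        if close in edges and can_use(cur, entry):
            consume(cur, entry, 1)
            start_circle()
            consume(cur, entry, -1)
        for nxt in adj[cur]:
            t, side = nxt
            if rem[t] <= 0 or not can_use(cur, nxt):
                continue
            sign = 1 if side == "head" else -1
            consume(cur, nxt, 1)
            rem[t] -= 1
            circles[-1].append((t, sign))
            extend(entry, exit_end(t, sign))
            circles[-1].pop()
            rem[t] += 1
            consume(cur, nxt, -1)

    start_circle()
    return list(results.values())


# ---------------------------------------------------------------------------
# Mixture estimation from junction-spanning read counts
# ---------------------------------------------------------------------------


@dataclass
class MixtureEstimate:
    """Per-state frequencies with the junction evidence behind them."""

    frequencies: list[float]
    ratio: str
    n_diagnostic_reads: int
    n_sites: int
    flags: set[str] = field(default_factory=set)
    site_details: list[dict] = field(default_factory=list)


def _ratio_string(freqs: list[float]) -> str:
    ints = [round(f * 10) for f in freqs]
    g = 0
    for v in ints:
        g = gcd(g, v)
    if g > 1:
        ints = [v // g for v in ints]
    return ":".join(str(v) for v in ints)


def estimate_mixture(graph, states: list[ConformationSet]) -> MixtureEstimate:
    """Estimate conformation frequencies from spanning-read support.

    Diagnostic evidence comes from two feature kinds: junction edges present
    in some states but not others (inverted-repeat flip-flop), and
    through-repeat pairings (direct-repeat fused vs split), supported by
    reads whose ids occur on both the entry and the exit edge of a repeat.
    Per diagnostic site, a state's share is its supporting-read count over
    the site total; overall frequencies are the mean over sites.
    """
    if len(states) < 2:
        raise ValueError("mixture estimation needs at least two states")
    nodes, _ = _graph_parts(graph)
    support = {frozenset(e): set(ids) for e, ids in graph.edges.items()}
    n_states = len(states)
    all_idx = frozenset(range(n_states))

    sites = []  # each: list of (alternative_key, state_indices, read_id_set)

    # through-pairing sites at two-copy scaffolds
    for s, copy in sorted(nodes.items()):
        if copy < 2:
            continue
        values = [st.through_pairs(s) for st in states]
        if len(set(values)) < 2:
            continue
        common = frozenset.intersection(*values)
        alts = defaultdict(list)
        for i, v in enumerate(values):
            alts[v].append(i)
        entries = []
        for v, idxs in alts.items():
            ids: set = set()
            for pair in v - common:
                e_in, e_out = tuple(pair)
                ids |= support.get(e_in, set()) & support.get(e_out, set())
            entries.append((("pairing", s), frozenset(idxs), ids))
        sites.append(entries)

    # junction-presence sites (edges distinguishing states)
    edge_sets = [st.adjacency_edges() for st in states]
    sig_groups = defaultdict(set)
    for e in set().union(*edge_sets):
        sig = frozenset(i for i, es in enumerate(edge_sets) if e in es)
        if sig != all_idx:
            sig_groups[sig].add(e)
    done = set()
    for sig, es in sorted(sig_groups.items(), key=lambda kv: sorted(kv[0])):
        comp = all_idx - sig
        if sig in done or comp not in sig_groups:
            continue
        done |= {sig, comp}
        entries = []
        for part in (sig, comp):
            ids = set()
            for e in sig_groups[part]:
                ids |= support.get(e, set())
            entries.append((("junction", tuple(sorted(part))), part, ids))
        sites.append(entries)

    flags: set[str] = set()
    freqs = [0.0] * n_states
    counted_sites = 0
    all_reads: set = set()
    details = []
    for entries in sites:
        total = sum(len(ids) for _, _, ids in entries)
        details.append(
            {key: len(ids) for key, _, ids in entries}
        )
        if total == 0:
            continue
        counted_sites += 1
        for _, idxs, ids in entries:
            all_reads |= ids
            if not ids:
                flags.add("zero_count")
            share = len(ids) / total
            for i in idxs:
                freqs[i] += share
    if counted_sites == 0:
        flags.add("undefined")
        return MixtureEstimate(
            [float("nan")] * n_states, "undefined", 0, len(sites), flags, details
        )
    freqs = [f / counted_sites for f in freqs]
    return MixtureEstimate(
        freqs, _ratio_string(freqs), len(all_reads), counted_sites, flags, details
    )


# ---------------------------------------------------------------------------
# Component separation
# ---------------------------------------------------------------------------


@dataclass
class SeparationReport:
    ok: bool
    components: list[set]
    violations: list[str]


def check_component_separation(graph, states: list[ConformationSet]) -> SeparationReport:
    """Verify that molecule groups sharing no repeat never connect.

    Components are built from the first state by linking molecules that share
    a unit (the repeat-sharing relation); violations are junction edges that
    bridge components, or any state's molecule mixing scaffolds from more
    than one component.
    """
    if not states:
        return SeparationReport(True, [], [])
    base = states[0]
    parent = list(range(len(base.molecules)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    unit_home: dict[str, int] = {}
    for mi, m in enumerate(base.molecules):
        for u, _ in m.units:
            if u in unit_home:
                a, b = find(unit_home[u]), find(mi)
                parent[a] = b
            else:
                unit_home[u] = mi
    comp_of_unit = {u: find(mi) for u, mi in unit_home.items()}
    groups: dict[int, set] = defaultdict(set)
    for u, c in comp_of_unit.items():
        groups[c].add(u)
    components = list(groups.values())

    violations = []
    for e in graph.edges:
        ends = tuple(e)
        scafs = {ends[0][0], ends[-1][0]}
        comps = {comp_of_unit.get(s) for s in scafs if s in comp_of_unit}
        if len(comps) > 1:
            violations.append(f"junction edge {sorted(ends)} links separate components")
    for si, st in enumerate(states):
        for m in st.molecules:
            comps = {comp_of_unit.get(u) for u, _ in m.units if u in comp_of_unit}
            if len(comps) > 1:
                violations.append(
                    f"state {si} molecule {m.units} spans separate components"
                )
    return SeparationReport(not violations, components, violations)
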