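"""Recombination algebra, circular canonicalization, decomposition, mixture."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomosaic.conformations import (
    CircularMolecule,
    ConformationSet,
    GraphStructureError,
    RecombinationEvent,
    RepeatUnit,
    apply_recombination,
    check_component_separation,
    conformation_space,
    decompose_circles,
    estimate_mixture,
    molecule_length,
)
from mitomosaic.junctions import JunctionGraph

from conftest import MOLECULE_LENGTHS, TOTAL_LENGTH

signed_units = st.lists(
    st.tuples(st.sampled_from("ABCDE"), st.sampled_from([1, -1])),
    min_size=1,
    max_size=6,
)


class TestCanonicalForm:
    @settings(derandomize=True, max_examples=100)
    @given(units=signed_units, rot=st.integers(0, 5))
    def test_rotation_invariance(self, units, rot):
        m = CircularMolecule(tuple(units))
        r = rot % len(units)
        rotated = CircularMolecule(tuple(units[r:] + units[:r]))
        assert m.canonical() == rotated.canonical()

    @settings(derandomize=True, max_examples=100)
    @given(units=signed_units)
    def test_reverse_complement_invariance_and_idempotence(self, units):
        m = CircularMolecule(tuple(units))
        flipped = CircularMolecule(tuple((u, -s) for u, s in reversed(units)))
        assert m.canonical() == flipped.canonical()
        assert CircularMolecule(m.canonical()).canonical() == m.canonical()

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            CircularMolecule(())


class TestRecombinationAlgebra:
    def test_direct_fusion_adds_lengths(self, published_topology):
        # M4 (32,520) + M5 (113,793) fuse across O into the 146,313 bp ring
        base, ul, repeats, _ = published_topology
        fused = apply_recombination(base, RecombinationEvent("O", "fusion"))
        lengths = sorted(m.length(ul) for m in fused.molecules)
        assert 146313 in lengths
        assert len(fused.molecules) == 4

    def test_master_ring_lengths_from_fig3_merges(self, published_topology):
        base, ul, repeats, _ = published_topology
        s = apply_recombination(base, RecombinationEvent("H", "fusion"))
        s = apply_recombination(s, RecombinationEvent("J", "fusion"))
        s = apply_recombination(s, RecombinationEvent("O", "fusion"))
        lengths = sorted(m.length(ul) for m in s.molecules)
        assert lengths == [146313, 253259]

    def test_fission_then_fusion_restores_canonical_form(self, published_topology):
        base, ul, _, _ = published_topology
        fused = apply_recombination(base, RecombinationEvent("O", "fusion"))
        back = apply_recombination(fused, RecombinationEvent("O", "fission"))
        assert back.signature() == base.signature()

    def test_inverted_flipflop_exchanges_successors(self):
        # ...A I D ... F I' K... flips to ...A I F' ... D' I' K...
        m = CircularMolecule(
            (("A", 1), ("I", 1), ("D", 1), ("X", 1), ("F", 1), ("I", -1),
             ("K", 1), ("Y", 1))
        )
        state = ConformationSet([m])
        new = apply_recombination(state, RecombinationEvent("I", "inversion"))
        units = new.molecules[0].units
        # locate the +1 copy of I: its successor must now be F (reversed)
        i_plus = units.index(("I", 1))
        assert units[(i_plus + 1) % len(units)] == ("F", -1)
        assert units[(i_plus - 1) % len(units)] == ("A", 1)
        i_minus = units.index(("I", -1))
        assert units[(i_minus + 1) % len(units)] == ("K", 1)
        assert units[(i_minus - 1) % len(units)] == ("D", -1)

    def test_inversion_preserves_length_and_circle_count(self, published_topology):
        base, ul, _, _ = published_topology
        new = apply_recombination(base, RecombinationEvent("I", "inversion"))
        assert len(new.molecules) == len(base.molecules)
        assert new.total_length(ul) == base.total_length(ul)

    def test_mechanism_kind_mismatch_rejected(self, published_topology):
        base, _, repeats, _ = published_topology
        rep = {r.id: r for r in repeats}
        with pytest.raises(ValueError, match="direct"):
            apply_recombination(
                base, RecombinationEvent("I", "fusion"), rep["I"]
            )
        with pytest.raises(ValueError, match="inverted"):
            apply_recombination(
                base, RecombinationEvent("O", "inversion"), rep["O"]
            )


class TestConformationSpace:
    def test_no_repeats_base_only(self):
        base = ConformationSet([CircularMolecule((("A", 1), ("B", 1)))])
        space = conformation_space(base, [])
        assert len(space) == 1
        assert space[0].signature() == base.signature()

    def test_published_topology_space(self, published_topology):
        """Three independent direct repeats and one inverted pair give a
        2^4-state closure containing both the 5-circle and 2-circle forms."""
        base, ul, repeats, _ = published_topology
        space = conformation_space(base, repeats)
        assert len(space) == 16
        counts = sorted(len(s.molecules) for s in space)
        assert counts[0] == 2 and counts[-1] == 5
        assert {s.total_length(ul) for s in space} == {TOTAL_LENGTH}

    def test_two_independent_direct_repeats_four_states(self):
        base = ConformationSet(
            [
                CircularMolecule((("R1", 1), ("a", 1))),
                CircularMolecule((("R1", 1), ("b", 1))),
                CircularMolecule((("R2", 1), ("c", 1))),
                CircularMolecule((("R2", 1), ("d", 1))),
            ]
        )
        reps = [RepeatUnit("R1", 1000, "direct"), RepeatUnit("R2", 1000, "direct")]
        assert len(conformation_space(base, reps)) == 4

    def test_state_graph_symmetric(self, published_topology):
        # reachability is symmetric: the closure from any state is the closure
        base, _, repeats, _ = published_topology
        space = conformation_space(base, repeats)
        sigs = {s.signature() for s in space}
        other = conformation_space(space[-1], repeats)
        assert {s.signature() for s in other} == sigs

    def test_gc_content_invariant_under_inversion(self, tiny_master):
        inv = next(r for r in tiny_master.repeat_units if r.kind == "inverted")
        base = tiny_master.base_conformation
        flipped = apply_recombination(
            base, RecombinationEvent(inv.id, "inversion")
        )
        def gc(state):
            s = "".join(tiny_master.circle_sequence(m) for m in state.molecules)
            return s.count("G") + s.count("C")
        assert gc(base) == gc(flipped)


class TestMoleculeLength:
    def test_published_molecule_lengths_sum(self, published_topology):
        base, ul, _, mols = published_topology
        for name, m in mols.items():
            assert molecule_length(m, ul) == MOLECULE_LENGTHS[name]
        assert sum(molecule_length(m, ul) for m in mols.values()) == TOTAL_LENGTH

    def test_unknown_unit_rejected(self):
        with pytest.raises(KeyError):
            molecule_length(CircularMolecule((("Z", 1),)), {"A": 10})

    def test_single_unit(self):
        assert molecule_length(CircularMolecule((("A", 1),)), {"A": 123}) == 123


def _graph(nodes, edge_list, reads=None):
    g = JunctionGraph(nodes=dict(nodes))
    for i, e in enumerate(edge_list):
        g.edges[frozenset(e)] = set(reads[i]) if reads else {f"r{i}a", f"r{i}b"}
    return g


class TestDecomposeCircles:
    def test_single_node_self_edge(self):
        g = _graph({"A": 1}, [(("A", "head"), ("A", "tail"))])
        states = decompose_circles(g)
        assert len(states) == 1
        assert len(states[0].molecules) == 1

    def test_three_cycle_single_state(self):
        g = _graph(
            {"A": 1, "B": 1, "C": 1},
            [
                (("A", "tail"), ("B", "head")),
                (("B", "tail"), ("C", "head")),
                (("C", "tail"), ("A", "head")),
            ],
        )
        states = decompose_circles(g)
        assert len(states) == 1
        assert states[0].molecules[0].canonical() == CircularMolecule(
            (("A", 1), ("B", 1), ("C", 1))
        ).canonical()

    def test_direct_repeat_graph_yields_fused_and_split(self):
        # repeat R bridges circles [R,a] and [R,b]; the same four edges admit
        # both the split (two circles) and fused (one circle) conformations
        g = _graph(
            {"R": 2, "a": 1, "b": 1},
            [
                (("R", "tail"), ("a", "head")),
                (("a", "tail"), ("R", "head")),
                (("R", "tail"), ("b", "head")),
                (("b", "tail"), ("R", "head")),
            ],
        )
        states = decompose_circles(g)
        sizes = sorted(len(s.molecules) for s in states)
        assert sizes == [1, 2]

    def test_missing_end_raises_structural_error(self):
        g = _graph({"A": 1, "B": 1}, [(("A", "tail"), ("B", "head"))])
        with pytest.raises(GraphStructureError, match="A|B"):
            decompose_circles(g)

    def test_unsatisfiable_graph_returns_empty(self):
        # all four ends touched, but no circle can close
        g = _graph(
            {"A": 1, "B": 1},
            [
                (("A", "tail"), ("B", "head")),
                (("A", "head"), ("A", "head")),
                (("B", "tail"), ("B", "tail")),
            ],
        )
        assert decompose_circles(g) == []


class TestEstimateMixture:
    def _two_state_setup(self, n_split, n_fused):
        """Reads through repeat R: split-state reads pair entry a with exit
        a (and b with b); fused-state reads cross over (a with b)."""
        in_a = frozenset(((("a", "tail")), ("R", "head")))
        out_a = frozenset(((("R", "tail")), ("a", "head")))
        in_b = frozenset(((("b", "tail")), ("R", "head")))
        out_b = frozenset(((("R", "tail")), ("b", "head")))
        split = ConformationSet(
            [
                CircularMolecule((("R", 1), ("a", 1))),
                CircularMolecule((("R", 1), ("b", 1))),
            ]
        )
        fused = ConformationSet(
            [CircularMolecule((("R", 1), ("a", 1), ("R", 1), ("b", 1)))]
        )
        s_a = {f"s{i}" for i in range(0, n_split, 2)}
        s_b = {f"s{i}" for i in range(1, n_split, 2)}
        f_a = {f"f{i}" for i in range(0, n_fused, 2)}
        f_b = {f"f{i}" for i in range(1, n_fused, 2)}
        edges = {
            in_a: s_a | f_b,
            out_a: s_a | f_a,
            in_b: s_b | f_a,
            out_b: s_b | f_b,
        }
        g = JunctionGraph(nodes={"R": 2, "a": 1, "b": 1}, edges=edges)
        return g, [split, fused]

    def test_even_counts_give_one_to_one(self):
        g, states = self._two_state_setup(10, 10)
        est = estimate_mixture(g, states)
        assert est.frequencies == [0.5, 0.5]
        assert est.ratio == "1:1"
        assert est.n_diagnostic_reads == 20
        assert not est.flags

    def test_one_sided_counts_flagged(self):
        g, states = self._two_state_setup(8, 0)
        est = estimate_mixture(g, states)
        assert est.frequencies == [1.0, 0.0]
        assert "zero_count" in est.flags

    def test_no_diagnostic_reads_undefined(self):
        g, states = self._two_state_setup(0, 0)
        est = estimate_mixture(g, states)
        assert "undefined" in est.flags

    def test_single_state_rejected(self):
        g, states = self._two_state_setup(1, 1)
        with pytest.raises(ValueError):
            estimate_mixture(g, states[:1])


class TestComponentSeparation:
    def test_two_components_with_no_cross_edges_hold(self, published_topology):
        base, _, repeats, _ = published_topology
        space = conformation_space(base, repeats)
        g = _graph({u: 1 for m in base.molecules for u, _ in m.units}, [])
        g.edges = {e: {"r"} for e in base.adjacency_edges()}
        rep = check_component_separation(g, space)
        assert rep.ok
        assert len(rep.components) == 2

    def test_cross_component_edge_reported(self, published_topology):
        base, _, repeats, _ = published_topology
        g = _graph({u: 1 for m in base.molecules for u, _ in m.units}, [])
        g.edges = {e: {"r"} for e in base.adjacency_edges()}
        g.edges[frozenset(((("a1", "tail")), ("d", "head")))] = {"chimera"}
        rep = check_component_separation(g, [base])
        assert not rep.ok
        assert any("links separate components" in v for v in rep.violations)

    def test_single_component_vacuously_holds(self):
        base = ConformationSet([CircularMolecule((("A", 1), ("B", 1)))])
        g = _graph({"A": 1, "B": 1}, [])
        g.edges = {e: {"r"} for e in base.adjacency_edges()}
        rep = check_component_separation(g, [base])
        assert rep.ok
        assert len(rep.components) == 1
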