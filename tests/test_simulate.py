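"""Generator contracts: topology, determinism, read statistics, insertions."""

import numpy as np
import pytest

from mitomosaic.simulate import (
    LongReadParams,
    RepeatSpec,
    ShortReadParams,
    SimulationConfig,
    SizingError,
    build_master_genome,
    enumerate_true_conformations,
    insert_plastid_fragments,
    simulate_long_reads,
    simulate_short_reads,
)
from mitomosaic.sequtil import random_seq, revcomp

from conftest import tiny_config


def _contains_circular(circle_seq: str, read: str) -> bool:
    doubled = circle_seq + circle_seq
    return read in doubled or revcomp(read) in doubled


class TestBuildMasterGenome:
    def test_no_repeats_single_state(self):
        cfg = tiny_config(repeat_specs=())
        m = build_master_genome(cfg)
        assert len(m.truth_conformation_space) == 1

    def test_one_shared_direct_repeat_two_states(self):
        cfg = tiny_config(
            n_single_copy_units=2,
            repeat_specs=(RepeatSpec(1200, "direct"),),
            layout=(("U01", "D1"), ("D1", "U02")),
        )
        m = build_master_genome(cfg)
        sizes = sorted(len(s.molecules) for s in m.truth_conformation_space)
        assert sizes == [1, 2]  # fused and split

    def test_two_independent_direct_repeats_four_states(self):
        cfg = tiny_config(
            n_single_copy_units=4,
            repeat_specs=(RepeatSpec(1200, "direct"), RepeatSpec(1200, "direct")),
            layout=(("U01", "D1"), ("D1", "U02"), ("U03", "D2"), ("D2", "U04")),
        )
        m = build_master_genome(cfg)
        assert len(m.truth_conformation_space) == 4

    def test_inverted_pair_two_states_same_sizes(self):
        cfg = tiny_config(
            n_single_copy_units=2,
            repeat_specs=(RepeatSpec(1200, "inverted"),),
            layout=(("U01", "V1", "U02", "-V1"),),
        )
        m = build_master_genome(cfg)
        space = m.truth_conformation_space
        assert len(space) == 2
        lens = {s.total_length(m.unit_lengths) for s in space}
        assert len(lens) == 1
        assert all(len(s.molecules) == 1 for s in space)

    def test_seeded_determinism(self):
        m1 = build_master_genome(tiny_config(seed=5))
        m2 = build_master_genome(tiny_config(seed=5))
        m3 = build_master_genome(tiny_config(seed=6))
        assert m1.unit_seqs == m2.unit_seqs
        assert m1.unit_seqs != m3.unit_seqs

    def test_repeat_copy_invariants(self, tiny_master):
        counts = tiny_master.base_conformation.unit_copy_counts()
        rep_ids = {r.id for r in tiny_master.repeat_units}
        for u, n in counts.items():
            assert n == (2 if u in rep_ids else 1)

    def test_repeat_alone_in_circle_rejected(self):
        cfg = tiny_config(
            n_single_copy_units=1,
            repeat_specs=(RepeatSpec(1200, "direct"),),
            layout=(("D1",), ("D1", "U01")),
        )
        with pytest.raises(SizingError):
            build_master_genome(cfg)

    def test_length_conservation_across_truth_space(self, tiny_master):
        ul = tiny_master.unit_lengths
        totals = {s.total_length(ul) for s in tiny_master.truth_conformation_space}
        assert len(totals) == 1

    def test_enumerate_matches_stored_space(self, tiny_master):
        space = enumerate_true_conformations(tiny_master)
        assert {s.signature() for s in space} == {
            s.signature() for s in tiny_master.truth_conformation_space
        }


class TestLongReads:
    def test_zero_error_reads_are_circular_substrings(self, tiny_master):
        cfg = tiny_master.config
        rs = simulate_long_reads(tiny_master, cfg)
        assert len(rs.reads) == cfg.long_read_params.count
        lengths = tiny_master.unit_lengths
        for t in rs.truth[:50]:
            mol = tiny_master.truth_conformation_space[t.state].molecules[t.molecule]
            circle = tiny_master.circle_sequence(mol)
            assert _contains_circular(circle, rs.reads[t.read_id])

    def test_total_bases_law_of_large_numbers(self):
        # single big circle so truncation is negligible
        cfg = tiny_config(
            n_single_copy_units=8,
            unit_length_range=(8000, 8000),
            repeat_specs=(),
            long_read_params=LongReadParams(count=2000, mean_length=8000,
                                            error_rate=0.0),
        )
        m = build_master_genome(cfg)
        rs = simulate_long_reads(m, cfg)
        total = sum(len(s) for s in rs.reads.values())
        assert abs(total - 1.6e7) <= 0.05 * 1.6e7

    def test_single_state_frequencies(self, tiny_master):
        cfg = tiny_config(seed=7, conformation_frequencies={3: 1.0})
        rs = simulate_long_reads(tiny_master, cfg)
        assert {t.state for t in rs.truth} == {3}

    def test_mean_exceeding_longest_circle_warns_and_truncates(self):
        cfg = tiny_config(
            n_single_copy_units=2,
            repeat_specs=(),
            layout=(("U01", "U02"),),
            unit_length_range=(1500, 1500),
            long_read_params=LongReadParams(count=20, mean_length=10000,
                                            error_rate=0.0),
        )
        m = build_master_genome(cfg)
        with pytest.warns(UserWarning, match="truncated"):
            rs = simulate_long_reads(m, cfg)
        assert all(len(s) <= 3000 for s in rs.reads.values())

    def test_error_injection_changes_sequences(self, tiny_master):
        cfg = tiny_config(
            seed=7, long_read_params=LongReadParams(count=30, mean_length=4000,
                                                    error_rate=0.1)
        )
        rs = simulate_long_reads(tiny_master, cfg)
        lengths = tiny_master.unit_lengths
        changed = 0
        for t in rs.truth:
            mol = tiny_master.truth_conformation_space[t.state].molecules[t.molecule]
            if not _contains_circular(tiny_master.circle_sequence(mol),
                                      rs.reads[t.read_id]):
                changed += 1
        assert changed >= 25


class TestShortReads:
    def test_pair_count_formula(self):
        # 100 kb genome at 50x with 150 bp reads -> 16,667 pairs
        cfg = tiny_config(
            n_single_copy_units=8,
            unit_length_range=(12500, 12500),
            repeat_specs=(),
            short_read_params=ShortReadParams(coverage=50, read_length=150,
                                              error_rate=0.0),
        )
        m = build_master_genome(cfg)
        assert m.total_length() == 100000
        rs = simulate_short_reads(m, cfg)
        n_pairs = len(rs.truth)
        assert abs(n_pairs - 16667) <= 0.02 * 16667
        assert len(rs.reads) == 2 * n_pairs

    def test_zero_error_mates_exact_and_opposed(self, tiny_master):
        cfg = tiny_config(seed=7,
                          short_read_params=ShortReadParams(coverage=2,
                                                            error_rate=0.0))
        rs = simulate_short_reads(tiny_master, cfg)
        for t in rs.truth[:40]:
            mol = tiny_master.truth_conformation_space[t.state].molecules[t.molecule]
            circle = tiny_master.circle_sequence(mol)
            r1 = rs.reads[f"{t.read_id}/1"]
            r2 = rs.reads[f"{t.read_id}/2"]
            assert _contains_circular(circle, r1)
            assert _contains_circular(circle, r2)

    def test_insert_mean_below_twice_read_length_rejected(self, tiny_master):
        cfg = tiny_config(
            short_read_params=ShortReadParams(read_length=150, insert_mean=200)
        )
        with pytest.raises(ValueError, match="insert mean"):
            simulate_short_reads(tiny_master, cfg)


class TestPlastidInsertions:
    def donor(self, seed=9, length=20000):
        return random_seq(np.random.default_rng(seed), length, 0.37)

    def test_zero_divergence_insert_grows_host_exactly(self):
        cfg = tiny_config(plastid_fragment_specs=((9798, 0.0),),
                          unit_length_range=(12000, 15000))
        m = build_master_genome(cfg)
        before = m.unit_lengths
        insert_plastid_fragments(m, self.donor(), cfg)
        after = m.unit_lengths
        frag = m.plastid_truth[0]
        assert frag.identity == 100.0
        assert after[frag.mt_molecule] == before[frag.mt_molecule] + 9798

    def test_realized_divergence_close_to_requested(self):
        cfg = tiny_config(plastid_fragment_specs=((5000, 0.05),))
        m = build_master_genome(cfg)
        insert_plastid_fragments(m, self.donor(), cfg)
        assert abs(m.plastid_truth[0].identity - 95.0) <= 1.0

    def test_empty_spec_leaves_master_unchanged(self, tiny_master):
        before = dict(tiny_master.unit_seqs)
        insert_plastid_fragments(tiny_master, self.donor(), tiny_master.config)
        assert tiny_master.unit_seqs == before
        assert tiny_master.plastid_truth == []

    def test_divergence_out_of_range_rejected(self):
        cfg = tiny_config(plastid_fragment_specs=((500, 1.0),))
        with pytest.raises(ValueError):
            build_master_genome(cfg)

    def test_fragment_longer_than_donor_rejected(self):
        cfg = tiny_config(plastid_fragment_specs=((30000, 0.0),))
        m = build_master_genome(cfg)
        with pytest.raises(ValueError, match="donor"):
            insert_plastid_fragments(m, self.donor(length=10000), cfg)


def test_config_invariant_validation():
    with pytest.raises(ValueError):
        SimulationConfig(conformation_frequencies={0: 0.5, 1: 0.6}).validate()
    with pytest.raises(ValueError):
        SimulationConfig(unit_length_range=(0, 100)).validate()
    with pytest.raises(ValueError):
        SimulationConfig(
            long_read_params=LongReadParams(error_rate=1.0)
        ).validate()
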