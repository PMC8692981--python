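"""Shared fixtures: the published-table molecule topology and small
synthetic genomes used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from mitomosaic.conformations import CircularMolecule, ConformationSet, RepeatUnit
from mitomosaic.simulate import (
    LongReadParams,
    RepeatSpec,
    ShortReadParams,
    SimulationConfig,
    build_master_genome,
)

# Published scaffold and molecule scales: five basic circles M1..M5, four
# long repeats (H, J, O direct; I inverted, both copies on M1), merging to
# two master rings LS1 = M1+M2+M3 and LS2 = M4+M5.
MOLECULE_LENGTHS = {
    "M1": 169330,
    "M2": 44455,
    "M3": 39474,
    "M4": 32520,
    "M5": 113793,
}
REPEAT_LENGTHS = {"H": 5212, "I": 2351, "J": 3908, "O": 4926}
SCAFFOLD_LENGTHS_TABLE1 = [
    39443, 3908, 39470, 35384, 39313, 34472, 5212, 27177,
    5443, 8311, 2351, 27635, 4926, 56817, 42335, 9760,
]
MTPT_LENGTHS = [9798, 859, 342, 273]
TOTAL_LENGTH = 399572


@pytest.fixture(scope="session")
def published_topology():
    """Base conformation with the published molecule/repeat scales.

    Single-copy filler units absorb the residual length of each molecule so
    every CircularMolecule length matches its printed value exactly.
    """
    unit_lengths = dict(REPEAT_LENGTHS)
    m1_filler = MOLECULE_LENGTHS["M1"] - (
        2 * REPEAT_LENGTHS["I"] + REPEAT_LENGTHS["H"] + REPEAT_LENGTHS["J"]
    )
    unit_lengths.update(
        {
            "a1": 40000,
            "a2": 40000,
            "a3": 40000,
            "a4": m1_filler - 120000,
            "b": MOLECULE_LENGTHS["M2"] - REPEAT_LENGTHS["H"],
            "c": MOLECULE_LENGTHS["M3"] - REPEAT_LENGTHS["J"],
            "d": MOLECULE_LENGTHS["M4"] - REPEAT_LENGTHS["O"],
            "e": MOLECULE_LENGTHS["M5"] - REPEAT_LENGTHS["O"],
        }
    )
    molecules = {
        "M1": CircularMolecule(
            (("a1", 1), ("I", 1), ("a2", 1), ("H", 1),
             ("a3", 1), ("I", -1), ("a4", 1), ("J", 1))
        ),
        "M2": CircularMolecule((("H", 1), ("b", 1))),
        "M3": CircularMolecule((("J", 1), ("c", 1))),
        "M4": CircularMolecule((("O", 1), ("d", 1))),
        "M5": CircularMolecule((("O", 1), ("e", 1))),
    }
    repeats = [
        RepeatUnit("H", REPEAT_LENGTHS["H"], "direct"),
        RepeatUnit("I", REPEAT_LENGTHS["I"], "inverted"),
        RepeatUnit("J", REPEAT_LENGTHS["J"], "direct"),
        RepeatUnit("O", REPEAT_LENGTHS["O"], "direct"),
    ]
    base = ConformationSet(list(molecules.values()))
    return base, unit_lengths, repeats, molecules


def tiny_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast five-circle genome (~30 kb) for unit tests."""
    defaults = dict(
        n_single_copy_units=8,
        unit_length_range=(2500, 3500),
        repeat_specs=(
            RepeatSpec(1200, "direct"),
            RepeatSpec(1200, "direct"),
            RepeatSpec(1200, "direct"),
            RepeatSpec(1200, "inverted"),
        ),
        long_read_params=LongReadParams(count=200, mean_length=4000,
                                        error_rate=0.0, length_dispersion=0.3),
        short_read_params=ShortReadParams(coverage=50.0),
        rng_seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_master():
    return build_master_genome(tiny_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
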