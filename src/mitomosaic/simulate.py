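"""Synthetic multipartite mitogenome generator with full ground truth.

Emulates the statistical structure the pipeline assumes: a circular
mitogenome of single-copy units plus 2-4 long (>1 kb) repeat units present in
two copies, arranged as several circles in two recombination components; a
truth conformation space closed under repeat-mediated recombination;
long reads drawn from a conformation mixture; paired short reads at
configurable coverage; and plastid-derived insertions at controlled
divergence.

The default layout mirrors the five-circle architecture resolved in marama:
a hub circle carrying one copy of each bridging direct repeat plus both
copies of any inverted repeat, satellite circles carrying the second copies,
and a separate two-circle component joined by its own direct repeat — so
recombination can merge each component into one master ring but can never
join the two components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .conformations import (
    CircularMolecule,
    ConformationSet,
    RepeatUnit,
    conformation_space,
)
from .mtpt import PlastidFragment
from .sequtil import Scaffold, mutate_substitutions, random_seq, revcomp

__all__ = [
    "RepeatSpec",
    "LongReadParams",
    "ShortReadParams",
    "SimulationConfig",
    "MasterGenome",
    "SimulatedReadSet",
    "build_master_genome",
    "enumerate_true_conformations",
    "simulate_long_reads",
    "simulate_short_reads",
    "insert_plastid_fragments",
]


@dataclass(frozen=True)
class RepeatSpec:
    length: int
    kind: str  # 'direct' | 'inverted'


@dataclass(frozen=True)
class LongReadParams:
    """Single-molecule long-read model (log-normal lengths, mixed errors)."""

    count: int = 1000
    mean_length: int = 8000
    length_dispersion: float = 0.4  # sigma of log length
    error_rate: float = 0.10
    error_mix: tuple[float, float, float] = (0.25, 0.45, 0.30)  # sub:ins:del


@dataclass(frozen=True)
class ShortReadParams:
    coverage: float = 50.0
    read_length: int = 150
    insert_mean: int = 400
    insert_sd: float = 40.0
    error_rate: float = 0.002


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults sit at the study scale
    (~200 kb genome, units 8-30 kb, repeats 2-5 kb, long reads ~8 kb)."""

    n_single_copy_units: int = 10
    unit_length_range: tuple[int, int] = (8000, 30000)
    repeat_specs: tuple[RepeatSpec, ...] = (
        RepeatSpec(5212, "direct"),
        RepeatSpec(3908, "direct"),
        RepeatSpec(4926, "direct"),
        RepeatSpec(2351, "inverted"),
    )
    plastid_fragment_specs: tuple[tuple[int, float], ...] = ()
    conformation_frequencies: dict[int, float] | None = None
    long_read_params: LongReadParams = field(default_factory=LongReadParams)
    short_read_params: ShortReadParams = field(default_factory=ShortReadParams)
    gc: float = 0.447
    rng_seed: int = 0
    layout: tuple[tuple[str, ...], ...] | None = None  # signed unit names

    def validate(self) -> None:
        lo, hi = self.unit_length_range
        if not (0 < lo <= hi):
            raise ValueError("unit_length_range must be positive and ordered")
        if self.n_single_copy_units < 1:
            raise ValueError("need at least one single-copy unit")
        for spec in self.repeat_specs:
            if spec.length <= 0:
                raise ValueError("repeat lengths must be positive")
            if spec.kind not in ("direct", "inverted"):
                raise ValueError(f"bad repeat kind {spec.kind!r}")
        for length, div in self.plastid_fragment_specs:
            if length <= 0:
                raise ValueError("plastid fragment lengths must be positive")
            if not 0 <= div < 1:
                raise ValueError(f"divergence must be in [0,1), got {div}")
        for p in (self.long_read_params.error_rate, self.short_read_params.error_rate):
            if not 0 <= p < 1:
                raise ValueError(f"error rate must be in [0,1), got {p}")
        if self.conformation_frequencies is not None:
            tot = sum(self.conformation_frequencies.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"conformation frequencies sum to {tot}, not 1")
            if any(f < 0 for f in self.conformation_frequencies.values()):
                raise ValueError("conformation frequencies must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "repeat_specs" in raw:
            raw["repeat_specs"] = tuple(
                RepeatSpec(int(r[0]), str(r[1])) for r in raw["repeat_specs"]
            )
        if "plastid_fragment_specs" in raw:
            raw["plastid_fragment_specs"] = tuple(
                (int(a), float(b)) for a, b in raw["plastid_fragment_specs"]
            )
        if "long_read_params" in raw:
            lr = dict(raw["long_read_params"])
            if "error_mix" in lr:
                lr["error_mix"] = tuple(lr["error_mix"])
            raw["long_read_params"] = LongReadParams(**lr)
        if "short_read_params" in raw:
            raw["short_read_params"] = ShortReadParams(**raw["short_read_params"])
        if "unit_length_range" in raw:
            raw["unit_length_range"] = tuple(raw["unit_length_range"])
        if "layout" in raw and raw["layout"] is not None:
            raw["layout"] = tuple(tuple(c) for c in raw["layout"])
        if "conformation_frequencies" in raw and raw["conformation_frequencies"]:
            raw["conformation_frequencies"] = {
                int(k): float(v) for k, v in raw["conformation_frequencies"].items()
            }
        return cls(**raw)


class SizingError(ValueError):
    """A repeat does not fit inside its host circle."""


def five_circle_demo_config(
    seed: int = 0,
    long_read_count: int = 1000,
    long_read_error: float = 0.10,
    coverage: float = 50.0,
) -> SimulationConfig:
    """The five-circle / two-master-ring demonstration genome.

    A desk-scale analogue of the resolved marama architecture: eight
    single-copy units of 7-9.5 kb, three direct repeats bridging the circles
    of two separate components, and one inverted repeat inside the hub circle
    (~90 kb total). Small enough that the default long-read budget yields
    several hundred reads spanning entire repeats — the evidence class that
    separates fused from split conformations.
    """
    return SimulationConfig(
        n_single_copy_units=8,
        unit_length_range=(7000, 9500),
        repeat_specs=(
            RepeatSpec(2000, "direct"),
            RepeatSpec(2000, "direct"),
            RepeatSpec(2000, "direct"),
            RepeatSpec(2000, "inverted"),
        ),
        long_read_params=LongReadParams(
            count=long_read_count, mean_length=8000, error_rate=long_read_error
        ),
        short_read_params=ShortReadParams(coverage=coverage),
        rng_seed=seed,
    )


def default_layout(
    n_single: int, repeat_specs: tuple[RepeatSpec, ...]
) -> tuple[tuple[str, ...], ...]:
    """Signed-unit circle layout mirroring the marama-style architecture.

    Unit names: singles U01.., direct repeats D1.., inverted repeats V1..;
    a leading '-' marks reverse orientation. When two or more direct repeats
    exist the last one forms a separate two-circle component.
    """
    n_dir = sum(1 for s in repeat_specs if s.kind == "direct")
    n_inv = len(repeat_specs) - n_dir
    direct = [f"D{i + 1}" for i in range(n_dir)]
    inverted = [f"V{i + 1}" for i in range(n_inv)]
    comp1_d = direct[:-1] if len(direct) >= 2 else direct
    comp2_d = direct[len(comp1_d) :]

    need = (1 + len(inverted) + len(comp1_d)) + len(comp1_d) + 2 * len(comp2_d)
    if n_single < need:
        raise ValueError(
            f"layout needs at least {need} single-copy units, got {n_single}"
        )
    singles = iter(f"U{i + 1:02d}" for i in range(n_single))

    hub: list[str] = [next(singles)]
    for v in inverted:
        hub += [v, next(singles)]
    for d in comp1_d:
        hub += [d, next(singles)]
    for v in reversed(inverted):
        hub += [f"-{v}"]  # the wrap back to the circle start separates copies
    circles = [hub]
    for d in comp1_d:
        circles.append([d, next(singles)])
    for d in comp2_d:
        circles.append([d, next(singles)])
        circles.append([d, next(singles)])
    # spread any remaining singles round-robin
    for i, u in enumerate(singles):
        circles[i % len(circles)].append(u)
    return tuple(tuple(c) for c in circles)


@dataclass
class MasterGenome:
    """The simulated genome: scaffolds, repeats, and its conformation space."""

    units: list[Scaffold]
    repeat_units: list[RepeatUnit]
    base_conformation: ConformationSet
    truth_conformation_space: list[ConformationSet]
    plastid_truth: list[PlastidFragment] = field(default_factory=list)
    config: SimulationConfig | None = None

    @property
    def unit_seqs(self) -> dict[str, str]:
        return {u.id: u.seq for u in self.units}

    @property
    def unit_lengths(self) -> dict[str, int]:
        return {u.id: len(u.seq) for u in self.units}

    def total_length(self) -> int:
        return self.base_conformation.total_length(self.unit_lengths)

    def circle_sequence(self, molecule: CircularMolecule) -> str:
        seqs = self.unit_seqs
        return "".join(
            seqs[u] if s > 0 else revcomp(seqs[u]) for u, s in molecule.units
        )

    def molecule_sequences(self, state_index: int = 0) -> dict[str, str]:
        state = self.truth_conformation_space[state_index]
        return {
            f"state{state_index}_mol{i + 1}": self.circle_sequence(m)
            for i, m in enumerate(state.molecules)
        }


def _parse_signed(name: str) -> tuple[str, int]:
    return (name[1:], -1) if name.startswith("-") else (name, 1)


def build_master_genome(config: SimulationConfig) -> MasterGenome:
    """Draw unit sequences and assemble the base conformation and its
    recombination closure. Deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    layout = config.layout or default_layout(
        config.n_single_copy_units, config.repeat_specs
    )

    rep_kind: dict[str, RepeatSpec] = {}
    di = vi = 0
    for i, spec in enumerate(config.repeat_specs):
        if spec.kind == "direct":
            di += 1
            rep_kind[f"D{di}"] = spec
        else:
            vi += 1
            rep_kind[f"V{vi}"] = spec

    unit_names: list[str] = []
    for circle in layout:
        for name in circle:
            u, _ = _parse_signed(name)
            if u not in unit_names:
                unit_names.append(u)

    lo, hi = config.unit_length_range
    lengths: dict[str, int] = {}
    for u in unit_names:
        if u in rep_kind:
            lengths[u] = rep_kind[u].length
        else:
            lengths[u] = int(rng.integers(lo, hi + 1))

    molecules = [
        CircularMolecule(tuple(_parse_signed(n) for n in circle)) for circle in layout
    ]
    base = ConformationSet(molecules)

    counts = base.unit_copy_counts()
    for u in unit_names:
        want = 2 if u in rep_kind else 1
        if counts.get(u) != want:
            raise ValueError(
                f"unit {u!r} appears {counts.get(u)} times in the layout, "
                f"expected {want}"
            )
    for m in molecules:
        circ_len = m.length(lengths)
        for u, _ in m.units:
            if u in rep_kind and lengths[u] >= circ_len:
                raise SizingError(
                    f"repeat {u!r} ({lengths[u]} bp) does not fit inside its "
                    f"host circle ({circ_len} bp)"
                )

    seqs = {u: random_seq(rng, lengths[u], config.gc) for u in unit_names}
    units = [Scaffold(u, seqs[u]) for u in unit_names]

    repeat_units = []
    for u, spec in rep_kind.items():
        if u not in seqs:
            continue
        locs = []
        for mi, m in enumerate(molecules):
            offset = 0
            for uu, s in m.units:
                if uu == u:
                    locs.append(
                        (f"mol{mi + 1}", (offset, offset + lengths[u]),
                         "+" if s > 0 else "-")
                    )
                offset += lengths[uu]
        repeat_units.append(
            RepeatUnit(id=u, length=lengths[u], kind=spec.kind,
                       copy_locations=tuple(locs))
        )

    space = conformation_space(base, repeat_units)
    return MasterGenome(
        units=units,
        repeat_units=repeat_units,
        base_conformation=base,
        truth_conformation_space=space,
        config=config,
    )


def enumerate_true_conformations(master: MasterGenome) -> list[ConformationSet]:
    """Closure of the base conformation under single recombination events."""
    return conformation_space(master.base_conformation, master.repeat_units)


def insert_plastid_fragments(
    master: MasterGenome, plastid_genome: str, config: SimulationConfig | None = None
) -> MasterGenome:
    """Copy fragments from a donor plastid genome into single-copy scaffolds.

    Each spec (length, divergence) takes a random donor interval, applies
    substitutions to the requested divergence, and splices the result into a
    random single-copy scaffold; truth intervals are recorded in both
    coordinate systems with the realized identity. Returns the same
    MasterGenome, updated in place.
    """
    config = config or master.config
    specs = config.plastid_fragment_specs
    if not specs:
        return master
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 0x9E3779B9]).generate_state(1)[0]
    )
    repeat_ids = {r.id for r in master.repeat_units}
    hosts = [u for u in master.units if u.id not in repeat_ids]

    for length, divergence in specs:
        if not 0 <= divergence < 1:
            raise ValueError(f"divergence must be in [0,1), got {divergence}")
        if length >= len(plastid_genome):
            raise ValueError(
                f"fragment of {length} bp exceeds the {len(plastid_genome)} bp donor"
            )
        cp_start = int(rng.integers(0, len(plastid_genome) - length + 1))
        fragment = plastid_genome[cp_start : cp_start + length]
        mutated, n_sub = mutate_substitutions(rng, fragment, divergence)
        host = hosts[int(rng.integers(len(hosts)))]
        taken = [
            f.mt_interval for f in master.plastid_truth
            if f.mt_molecule == host.id
        ]
        pos = None
        for _ in range(100):
            cand = int(rng.integers(1, len(host.seq)))
            if all(not (s <= cand < e) for s, e in taken):
                pos = cand
                break
        if pos is None:  # pragma: no cover - host saturated with inserts
            raise ValueError(f"no insertion site left on scaffold {host.id!r}")
        # earlier truth intervals downstream of this site shift right
        for f in master.plastid_truth:
            if f.mt_molecule == host.id and f.mt_interval[0] >= pos:
                f.mt_interval = (
                    f.mt_interval[0] + len(mutated),
                    f.mt_interval[1] + len(mutated),
                )
        host.seq = host.seq[:pos] + mutated + host.seq[pos:]
        master.plastid_truth.append(
            PlastidFragment(
                mt_molecule=host.id,
                mt_interval=(pos, pos + length),
                cp_interval=(cp_start, cp_start + length),
                strand="+",
                identity=100.0 * (length - n_sub) / length,
                length=length,
            )
        )
    # repeat copy coordinates may have shifted; recompute
    lengths = master.unit_lengths
    new_reps = []
    for rep in master.repeat_units:
        locs = []
        for mi, m in enumerate(master.base_conformation.molecules):
            offset = 0
            for uu, s in m.units:
                if uu == rep.id:
                    locs.append(
                        (f"mol{mi + 1}", (offset, offset + rep.length),
                         "+" if s > 0 else "-")
                    )
                offset += lengths[uu]
        new_reps.append(replace(rep, copy_locations=tuple(locs)))
    master.repeat_units = new_reps
    return master


@dataclass
class ReadTruth:
    read_id: str
    state: int
    molecule: int
    start: int
    strand: str


@dataclass
class SimulatedReadSet:
    """Reads plus per-read ground truth (source state, circle, start, strand)."""

    reads: dict[str, str]
    truth: list[ReadTruth]
    paired: bool = False
    quality_char: str = "I"

    def truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tstate\tcircle\tstart\tstrand\n")
            for t in self.truth:
                fh.write(f"{t.read_id}\t{t.state}\t{t.molecule}\t{t.start}"
                         f"\t{t.strand}\n")


def _inject_errors(rng, seq: str, rate: float, mix) -> str:
    if rate <= 0 or not seq:
        return seq
    L = len(seq)
    pos = np.flatnonzero(rng.random(L) < rate)
    if len(pos) == 0:
        return seq
    p = np.asarray(mix, dtype=float)
    p = p / p.sum()
    kinds = rng.choice(3, size=len(pos), p=p)  # 0 sub, 1 ins, 2 del
    bases = "ACGT"
    out = []
    prev = 0
    for i, k in zip(pos, kinds):
        out.append(seq[prev:i])
        if k == 0:
            alts = [b for b in bases if b != seq[i]]
            out.append(alts[int(rng.integers(3))])
        elif k == 1:
            out.append(seq[i])
            out.append(bases[int(rng.integers(4))])
        prev = i + 1
    out.append(seq[prev:])
    return "".join(out)


def _state_frequencies(master: MasterGenome, config: SimulationConfig):
    n = len(master.truth_conformation_space)
    freqs = config.conformation_frequencies
    if freqs is None:
        freqs = {0: 1.0}
    if any(not 0 <= k < n for k in freqs):
        raise ValueError(f"conformation frequency keys must index the {n} states")
    probs = np.zeros(n)
    for k, f in freqs.items():
        probs[k] = f
    return probs


def simulate_long_reads(
    master: MasterGenome, config: SimulationConfig | None = None
) -> SimulatedReadSet:
    """Long reads from the conformation mixture, uniform circular starts.

    Read source states are multinomial at the configured frequencies, start
    positions uniform on circular coordinates (reads may wrap the origin,
    handled by sampling from the doubled circle sequence), lengths
    log-normal, and errors injected at the configured per-base rate with the
    configured substitution:insertion:deletion mix.
    """
    config = config or master.config
    params = config.long_read_params
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 1]).generate_state(1)[0]
    )
    probs = _state_frequencies(master, config)
    lengths = master.unit_lengths
    states = master.truth_conformation_space
    circle_lens = [
        np.array([m.length(lengths) for m in st.molecules], dtype=float)
        for st in states
    ]
    max_circle = max(float(cl.max()) for cl in circle_lens)
    if params.mean_length > max_circle:
        warnings.warn(
            f"mean read length {params.mean_length} exceeds the longest circle "
            f"({int(max_circle)} bp); reads will be truncated",
            stacklevel=2,
        )
    doubled: dict[tuple[int, int], str] = {}

    mu = np.log(params.mean_length) - params.length_dispersion**2 / 2
    reads: dict[str, str] = {}
    truth: list[ReadTruth] = []
    state_draws = rng.choice(len(states), size=params.count, p=probs)
    for i in range(params.count):
        si = int(state_draws[i])
        cl = circle_lens[si]
        mi = int(rng.choice(len(cl), p=cl / cl.sum()))
        key = (si, mi)
        if key not in doubled:
            s = master.circle_sequence(states[si].molecules[mi])
            doubled[key] = s + s
        circ_len = int(cl[mi])
        L = int(rng.lognormal(mu, params.length_dispersion))
        L = max(100, min(L, circ_len))
        start = int(rng.integers(circ_len))
        raw = doubled[key][start : start + L]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = revcomp(raw)
        rid = f"lr{i + 1:05d}"
        reads[rid] = _inject_errors(rng, raw, params.error_rate, params.error_mix)
        truth.append(ReadTruth(rid, si, mi, start, strand))
    return SimulatedReadSet(reads=reads, truth=truth, paired=False)


def simulate_short_reads(
    master: MasterGenome, config: SimulationConfig | None = None
) -> SimulatedReadSet:
    """Paired short reads at the configured coverage.

    Pair count = coverage x total_length / (2 x read_length); inserts are
    normal at the configured mean/sd (floored at the insert minimum of twice
    the read length); mates sit on opposite strands. Substitution errors
    only. Mate ids carry /1 and /2 suffixes.
    """
    config = config or master.config
    params = config.short_read_params
    if params.insert_mean < 2 * params.read_length:
        raise ValueError(
            f"insert mean {params.insert_mean} < 2 x read length "
            f"{params.read_length}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 2]).generate_state(1)[0]
    )
    probs = _state_frequencies(master, config)
    lengths = master.unit_lengths
    states = master.truth_conformation_space
    circle_lens = [
        np.array([m.length(lengths) for m in st.molecules], dtype=float)
        for st in states
    ]
    total = master.total_length()
    n_pairs = int(round(params.coverage * total / (2 * params.read_length)))
    doubled: dict[tuple[int, int], str] = {}
    reads: dict[str, str] = {}
    truth: list[ReadTruth] = []
    rl = params.read_length
    state_draws = rng.choice(len(states), size=n_pairs, p=probs)
    for i in range(n_pairs):
        si = int(state_draws[i])
        cl = circle_lens[si]
        mi = int(rng.choice(len(cl), p=cl / cl.sum()))
        key = (si, mi)
        if key not in doubled:
            s = master.circle_sequence(states[si].molecules[mi])
            doubled[key] = s + s
        circ_len = int(cl[mi])
        ins = int(round(rng.normal(params.insert_mean, params.insert_sd)))
        ins = max(2 * rl, min(ins, circ_len))
        start = int(rng.integers(circ_len))
        frag = doubled[key][start : start + ins]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        r1 = _inject_errors(rng, frag[:rl], params.error_rate, (1, 0, 0))
        r2 = _inject_errors(rng, revcomp(frag[-rl:]), params.error_rate, (1, 0, 0))
        pid = f"sr{i + 1:06d}"
        reads[f"{pid}/1"] = r1
        reads[f"{pid}/2"] = r2
        truth.append(ReadTruth(pid, si, mi, start, strand))
    return SimulatedReadSet(reads=reads, truth=truth, paired=True)
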