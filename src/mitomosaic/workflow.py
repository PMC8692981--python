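"""End-to-end resolution workflows on fully ground-truthed synthetic data.

These functions wire the stages together the way the method runs on real
data — simulate (or load) reads, map to terminal anchors, build the junction
graph, profile depth, flag repeats, decompose circles, estimate the
conformation mixture, and check component separation — and return the
measured quantities alongside the generator truth for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformations import (
    ConformationSet,
    check_component_separation,
    decompose_circles,
    estimate_mixture,
)
from .depth import DepthTable, depth_profile
from .junctions import (
    JunctionGraph,
    build_graph,
    call_spanning,
    extract_anchors,
    flag_repeat_nodes,
    map_reads_to_anchors,
)
from .mtpt import find_mtpt
from .sequtil import random_seq
from .simulate import (
    MasterGenome,
    SimulationConfig,
    build_master_genome,
    five_circle_demo_config,
    insert_plastid_fragments,
    simulate_long_reads,
    simulate_short_reads,
)

__all__ = ["StructureRecovery", "recover_structure", "mtpt_roundtrip"]


@dataclass
class StructureRecovery:
    """Everything the structure-recovery workflow measured."""

    master: MasterGenome
    graph: JunctionGraph
    depth: DepthTable
    states: list[ConformationSet]
    repeat_ratios: dict[str, float]
    flagged_repeats: set[str]
    mixture_frequencies: list[float] = field(default_factory=list)
    mixture_ratio: str = ""
    n_diagnostic_reads: int = 0
    separation_ok: bool = True
    n_components: int = 0
    mixed_state_indices: tuple[int, int] | None = None


def recover_structure(
    config: SimulationConfig | None = None,
    seed: int = 0,
    mixture: str = "base+fused",
) -> StructureRecovery:
    """Simulate a conformation mixture and re-derive the structure blind.

    With ``mixture='base+fused'`` long reads are drawn 50/50 from the base
    (all-split) state and the fully fused master-ring state, mirroring the
    coexistence of the five basic circles and the two large rings observed
    in real organelle preparations. Only read sequences reach the analysis
    stages; the generator truth is kept solely for the returned comparison
    fields.
    """
    cfg = config or five_circle_demo_config(seed=seed)
    cfg.rng_seed = seed
    master = build_master_genome(cfg)
    states_truth = master.truth_conformation_space
    if mixture == "base+fused":
        fused = min(
            range(len(states_truth)),
            key=lambda i: (len(states_truth[i].molecules), i),
        )
        cfg.conformation_frequencies = {0: 0.5, fused: 0.5}
        mixed = (0, fused)
    else:
        mixed = None

    long_reads = simulate_long_reads(master, cfg)
    short_reads = simulate_short_reads(master, cfg)

    anchors = extract_anchors(master.unit_seqs, 500)
    chains = map_reads_to_anchors(long_reads.reads, anchors)
    graph = build_graph(call_spanning(chains), scaffolds=master.unit_seqs)
    table = depth_profile(short_reads.reads, master.unit_seqs)
    graph = flag_repeat_nodes(graph, table)

    states = decompose_circles(graph)
    ratios = {sid: table.ratio(sid) for sid in graph.nodes}

    result = StructureRecovery(
        master=master,
        graph=graph,
        depth=table,
        states=states,
        repeat_ratios=ratios,
        flagged_repeats=set(graph.repeat_flags),
        mixed_state_indices=mixed,
    )
    if mixed is not None:
        est = estimate_mixture(
            graph, [states_truth[mixed[0]], states_truth[mixed[1]]]
        )
        result.mixture_frequencies = est.frequencies
        result.mixture_ratio = est.ratio
        result.n_diagnostic_reads = est.n_diagnostic_reads
    sep = check_component_separation(graph, states_truth)
    result.separation_ok = sep.ok
    result.n_components = len(sep.components)
    return result


def mtpt_roundtrip(
    seed: int = 0,
    divergences: tuple[float, ...] = (0.0, 0.02, 0.05, 0.10),
    fragment_length: int = 3000,
    donor_length: int = 30000,
):
    """Insert plastid fragments at several divergences and re-detect them.

    Returns a list of dicts with the truth fragment, the best matching call,
    their reciprocal overlap, and the identity error in points.
    """
    cfg = five_circle_demo_config(seed=seed)
    cfg.plastid_fragment_specs = tuple((fragment_length, d) for d in divergences)
    cfg.rng_seed = seed
    master = build_master_genome(cfg)
    donor = random_seq(
        np.random.default_rng(np.random.SeedSequence([seed, 7]).generate_state(1)[0]),
        donor_length,
        0.37,
    )
    insert_plastid_fragments(master, donor, cfg)
    calls = find_mtpt(master.unit_seqs, donor)

    results = []
    for truth in master.plastid_truth:
        best, best_ov = None, 0.0
        for c in calls:
            if c.mt_molecule != truth.mt_molecule:
                continue
            s = max(c.mt_interval[0], truth.mt_interval[0])
            e = min(c.mt_interval[1], truth.mt_interval[1])
            ov = max(0, e - s) / max(
                c.mt_interval[1] - c.mt_interval[0],
                truth.mt_interval[1] - truth.mt_interval[0],
            )
            if ov > best_ov:
                best, best_ov = c, ov
        results.append(
            {
                "truth": truth,
                "call": best,
                "reciprocal_overlap": best_ov,
                "identity_error": (
                    abs(best.identity - truth.identity) if best else float("inf")
                ),
            }
        )
    return results
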