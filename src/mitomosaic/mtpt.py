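"""Mitochondrial plastid DNA (MTPT) detection.

Chloroplast-derived fragments inside a mitogenome are found as local
alignments between the mitochondrial molecules and the plastid genome. The
default identity floor (70%) sits below the ~74% divergence floor seen in
real organelle transfers so the oldest detectable fragment class is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import kmer_seed_index, local_align
from .sequtil import IntervalUnion, round_half_up

__all__ = ["PlastidFragment", "find_mtpt", "coverage_fraction"]


@dataclass
class PlastidFragment:
    """An aligned mitochondrial/plastid interval pair."""

    mt_molecule: str
    mt_interval: tuple[int, int]  # 0-based half-open on the mt molecule
    cp_interval: tuple[int, int]  # on the plastid genome, forward coords
    strand: str
    identity: float  # percent
    length: int  # mt interval length

    @property
    def mt_location(self) -> tuple[str, tuple[int, int]]:
        return (self.mt_molecule, self.mt_interval)


def find_mtpt(
    mt_molecules,
    cp_genome: str,
    min_length: int = 200,
    min_identity: float = 70.0,
    k: int = 13,
) -> list[PlastidFragment]:
    """All mt regions homologous to the plastid genome, longest first.

    Overlapping mt intervals on one molecule are merged to their union; the
    best-identity piece supplies the plastid-side interval of a merged
    record. Returns an empty list when nothing aligns.
    """
    if not cp_genome:
        raise ValueError("plastid genome must be non-empty")
    mols = mt_molecules if isinstance(mt_molecules, dict) else dict(mt_molecules)
    index = kmer_seed_index({"cp": cp_genome}, k)
    frags: list[PlastidFragment] = []
    for mid, seq in mols.items():
        alns = local_align(
            (mid, seq), index=index, min_identity=min_identity, min_length=min_length
        )
        per_mol = [
            PlastidFragment(
                mt_molecule=mid,
                mt_interval=a.query_interval,
                cp_interval=a.target_interval,
                strand=a.strand,
                identity=a.identity,
                length=a.query_span,
            )
            for a in alns
        ]
        frags.extend(_merge_overlapping(per_mol))
    frags.sort(key=lambda f: (-f.length, f.mt_molecule, f.mt_interval))
    return frags


def _merge_overlapping(frags: list[PlastidFragment]) -> list[PlastidFragment]:
    frags = sorted(frags, key=lambda f: f.mt_interval)
    merged: list[PlastidFragment] = []
    for f in frags:
        if merged and f.mt_interval[0] < merged[-1].mt_interval[1]:
            prev = merged[-1]
            best = prev if prev.identity >= f.identity else f
            iv = (prev.mt_interval[0], max(prev.mt_interval[1], f.mt_interval[1]))
            merged[-1] = PlastidFragment(
                mt_molecule=prev.mt_molecule,
                mt_interval=iv,
                cp_interval=best.cp_interval,
                strand=best.strand,
                identity=best.identity,
                length=iv[1] - iv[0],
            )
        else:
            merged.append(f)
    return merged


def coverage_fraction(
    fragments, genome_length: int, coordinate_space: str = "mt"
) -> float:
    """Percent of a genome covered by the fragment intervals (union).

    ``coordinate_space`` selects which side's intervals are pooled: 'mt' uses
    the mitochondrial intervals of all fragments, 'cp' the plastid-side ones
    (the two differ when several mt fragments trace back to overlapping donor
    regions). Rounded half-up to one decimal.
    """
    if genome_length <= 0:
        raise ValueError(f"genome_length must be positive, got {genome_length}")
    if coordinate_space not in ("mt", "cp"):
        raise ValueError("coordinate_space must be 'mt' or 'cp'")
    union = IntervalUnion()
    for f in fragments:
        if isinstance(f, PlastidFragment):
            iv = f.mt_interval if coordinate_space == "mt" else f.cp_interval
        else:
            iv = f  # plain (start, end) pairs are accepted
        if iv[0] < 0 or iv[1] > genome_length:
            raise ValueError(f"interval {iv} outside genome of {genome_length} bp")
        union.add(*iv)
    return round_half_up(100.0 * union.covered() / genome_length, 1)
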