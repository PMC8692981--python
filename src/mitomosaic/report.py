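"""Genome statistics, sequence I/O round-trips, and packaged reference tables.

The summary mirrors the reporting style of organelle genome papers:
scaffold length statistics (median by the midpoint convention), per-molecule
base composition to two decimals, total genome length as the sum of molecule
lengths, and the repeat / MTPT genome fractions to one decimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .depth import repeat_genome_fraction
from .mtpt import coverage_fraction
from .sequtil import round_half_up

__all__ = [
    "CompositionRow",
    "SummaryReport",
    "base_composition",
    "summary_stats",
    "roundtrip_sequences",
    "load_table1",
    "load_table2",
]


@dataclass
class CompositionRow:
    """Base composition of one molecule, percentages to 2 decimals."""

    molecule: str
    A: float
    C: float
    G: float
    T: float
    GC: float
    length: int
    n_ambiguous: int = 0


def base_composition(sequence: str, molecule: str = "") -> CompositionRow:
    """A/C/G/T percentages (half-up, 2 decimals) and GC content.

    Ambiguity codes are counted separately and excluded from the
    percentages; GC is rounded from the raw C+G fraction.
    """
    if not sequence:
        raise ValueError("cannot compute composition of an empty sequence")
    s = sequence.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    acgt = sum(counts.values())
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    pct = {b: 100.0 * c / acgt for b, c in counts.items()}
    return CompositionRow(
        molecule=molecule,
        A=round_half_up(pct["A"], 2),
        C=round_half_up(pct["C"], 2),
        G=round_half_up(pct["G"], 2),
        T=round_half_up(pct["T"], 2),
        GC=round_half_up(pct["C"] + pct["G"], 2),
        length=len(s),
        n_ambiguous=len(s) - acgt,
    )


@dataclass
class SummaryReport:
    """Headline genome statistics."""

    n_scaffolds: int
    scaffold_min: int
    scaffold_max: int
    scaffold_median: float
    molecule_lengths: list[int]
    total_length: int
    repeat_fraction: float
    mtpt_fraction: float
    compositions: list[CompositionRow] = field(default_factory=list)


def _median_midpoint(values: list[int]) -> float:
    """Mean of the two central values for even counts."""
    v = sorted(values)
    n = len(v)
    mid = n // 2
    if n % 2:
        return float(v[mid])
    return (v[mid - 1] + v[mid]) / 2


def summary_stats(
    scaffold_lengths,
    molecule_lengths,
    repeats=(),
    mtpt_fragments=(),
) -> SummaryReport:
    """Scaffold stats, molecule totals, and repeat / MTPT genome fractions."""
    sl = list(scaffold_lengths)
    ml = list(molecule_lengths)
    if not sl or not ml:
        raise ValueError("length lists must be non-empty")
    total = sum(ml)
    return SummaryReport(
        n_scaffolds=len(sl),
        scaffold_min=min(sl),
        scaffold_max=max(sl),
        scaffold_median=_median_midpoint(sl),
        molecule_lengths=ml,
        total_length=total,
        repeat_fraction=repeat_genome_fraction(repeats, total) if repeats else 0.0,
        mtpt_fraction=(
            coverage_fraction(mtpt_fragments, total, "mt") if mtpt_fragments else 0.0
        ),
    )


def roundtrip_sequences(path, records=None, circular: bool = False):
    """Write records to FASTA/FASTQ (by extension) and/or read them back.

    With ``records`` given they are written first (FASTA wrapped at 70
    columns; ``circular=True`` adds ``circular=true`` to descriptions), then
    the file is re-read and the parsed records returned as (id, seq) pairs in
    file order. Malformed input raises with the offending line number.
    """
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    if records is not None:
        recs = []
        items = records.items() if isinstance(records, dict) else records
        for rid, seq in items:
            r = SeqRecord(Seq(seq), id=rid,
                          description="circular=true" if circular else "")
            if fmt == "fastq":
                r.letter_annotations["phred_quality"] = [40] * len(seq)
            recs.append(r)
        with open(path, "w") as fh:
            if fmt == "fasta":
                writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
                writer.write_file(recs)
            else:
                SeqIO.write(recs, fh, "fastq")
    _validate_format(path, fmt)
    out = [(r.id, str(r.seq)) for r in SeqIO.parse(path, fmt)]
    if not out:
        warnings.warn(f"{path} contains no records", stacklevel=2)
    return out


def _validate_format(path: Path, fmt: str) -> None:
    lead = ">" if fmt == "fasta" else "@"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(lead):
                    raise ValueError(
                        f"{path}: line {lineno}: expected a {fmt} header "
                        f"starting with {lead!r}"
                    )
                return


def _load_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("mitomosaic").joinpath("data", name)
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def load_table1() -> pd.DataFrame:
    """Primary scaffold lengths of the marama mitogenome assembly
    (unit, length_bp); 16 rows as printed."""
    return _load_packaged("table1_scaffolds.tsv")


def load_table2() -> pd.DataFrame:
    """Subgenome features of the marama mitogenome: per-molecule base
    composition and length for the five basic circles (M1-M5) and the two
    recombined master rings (LS1, LS2)."""
    return _load_packaged("table2_molecules.tsv")
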