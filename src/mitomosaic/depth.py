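"""Short-read depth profiling and long-repeat discovery.

Two-copy repeats collapse into a single scaffold during assembly, so short
reads from both genomic copies pile onto it and its depth of coverage runs at
about twice the single-copy baseline. ``depth_profile`` measures per-scaffold
depth by exact k-mer assignment (multi-mapping k-mers split fractionally so
the x2 signal survives shared sequence); ``find_long_repeats`` finds the >1 kb
near-identical segment pairs directly from assembled molecule sequences.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from statistics import median

import numpy as np

from .align import kmer_seed_index, local_align
from .conformations import RepeatUnit
from .sequtil import revcomp, round_half_up

__all__ = [
    "DepthRow",
    "DepthTable",
    "depth_profile",
    "find_long_repeats",
    "repeat_genome_fraction",
]


@dataclass
class DepthRow:
    median: float
    mean: float
    positional: np.ndarray  # depth at each k-mer start position


@dataclass
class DepthTable:
    """Per-scaffold depth plus the genome single-copy baseline.

    The baseline is the median of per-scaffold medians over scaffolds whose
    ratio to a provisional all-scaffold baseline stays below 1.5 (i.e. the
    presumed single-copy set).
    """

    per_scaffold: dict[str, DepthRow]
    baseline: float
    k: int

    def ratio(self, scaffold_id: str) -> float:
        if self.baseline <= 0:
            return 1.0
        return self.per_scaffold[scaffold_id].median / self.baseline

    def medians(self) -> dict[str, float]:
        return {sid: row.median for sid, row in self.per_scaffold.items()}


def _canonical(kmer: str, rc_kmer: str) -> str:
    return kmer if kmer <= rc_kmer else rc_kmer


def depth_profile(short_reads, scaffolds, k: int = 21) -> DepthTable:
    """Per-position depth from exact canonical k-mer matches.

    Each read k-mer that matches the index adds 1/n at the start position of
    each of its n matching scaffold locations, so per-scaffold medians track
    read coverage while two-copy sequence shared between scaffolds still
    accumulates both copies' reads. Depth is defined over k-mer start
    positions [0, L-k].
    """
    seqs = _seqdict(scaffolds)
    reads = _seqdict(short_reads)
    if not seqs or not reads:
        raise ValueError("reads and scaffolds must be non-empty")
    max_read = max(len(r) for r in reads.values())
    if k > max_read:
        raise ValueError(f"k={k} exceeds the longest read ({max_read} bp)")

    postings: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for sid, seq in seqs.items():
        rc = revcomp(seq)
        L = len(seq)
        for i in range(L - k + 1):
            postings[_canonical(seq[i : i + k], rc[L - k - i : L - i])].append((sid, i))
    postings = dict(postings)

    arrays = {sid: np.zeros(max(1, len(seq) - k + 1)) for sid, seq in seqs.items()}
    for rseq in reads.values():
        if len(rseq) < k:
            continue
        rc = revcomp(rseq)
        L = len(rseq)
        # a read covers L positions but contributes only L-k+1 k-mer starts;
        # rescale so the per-position depth tracks read coverage
        scale = L / (L - k + 1)
        for i in range(L - k + 1):
            hit = postings.get(_canonical(rseq[i : i + k], rc[L - k - i : L - i]))
            if not hit:
                continue
            w = scale / len(hit)
            for sid, pos in hit:
                arrays[sid][pos] += w

    per = {
        sid: DepthRow(float(np.median(a)), float(a.mean()), a)
        for sid, a in arrays.items()
    }
    meds = sorted(r.median for r in per.values())
    base0 = median(meds) if meds else 0.0
    single = [m for m in meds if base0 == 0 or m / base0 < 1.5]
    baseline = float(median(single)) if single else float(base0)
    return DepthTable(per_scaffold=per, baseline=baseline, k=k)


def _seqdict(x) -> dict[str, str]:
    if isinstance(x, dict):
        return {k: getattr(v, "seq", v) for k, v in x.items()}
    out = {}
    for item in x:
        if isinstance(item, tuple):
            out[item[0]] = item[1]
        else:
            out[item.id] = item.seq
    return out


def find_long_repeats(
    molecules,
    min_repeat_len: int = 1000,
    min_identity: float = 98.0,
    k: int = 21,
    circular: bool = True,
) -> list[RepeatUnit]:
    """All maximal two-copy segments >= ``min_repeat_len`` at >= ``min_identity``.

    Molecules are treated as circles (sequences are doubled internally so
    origin-crossing copies are found; reported coordinates are reduced modulo
    the molecule length, an interval end past the length denotes wraparound).
    Copies on the same strand make a direct repeat, opposite strands an
    inverted one.
    """
    seqs = _seqdict(molecules)
    doubled = {
        sid: (s + s if circular and len(s) >= k else s) for sid, s in seqs.items()
    }
    index = kmer_seed_index(doubled, k)
    found = []  # (qmol, qiv, tmol, tiv, strand, identity, length)
    for qid, qseq in seqs.items():
        alns = local_align(
            (qid, qseq),
            index=index,
            min_identity=min_identity,
            min_length=min_repeat_len,
            join_gap=200,
        )
        L = len(seqs[qid])
        for a in alns:
            tid = a.target_id
            Lt = len(seqs[tid])
            ts, te = a.target_interval
            ts_mod = ts % Lt
            tiv = (ts_mod, ts_mod + (te - ts))
            if tid == qid and a.strand == "+":
                qs = a.query_interval[0]
                if (ts - qs) % Lt == 0 or abs(ts_mod - qs) < k:
                    continue  # the segment aligned to itself
            found.append(
                (qid, a.query_interval, tid, tiv, a.strand, a.identity, a.length)
            )

    # deduplicate symmetric / re-discovered pairs; keep the longest extent
    kept = []
    for cand in sorted(found, key=lambda f: -f[6]):
        if not any(_same_pair(cand, other) for other in kept):
            kept.append(cand)

    repeats = []
    for n, (qm, qiv, tm, tiv, strand, ident, length) in enumerate(
        sorted(kept, key=lambda f: (-f[6], f[0], f[1]))
    ):
        kind = "direct" if strand == "+" else "inverted"
        repeats.append(
            RepeatUnit(
                id=f"rep{n + 1}",
                length=length,
                kind=kind,
                copy_locations=((qm, qiv, "+"), (tm, tiv, strand)),
            )
        )
    return repeats


def _loc_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _same_pair(f1, f2) -> bool:
    """Two found pairs describe the same repeat (in either copy order)."""
    locs1 = ((f1[0], f1[1]), (f1[2], f1[3]))
    locs2 = ((f2[0], f2[1]), (f2[2], f2[3]))
    for l2 in (locs2, locs2[::-1]):
        ok = True
        for (m1, iv1), (m2, iv2) in zip(locs1, l2):
            span = min(iv1[1] - iv1[0], iv2[1] - iv2[0])
            if m1 != m2 or _loc_overlap(iv1, iv2) < 0.5 * span:
                ok = False
                break
        if ok:
            return True
    return False


def repeat_genome_fraction(repeats, total_length: int) -> float:
    """Percent of the genome occupied by two-copy repeats.

    100 x (sum of 2 x length over repeats) / total_length, rounded half-up to
    one decimal — each repeat is present twice, and the total genome length
    counts both copies.
    """
    if total_length <= 0:
        raise ValueError(f"total_length must be positive, got {total_length}")
    s = sum(2 * (r.length if hasattr(r, "length") else r) for r in repeats)
    return round_half_up(100.0 * s / total_length, 1)
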