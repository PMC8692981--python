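"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
full quadratic Smith-Waterman for local alignment identity, token-list
enumeration for circular decompositions, per-base marking for interval
unions, sliding windows for k-mer postings, and per-diagonal numpy scans for
exact repeat pairs.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

GAP = -2
MATCH = 1
MISMATCH = -1


def smith_waterman_identity(q: str, t: str):
    """Optimal local alignment by full DP; returns (score, identity_pct).

    Unit scores (match +1, mismatch -1, gap -2); identity is matches over
    alignment columns of one optimal traceback (diagonal preferred).
    """
    n, m = len(q), len(t)
    qa = np.frombuffer(q.encode(), dtype="S1")
    ta = np.frombuffer(t.encode(), dtype="S1")
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    js = np.arange(1, m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        s = np.where(ta == qa[i - 1], MATCH, MISMATCH).astype(np.int32)
        base = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + GAP)
        base = np.maximum(base, 0)
        acc = np.maximum.accumulate(
            np.concatenate(([np.int32(0)], base - GAP * js))
        )
        H[i, 1:] = np.maximum(base, acc[1:] + GAP * js)
    score = int(H.max())
    if score == 0:
        return 0, 0.0
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    matches = cols = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        diag = H[i - 1, j - 1] + (MATCH if q[i - 1] == t[j - 1] else MISMATCH)
        if h == diag:
            matches += q[i - 1] == t[j - 1]
            cols += 1
            i, j = i - 1, j - 1
        elif h == H[i - 1, j] + GAP:
            cols += 1
            i -= 1
        elif h == H[i, j - 1] + GAP:
            cols += 1
            j -= 1
        else:
            break
    return score, 100.0 * matches / cols


def naive_kmer_postings(seqs: dict[str, str], k: int):
    """Sliding-window enumeration of both-strand k-mer postings."""
    comp = str.maketrans("ACGT", "TGCA")
    postings = defaultdict(list)
    for sid, seq in seqs.items():
        rc = seq.translate(comp)[::-1]
        for i in range(len(seq) - k + 1):
            postings[seq[i : i + k]].append((sid, i, "+"))
            postings[rc[i : i + k]].append((sid, i, "-"))
    return dict(postings)


def interval_union_length(intervals, genome_length: int) -> int:
    """Per-base marking of half-open intervals."""
    mask = np.zeros(genome_length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())


def _exit(u, s):
    return (u, "tail" if s > 0 else "head")


def _entry(u, s):
    return (u, "head" if s > 0 else "tail")


def _circle_edges(circle):
    n = len(circle)
    out = set()
    for i in range(n):
        u, s = circle[i]
        v, t = circle[(i + 1) % n]
        out.add(frozenset((_exit(u, s), _entry(v, t))))
    return out


def _canonical_circle(circle):
    readings = [tuple(circle), tuple((u, -s) for u, s in reversed(circle))]
    best = None
    for r in readings:
        for i in range(len(r)):
            cand = r[i:] + r[:i]
            if best is None or cand < best:
                best = cand
    return best


def brute_force_decompositions(nodes: dict[str, int], edges: set) -> set:
    """All circular decompositions by token-list enumeration.

    Tokens (one per scaffold copy) are arranged into signed circles; every
    partial adjacency is checked against the edge set as it is laid down.
    Returns the set of canonical conformation signatures.
    """
    tokens: list[str] = []
    for s in sorted(nodes):
        tokens += [s] * nodes[s]
    results = set()

    def rec(remaining: list[str], circles, cur):
        if cur is None:
            if not remaining:
                sig = tuple(sorted(_canonical_circle(c) for c in circles))
                results.add(sig)
                return
            first = remaining[0]
            rec(remaining[1:], circles, [(first, 1)])
            return
        # option 1: close the current circle
        u, s = cur[-1]
        v, t = cur[0]
        if frozenset((_exit(u, s), _entry(v, t))) in edges:
            rec(remaining, circles + [cur], None)
        # option 2: extend with any remaining token, either sign
        seen = set()
        for i, tok in enumerate(remaining):
            if tok in seen:
                continue
            seen.add(tok)
            rest = remaining[:i] + remaining[i + 1 :]
            for sign in (1, -1):
                if frozenset((_exit(u, s), _entry(tok, sign))) in edges:
                    rec(rest, circles, cur + [(tok, sign)])

    rec(tokens, [], None)
    return results


def exact_repeat_pairs(seq: str, min_len: int):
    """Maximal exact repeated segment pairs within one (linear) sequence.

    Per-diagonal numpy match runs, forward (direct) and against the reverse
    complement (inverted). Returns tuples (start1, start2, length, kind) with
    start1 < start2, each run maximal, length >= min_len.
    """
    comp = str.maketrans("ACGT", "TGCA")
    a = np.frombuffer(seq.encode(), dtype="S1")
    n = len(a)
    out = []
    for d in range(1, n):
        eq = a[: n - d] == a[d:]
        for s, ln in _runs(eq):
            if ln >= min_len:
                out.append((s, s + d, ln, "direct"))
    rc = np.frombuffer(seq.translate(comp)[::-1].encode(), dtype="S1")
    seen = set()
    for d in range(-(n - 1), n):
        if d >= 0:
            eq = a[: n - d] == rc[d:]
            off_a, off_r = 0, d
        else:
            eq = a[-d:] == rc[: n + d]
            off_a, off_r = -d, 0
        for s, ln in _runs(eq):
            if ln < min_len:
                continue
            s1 = off_a + s  # on seq
            s2 = n - (off_r + s + ln)  # rc run start mapped back to seq
            key = tuple(sorted([(s1, ln), (s2, ln)]))
            if s1 == s2 or key in seen:
                continue
            seen.add(key)
            out.append((min(s1, s2), max(s1, s2), ln, "inverted"))
    return out


def _runs(mask: np.ndarray):
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e - s)
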