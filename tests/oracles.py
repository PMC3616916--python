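"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (full enumeration, plain python) kept
separate from the library code paths they check.
"""

from __future__ import annotations

from itertools import combinations

STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def brute_force_orf(seq: str, frames=(1, 2, 3)):
    """Enumerate every maximal stop-free in-frame interval in every frame.

    Returns (frame, start, end, has_start) on forward-read coordinates with
    the same tie-breaks the library documents: longest, then frame order,
    then smaller scan start.
    """
    seq = seq.upper()
    n = len(seq)
    candidates = []  # (length, frame_order, scan_start, frame, fwd_start, fwd_end, sub)
    for order, f in enumerate(frames):
        s = seq if f > 0 else seq.translate(_COMP)[::-1]
        off = f - 1 if f > 0 else -f - 1
        for i in range(off, n - 2, 3):
            j = i
            while j + 3 <= n and s[j : j + 3] not in STOPS:
                j += 3
            sub = s[i:j]
            if f > 0:
                fwd = (i, j)
            else:
                fwd = (n - j, n - i)
            candidates.append((j - i, order, i, f, fwd[0], fwd[1], sub))
        # also the degenerate zero-length interval at the frame offset
        candidates.append((0, order, off, f, off if f > 0 else n - off, off if f > 0 else n - off, ""))
    length, _, _, f, start, end, sub = sorted(
        candidates, key=lambda c: (-c[0], c[1], c[2])
    )[0]
    has_start = any(sub[k : k + 3] == "ATG" for k in range(0, len(sub) - 2, 3))
    return f, start, end, has_start


def brute_force_filter(rows, e_max=1e-5, min_len=33):
    """Row-by-row scan of (e_value, aligned_length) pairs."""
    return [
        idx
        for idx, (e, length) in enumerate(rows)
        if e <= e_max and length >= min_len
    ]


def brute_force_exclusive(presence: dict[str, set[str]], focal) -> set[str]:
    """Set-algebra enumeration: families present in >=1 focal, 0 non-focal.

    ``presence`` maps family -> set of species carrying it.
    """
    focal = set(focal)
    return {
        fam
        for fam, species in presence.items()
        if species & focal and not (species - focal)
    }


def brute_force_quantile(values, q: float) -> float:
    """Sort-and-interpolate empirical quantile (linear between order stats)."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q
    lo = int(h)
    if lo >= n - 1:
        return xs[-1]
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])


def brute_force_best_hit(rows):
    """Best hit per query from (query, subject, e_value, bit_score) tuples."""
    best: dict[str, tuple] = {}
    for q, s, e, b in rows:
        cur = best.get(q)
        if cur is None or (e, -b, s) < (cur[2], -cur[3], cur[1]):
            best[q] = (q, s, e, b)
    return best


def enumerate_exclusive_counts(presence: dict[str, set[str]], species, k: int):
    """Exclusive-family count for every k-combination of species."""
    return {
        combo: len(brute_force_exclusive(presence, combo))
        for combo in combinations(sorted(species), k)
    }
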