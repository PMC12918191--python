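"""Optimized Spectral Alignment: threshold-scored dynamic programming.

Two sorted peak lists are aligned with a Needleman–Wunsch-style recurrence
over a zero-initialized (m+1)×(n+1) matrix

    dp[i,j] = max( dp[i-1,j-1] + final_score,
                   dp[i-1,j]   + gap_penalty,
                   dp[i,j-1]   + gap_penalty )

where ``final_score`` is the intensity score when |Δm/z| ≤ mz_tolerance and a
fixed mismatch penalty of −1 otherwise.  The zero-initialized boundary makes
leading gaps free (a semi-global flavor); trailing gaps are charged on the
way to the dp[m,n] corner, which is the reported raw score.  When several
tracebacks achieve the optimum, the one minimizing the city-block distance
Σ|qs_mz − ss_mz| over its aligned pairs is chosen (accumulated without the
tolerance gate); any residual tie is broken deterministically
diagonal > up > left.

``osa_brute_force`` enumerates every monotone alignment under the same
boundary convention and exists purely as an independent oracle for tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

MISMATCH_SCORE = -1.0


@dataclass(frozen=True)
class OSAParams:
    """Alignment parameters.

    mz_tolerance: Da window within which two peaks may be matched (0.005).
    gap_penalty: negative score per charged gap step (−0.1); must be smaller
        in magnitude than the mismatch penalty (−1).
    use_intensities: when off, every in-tolerance match scores exactly 1.
    """

    mz_tolerance: float = 0.005
    gap_penalty: float = -0.1
    mismatch_score: float = MISMATCH_SCORE
    use_intensities: bool = False

    def __post_init__(self):
        if self.mz_tolerance <= 0:
            raise ValueError("mz_tolerance must be > 0")
        if self.gap_penalty >= 0:
            raise ValueError("gap_penalty must be negative")
        if abs(self.gap_penalty) >= abs(self.mismatch_score):
            raise ValueError("|gap_penalty| must be < |mismatch_score|")


@dataclass
class AlignmentResult:
    raw_score: float
    normalized_score: float
    pairs: list[tuple[int, int]] = field(default_factory=list)
    global_cityblock: float = 0.0


def intensity_score(qi: float, sj: float) -> float:
    """1 / (1 + |qi − sj|²) on max-normalized intensities; 1 iff equal."""
    d = qi - sj
    return 1.0 / (1.0 + d * d)


def _as_arrays(peaks) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(peaks, "mz_array"):
        return peaks.mz_array, peaks.intensity_array
    arr = np.asarray(list(peaks), dtype=float)
    if arr.size == 0:
        return np.empty(0), np.empty(0)
    return arr[:, 0], arr[:, 1]


def _check_sorted(mz: np.ndarray, label: str) -> None:
    if mz.size > 1 and np.any(np.diff(mz) < 0):
        raise ValueError(f"{label} peak list must be sorted ascending in m/z")


def _normalize(intensity: np.ndarray) -> np.ndarray:
    top = intensity.max() if intensity.size else 0.0
    return intensity / top if top > 0 else intensity


def _prepare(qs, ss, params):
    qmz, qint = _as_arrays(qs)
    smz, sint = _as_arrays(ss)
    _check_sorted(qmz, "query")
    _check_sorted(smz, "subject")
    if params.use_intensities:
        qint = _normalize(qint)
        sint = _normalize(sint)
    return qmz, qint, smz, sint


def _final_score(qmz, qint, smz, sint, i, j, params) -> float:
    """Score of aligning query peak i with subject peak j (0-based)."""
    if abs(qmz[i] - smz[j]) <= params.mz_tolerance:
        return intensity_score(qint[i], sint[j]) if params.use_intensities else 1.0
    return params.mismatch_score


def osa_score(qs, ss, params: OSAParams | None = None) -> AlignmentResult:
    """Align two sorted peak lists and return score, pairs and tie-break.

    Inputs may be :class:`~speclib_repair.spectral_io.Spectrum` objects or
    iterables of (mz, intensity) pairs.  ``raw_score`` is dp[m,n];
    ``normalized_score`` is raw/max(m, n) clipped to [0, 1] for reporting.
    """
    if params is None:
        params = OSAParams()
    qmz, qint, smz, sint = _prepare(qs, ss, params)
    m, n = len(qmz), len(smz)
    gap = params.gap_penalty

    dp = [[0.0] * (n + 1) for _ in range(m + 1)]
    cb = [[0.0] * (n + 1) for _ in range(m + 1)]  # min city-block among optima
    for i in range(1, m + 1):
        di, ci = dp[i], cb[i]
        dim1, cim1 = dp[i - 1], cb[i - 1]
        for j in range(1, n + 1):
            fs = _final_score(qmz, qint, smz, sint, i - 1, j - 1, params)
            diag = dim1[j - 1] + fs
            up = dim1[j] + gap
            left = di[j - 1] + gap
            best = max(diag, up, left)
            di[j] = best
            c = None
            if diag == best:
                c = cim1[j - 1] + abs(qmz[i - 1] - smz[j - 1])
            if up == best and (c is None or cim1[j] < c):
                c = cim1[j]
            if left == best and (c is None or ci[j - 1] < c):
                c = ci[j - 1]
            ci[j] = c

    pairs, cityblock = _traceback(dp, cb, qmz, qint, smz, sint, params)
    raw = dp[m][n]
    denom = max(m, n)
    normalized = min(1.0, max(0.0, raw / denom)) if denom else 0.0
    return AlignmentResult(raw_score=raw, normalized_score=normalized,
                           pairs=pairs, global_cityblock=cityblock)


def _traceback(dp, cb, qmz, qint, smz, sint, params):
    m, n = len(qmz), len(smz)
    gap = params.gap_penalty
    pairs: list[tuple[int, int]] = []
    i, j = m, n
    while i > 0 and j > 0:
        target, ctarget = dp[i][j], cb[i][j]
        fs = _final_score(qmz, qint, smz, sint, i - 1, j - 1, params)
        step_cb = abs(qmz[i - 1] - smz[j - 1])
        if dp[i - 1][j - 1] + fs == target and cb[i - 1][j - 1] + step_cb == ctarget:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif dp[i - 1][j] + gap == target and cb[i - 1][j] == ctarget:
            i -= 1
        elif dp[i][j - 1] + gap == target and cb[i][j - 1] == ctarget:
            j -= 1
        else:  # pragma: no cover - accumulators are filled consistently
            raise AssertionError("inconsistent traceback state")
    pairs.reverse()
    return pairs, cb[m][n]


def traceback_min_cityblock(qs, ss, params: OSAParams | None = None):
    """Return (pairs, global_cityblock) of the minimum-city-block optimum.

    Convenience wrapper over :func:`osa_score` exposing only the chosen
    traceback.
    """
    res = osa_score(qs, ss, params)
    return res.pairs, res.global_cityblock


_BRUTE_FORCE_LIMIT = 8


def _monotone_matchings(m: int, n: int):
    """Yield every monotone set of index pairs between ranges m and n."""
    def rec(start_i, start_j):
        yield ()
        for i in range(start_i, m):
            for j in range(start_j, n):
                for rest in rec(i + 1, j + 1):
                    yield ((i, j),) + rest
    yield from rec(0, 0)


def osa_brute_force_full(qs, ss, params: OSAParams | None = None):
    """Exhaustive oracle: (raw_score, global_cityblock, pairs).

    Enumerates all monotone alignments; per alignment the score is the sum
    of pair scores plus gap penalties for unmatched peaks between and after
    matches, with free leading skips along one zero-initialized boundary
    (cost gap·min(i₁, j₁) ahead of the first pair).  Selection is by maximal
    score, then minimal city-block.  Test oracle only; sizes are capped.
    """
    if params is None:
        params = OSAParams()
    qmz, qint, smz, sint = _prepare(qs, ss, params)
    m, n = len(qmz), len(smz)
    if m > _BRUTE_FORCE_LIMIT or n > _BRUTE_FORCE_LIMIT:
        raise ValueError(f"brute force capped at {_BRUTE_FORCE_LIMIT} peaks")
    gap = params.gap_penalty

    best = None
    for pairs in _monotone_matchings(m, n):
        if pairs:
            i1, j1 = pairs[0]
            score = gap * min(i1, j1)
            cityblock = 0.0
            prev = None
            for (i, j) in pairs:
                if prev is not None:
                    score += gap * ((i - prev[0] - 1) + (j - prev[1] - 1))
                score += _final_score(qmz, qint, smz, sint, i, j, params)
                cityblock += abs(qmz[i] - smz[j])
                prev = (i, j)
            score += gap * ((m - 1 - prev[0]) + (n - 1 - prev[1]))
        else:
            score = gap * min(m, n)
            cityblock = 0.0
        key = (score, -cityblock)
        if best is None or key > best[0]:
            best = (key, pairs)
    (score, neg_cb), pairs = best
    return score, -neg_cb, list(pairs)


def osa_brute_force(qs, ss, params: OSAParams | None = None) -> float:
    """Exhaustive-alignment raw score (independent test oracle)."""
    return osa_brute_force_full(qs, ss, params)[0]
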