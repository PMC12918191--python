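"""Spectral comparison metrics benchmarked alongside the DP alignment.

Three families:

* peak-matching similarities — greedy cosine (matchms-style: greedily pair
  peaks within an m/z tolerance in descending intensity-product order, score
  Σ qᵢsⱼ / √(Σqᵢ²·Σsⱼ²)) and spectral-entropy similarity
  (1 − (2·S_mix − S_q − S_s)/ln 4 over Shannon entropies of the two
  probability-normalized spectra and their half-weight mixture);
* generic vector distances (SciPy) — city-block, Bray–Curtis, Canberra,
  Euclidean, squared Euclidean, Minkowski (p=3), Chebyshev, correlation,
  cosine and Jensen–Shannon — computed on fixed-width binned intensity
  vectors over the union m/z range of the pair, since unequal-length peak
  lists are not directly comparable as vectors;
* the DP alignment itself, registered under ``osa``.

A registry maps metric names to :class:`MetricSpec` objects so workflows can
address any metric uniformly and know whether to maximize (similarity) or
minimize (distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import distance as _sdist
from scipy.stats import entropy as _shannon

from .osa import OSAParams, _as_arrays, osa_score

DEFAULT_BIN_WIDTH = 0.01  # Da; how generic vector metrics see a spectrum
DEFAULT_COSINE_TOLERANCE = 0.1  # Da, matchms default
DEFAULT_ENTROPY_TOLERANCE = 0.02  # Da, spectral-entropy convention

INTENSITY_AWARE = ("osa", "entropy", "cosine_greedy")


def cosine_greedy(qs, ss, tolerance: float = DEFAULT_COSINE_TOLERANCE) -> float:
    """Greedy-cosine similarity in [0, 1]; 1 for identical spectra.

    Peaks are max-normalized per spectrum, candidate pairs within
    ``tolerance`` are taken greedily in descending intensity-product order
    (ties: smaller |Δm/z|, then index), each peak used once.
    """
    qmz, qint = _as_arrays(qs)
    smz, sint = _as_arrays(ss)
    if qmz.size == 0 or smz.size == 0:
        return 0.0
    qint = qint / qint.max() if qint.max() > 0 else qint
    sint = sint / sint.max() if sint.max() > 0 else sint
    lo = np.searchsorted(smz, qmz - tolerance, side="left")
    hi = np.searchsorted(smz, qmz + tolerance, side="right")
    if not np.any(hi > lo):
        return 0.0
    candidates = []
    for i in range(qmz.size):
        for j in range(lo[i], hi[i]):
            candidates.append((-qint[i] * sint[j], abs(qmz[i] - smz[j]), i, j))
    candidates.sort()
    used_q: set[int] = set()
    used_s: set[int] = set()
    num = 0.0
    for negprod, _, i, j in candidates:
        if i in used_q or j in used_s:
            continue
        used_q.add(i)
        used_s.add(j)
        num -= negprod
    denom = np.sqrt((qint ** 2).sum() * (sint ** 2).sum())
    return float(num / denom) if denom > 0 else 0.0


def _merge_within(mz: np.ndarray, inten: np.ndarray, tolerance: float):
    """Consolidate peaks closer than ``tolerance`` (greedy, left to right).

    Cluster anchor is the first peak; merged m/z is the intensity-weighted
    mean, intensities sum.
    """
    if mz.size == 0:
        return mz, inten
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    out_mz, out_int = [], []
    anchor = mz[0]
    acc_w, acc_i = mz[0] * inten[0], inten[0]
    for k in range(1, mz.size):
        if mz[k] - anchor <= tolerance:
            acc_w += mz[k] * inten[k]
            acc_i += inten[k]
        else:
            out_mz.append(acc_w / acc_i if acc_i > 0 else anchor)
            out_int.append(acc_i)
            anchor = mz[k]
            acc_w, acc_i = mz[k] * inten[k], inten[k]
    out_mz.append(acc_w / acc_i if acc_i > 0 else anchor)
    out_int.append(acc_i)
    return np.array(out_mz), np.array(out_int)


def spectral_entropy(peaks, tolerance: float = DEFAULT_ENTROPY_TOLERANCE) -> float:
    """Shannon entropy −Σ p ln p of a tolerance-merged, sum-normalized spectrum."""
    mz, inten = _as_arrays(peaks)
    if mz.size == 0:
        return 0.0
    _, inten = _merge_within(mz, inten, tolerance)
    total = inten.sum()
    if total <= 0:
        return 0.0
    return float(_shannon(inten / total))


def entropy_similarity(qs, ss, tolerance: float = DEFAULT_ENTROPY_TOLERANCE) -> float:
    """Spectral-entropy similarity in [0, 1].

    1 − (2·S_mix − S_q − S_s)/ln 4, with S the Shannon entropy of the
    sum-normalized (tolerance-merged) spectrum and S_mix the entropy of the
    half-weight merged mixture.
    """
    qmz, qint = _as_arrays(qs)
    smz, sint = _as_arrays(ss)
    if qmz.size == 0 or smz.size == 0:
        return 0.0
    qmz, qint = _merge_within(qmz, qint, tolerance)
    smz, sint = _merge_within(smz, sint, tolerance)
    if qint.sum() <= 0 or sint.sum() <= 0:
        return 0.0
    qp = qint / qint.sum()
    sp = sint / sint.sum()
    s_q = float(_shannon(qp))
    s_s = float(_shannon(sp))
    mix_mz = np.concatenate([qmz, smz])
    mix_p = np.concatenate([qp / 2.0, sp / 2.0])
    mix_mz, mix_p = _merge_within(mix_mz, mix_p, tolerance)
    s_mix = float(_shannon(mix_p))
    sim = 1.0 - (2.0 * s_mix - s_q - s_s) / np.log(4.0)
    return float(min(1.0, max(0.0, sim)))


def bin_spectrum(peaks, bin_width: float = DEFAULT_BIN_WIDTH,
                 mz_range: tuple[float, float] | None = None) -> np.ndarray:
    """Sum intensities into half-open bins [k·w, (k+1)·w).

    ``mz_range`` (lo, hi) fixes the vector extent so paired spectra can be
    binned over their union range; by default the spectrum's own range is
    used.  Peaks outside the range are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mz, inten = _as_arrays(peaks)
    if mz_range is None:
        if mz.size == 0:
            return np.zeros(0)
        mz_range = (float(mz.min()), float(mz.max()))
    k_lo = int(np.floor(mz_range[0] / bin_width))
    k_hi = int(np.floor(mz_range[1] / bin_width))
    vec = np.zeros(k_hi - k_lo + 1)
    if mz.size:
        idx = np.floor(mz / bin_width).astype(int) - k_lo
        keep = (idx >= 0) & (idx < vec.size)
        np.add.at(vec, idx[keep], inten[keep])
    return vec


def bin_pair(qs, ss, bin_width: float = DEFAULT_BIN_WIDTH):
    """Bin two spectra over their shared (union) m/z range."""
    qmz, _ = _as_arrays(qs)
    smz, _ = _as_arrays(ss)
    allmz = np.concatenate([qmz, smz])
    if allmz.size == 0:
        return np.zeros(1), np.zeros(1)
    rng = (float(allmz.min()), float(allmz.max()))
    return bin_spectrum(qs, bin_width, rng), bin_spectrum(ss, bin_width, rng)


_JS_MAX = float(np.sqrt(np.log(2.0)))

VECTOR_METRIC_NAMES = (
    "cityblock", "braycurtis", "canberra", "euclidean", "sqeuclidean",
    "minkowski", "chebyshev", "correlation", "cosine", "jensenshannon",
)


def vector_distance(name: str, u, v, p: float = 3.0) -> float:
    """Dispatch a named SciPy vector distance on equal-length vectors.

    Degenerate inputs for the normalized metrics (all-zero vector for
    cosine/correlation/Jensen–Shannon, zero variance for correlation) are
    defined as the maximal distance, with a warning — unless the vectors are
    identical, which is distance 0 by convention.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if name not in VECTOR_METRIC_NAMES:
        raise KeyError(f"unknown vector metric {name!r}")
    if name in ("cosine", "correlation", "jensenshannon"):
        degenerate = (not np.any(u)) or (not np.any(v))
        if name == "correlation":
            degenerate = degenerate or np.ptp(u) == 0 or np.ptp(v) == 0
        if degenerate:
            if np.array_equal(u, v):
                return 0.0
            maximal = {"cosine": 1.0, "correlation": 2.0, "jensenshannon": _JS_MAX}[name]
            warnings.warn(f"{name}: degenerate input vector; reporting maximal "
                          f"distance {maximal}", UserWarning, stacklevel=2)
            return maximal
    if name == "minkowski":
        return float(_sdist.minkowski(u, v, p=p))
    return float(getattr(_sdist, name)(u, v))


@dataclass(frozen=True)
class MetricSpec:
    """A named comparison metric and how to interpret its output.

    ``kind`` is ``similarity`` (best match by maximum) or ``distance``
    (best match by minimum).
    """

    name: str
    kind: str
    tolerance: float | None = None
    bin_width: float | None = None
    p: float | None = None

    def compare(self, query, subject, use_intensities: bool = True) -> float:
        """Score one spectrum pair; with ``use_intensities`` off, every peak
        weighs 1 and only the m/z layout matters."""
        qmz, qint = _as_arrays(query)
        smz, sint = _as_arrays(subject)
        if not use_intensities:
            qint = np.ones_like(qmz)
            sint = np.ones_like(smz)
        qs = np.column_stack([qmz, qint]) if qmz.size else np.empty((0, 2))
        ss = np.column_stack([smz, sint]) if smz.size else np.empty((0, 2))
        if self.name == "osa":
            params = OSAParams(mz_tolerance=self.tolerance,
                               use_intensities=use_intensities)
            return osa_score(qs, ss, params).normalized_score
        if self.name == "cosine_greedy":
            return cosine_greedy(qs, ss, self.tolerance)
        if self.name == "entropy":
            return entropy_similarity(qs, ss, self.tolerance)
        u, v = bin_pair(qs, ss, self.bin_width)
        return vector_distance(self.name, u, v, p=self.p or 3.0)

    @property
    def intensity_aware(self) -> bool:
        return self.name in INTENSITY_AWARE


_REGISTRY: dict[str, MetricSpec] = {
    "osa": MetricSpec("osa", "similarity", tolerance=0.005),
    "cosine_greedy": MetricSpec("cosine_greedy", "similarity",
                                tolerance=DEFAULT_COSINE_TOLERANCE),
    "entropy": MetricSpec("entropy", "similarity",
                          tolerance=DEFAULT_ENTROPY_TOLERANCE),
}
for _name in VECTOR_METRIC_NAMES:
    _REGISTRY[_name] = MetricSpec(_name, "distance", bin_width=DEFAULT_BIN_WIDTH,
                                  p=3.0 if _name == "minkowski" else None)


def metric_names() -> tuple[str, ...]:
    return tuple(_REGISTRY)


def get_metric(name: str, **overrides) -> MetricSpec:
    """Look up a metric by name, optionally overriding tolerance/bin width/p."""
    try:
        spec = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown metric {name!r}; known: {', '.join(_REGISTRY)}")
    return replace(spec, **overrides) if overrides else spec
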