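"""Similarity/distance metrics against direct-formula and matchms oracles."""

import numpy as np
import pytest

from speclib_repair.metrics import (
    MetricSpec,
    VECTOR_METRIC_NAMES,
    bin_pair,
    bin_spectrum,
    cosine_greedy,
    entropy_similarity,
    get_metric,
    metric_names,
    spectral_entropy,
    vector_distance,
)

# ------------------------------------------------------------------ oracles


def oracle_distance(name, u, v):
    """Textbook formulas, written independently of scipy."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    d = u - v
    if name == "cityblock":
        return np.abs(d).sum()
    if name == "euclidean":
        return np.sqrt((d ** 2).sum())
    if name == "sqeuclidean":
        return (d ** 2).sum()
    if name == "chebyshev":
        return np.abs(d).max()
    if name == "minkowski":
        return (np.abs(d) ** 3).sum() ** (1 / 3)
    if name == "braycurtis":
        return np.abs(d).sum() / np.abs(u + v).sum()
    if name == "canberra":
        denom = np.abs(u) + np.abs(v)
        terms = np.where(denom > 0, np.abs(d) / np.where(denom > 0, denom, 1), 0.0)
        return terms.sum()
    if name == "cosine":
        return 1 - (u @ v) / np.sqrt((u @ u) * (v @ v))
    if name == "correlation":
        uc, vc = u - u.mean(), v - v.mean()
        return 1 - (uc @ vc) / np.sqrt((uc @ uc) * (vc @ vc))
    if name == "jensenshannon":
        p, q = u / u.sum(), v / v.sum()
        m = (p + q) / 2

        def kl(a, b):
            mask = a > 0
            return (a[mask] * np.log(a[mask] / b[mask])).sum()

        return np.sqrt((kl(p, m) + kl(q, m)) / 2)
    raise KeyError(name)


def oracle_entropy_similarity(qs, ss):
    """Direct evaluation for peak lists with exactly aligned m/z grids."""
    def dist(peaks, grid):
        vec = np.zeros(len(grid))
        for mz, inten in peaks:
            vec[grid.index(mz)] += inten
        return vec / vec.sum()

    grid = sorted({mz for mz, _ in qs} | {mz for mz, _ in ss})
    p, q = dist(qs, grid), dist(ss, grid)
    mix = (p + q) / 2

    def shannon(x):
        x = x[x > 0]
        return float(-(x * np.log(x)).sum())

    return 1 - (2 * shannon(mix) - shannon(p) - shannon(q)) / np.log(4)


# ------------------------------------------------------------------ cosine


def test_cosine_greedy_extremes():
    peaks = [(100.0, 1.0), (200.0, 0.5)]
    assert cosine_greedy(peaks, peaks) == pytest.approx(1.0)
    assert cosine_greedy([(100.0, 1.0)], [(150.0, 1.0)], tolerance=0.1) == 0.0
    assert cosine_greedy([], [(100.0, 1.0)]) == 0.0


def test_cosine_greedy_partial_overlap_value():
    # one matched pair out of two query peaks: 1/sqrt(1.25) (matchms value)
    value = cosine_greedy([(100.0, 1.0), (200.0, 0.5)], [(100.0, 1.0)], 0.1)
    assert value == pytest.approx(0.8944271909999159)


def test_cosine_greedy_matches_matchms(rng):
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import CosineGreedy

    for _ in range(100):
        m, n = rng.integers(1, 10, 2)
        qmz = np.sort(rng.uniform(50, 500, m))
        smz = np.sort(rng.uniform(50, 500, n))
        if m > 2 and n > 2:  # plant some in-tolerance pairs
            smz[:2] = np.sort(qmz[:2] + rng.normal(0, 0.03, 2))
            smz = np.sort(smz)
        qint = rng.uniform(0.01, 1, m)
        sint = rng.uniform(0.01, 1, n)
        mine = cosine_greedy(np.column_stack([qmz, qint]),
                             np.column_stack([smz, sint]), 0.1)
        ref = float(CosineGreedy(tolerance=0.1).pair(
            matchms.Spectrum(mz=qmz, intensities=qint, metadata={},
                             metadata_harmonization=False),
            matchms.Spectrum(mz=smz, intensities=sint, metadata={},
                             metadata_harmonization=False))["score"])
        assert mine == pytest.approx(ref, abs=1e-9)


def test_cosine_greedy_symmetric(rng):
    for _ in range(20):
        qs = sorted((float(m), float(i)) for m, i in
                    zip(rng.uniform(50, 500, 5), rng.uniform(0.1, 1, 5)))
        ss = sorted((float(m), float(i)) for m, i in
                    zip(rng.uniform(50, 500, 5), rng.uniform(0.1, 1, 5)))
        assert cosine_greedy(qs, ss) == pytest.approx(cosine_greedy(ss, qs))


# ------------------------------------------------------------------ entropy


def test_entropy_similarity_extremes():
    peaks = [(100.0, 1.0), (200.0, 0.5)]
    assert entropy_similarity(peaks, peaks) == pytest.approx(1.0)
    assert entropy_similarity([(100.0, 1.0)], [(200.0, 1.0)]) == pytest.approx(0.0)


def test_entropy_similarity_against_direct_evaluation():
    qs = [(100.0, 1.0)]
    ss = [(100.0, 1.0), (200.0, 1.0)]
    expected = oracle_entropy_similarity(qs, ss)
    assert expected == pytest.approx(0.688722, abs=1e-6)
    assert entropy_similarity(qs, ss) == pytest.approx(expected, abs=1e-9)
    qs2 = [(100.0, 0.3), (150.0, 0.7), (300.0, 1.0)]
    ss2 = [(100.0, 0.5), (300.0, 1.0)]
    assert entropy_similarity(qs2, ss2) == pytest.approx(
        oracle_entropy_similarity(qs2, ss2), abs=1e-9)


def test_entropy_similarity_symmetric_and_bounded(rng):
    for _ in range(30):
        qs = sorted((float(m), float(i)) for m, i in
                    zip(rng.uniform(50, 500, 6), rng.uniform(0.01, 1, 6)))
        ss = sorted((float(m), float(i)) for m, i in
                    zip(rng.uniform(50, 500, 4), rng.uniform(0.01, 1, 4)))
        a = entropy_similarity(qs, ss)
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(entropy_similarity(ss, qs), abs=1e-12)


def test_spectral_entropy_merges_within_tolerance():
    # two peaks 0.01 Da apart merge into one at the default 0.02 tolerance
    assert spectral_entropy([(100.00, 1.0), (100.01, 1.0)]) == pytest.approx(0.0)


# ------------------------------------------------------------------ binning


def test_bin_spectrum_examples():
    assert bin_spectrum([(100.001, 1.0), (100.004, 2.0)], 0.01).tolist() == [3.0]
    assert bin_spectrum([], 0.01).size == 0
    # half-open convention: a value exactly on the edge goes to the upper bin
    vec = bin_spectrum([(100.00, 1.0), (100.01, 1.0)], 0.01, (100.0, 100.01))
    assert vec.tolist() == [1.0, 1.0]


def test_bin_pair_union_range():
    u, v = bin_pair([(100.0, 1.0)], [(100.05, 2.0)], 0.01)
    assert u.size == v.size == 6
    assert u.sum() == 1.0 and v.sum() == 2.0


# ------------------------------------------------------------------ vectors


def test_vector_distance_examples():
    assert vector_distance("cityblock", [1, 2], [1, 2]) == 0.0
    assert vector_distance("cityblock", [1, 0], [0, 1]) == 2.0
    assert vector_distance("jensenshannon", [1, 0], [0.5, 0.5]) == \
        pytest.approx(0.4645, abs=1e-4)


@pytest.mark.parametrize("name", VECTOR_METRIC_NAMES)
def test_vector_distances_match_direct_formulas(name, rng):
    for _ in range(100):
        size = int(rng.integers(2, 30))
        u = rng.uniform(0, 1, size)
        v = rng.uniform(0, 1, size)
        assert vector_distance(name, u, v) == pytest.approx(
            oracle_distance(name, u, v), abs=1e-9)


@pytest.mark.parametrize("name", VECTOR_METRIC_NAMES)
def test_vector_distance_self_is_zero(name, rng):
    u = rng.uniform(0.1, 1, 12)
    assert vector_distance(name, u, u) == pytest.approx(0.0, abs=1e-12)


def test_vector_distance_guards():
    with pytest.raises(ValueError, match="length"):
        vector_distance("cityblock", [1, 2], [1, 2, 3])
    with pytest.raises(KeyError):
        vector_distance("hamming", [1], [1])
    with pytest.warns(UserWarning, match="degenerate"):
        assert vector_distance("cosine", [0, 0], [1, 0]) == 1.0
    with pytest.warns(UserWarning, match="degenerate"):
        assert vector_distance("jensenshannon", [0, 0], [1, 0]) == \
            pytest.approx(np.sqrt(np.log(2)))
    with pytest.warns(UserWarning, match="degenerate"):
        assert vector_distance("correlation", [1, 1], [1, 0]) == 2.0
    # identical degenerate vectors are distance 0 by convention
    assert vector_distance("cosine", [0, 0], [0, 0]) == 0.0


# ------------------------------------------------------------------ registry


def test_registry_kinds_and_extremal_self_comparison(tiny_library):
    sp = tiny_library[0]
    for name in metric_names():
        spec = get_metric(name)
        assert isinstance(spec, MetricSpec)
        value = spec.compare(sp, sp, use_intensities=True)
        if spec.kind == "similarity":
            assert value == pytest.approx(1.0)
        else:
            assert value == pytest.approx(0.0, abs=1e-12)


def test_get_metric_unknown_and_overrides():
    with pytest.raises(KeyError, match="unknown metric"):
        get_metric("nope")
    assert get_metric("osa", tolerance=0.01).tolerance == 0.01
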