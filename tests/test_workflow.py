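"""Candidate retrieval, best-match selection, match typing, prediction."""

import numpy as np
import pytest

from speclib_repair.adducts import parse_adduct, theoretical_precursor_mz
from speclib_repair.metrics import get_metric
from speclib_repair.spectral_io import SpectralLibrary, Spectrum
from speclib_repair.workflow import (
    MatchRecord,
    benchmark,
    best_match,
    canonical_adduct,
    classify_match,
    find_candidates,
    predict_adduct,
    reliability_assessment,
)

PEAKS = [(100.0, 1.0), (150.0, 0.5), (300.0, 0.8)]


def make_spectrum(**meta):
    peaks = meta.pop("peaks", PEAKS)
    return Spectrum(metadata=meta, peaks=peaks)


@pytest.fixture
def subject_library():
    return SpectralLibrary(name="subject", spectra=[
        make_spectrum(spectrum_id="s0", inchikey="KEY1", ionmode="positive",
                      adduct="[M+H]+", precursor_mz="181.07"),
        make_spectrum(spectrum_id="s1", inchikey="KEY1", ionmode="positive",
                      adduct="[M+Na]+", precursor_mz="203.05"),
        make_spectrum(spectrum_id="s2", inchikey="KEY1", ionmode="negative",
                      adduct="[M-H]-", precursor_mz="179.06"),
        make_spectrum(spectrum_id="s3", inchikey="KEY2", ionmode="positive",
                      adduct="[M+H]+", precursor_mz="151.01"),
        make_spectrum(spectrum_id="s4", inchikey="KEY3", formula="C6H12O6",
                      ionmode="positive", adduct="UNKNOWN"),
    ])


def test_find_candidates_filters_identifier_and_mode(subject_library):
    query = make_spectrum(inchikey="KEY1", ionmode="positive")
    found = find_candidates(query, subject_library)
    assert [s.metadata["spectrum_id"] for s in found] == ["s0", "s1"]


def test_find_candidates_unknown_mode_or_missing_identifier(subject_library):
    assert find_candidates(make_spectrum(inchikey="KEY1"),
                           subject_library) == []
    assert find_candidates(make_spectrum(ionmode="positive"),
                           subject_library) == []


def test_find_candidates_formula_is_loose():
    lib = SpectralLibrary(name="s", spectra=[
        make_spectrum(spectrum_id="iso1", formula="C6H12O6", inchikey="A",
                      ionmode="positive"),
        make_spectrum(spectrum_id="iso2", formula="C6H12O6", inchikey="B",
                      ionmode="positive"),
    ])
    query = make_spectrum(formula="C6H12O6", ionmode="positive")
    found = find_candidates(query, lib, identifier="formula")
    assert {s.metadata["spectrum_id"] for s in found} == {"iso1", "iso2"}


def test_best_match_extremal_and_tie_rules(subject_library):
    query = make_spectrum(inchikey="KEY1", ionmode="positive",
                          precursor_mz="181.08")
    # similarity: the identical-peak candidates tie at 1.0; precursor
    # proximity picks s0 (|Δ|=0.01 vs 21.97)
    winner, score = best_match(query, list(subject_library[:2]),
                               get_metric("cosine_greedy"))
    assert winner.metadata["spectrum_id"] == "s0"
    assert score == pytest.approx(1.0)
    # distance metric: minimum wins
    far = make_spectrum(spectrum_id="far",
                        peaks=[(101.0, 1.0), (151.0, 0.5), (301.0, 0.8)])
    winner, score = best_match(query, [far, subject_library[0]],
                               get_metric("cityblock"))
    assert winner.metadata["spectrum_id"] == "s0"
    assert score == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        best_match(query, [], get_metric("osa"))


@pytest.mark.parametrize("q_adduct, q_prec, s_adduct, s_prec, expected", [
    ("[M+H]+", "181.07", "[M+H]+", "181.08", "both"),
    ("[M+H]+", None, "[M+H]+", "181.07", "adduct_only"),
    ("[M+H]+", "181.07", "[M+Na]+", "181.30", "precursor_only"),
    ("[M+H]+", "181.07", "[M+Na]+", "181.90", "mismatch"),
    ("[M+H2O+H]+", "181.07", "[M+H+H2O]+", "189.99", "adduct_only"),
    (None, None, "[M+H]+", "181.07", "mismatch"),
])
def test_classify_match(q_adduct, q_prec, s_adduct, s_prec, expected):
    qmeta = {"ionmode": "positive"}
    if q_adduct:
        qmeta["adduct"] = q_adduct
    if q_prec:
        qmeta["precursor_mz"] = q_prec
    smeta = {"ionmode": "positive", "adduct": s_adduct, "precursor_mz": s_prec}
    assert classify_match(make_spectrum(**qmeta), make_spectrum(**smeta)) == expected


def test_classify_match_symmetric_when_fields_present():
    a = make_spectrum(adduct="[M+H]+", precursor_mz="181.07")
    b = make_spectrum(adduct="[M+Na]+", precursor_mz="181.30")
    assert classify_match(a, b) == classify_match(b, a)


def test_canonical_adduct_none_for_missing_or_malformed():
    assert canonical_adduct(make_spectrum(adduct="UNKNOWN")) is None
    assert canonical_adduct(make_spectrum(adduct="[M+Zz]+")) is None
    assert canonical_adduct(make_spectrum()) is None
    assert canonical_adduct(make_spectrum(adduct="[M+H2O+H]+")) == "[M+H+H2O]+"


def test_predict_adduct_failure_paths(subject_library):
    no_candidates = make_spectrum(inchikey="KEY9", ionmode="positive")
    rec = predict_adduct(no_candidates, subject_library, "osa")
    assert rec.match_type == "failure" and rec.subject_id is None
    # candidates exist but all carry UNKNOWN adducts
    unknowable = make_spectrum(inchikey="KEY3", ionmode="positive")
    rec = predict_adduct(unknowable, subject_library, "osa")
    assert rec.match_type == "failure"
    # min_score withholds a weak prediction
    weird = make_spectrum(inchikey="KEY1", ionmode="positive",
                          peaks=[(99.0, 1.0), (400.0, 1.0)])
    rec = predict_adduct(weird, subject_library, "osa", min_score=0.95)
    assert rec.match_type == "failure"


def test_predict_adduct_emits_theoretical_precursor(subject_library):
    query = make_spectrum(inchikey="KEY1", ionmode="positive",
                          exact_mass="180.063388")
    rec = predict_adduct(query, subject_library, "osa")
    assert rec.predicted_adduct == "[M+H]+"
    expected = theoretical_precursor_mz(parse_adduct("[M+H]+"), 180.063388)
    assert rec.theoretical_precursor_mz == pytest.approx(expected, abs=1e-9)


def test_planted_adduct_recovery_sample(benchmark_suite, integrated_subject):
    blanked = [sp for sp in benchmark_suite.hmdb_like
               if "adduct" not in sp.metadata][:10]
    assert blanked
    for sp in blanked:
        rec = predict_adduct(sp, integrated_subject, "osa")
        truth = benchmark_suite.truth[sp.metadata["spectrum_id"]]["adduct"]
        assert rec.predicted_adduct == truth


def test_match_record_validates_type():
    with pytest.raises(ValueError):
        MatchRecord(query_id="q", subject_id=None, metric="osa", score=None,
                    match_type="bogus")


def test_benchmark_partitions_queries(benchmark_suite, integrated_subject):
    report = benchmark(benchmark_suite.hmdb_like, integrated_subject,
                       ["osa"], level="mz_only")
    counts = report.results["osa"]["counts"]
    assert sum(counts.values()) == len(benchmark_suite.hmdb_like)
    # half the library has no identifiable adduct: counted as failures
    assert counts["failure"] == 50


def test_benchmark_level_two_gates_metrics(benchmark_suite, integrated_subject):
    small = SpectralLibrary(name="q", spectra=list(benchmark_suite.hmdb_like[:4]))
    with pytest.warns(UserWarning, match="not designed for intensities"):
        report = benchmark(small, integrated_subject,
                           ["cityblock", "cosine_greedy"],
                           level="mz_and_intensity")
    assert "cityblock" not in report.results
    assert "cosine_greedy" in report.results


def test_benchmark_empty_query_library(integrated_subject):
    report = benchmark(SpectralLibrary(name="q", spectra=[]),
                       integrated_subject, ["osa"])
    assert report.results["osa"]["match_rate"] is None


def test_precursor_adduct_coherence(benchmark_suite):
    """Fixture precursors sit within 0.25 Da of the theoretical value."""
    checked = 0
    for lib in benchmark_suite.libraries:
        for sp in lib:
            truth = benchmark_suite.truth[sp.metadata["spectrum_id"]]
            if sp.precursor_mz is None:
                continue
            assert abs(sp.precursor_mz -
                       truth["theoretical_precursor_mz"]) < 0.25
            checked += 1
    assert checked > 100


def test_reliability_determinism_and_planted_consistency(reliability_pair):
    lib_a, lib_b, _ = reliability_pair
    kwargs = dict(n=60, reps=2, threshold=0.95, seed=5)
    df1 = reliability_assessment(lib_a, lib_b, **kwargs)
    df2 = reliability_assessment(lib_a, lib_b, **kwargs)
    assert df1.equals(df2)
    # fields planted consistent are exactly zero where defined
    for anchor in ("inchikey", "name", "formula"):
        for other in ("inchikey", "name", "formula"):
            v = df1.loc[anchor, other]
            assert np.isnan(v) or v == 0.0


def test_reliability_clamps_sample_size():
    spectra = [make_spectrum(spectrum_id=f"x{i}", name=f"c{i}", inchikey=f"K{i}",
                             smiles="CC", formula="C2H6")
               for i in range(5)]
    lib_a = SpectralLibrary(name="a", spectra=spectra)
    lib_b = SpectralLibrary(name="b", spectra=[sp.copy() for sp in spectra])
    with pytest.warns(UserWarning, match="clamped"):
        df = reliability_assessment(lib_a, lib_b, n=50, reps=1, seed=3)
    assert df.loc["inchikey", "name"] == 0.0
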