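"""Adduct matching, prediction, benchmarking and metadata reliability.

The central repair operation: for a query spectrum lacking adduct metadata,
retrieve subject spectra of the same compound (by InChIKey, SMILES or
molecular formula) acquired in the same ionization mode, rank them under a
chosen similarity or distance metric, and copy the best match's canonical
adduct onto the query.  Queries with known adducts double as ground truth
for benchmarking metrics against each other, with a match defined as
concordance in canonical adduct form or a precursor m/z deviation ≤ 0.5 Da.

Failures are first-class outcomes, never exceptions: a query without a
usable identifier, without a known ion mode, with no congruent-mode subject
spectra, or whose candidate adducts are all unknown yields a failure record,
mirroring how unrepairable spectra are accounted for in library curation.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adducts import (
    AdductParseError,
    canonical_string,
    is_missing_adduct,
    parse_adduct,
    theoretical_precursor_mz,
)
from .metrics import MetricSpec, cosine_greedy, get_metric
from .spectral_io import SpectralLibrary, Spectrum

PRECURSOR_MATCH_TOLERANCE = 0.5  # Da
MATCH_TYPES = ("both", "adduct_only", "precursor_only", "mismatch", "failure")
IDENTIFIER_FIELDS = ("inchikey", "smiles", "formula")
RELIABILITY_FIELDS = ("name", "inchikey", "smiles", "formula")


@dataclass
class MatchRecord:
    """One query-vs-subject comparison outcome."""

    query_id: str
    subject_id: str | None
    metric: str
    score: float | None
    match_type: str
    predicted_adduct: str | None = None
    precursor_delta: float | None = None
    theoretical_precursor_mz: float | None = None

    def __post_init__(self):
        if self.match_type not in MATCH_TYPES:
            raise ValueError(f"unknown match type {self.match_type!r}")


@dataclass
class BenchmarkReport:
    """Per-metric match rates and match-type counts for one comparison."""

    level: str
    total_queries: int
    results: dict[str, dict] = field(default_factory=dict)

    def match_rate(self, metric: str) -> float | None:
        return self.results[metric]["match_rate"]


def spectrum_id(sp: Spectrum, fallback: str = "?") -> str:
    return sp.metadata.get("spectrum_id", fallback)


def canonical_adduct(sp: Spectrum) -> str | None:
    """The spectrum's adduct as a canonical string, or None.

    Missing, placeholder and unparsable adduct annotations all map to None:
    for matching purposes they are equally unusable.
    """
    raw = sp.metadata.get("adduct")
    if raw is None:
        return None
    try:
        form = parse_adduct(raw)
    except AdductParseError:
        return None
    if is_missing_adduct(form):
        return None
    return canonical_string(form)


def find_candidates(query: Spectrum, subject: SpectralLibrary,
                    identifier: str = "inchikey") -> list[Spectrum]:
    """Subject spectra sharing the query's identifier and ion mode.

    InChIKey comparison uses the full 27-character key; formula matching is
    documentedly loose (isomers share formulas).  A query without the
    identifier or with unknown ion mode yields no candidates — the caller
    records a failure.  Subject order is preserved.
    """
    if identifier not in IDENTIFIER_FIELDS:
        raise ValueError(f"identifier must be one of {IDENTIFIER_FIELDS}")
    value = query.metadata.get(identifier)
    mode = query.ionmode
    if not value or mode == "unknown":
        return []
    return [sp for sp in subject
            if sp.metadata.get(identifier) == value and sp.ionmode == mode]


def best_match(query: Spectrum, candidates: list[Spectrum],
               metric: MetricSpec, use_intensities: bool = True):
    """Extremal-score candidate; ties broken by precursor proximity then order."""
    if not candidates:
        raise ValueError("candidates must be non-empty")
    scores = [metric.compare(query, c, use_intensities=use_intensities)
              for c in candidates]
    extremal = max(scores) if metric.kind == "similarity" else min(scores)
    qprec = query.precursor_mz

    def tie_key(idx: int):
        sprec = candidates[idx].precursor_mz
        delta = abs(qprec - sprec) if qprec is not None and sprec is not None \
            else float("inf")
        return (delta, idx)

    tied = [i for i, s in enumerate(scores) if s == extremal]
    winner = min(tied, key=tie_key)
    return candidates[winner], scores[winner]


def classify_match(query: Spectrum, subject: Spectrum,
                   precursor_tolerance: float = PRECURSOR_MATCH_TOLERANCE) -> str:
    """Type a spectrum pair by adduct and precursor m/z concordance.

    Adduct concordance compares canonical strings; precursor concordance is
    |Δ m/z| ≤ 0.5 Da.  A field missing on either side makes that criterion
    non-concordant (never an error).
    """
    qa, sa = canonical_adduct(query), canonical_adduct(subject)
    adduct_ok = qa is not None and qa == sa
    qp, sp = query.precursor_mz, subject.precursor_mz
    precursor_ok = qp is not None and sp is not None \
        and abs(qp - sp) <= precursor_tolerance
    if adduct_ok and precursor_ok:
        return "both"
    if adduct_ok:
        return "adduct_only"
    if precursor_ok:
        return "precursor_only"
    return "mismatch"


def _failure(query: Spectrum, metric_name: str, fallback_id: str) -> MatchRecord:
    return MatchRecord(query_id=spectrum_id(query, fallback_id), subject_id=None,
                       metric=metric_name, score=None, match_type="failure")


def predict_adduct(query: Spectrum, subject: SpectralLibrary,
                   metric: MetricSpec | str = "osa",
                   identifier: str = "inchikey",
                   min_score: float | None = None,
                   use_intensities: bool = True,
                   fallback_id: str = "?") -> MatchRecord:
    """Predict the adduct of an annotation-deficient query spectrum.

    Retrieves congruent candidates, keeps those with a usable adduct, ranks
    them under ``metric`` and copies the winner's canonical adduct.  When
    the query carries an exact mass, the theoretical precursor m/z of the
    predicted adduct is emitted alongside.  ``min_score`` (similarity
    metrics: lower bound; distance metrics: upper bound) withholds
    low-confidence predictions as failures.
    """
    if isinstance(metric, str):
        metric = get_metric(metric)
    candidates = [c for c in find_candidates(query, subject, identifier)
                  if canonical_adduct(c) is not None]
    if not candidates:
        return _failure(query, metric.name, fallback_id)
    subject_best, score = best_match(query, candidates, metric, use_intensities)
    if min_score is not None:
        withheld = score < min_score if metric.kind == "similarity" \
            else score > min_score
        if withheld:
            return _failure(query, metric.name, fallback_id)
    predicted = canonical_adduct(subject_best)
    theo = None
    exact_mass = query.metadata.get("exact_mass")
    if exact_mass:
        try:
            theo = theoretical_precursor_mz(parse_adduct(predicted),
                                            float(exact_mass))
        except (ValueError, KeyError):
            theo = None
    qp, sp = query.precursor_mz, subject_best.precursor_mz
    delta = abs(qp - sp) if qp is not None and sp is not None else None
    return MatchRecord(
        query_id=spectrum_id(query, fallback_id),
        subject_id=spectrum_id(subject_best),
        metric=metric.name, score=score,
        match_type=classify_match(query, subject_best),
        predicted_adduct=predicted, precursor_delta=delta,
        theoretical_precursor_mz=theo)


def benchmark(query_lib: SpectralLibrary, subject_lib: SpectralLibrary,
              metrics, level: str = "mz_only",
              identifier: str = "inchikey") -> BenchmarkReport:
    """Score every query against the subject library under each metric.

    ``level`` selects the comparison depth: ``mz_only`` flattens all
    intensities to one, ``mz_and_intensity`` uses intensities and is
    restricted to the metrics designed for them (osa, entropy,
    cosine_greedy); incompatible metrics are skipped with a warning.
    Queries whose own adduct cannot be identified are counted as failures —
    their match type is undeterminable.  The match rate is the percentage
    of queries typed both/adduct_only/precursor_only.
    """
    if level not in ("mz_only", "mz_and_intensity"):
        raise ValueError("level must be 'mz_only' or 'mz_and_intensity'")
    use_intensities = level == "mz_and_intensity"
    report = BenchmarkReport(level=level, total_queries=len(query_lib))
    for metric in metrics:
        spec = get_metric(metric) if isinstance(metric, str) else metric
        if use_intensities and not spec.intensity_aware:
            warnings.warn(f"metric {spec.name!r} is not designed for "
                          f"intensities; skipped at level 2", UserWarning,
                          stacklevel=2)
            continue
        records: list[MatchRecord] = []
        counts: Counter = Counter()
        for i, query in enumerate(query_lib):
            fallback = f"{query_lib.name}[{i}]"
            if canonical_adduct(query) is None:
                rec = _failure(query, spec.name, fallback)
            else:
                rec = predict_adduct(query, subject_lib, spec,
                                     identifier=identifier,
                                     use_intensities=use_intensities,
                                     fallback_id=fallback)
            records.append(rec)
            counts[rec.match_type] += 1
        total = len(records)
        matched = counts["both"] + counts["adduct_only"] + counts["precursor_only"]
        report.results[spec.name] = {
            "match_rate": 100.0 * matched / total if total else None,
            "counts": counts,
            "records": records,
        }
    return report


def _prepared_peaks(sp: Spectrum):
    inten = sp.intensity_array
    top = inten.max() if inten.size else 0.0
    return sp.mz_array, inten / top if top > 0 else inten


def reliability_assessment(lib_a: SpectralLibrary, lib_b: SpectralLibrary,
                           n: int = 5000, reps: int = 10,
                           threshold: float = 0.95, seed: int = 0,
                           fields=RELIABILITY_FIELDS,
                           tolerance: float = 0.1) -> pd.DataFrame:
    """Per-field error rates among high-confidence random spectrum pairs.

    Per repetition (seeds ``seed, seed+1, ...``): sample ``n`` spectra from
    each library without replacement, match every query against every
    subject with greedy cosine, keep each query's best subject when its
    score reaches ``threshold``, and for every anchor field F compute
    error_rate(G | F) = % of kept pairs agreeing on F but differing on G.
    Rates are averaged over repetitions; cells with no eligible pairs are
    NaN.
    """
    n_eff = min(n, len(lib_a), len(lib_b))
    if n_eff < n:
        warnings.warn(f"sample size clamped from {n} to {n_eff} "
                      f"(libraries hold {len(lib_a)} and {len(lib_b)} spectra)",
                      UserWarning, stacklevel=2)
    fields = tuple(fields)
    sums = np.zeros((len(fields), len(fields)))
    counts = np.zeros((len(fields), len(fields)))
    any_kept = False
    for rep in range(reps):
        rng = np.random.default_rng(seed + rep)
        idx_a = rng.choice(len(lib_a), size=n_eff, replace=False)
        idx_b = rng.choice(len(lib_b), size=n_eff, replace=False)
        sample_a = [lib_a[i] for i in idx_a]
        sample_b = [lib_b[i] for i in idx_b]
        prepped_b = [_prepared_peaks(sp) for sp in sample_b]
        kept: list[tuple[Spectrum, Spectrum]] = []
        for qa in sample_a:
            qmz, qint = _prepared_peaks(qa)
            qpeaks = np.column_stack([qmz, qint])
            best_score, best_j = -1.0, -1
            for j, (smz, sint) in enumerate(prepped_b):
                score = cosine_greedy(qpeaks, np.column_stack([smz, sint]),
                                      tolerance)
                if score > best_score:
                    best_score, best_j = score, j
            if best_j >= 0 and best_score >= threshold:
                kept.append((qa, sample_b[best_j]))
        if not kept:
            continue
        any_kept = True
        for fi, anchor in enumerate(fields):
            eligible = [(qa, sb) for qa, sb in kept
                        if qa.metadata.get(anchor) is not None
                        and qa.metadata.get(anchor) == sb.metadata.get(anchor)]
            for gi, other in enumerate(fields):
                pairs = [(qa, sb) for qa, sb in eligible
                         if qa.metadata.get(other) is not None
                         and sb.metadata.get(other) is not None]
                if not pairs:
                    continue
                mism = sum(qa.metadata[other] != sb.metadata[other]
                           for qa, sb in pairs)
                sums[fi, gi] += 100.0 * mism / len(pairs)
                counts[fi, gi] += 1
    if not any_kept:
        warnings.warn("no spectrum pair passed the similarity threshold",
                      UserWarning, stacklevel=2)
    with np.errstate(invalid="ignore"):
        rates = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(rates, index=list(fields), columns=list(fields))
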