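"""Library-level services: HMDB construction, subsetting, statistics.

HMDB distributes experimental MS/MS spectra as per-spectrum XML files that
lack compound identifiers; those live in a separate CSV export.  ``build_hmdb``
joins the two on the HMDB accession and emits a library that passes the same
invariants as any MSP-derived one, with an explicit count of spectra dropped
for want of compound metadata.  ``subset_library`` applies conjunctive
metadata predicates (exact values for categorical fields, closed intervals
for continuous ones), and ``library_stats`` reports the annotation
completeness measures used to profile open libraries: missing-adduct
fraction, ion-mode distributions at spectrum and identifier level, spectra
per InChIKey, adduct-form frequencies.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .adducts import AdductParseError, is_missing_adduct, parse_adduct
from .spectral_io import (
    STANDARD_FIELDS,
    SpectralLibrary,
    Spectrum,
    SpectrumParseError,
    normalize_key,
    read_compound_csv,
    read_hmdb_xml,
)
from .workflow import canonical_adduct


@dataclass(frozen=True)
class SubsetCriteria:
    """Conjunctive metadata predicates.

    ``equals``: field -> set of admissible exact values (categorical).
    ``ranges``: field -> closed interval [lo, hi] on float-parsed values
    (continuous fields such as precursor_mz or exact_mass).  A spectrum
    missing a predicated field fails that predicate.
    """

    equals: dict[str, set] = field(default_factory=dict)
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.equals and not self.ranges:
            raise ValueError("criteria must contain at least one predicate")
        object.__setattr__(self, "equals",
                           {normalize_key(k): set(v) for k, v in self.equals.items()})
        object.__setattr__(self, "ranges",
                           {normalize_key(k): (float(lo), float(hi))
                            for k, (lo, hi) in self.ranges.items()})
        for fname, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"range for {fname!r} has lo > hi")

    @property
    def fields(self) -> set[str]:
        return set(self.equals) | set(self.ranges)


@dataclass
class LibraryStats:
    """Descriptive annotation-completeness statistics for one library."""

    n_spectra: int
    missing_adduct_count: int
    missing_adduct_pct: float
    ionmode_spectra: Counter
    ionmode_identifiers: Counter
    n_identifiers: int
    spectra_per_inchikey_mean: float
    spectra_per_inchikey_max: int
    adduct_frequency: Counter


def build_hmdb(xml_dir, compound_csv, name: str = "hmdb"):
    """Join HMDB-style spectrum XMLs with the compound CSV into a library.

    Each parsed spectrum is joined on its HMDB accession; joined spectra
    gain inchikey/smiles/formula/exact_mass/name.  Spectra without compound
    metadata are dropped and counted.  Returns ``(library, report)`` with
    report keys parsed/joined/dropped_no_compound/parse_errors.
    """
    xml_dir = Path(xml_dir)
    compounds = read_compound_csv(compound_csv)
    paths = sorted(xml_dir.glob("*.xml"))
    if not paths:
        warnings.warn(f"no XML spectra found under {xml_dir}", UserWarning,
                      stacklevel=2)
    spectra = []
    report = {"parsed": 0, "joined": 0, "dropped_no_compound": 0,
              "parse_errors": 0}
    for path in paths:
        try:
            sp = read_hmdb_xml(path)
        except SpectrumParseError as exc:
            warnings.warn(str(exc), UserWarning, stacklevel=2)
            report["parse_errors"] += 1
            continue
        report["parsed"] += 1
        entry = compounds.get(sp.metadata["hmdb_id"])
        if entry is None:
            report["dropped_no_compound"] += 1
            continue
        for key, value in entry.items():
            sp.metadata[key] = f"{value:.6f}" if key == "exact_mass" \
                else str(value)
        sp.metadata["source_library"] = name
        spectra.append(sp)
        report["joined"] += 1
    return SpectralLibrary(name=name, spectra=spectra), report


def subset_library(lib: SpectralLibrary, criteria: SubsetCriteria,
                   name: str | None = None) -> SpectralLibrary:
    """Spectra satisfying every predicate (conjunction).

    Unknown field names (neither standard nor present in the library) raise
    with the list of known fields; a known-but-absent field simply fails
    for every spectrum.
    """
    known = set(STANDARD_FIELDS)
    for sp in lib:
        known.update(sp.metadata)
    unknown = criteria.fields - known
    if unknown:
        raise ValueError(
            f"unknown field(s) {sorted(unknown)}; known fields: {sorted(known)}")

    def admit(sp: Spectrum) -> bool:
        for fname, values in criteria.equals.items():
            if sp.metadata.get(fname) not in values:
                return False
        for fname, (lo, hi) in criteria.ranges.items():
            raw = sp.metadata.get(fname)
            if raw is None:
                return False
            try:
                v = float(raw)
            except ValueError:
                return False
            if not lo <= v <= hi:
                return False
        return True

    return SpectralLibrary(name=name or f"{lib.name}_subset",
                           spectra=[sp for sp in lib if admit(sp)])


def _adduct_missing(sp: Spectrum) -> bool:
    raw = sp.metadata.get("adduct")
    if raw is None or not raw.strip():
        return True
    try:
        return is_missing_adduct(parse_adduct(raw))
    except AdductParseError:
        return False  # present but malformed: annotated, just badly


def library_stats(lib: SpectralLibrary) -> LibraryStats:
    """Compute completeness statistics (see :class:`LibraryStats`)."""
    n = len(lib)
    missing = sum(_adduct_missing(sp) for sp in lib)
    ionmode_spectra = Counter(sp.ionmode for sp in lib)
    modes_by_key: dict[str, set] = {}
    per_key: Counter = Counter()
    adduct_freq: Counter = Counter()
    for sp in lib:
        key = sp.metadata.get("inchikey")
        if key:
            per_key[key] += 1
            modes_by_key.setdefault(key, set()).add(sp.ionmode)
        ca = canonical_adduct(sp)
        if ca:
            adduct_freq[ca] += 1
    ionmode_identifiers: Counter = Counter()
    for modes in modes_by_key.values():
        known = modes - {"unknown"}
        if known == {"positive"}:
            ionmode_identifiers["positive_only"] += 1
        elif known == {"negative"}:
            ionmode_identifiers["negative_only"] += 1
        elif known == {"positive", "negative"}:
            ionmode_identifiers["both"] += 1
        else:
            ionmode_identifiers["missing"] += 1
    return LibraryStats(
        n_spectra=n,
        missing_adduct_count=missing,
        missing_adduct_pct=100.0 * missing / n if n else 0.0,
        ionmode_spectra=ionmode_spectra,
        ionmode_identifiers=ionmode_identifiers,
        n_identifiers=len(per_key),
        spectra_per_inchikey_mean=(sum(per_key.values()) / len(per_key))
        if per_key else 0.0,
        spectra_per_inchikey_max=max(per_key.values()) if per_key else 0,
        adduct_frequency=adduct_freq,
    )


def merge_libraries(libraries, name: str) -> SpectralLibrary:
    """Concatenate libraries, stamping each spectrum's source if unset."""
    spectra = []
    for lib in libraries:
        for sp in lib:
            sp = sp.copy()
            sp.metadata.setdefault("source_library", lib.name)
            spectra.append(sp)
    return SpectralLibrary(name=name, spectra=spectra)


def pairwise_exclusion_sets(libraries):
    """Each library (restricted to the shared InChIKeys) vs the rest merged.

    The query side keeps only spectra whose InChIKey lies in the
    intersection across all libraries; the subject side is the
    concatenation of the remaining libraries.  An empty intersection warns
    and yields empty query sets.
    """
    if len(libraries) < 2:
        raise ValueError("need at least two libraries")
    key_sets = [{sp.metadata.get("inchikey") for sp in lib
                 if sp.metadata.get("inchikey")} for lib in libraries]
    shared = set.intersection(*key_sets)
    if not shared:
        warnings.warn("no InChIKey is shared by all libraries; query sets "
                      "are empty", UserWarning, stacklevel=2)
    pairs = []
    for i, lib in enumerate(libraries):
        query = SpectralLibrary(
            name=f"{lib.name}_shared",
            spectra=[sp for sp in lib if sp.metadata.get("inchikey") in shared])
        others = [l for j, l in enumerate(libraries) if j != i]
        subject = merge_libraries(others, name="+".join(l.name for l in others))
        pairs.append((query, subject))
    return pairs
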