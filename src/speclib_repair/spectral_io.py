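"""Reading and writing MS/MS spectral libraries.

Supports the NIST-style MSP text dialect (repeated blocks of ``KEY: VALUE``
metadata lines, a ``Num Peaks: N`` line, then ``N`` whitespace-separated peak
lines), an HMDB-style per-spectrum XML format, and the compound-metadata CSV
exported by the HMDB Metabolite Browser.  All readers normalize metadata keys
to lower-cased canonical names and fold ion-mode vocabulary onto
``{positive, negative, unknown}`` so that downstream matching can treat ion
mode as a hard filter.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
from lxml import etree


class MSPFormatWarning(UserWarning):
    """A malformed MSP block was skipped (never silently truncated)."""


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed into a valid record."""


class SchemaError(ValueError):
    """A delimited input file is missing a required column."""


class Peak(NamedTuple):
    """One centroided peak: m/z in Da (Th) and a non-negative intensity."""

    mz: float
    intensity: float


# Synonym table applied after case-folding and space/hyphen -> underscore.
# Keys already canonical map to themselves implicitly.
KEY_SYNONYMS: dict[str, str] = {
    "precursormz": "precursor_mz",
    "precursor_m/z": "precursor_mz",
    "ion_mode": "ionmode",
    "ionization_mode": "ionmode",
    "ionization": "ionmode",
    "precursortype": "adduct",
    "precursor_type": "adduct",
    "adducttype": "adduct",
    "adduct_type": "adduct",
    "exactmass": "exact_mass",
    "molecular_formula": "formula",
    "chemical_formula": "formula",
    "compound_name": "name",
    "monisotopic_molecular_weight": "exact_mass",
}

_POSITIVE = {"p", "pos", "positive", "+", "1", "positive_mode"}
_NEGATIVE = {"n", "neg", "negative", "-", "−", "-1", "negative_mode"}

STANDARD_FIELDS = (
    "name",
    "inchikey",
    "inchi",
    "smiles",
    "formula",
    "exact_mass",
    "adduct",
    "precursor_mz",
    "ionmode",
    "source_library",
    "spectrum_id",
    "hmdb_id",
    "collision_energy",
    "retention_time",
)


def normalize_key(key: str) -> str:
    """Case-fold a metadata key and map known synonyms to canonical names."""
    k = key.strip().lower().replace(" ", "_").replace("-", "_")
    return KEY_SYNONYMS.get(k, k)


def normalize_ionmode(value: str | None) -> str:
    """Fold an ion-mode string onto {positive, negative, unknown}."""
    if value is None:
        return "unknown"
    v = value.strip().lower()
    if v in _POSITIVE:
        return "positive"
    if v in _NEGATIVE:
        return "negative"
    return "unknown"


def _clean_peaks(peaks) -> list[Peak]:
    """Sort peaks ascending in m/z and merge exact duplicates by summing.

    Duplicate m/z values are merged so the strictly-ascending invariant
    required by alignment preprocessing holds.
    """
    out: list[Peak] = []
    for p in peaks:
        mz, inten = float(p[0]), float(p[1])
        if mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {mz}")
        if inten < 0:
            raise ValueError(f"peak intensity must be non-negative, got {inten}")
        out.append(Peak(mz, inten))
    out.sort(key=lambda p: p.mz)
    merged: list[Peak] = []
    for p in out:
        if merged and p.mz == merged[-1].mz:
            merged[-1] = Peak(p.mz, merged[-1].intensity + p.intensity)
        else:
            merged.append(p)
    return merged


@dataclass(eq=False)
class Spectrum:
    """One MS/MS record: a metadata map plus a peak list sorted by m/z.

    Metadata keys are lower-cased canonical names; the ``ionmode`` value, if
    present, is normalized on construction.
    """

    metadata: dict[str, str] = field(default_factory=dict)
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.metadata = {normalize_key(k): v for k, v in self.metadata.items()}
        if "ionmode" in self.metadata:
            self.metadata["ionmode"] = normalize_ionmode(self.metadata["ionmode"])
        self.peaks = _clean_peaks(self.peaks)
        self._mz = None
        self._intensity = None

    @property
    def ionmode(self) -> str:
        return normalize_ionmode(self.metadata.get("ionmode"))

    def get(self, key: str, default: str | None = None) -> str | None:
        return self.metadata.get(normalize_key(key), default)

    @property
    def mz_array(self) -> np.ndarray:
        if self._mz is None:
            self._mz = np.array([p.mz for p in self.peaks], dtype=float)
        return self._mz

    @property
    def intensity_array(self) -> np.ndarray:
        if self._intensity is None:
            self._intensity = np.array([p.intensity for p in self.peaks], dtype=float)
        return self._intensity

    @property
    def precursor_mz(self) -> float | None:
        v = self.metadata.get("precursor_mz")
        if v is None:
            return None
        try:
            return float(v)
        except ValueError:
            return None

    def __len__(self) -> int:
        return len(self.peaks)

    def copy(self) -> "Spectrum":
        return Spectrum(metadata=dict(self.metadata), peaks=list(self.peaks))


@dataclass
class SpectralLibrary:
    """Ordered collection of spectra with a provenance label."""

    name: str
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("library name must be non-empty")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]


_KV_RE = re.compile(r"^([^:=]+?)\s*[:=]\s?(.*)$")


def _parse_msp_block(lines: list[str]) -> Spectrum:
    metadata: dict[str, str] = {}
    declared: int | None = None
    peak_lines: list[str] = []
    it = iter(lines)
    for line in it:
        m = _KV_RE.match(line)
        if m and normalize_key(m.group(1)) == "num_peaks":
            try:
                declared = int(m.group(2).strip())
            except ValueError as exc:
                raise SpectrumParseError(f"bad peak count {m.group(2)!r}") from exc
            peak_lines = list(it)  # everything after the count line
            break
        if not m:
            raise SpectrumParseError(f"unparsable metadata line {line!r}")
        metadata[normalize_key(m.group(1))] = m.group(2).strip()
    if declared is None:
        raise SpectrumParseError("missing 'Num Peaks' line")
    if len(peak_lines) != declared:
        raise SpectrumParseError(
            f"declared {declared} peaks but found {len(peak_lines)} peak lines"
        )
    peaks = []
    for line in peak_lines:
        parts = line.replace(";", " ").split()
        if len(parts) < 2:
            raise SpectrumParseError(f"unparsable peak line {line!r}")
        try:
            peaks.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise SpectrumParseError(f"unparsable peak line {line!r}") from exc
    try:
        return Spectrum(metadata=metadata, peaks=peaks)
    except ValueError as exc:
        raise SpectrumParseError(str(exc)) from exc


def read_msp(path) -> SpectralLibrary:
    """Read an MSP file into a :class:`SpectralLibrary`.

    Malformed blocks (missing/incorrect peak count, unparsable lines) are
    skipped with an :class:`MSPFormatWarning`; well-formed blocks are kept.
    An empty file yields an empty library.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    blocks: list[list[str]] = []
    current: list[str] = []
    for raw in text.splitlines():
        line = raw.rstrip()
        if not line.strip():
            if current:
                blocks.append(current)
                current = []
        else:
            current.append(line)
    if current:
        blocks.append(current)

    spectra: list[Spectrum] = []
    for i, block in enumerate(blocks):
        try:
            spectra.append(_parse_msp_block(block))
        except SpectrumParseError as exc:
            warnings.warn(
                f"{path.name}: skipping block {i + 1}: {exc}", MSPFormatWarning,
                stacklevel=2,
            )
    return SpectralLibrary(name=path.stem, spectra=spectra)


def write_msp(lib: SpectralLibrary, path) -> Path:
    """Write a library in the canonical MSP dialect.

    Upper-cased keys with ``:`` separators, a ``NUM PEAKS`` line, and
    tab-separated peak lines with six decimal places, blank line between
    blocks.  ``read_msp(write_msp(lib))`` reproduces metadata strings exactly
    and peak values to 1e-6.
    """
    path = Path(path)
    out: list[str] = []
    for sp in lib.spectra:
        for key, value in sp.metadata.items():
            out.append(f"{key.upper()}: {value}")
        out.append(f"NUM PEAKS: {len(sp.peaks)}")
        for p in sp.peaks:
            out.append(f"{p.mz:.6f}\t{p.intensity:.6f}")
        out.append("")
    path.write_text("\n".join(out), encoding="utf-8")
    return path


def read_hmdb_xml(path) -> Spectrum:
    """Parse one HMDB-style spectrum XML file.

    Expected elements (fixture schema, emulating HMDB experimental MS/MS
    XML): ``database-id`` (required), ``ionization-mode`` (optional),
    ``collision-energy-voltage`` (optional), and a peak list of
    ``ms-ms-peak`` entries each holding ``mass-charge`` and ``intensity``.
    Adduct and precursor m/z are typically absent from these files; that is
    the deficiency this package repairs.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SpectrumParseError(f"{path}: not well-formed XML: {exc}") from exc
    root = tree.getroot()
    dbid = root.findtext(".//database-id")
    if not dbid or not dbid.strip():
        raise SpectrumParseError(f"{path}: missing database-id")
    metadata = {"hmdb_id": dbid.strip()}
    ionization = root.findtext(".//ionization-mode")
    metadata["ionmode"] = normalize_ionmode(ionization)
    energy = root.findtext(".//collision-energy-voltage")
    if energy and energy.strip():
        metadata["collision_energy"] = energy.strip()
    peaks = []
    for node in root.iterfind(".//ms-ms-peak"):
        mz = node.findtext("mass-charge")
        inten = node.findtext("intensity")
        if mz is None or inten is None:
            raise SpectrumParseError(f"{path}: peak entry missing mass-charge/intensity")
        peaks.append((float(mz), float(inten)))
    if not peaks:
        raise SpectrumParseError(f"{path}: no peaks in peak list")
    return Spectrum(metadata=metadata, peaks=peaks)


_COMPOUND_REQUIRED = ("hmdb_id", "name", "inchikey", "smiles", "formula", "exact_mass")


def read_compound_csv(path) -> dict[str, dict]:
    """Read compound metadata keyed by HMDB id.

    Required columns (after key normalization / synonym mapping):
    hmdb_id, name, inchikey, smiles, formula, exact_mass.  ``exact_mass`` is
    parsed as Da and omitted from a row's entry when empty.  Duplicate ids:
    last row wins, with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    df.columns = [normalize_key(c) for c in df.columns]
    missing = [c for c in _COMPOUND_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    table: dict[str, dict] = {}
    for _, row in df.iterrows():
        hid = row["hmdb_id"]
        if not isinstance(hid, str) or not hid.strip():
            continue
        hid = hid.strip()
        if hid in table:
            warnings.warn(f"{path.name}: duplicate id {hid}; keeping last row",
                          UserWarning, stacklevel=2)
        entry: dict = {}
        for col in ("name", "inchikey", "smiles", "formula"):
            v = row[col]
            if isinstance(v, str) and v.strip():
                entry[col] = v.strip()
        em = row["exact_mass"]
        if isinstance(em, str) and em.strip():
            try:
                entry["exact_mass"] = float(em)
            except ValueError:
                warnings.warn(f"{path.name}: {hid}: unparsable exact_mass {em!r}",
                              UserWarning, stacklevel=2)
        table[hid] = entry
    return table
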