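"""Deterministic synthetic compounds, spectra and libraries with planted truth.

Every workflow in this package is testable offline: this module generates
pseudo-compounds (format-valid 27-character InChIKey-like identifiers,
formulas with planted isomer pairs, masses in the small-molecule range),
per-(compound, adduct) fragmentation patterns, replicate spectra with
controlled m/z and intensity jitter, and metadata corruptions applied at
exact counts so tests can assert on them.  A ground-truth record exists for
every generated spectrum, including corrupted ones, so downstream match
rates are computed against planted truth rather than assumptions.

Fragmentation patterns are arbitrary hash-derived pseudo-spectra: the
matching method only ever sees peak-list similarity, so chemical realism of
the fragments is irrelevant — but the pattern is a deterministic function of
the (compound, adduct) pair, because real fragmentation differs by adduct
and adduct prediction via best-match would otherwise be unidentifiable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .adducts import (
    canonical_string,
    enumerate_permutations,
    parse_adduct,
    theoretical_precursor_mz,
)
from .spectral_io import Peak, SpectralLibrary, Spectrum

_H = 1.00782503207
_C = 12.0
_N = 14.0030740048
_O = 15.9949146196

_LETTERS = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
_SMILES_FRAGS = ("C", "CC", "C(=O)", "O", "N", "c1ccccc1", "C(C)", "OC",
                 "C(=O)O", "CN", "C=C", "S")

POSITIVE_ADDUCTS = ("[M+H]+", "[M+Na]+", "[M+NH4]+", "[M+H-H2O]+", "[M+K]+")
NEGATIVE_ADDUCTS = ("[M-H]-", "[M+Cl]-", "[M+HCOO]-", "[M-H-H2O]-")


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from string parts (hash() is salted)."""
    digest = hashlib.blake2s("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SyntheticCompound:
    """A pseudo-compound: identifiers, formula and neutral monoisotopic mass."""

    inchikey: str
    smiles: str
    variant_smiles: str
    formula: str
    exact_mass: float
    name: str


@dataclass(frozen=True)
class CorruptionPlan:
    """Exact-count metadata corruptions and peak jitter for one library.

    Fractions are applied as round(fraction·n) over a seeded permutation of
    the spectra, so tests can assert exact counts.  Jitter standard
    deviations are in Da (m/z, additive) and in log-intensity units
    (multiplicative).
    """

    fraction_blank_adduct: float = 0.0
    fraction_permuted_adduct: float = 0.0
    fraction_malformed_adduct: float = 0.0
    fraction_noncanonical_smiles: float = 0.0
    mz_jitter_sd: float = 0.002
    intensity_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_blank_adduct", "fraction_permuted_adduct",
                     "fraction_malformed_adduct", "fraction_noncanonical_smiles"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mz_jitter_sd < 0 or self.intensity_jitter_sd < 0:
            raise ValueError("jitter standard deviations must be >= 0")


def make_compounds(n: int, seed: int) -> list[SyntheticCompound]:
    """Generate ``n`` deterministic pseudo-compounds.

    Masses lie in [80, 900] Da and are consistent with the generated
    CHNO formula.  Every compound at index i ≡ 1 (mod 10) shares its
    formula (hence exact mass) with compound i−1, planting isomer pairs
    that exercise the looseness of formula-based identifier matching.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[SyntheticCompound] = []
    for i in range(n):
        key = "-".join(["".join(rng.choice(_LETTERS, 14)),
                        "".join(rng.choice(_LETTERS, 10)), "N"])
        frags = list(rng.choice(_SMILES_FRAGS, rng.integers(3, 7)))
        smiles = "".join(frags)
        variant = "".join(reversed(frags))
        if variant == smiles:
            variant = smiles + "O"
        if i % 10 == 1 and i > 0:
            formula, mass = out[-1].formula, out[-1].exact_mass
        else:
            while True:
                nc = int(rng.integers(4, 28))
                nh = int(rng.integers(nc, 2 * nc + 3))
                no = int(rng.integers(0, 9))
                nn = int(rng.integers(0, 5))
                mass = nc * _C + nh * _H + no * _O + nn * _N
                if 80.0 <= mass <= 900.0:
                    break
            formula = f"C{nc}H{nh}" + (f"N{nn}" if nn else "") + (f"O{no}" if no else "")
        out.append(SyntheticCompound(
            inchikey=key, smiles=smiles, variant_smiles=variant,
            formula=formula, exact_mass=round(mass, 6),
            name=f"compound_{i:04d}"))
    return out


def compound_adducts(compound: SyntheticCompound,
                     adducts_per_compound: int = 2) -> list[str]:
    """Deterministic adduct assignment for a compound (library-independent).

    Roughly half the compounds are positive-only, a quarter negative-only
    and a quarter observed in both modes, mirroring how open libraries mix
    ionization coverage.  The assignment depends only on the compound so
    the same species carries the same adducts in every generated library.
    """
    h = _stable_seed("adducts", compound.inchikey)
    mode = h % 4
    if mode == 0:
        pool = list(NEGATIVE_ADDUCTS)
    elif mode == 1:
        k = adducts_per_compound // 2 or 1
        pos = [POSITIVE_ADDUCTS[(h + i) % len(POSITIVE_ADDUCTS)] for i in range(k)]
        neg = [NEGATIVE_ADDUCTS[(h + i) % len(NEGATIVE_ADDUCTS)]
               for i in range(adducts_per_compound - k)]
        return list(dict.fromkeys(pos + neg))[:adducts_per_compound]
    else:
        pool = list(POSITIVE_ADDUCTS)
    start = h % len(pool)
    picked = [pool[(start + i) % len(pool)] for i in range(adducts_per_compound)]
    return list(dict.fromkeys(picked))


def base_pattern(compound: SyntheticCompound, adduct: str,
                 peaks_per_spectrum: int = 8) -> list[Peak]:
    """Deterministic pseudo-fragmentation pattern for a (compound, adduct)."""
    rng = np.random.default_rng(_stable_seed("pattern", compound.inchikey, adduct))
    mz = np.sort(rng.uniform(50.0, 480.0, peaks_per_spectrum))
    # enforce spacing well above alignment tolerance so patterns stay stable
    mz = mz + np.arange(peaks_per_spectrum) * 1.0
    inten = rng.uniform(0.05, 1.0, peaks_per_spectrum)
    inten = inten / inten.max()
    return [Peak(float(m), float(x)) for m, x in zip(mz, inten)]


def _noncanonical_permutation(adduct: str) -> str:
    """A parsable but non-canonical rendering of a canonical adduct."""
    form = parse_adduct(adduct)
    alternates = sorted(s for s in enumerate_permutations(form) if s != adduct)
    if alternates:
        return alternates[-1]
    inner, charge = adduct.rsplit("]", 1)
    return f"{inner} ]{charge}".replace("+", " + ", 1)


def _malform(adduct: str, k: int) -> str:
    """Cycle through parseable formatting corruptions of a canonical label."""
    variants = [
        "[" + adduct[1:adduct.index("]")].replace("+", " + ").replace("-", " - ")
        + "] " + adduct[adduct.index("]") + 1:],
        adduct[1:adduct.index("]")] + adduct[adduct.index("]") + 1:],
        adduct.replace("-", "−") if "-" in adduct else f" {adduct} ",
        adduct.replace("]+", "]1+").replace("]-", "]1-"),
    ]
    return variants[k % len(variants)]


def make_library(compounds: list[SyntheticCompound],
                 adducts_per_compound: int = 2,
                 peaks_per_spectrum: int = 8,
                 replicates: int = 2,
                 plan: CorruptionPlan | None = None,
                 name: str = "synthetic"):
    """Build one library plus its total ground-truth map.

    One spectrum per compound × assigned adduct × replicate: the
    (compound, adduct) base pattern with additive m/z jitter and
    multiplicative log-normal intensity jitter, precursor m/z set to the
    theoretical value plus jitter.  Corruptions are applied afterwards at
    exact counts.  Returns ``(library, truth)`` where ``truth`` maps
    spectrum_id to the planted adduct/identifier record.
    """
    if plan is None:
        plan = CorruptionPlan()
    rng = np.random.default_rng(_stable_seed("library", name, plan.seed))
    spectra: list[Spectrum] = []
    truth: dict[str, dict] = {}
    for comp in compounds:
        for adduct in compound_adducts(comp, adducts_per_compound):
            form = parse_adduct(adduct)
            prec = theoretical_precursor_mz(form, comp.exact_mass)
            base = base_pattern(comp, adduct, peaks_per_spectrum)
            for rep in range(replicates):
                mz = np.array([p.mz for p in base])
                inten = np.array([p.intensity for p in base])
                mz = mz + rng.normal(0.0, plan.mz_jitter_sd, mz.size)
                inten = inten * np.exp(rng.normal(0.0, plan.intensity_jitter_sd,
                                                  inten.size))
                inten = inten / inten.max()
                sid = f"{name}:{comp.name}:{adduct}:{rep}"
                meta = {
                    "spectrum_id": sid,
                    "name": comp.name,
                    "inchikey": comp.inchikey,
                    "smiles": comp.smiles,
                    "formula": comp.formula,
                    "exact_mass": f"{comp.exact_mass:.6f}",
                    "adduct": adduct,
                    "precursor_mz": f"{prec + rng.normal(0.0, plan.mz_jitter_sd):.9f}",
                    "ionmode": form.ionmode,
                    "source_library": name,
                }
                spectra.append(Spectrum(metadata=meta,
                                        peaks=list(zip(mz, inten))))
                truth[sid] = {
                    "adduct": adduct,
                    "inchikey": comp.inchikey,
                    "smiles": comp.smiles,
                    "formula": comp.formula,
                    "ionmode": form.ionmode,
                    "theoretical_precursor_mz": prec,
                }
    n = len(spectra)
    order = rng.permutation(n)
    k_blank = round(plan.fraction_blank_adduct * n)
    k_perm = round(plan.fraction_permuted_adduct * n)
    k_mal = round(plan.fraction_malformed_adduct * n)
    for idx in order[:k_blank]:
        sp = spectra[idx]
        sp.metadata.pop("adduct", None)
        sp.metadata.pop("precursor_mz", None)
        truth[sp.metadata["spectrum_id"]]["corruption"] = "blank_adduct"
    for idx in order[k_blank:k_blank + k_perm]:
        sp = spectra[idx]
        sp.metadata["adduct"] = _noncanonical_permutation(sp.metadata["adduct"])
        truth[sp.metadata["spectrum_id"]]["corruption"] = "permuted_adduct"
    for j, idx in enumerate(order[k_blank + k_perm:k_blank + k_perm + k_mal]):
        sp = spectra[idx]
        sp.metadata["adduct"] = _malform(sp.metadata["adduct"], j)
        truth[sp.metadata["spectrum_id"]]["corruption"] = "malformed_adduct"
    k_smiles = round(plan.fraction_noncanonical_smiles * n)
    smiles_order = np.random.default_rng(
        _stable_seed("smiles", name, plan.seed)).permutation(n)
    by_key = {c.inchikey: c for c in compounds}
    for idx in smiles_order[:k_smiles]:
        sp = spectra[idx]
        comp = by_key[sp.metadata["inchikey"]]
        sp.metadata["smiles"] = comp.variant_smiles
        truth[sp.metadata["spectrum_id"]]["noncanonical_smiles"] = True
    return SpectralLibrary(name=name, spectra=spectra), truth


@dataclass
class BenchmarkSuite:
    """Four overlapping subject libraries plus an annotation-deficient one."""

    libraries: list[SpectralLibrary]
    hmdb_like: SpectralLibrary
    truth: dict[str, dict]
    shared_inchikeys: set[str] = field(default_factory=set)


def make_benchmark_suite(seed: int = 1,
                         n_shared: int = 25,
                         n_unique: int = 3,
                         replicates: int = 2) -> BenchmarkSuite:
    """Fixture-scale emulation of the multi-library benchmarking topology.

    Four libraries share ``n_shared`` compounds (plus a few library-unique
    ones) with heterogeneous adduct formatting: one library annotates half
    its adducts as positional permutations, another malformats a third of
    them.  The fifth library mimics an HMDB-style collection in which half
    the spectra lack adduct and precursor m/z metadata entirely; it contains
    only shared compounds, so every blanked annotation is recoverable in
    principle from the other four.
    """
    compounds = make_compounds(n_shared + 4 * n_unique, seed)
    shared = compounds[:n_shared]
    extras = compounds[n_shared:]
    specs = [
        ("libA", CorruptionPlan(seed=seed)),
        ("libB", CorruptionPlan(fraction_permuted_adduct=0.5, seed=seed)),
        ("libC", CorruptionPlan(fraction_malformed_adduct=0.3, seed=seed)),
        ("libD", CorruptionPlan(seed=seed)),
    ]
    libraries = []
    truth: dict[str, dict] = {}
    for i, (name, plan) in enumerate(specs):
        members = shared + extras[i * n_unique:(i + 1) * n_unique]
        lib, t = make_library(members, replicates=replicates, plan=plan, name=name)
        libraries.append(lib)
        truth.update(t)
    hmdb, t = make_library(shared, replicates=replicates,
                           plan=CorruptionPlan(fraction_blank_adduct=0.5,
                                               seed=seed),
                           name="hmdb_like")
    truth.update(t)
    return BenchmarkSuite(libraries=libraries, hmdb_like=hmdb, truth=truth,
                          shared_inchikeys={c.inchikey for c in shared})


def make_reliability_pair(seed: int = 1,
                          n_compounds: int = 60,
                          replicates: int = 5,
                          noncanonical_smiles: float = 0.1):
    """Two libraries of the same compounds for metadata-reliability runs.

    Library A carries canonical SMILES throughout; library B replaces
    SMILES with a non-canonical variant for an exact fraction of spectra.
    Among identical-InChIKey high-confidence matches the SMILES mismatch
    rate therefore has a planted value of ``noncanonical_smiles``.
    """
    compounds = make_compounds(n_compounds, seed + 17)
    lib_a, truth_a = make_library(compounds, replicates=replicates,
                                  plan=CorruptionPlan(seed=seed), name="relA")
    lib_b, truth_b = make_library(compounds, replicates=replicates,
                                  plan=CorruptionPlan(
                                      fraction_noncanonical_smiles=noncanonical_smiles,
                                      seed=seed + 1),
                                  name="relB")
    return lib_a, lib_b, {**truth_a, **truth_b}


def write_hmdb_fixtures(out_dir, compounds: list[SyntheticCompound],
                        spectra_per_compound: int = 2, seed: int = 1,
                        missing_csv_fraction: float = 0.0):
    """Write synthetic HMDB-style XML spectra plus the compound CSV.

    Returns (xml_dir, csv_path, n_xml).  ``missing_csv_fraction`` drops an
    exact count of compounds from the CSV so join/drop accounting can be
    asserted.  All files are synthetic stand-ins for HMDB downloads.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    xml_dir = out_dir / "xml"
    xml_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_stable_seed("hmdb-fixture", seed))
    n_files = 0
    hmdb_ids = {}
    for i, comp in enumerate(compounds):
        hid = f"SYNHMDB{i:05d}"
        hmdb_ids[comp.inchikey] = hid
        adducts = compound_adducts(comp, adducts_per_compound=1)
        for k in range(spectra_per_compound):
            adduct = adducts[k % len(adducts)]
            form = parse_adduct(adduct)
            peaks = base_pattern(comp, adduct)
            rows = "\n".join(
                f"    <ms-ms-peak><mass-charge>{p.mz + rng.normal(0, 0.002):.6f}"
                f"</mass-charge><intensity>{p.intensity:.6f}</intensity></ms-ms-peak>"
                for p in peaks)
            text = (
                "<ms-ms-spectrum>\n"
                f"  <database-id>{hid}</database-id>\n"
                f"  <ionization-mode>{form.ionmode.capitalize()}</ionization-mode>\n"
                f"  <collision-energy-voltage>{10 * (k + 1)}</collision-energy-voltage>\n"
                "  <ms-ms-peaks>\n" + rows + "\n  </ms-ms-peaks>\n"
                "</ms-ms-spectrum>\n")
            (xml_dir / f"{hid}_spectrum_{k}.xml").write_text(text, encoding="utf-8")
            n_files += 1
    drop = round(missing_csv_fraction * len(compounds))
    kept = compounds[:len(compounds) - drop] if drop else compounds
    csv_path = out_dir / "compounds.csv"
    lines = ["hmdb_id,name,inchikey,smiles,chemical_formula,exact_mass"]
    for comp in kept:
        lines.append(",".join([hmdb_ids[comp.inchikey], comp.name, comp.inchikey,
                               comp.smiles, comp.formula, f"{comp.exact_mass:.6f}"]))
    csv_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return xml_dir, csv_path, n_files
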