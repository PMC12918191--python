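"""Adduct-string grammar and precursor m/z arithmetic.

An electrospray adduct such as ``[2M+Na]+`` describes how a neutral molecule
M appears as an ion: a multiplier (dimers, trimers), a multiset of gained and
lost neutral fragments (H, Na, H2O, ...), and a signed charge.  Open spectral
libraries write the same species many ways (``[M+H2O+H]+`` vs
``[M + H + H2O] +``); this module parses that heterogeneity into a structured
:class:`AdductForm`, renders one deterministic canonical string per species,
enumerates positional permutations of the ion sequence, and computes the
theoretical precursor m/z from a neutral exact mass:

    m/z = (k·M + Σ gains − Σ losses − z·m_e) / |z|

with neutral-fragment monoisotopic masses and the electron mass handled per
charge.  Fragment masses live in a user-extensible TSV shipped with the
package (Fiehn-lab-style ion dictionary).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

ELECTRON_MASS = 0.00054857990907


class AdductParseError(ValueError):
    """An adduct string could not be parsed; carries the offending substring."""

    def __init__(self, message: str, offending: str = ""):
        super().__init__(message)
        self.offending = offending


class _MissingAdduct:
    """Sentinel for absent/placeholder adducts ('', 'UNKNOWN', '?', ...).

    These are not parse errors: the repair workflow routes them to adduct
    prediction instead.
    """

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "MISSING_ADDUCT"


MISSING_ADDUCT = _MissingAdduct()
_MISSING_STRINGS = {"", "unknown", "?", "n/a", "na", "nan", "null", "none", "-"}


def is_missing_adduct(value) -> bool:
    return value is MISSING_ADDUCT


class IonMassTable(dict):
    """Token -> neutral monoisotopic fragment mass in Da."""

    @classmethod
    def from_tsv(cls, path) -> "IonMassTable":
        table = cls()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token, mass = line.split("\t")[:2]
            if token == "token":
                continue
            table[token] = float(mass)
        return table

    @classmethod
    def default(cls) -> "IonMassTable":
        ref = resources.files("speclib_repair.data").joinpath("ion_masses.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


_DEFAULT_TABLE: IonMassTable | None = None


def default_ion_masses() -> IonMassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = IonMassTable.default()
    return _DEFAULT_TABLE


def _order_tokens(counts: dict[str, int]) -> tuple[tuple[str, int], ...]:
    """Canonical group order: H first, then remaining tokens alphabetically."""
    keys = sorted(counts, key=lambda t: (t != "H", t))
    return tuple((k, counts[k]) for k in keys)


@dataclass(frozen=True)
class AdductForm:
    """Structured adduct: k·M plus gained/lost fragments and a signed charge."""

    multiplier: int
    gains: tuple[tuple[str, int], ...]
    losses: tuple[tuple[str, int], ...]
    charge: int

    def __post_init__(self):
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if self.charge == 0:
            raise ValueError("charge must be non-zero")
        object.__setattr__(self, "gains", _order_tokens(dict(self.gains)))
        object.__setattr__(self, "losses", _order_tokens(dict(self.losses)))

    @property
    def ionmode(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    def signed_ions(self) -> tuple[tuple[str, str], ...]:
        """Expand to one (sign, token) entry per ion occurrence."""
        seq = [("+", tok) for tok, n in self.gains for _ in range(n)]
        seq += [("-", tok) for tok, n in self.losses for _ in range(n)]
        return tuple(seq)


def _format_charge(charge: int) -> str:
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return sign if mag == 1 else f"{mag}{sign}"


def _parse_charge(text: str) -> int:
    t = text.strip()
    if re.fullmatch(r"\+{1,9}", t):
        return len(t)
    if re.fullmatch(r"-{1,9}", t):
        return -len(t)
    m = re.fullmatch(r"(\d+)([+-])", t) or re.fullmatch(r"([+-])(\d+)", t)
    if m:
        a, b = m.groups()
        mag = int(a) if a.isdigit() else int(b)
        sign = a if a in "+-" else b
        if mag == 0:
            raise AdductParseError("zero charge", text)
        return mag if sign == "+" else -mag
    raise AdductParseError(f"unparsable charge {text!r}", text)


def _match_token(body: str, pos: int, table: IonMassTable) -> str | None:
    """Longest token match at `pos`; exact case first, then case-insensitive."""
    best = None
    for tok in table:
        if body.startswith(tok, pos) and (best is None or len(tok) > len(best)):
            best = tok
    if best is not None:
        return best
    lower = body.lower()
    for tok in table:
        if lower.startswith(tok.lower(), pos) and (best is None or len(tok) > len(best)):
            best = tok
    return best


def _parse_body(body: str, table: IonMassTable) -> tuple[int, dict, dict]:
    m = re.match(r"^(\d*)[Mm]", body)
    if not m:
        raise AdductParseError(f"no molecule symbol in {body!r}", body)
    multiplier = int(m.group(1)) if m.group(1) else 1
    if multiplier < 1:
        raise AdductParseError("multiplier must be >= 1", m.group(1))
    pos = m.end()
    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    while pos < len(body):
        sign = body[pos]
        if sign not in "+-":
            raise AdductParseError(f"unparsable residue {body[pos:]!r}", body[pos:])
        pos += 1
        cm = re.match(r"\d+", body[pos:])
        count = 1
        if cm:
            count = int(cm.group(0))
            pos += cm.end()
        tok = _match_token(body, pos, table)
        if tok is None:
            residue = re.match(r"[A-Za-z0-9]*", body[pos:]).group(0) or body[pos:]
            raise AdductParseError(f"unknown ion token {residue!r}", residue)
        pos += len(tok)
        target = gains if sign == "+" else losses
        target[tok] = target.get(tok, 0) + count
    return multiplier, gains, losses


def parse_adduct(s: str, table: IonMassTable | None = None):
    """Parse an adduct string tolerantly into an :class:`AdductForm`.

    Accepts spacing, missing/doubled brackets, charge written as ``+``,
    ``2+``, ``+2``, ``++`` or inside the bracket, unicode minus signs, and a
    ``2M`` multiplier prefix.  Placeholder strings ('', 'UNKNOWN', '?', ...)
    return the :data:`MISSING_ADDUCT` sentinel.  Anything else that cannot be
    resolved raises :class:`AdductParseError` carrying the offending text.
    """
    if table is None:
        table = default_ion_masses()
    if s is None or s.strip().lower() in _MISSING_STRINGS:
        return MISSING_ADDUCT
    t = re.sub(r"\s+", "", s)
    t = t.replace("−", "-").replace("–", "-").replace("—", "-")
    t = t.replace("＋", "+")
    while "[[" in t:
        t = t.replace("[[", "[")
    while "]]" in t:
        t = t.replace("]]", "]")

    charge: int | None = None
    if "]" in t:
        inner, _, suffix = t.rpartition("]")
        inner = inner.lstrip("[")
        if suffix:
            charge = _parse_charge(suffix)
            body = inner
        else:
            cm = re.search(r"([+-]+)$", inner)
            if not cm:
                raise AdductParseError(f"missing charge in {s!r}", s)
            charge = _parse_charge(cm.group(1))
            body = inner[: cm.start()]
        mult, gains, losses = _parse_body(body, table)
    else:
        u = t.lstrip("[")
        # Charge split is ambiguous without brackets (is '4+' in 'M+NH4+' a
        # charge?), so try candidate splits and keep the first whose body
        # parses.
        candidates = []
        for pat in (r"([+-]\d+)$", r"([+-]+)$", r"(\d+[+-])$"):
            cm = re.search(pat, u)
            if cm:
                candidates.append((u[: cm.start()], cm.group(1)))
        err: Exception | None = None
        parsed = None
        for body, ctext in candidates:
            try:
                parsed = (_parse_body(body, table), _parse_charge(ctext))
                break
            except AdductParseError as exc:
                err = exc
        if parsed is None:
            if err is not None:
                raise err
            raise AdductParseError(f"missing charge in {s!r}", s)
        (mult, gains, losses), charge = parsed
    form = AdductForm(multiplier=mult, gains=tuple(gains.items()),
                      losses=tuple(losses.items()), charge=charge)
    return form


def canonical_string(a: AdductForm) -> str:
    """Render the deterministic canonical label for an adduct.

    Gains before losses; within each group H first, then tokens
    alphabetically; repeated ions collapsed to a count prefix; charge as
    ``+``/``-``/``2+``...  ``parse_adduct`` of the result reproduces ``a``.
    """
    parts = []
    for tok, n in a.gains:
        parts.append("+" + (f"{n}{tok}" if n > 1 else tok))
    for tok, n in a.losses:
        parts.append("-" + (f"{n}{tok}" if n > 1 else tok))
    mult = str(a.multiplier) if a.multiplier > 1 else ""
    return f"[{mult}M{''.join(parts)}]{_format_charge(a.charge)}"


def canonicalize(s: str, table: IonMassTable | None = None) -> str:
    """Parse-then-format convenience; missing adducts raise ValueError."""
    form = parse_adduct(s, table)
    if is_missing_adduct(form):
        raise ValueError(f"cannot canonicalize placeholder adduct {s!r}")
    return canonical_string(form)


_MAX_PERMUTED_IONS = 7


def enumerate_permutations(a: AdductForm) -> set[str]:
    """All positional orderings of the signed ion sequence, as strings.

    Every member parses back to a form whose canonical string equals
    ``canonical_string(a)``; repeated ions are rendered one occurrence at a
    time (``[M+H+H]2+``).
    """
    ions = a.signed_ions()
    if len(ions) > _MAX_PERMUTED_IONS:
        raise ValueError(f"refusing to permute {len(ions)} ions")
    mult = str(a.multiplier) if a.multiplier > 1 else ""
    charge = _format_charge(a.charge)
    out = set()
    for order in set(itertools.permutations(ions)):
        body = "".join(f"{sign}{tok}" for sign, tok in order)
        out.add(f"[{mult}M{body}]{charge}")
    return out


def adduct_mass_shift(a: AdductForm, table: IonMassTable | None = None) -> float:
    """Total mass shift Σ gains − Σ losses − z·m_e (before dividing by |z|)."""
    if table is None:
        table = default_ion_masses()
    shift = 0.0
    for tok, n in a.gains:
        if tok not in table:
            raise KeyError(f"ion token {tok!r} missing from mass table")
        shift += n * table[tok]
    for tok, n in a.losses:
        if tok not in table:
            raise KeyError(f"ion token {tok!r} missing from mass table")
        shift -= n * table[tok]
    return shift - a.charge * ELECTRON_MASS


def theoretical_precursor_mz(a: AdductForm, neutral_mass: float,
                             table: IonMassTable | None = None) -> float:
    """m/z of the adduct ion for a neutral monoisotopic mass in Da."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return (a.multiplier * neutral_mass + adduct_mass_shift(a, table)) / abs(a.charge)


def load_adduct_dictionary(path=None, table: IonMassTable | None = None) -> dict[str, AdductForm]:
    """Load the canonical adduct dictionary (TSV) as label -> AdductForm.

    Columns: canonical, charge, multiplier, composition, mass_shift.  Each
    row is validated: the canonical label must be a fixed point of
    parse/format and the stored mass shift must agree with the ion-mass
    table to 1e-4 Da.
    """
    if table is None:
        table = default_ion_masses()
    if path is None:
        ref = resources.files("speclib_repair.data").joinpath("adducts.tsv")
        with resources.as_file(ref) as p:
            lines = Path(p).read_text(encoding="utf-8").splitlines()
    else:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    out: dict[str, AdductForm] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("canonical\t"):
            continue
        canonical, charge, multiplier, _composition, mass_shift = line.split("\t")
        form = parse_adduct(canonical, table)
        if is_missing_adduct(form) or canonical_string(form) != canonical:
            raise ValueError(f"dictionary label {canonical!r} is not canonical")
        if form.charge != int(charge) or form.multiplier != int(multiplier):
            raise ValueError(f"dictionary row {canonical!r} inconsistent")
        if abs(adduct_mass_shift(form, table) - float(mass_shift)) > 1e-4:
            raise ValueError(f"dictionary mass shift for {canonical!r} inconsistent")
        out[canonical] = form
    return out
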