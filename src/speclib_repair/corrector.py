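"""Learned normalization of heterogeneous adduct strings.

Open libraries write the same adduct many ways — permuted ion order, spaces,
dropped or doubled brackets, charge inside the bracket, unicode minus signs.
The deterministic grammar in :mod:`speclib_repair.adducts` already resolves
anything parsable, so correction is rule-first: parsable strings are
canonicalized by the grammar with confidence 1.  A character n-gram
TF-IDF + single-hidden-layer MLP classifier backs it up for strings the
grammar cannot parse, trained on a corpus built from the canonical adduct
dictionary, all positional permutations of each label's ion sequence, and an
enumerated set of textual corruptions of each variant.  Predictions below a
confidence floor are reported uncorrected rather than silently relabeled.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.metrics import classification_report
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer
from sklearn.feature_extraction.text import TfidfVectorizer

from .adducts import (
    AdductParseError,
    canonical_string,
    enumerate_permutations,
    is_missing_adduct,
    load_adduct_dictionary,
    parse_adduct,
)

CONFIDENCE_FLOOR = 0.5
UNKNOWN_LABEL = "UNKNOWN"

_CHARGE_TAIL = r"([+-]\d+|\d+[+-]|[+-]+)"


def preprocess_adduct_text(s: str) -> str:
    """Best-effort, deterministic, idempotent textual normalization.

    Strips whitespace, folds unicode sign variants, unwraps doubled
    brackets, restores missing brackets around ``...M...`` bodies, moves a
    charge written inside the bracket outside, and renders the charge
    suffix canonically (``+``, ``-``, ``2+``, ...).  No chemistry is
    guessed: a string without a recognizable charge keeps none.
    """
    t = unicodedata.normalize("NFKC", s)
    t = t.replace("−", "-").replace("–", "-").replace("—", "-").replace("＋", "+")
    t = re.sub(r"\s+", "", t)
    if not t:
        return t
    while "[[" in t:
        t = t.replace("[[", "[")
    while "]]" in t:
        t = t.replace("]]", "]")
    # lone lowercase molecule symbol: start/'['/digit-prefixed m before +,-,]
    t = re.sub(r"(?<![A-Za-z])m(?=[+\-\]])", "M", t)
    if "[" not in t and "]" not in t and re.match(r"^\d*M[+-]", t):
        m = re.search(_CHARGE_TAIL + r"$", t)
        # trailing pure-sign run doubles as the charge; digit forms are
        # ambiguous without brackets (NH4+ ...), so only sign runs move out
        if m and re.fullmatch(r"[+-]+", m.group(1)) and len(t[: m.start()]) > 1 \
                and t[m.start() - 1] not in "+-":
            t = f"[{t[: m.start()]}]{m.group(1)}"
        else:
            t = f"[{t}]"
    if t.startswith("[") and "]" not in t:
        m = re.search(_CHARGE_TAIL + r"$", t)
        if m and m.start() > 1:
            t = f"{t[: m.start()]}]{m.group(1)}"
        else:
            t = t + "]"
    if t.endswith("]") and "[" in t:
        # charge written inside the bracket: "[M+H+]" -> "[M+H]+"
        m = re.search(r"([+-]+)\]$", t)
        if m and m.start() > t.index("[") + 1:
            t = f"{t[: m.start()]}]{m.group(1)}"
    if not t.startswith("[") and "]" in t:
        t = "[" + t
    m = re.match(r"^(.*\])" + _CHARGE_TAIL + r"$", t)
    if m:
        body, ctext = m.groups()
        if re.fullmatch(r"\+{1,9}", ctext):
            sign, mag = "+", len(ctext)
        elif re.fullmatch(r"-{1,9}", ctext):
            sign, mag = "-", len(ctext)
        else:
            sign = "+" if "+" in ctext else "-"
            mag = int(ctext.strip("+-") or 1)
        t = body + (sign if mag == 1 else f"{mag}{sign}")
    return t


def _corruption_variants(s: str) -> list[str]:
    """Enumerated textual corruptions of one bracketed adduct string.

    The corruption set (spaces around signs and before the charge, dropped
    and doubled brackets, charge inside the bracket, unicode minus,
    lowercase molecule symbol, ``1+``/``+1``/``++`` charge spellings,
    surrounding whitespace) emulates the formatting noise observed across
    open libraries.
    """
    m = re.match(r"^\[(.+)\](.+)$", s)
    if not m:
        return []
    inner, charge = m.groups()
    spaced_inner = re.sub(r"(?<=.)([+-])", r" \1 ", inner)
    out = [
        f"[{spaced_inner}] {charge}",
        f"[{inner}] {charge}",
        f"{inner}{charge}" if re.fullmatch(r"[+-]+", charge) else f"{inner}]{charge}",
        f"[[{inner}]]{charge}",
        f"  [{inner}]{charge} ",
        re.sub(r"(?<=\[)(\d*)M", r"\1m", s),
    ]
    if "-" in inner or "-" in charge:
        out.append(s.replace("-", "−"))
    if charge in ("+", "-"):
        out.append(f"[{inner}{charge}]")
        out.append(f"[{inner}]1{charge}")
        out.append(f"[{inner}]{charge}1")
    elif re.fullmatch(r"\d[+-]", charge):
        out.append(f"[{inner}]{charge[1] * int(charge[0])}")
        out.append(f"[{inner}]{charge[1]}{charge[0]}")
    return [v for v in dict.fromkeys(out) if v != s]


@dataclass
class LabeledAdductCorpus:
    """Training corpus of (raw string, canonical label, provenance) triples."""

    examples: list[tuple[str, str]] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def add(self, text: str, label: str, source: str) -> None:
        self.examples.append((text, label))
        self.provenance.append(source)

    @property
    def texts(self) -> list[str]:
        return [t for t, _ in self.examples]

    @property
    def labels(self) -> list[str]:
        return [l for _, l in self.examples]

    def __len__(self) -> int:
        return len(self.examples)


def build_corpus(dictionary: dict | list | None = None,
                 observed: list[str] = ()) -> LabeledAdductCorpus:
    """Assemble the labeled corpus from a canonical dictionary.

    Per canonical label: the label itself, every positional permutation of
    its ion sequence, and the corruption set applied to each of those
    strings.  Observed strings are labeled through the grammar; unparsable
    ones land in the ``UNKNOWN`` bucket.
    """
    if dictionary is None:
        dictionary = load_adduct_dictionary()
    if not isinstance(dictionary, dict):
        dictionary = {canonical_string(parse_adduct(lbl)): parse_adduct(lbl)
                      for lbl in dictionary}
    corpus = LabeledAdductCorpus()
    for label, form in dictionary.items():
        variants = {label} | enumerate_permutations(form)
        for base in sorted(variants):
            source = "dictionary" if base == label else "permutation"
            corpus.add(base, label, source)
            for corrupted in _corruption_variants(base):
                corpus.add(corrupted, label, source)
    seen = set(corpus.texts)
    for raw in observed:
        if raw in seen:
            continue
        try:
            form = parse_adduct(preprocess_adduct_text(raw))
        except AdductParseError:
            form = None
        if form is None or is_missing_adduct(form):
            corpus.add(raw, UNKNOWN_LABEL, "observed")
        else:
            corpus.add(raw, canonical_string(form), "observed")
    return corpus


def _preprocess_batch(texts):
    return [preprocess_adduct_text(t) for t in texts]


@dataclass
class CorrectorModel:
    """Fitted corrector: preprocessing + char 1–3-gram TF-IDF + MLP."""

    pipeline: Pipeline
    labels: tuple[str, ...]
    version: str = "1"

    def predict(self, s: str) -> tuple[str, float]:
        proba = self.pipeline.predict_proba([s])[0]
        k = int(np.argmax(proba))
        return self.pipeline.classes_[k], float(proba[k])


def train_corrector(corpus: LabeledAdductCorpus, seed: int = 7,
                    holdout: float = 0.2):
    """Fit the corrector and evaluate it on a stratified hold-out split.

    Labels with a single example cannot be split stratified and are
    excluded with a warning.  Returns ``(model, report)`` where the report
    carries overall hold-out accuracy and per-label precision/recall.
    """
    texts = np.array(corpus.texts, dtype=object)
    labels = np.array(corpus.labels, dtype=object)
    uniq, counts = np.unique(labels, return_counts=True)
    singletons = set(uniq[counts < 2])
    if singletons:
        warnings.warn(f"excluding {len(singletons)} single-example label(s) "
                      f"from the split: {sorted(singletons)}", UserWarning,
                      stacklevel=2)
        keep = ~np.isin(labels, sorted(singletons))
        texts, labels = texts[keep], labels[keep]
    x_train, x_test, y_train, y_test = train_test_split(
        texts, labels, test_size=holdout, stratify=labels, random_state=seed)
    pipeline = Pipeline([
        ("preprocess", FunctionTransformer(_preprocess_batch)),
        ("tfidf", TfidfVectorizer(analyzer="char", ngram_range=(1, 3),
                                  lowercase=False)),
        ("mlp", MLPClassifier(hidden_layer_sizes=(200,), max_iter=500,
                              random_state=seed)),
    ])
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        pipeline.fit(list(x_train), list(y_train))
    y_pred = pipeline.predict(list(x_test))
    accuracy = float(np.mean(y_pred == y_test))
    report = {
        "accuracy": accuracy,
        "n_train": int(len(x_train)),
        "n_holdout": int(len(x_test)),
        "n_labels": int(len(np.unique(labels))),
        "per_label": classification_report(y_test, y_pred, output_dict=True,
                                           zero_division=0),
    }
    model = CorrectorModel(pipeline=pipeline,
                           labels=tuple(pipeline.classes_))
    return model, report


@dataclass
class CorrectionResult:
    """Outcome of correcting one adduct string."""

    input: str
    label: str | None
    confidence: float
    source: str  # grammar | model | uncorrected | missing

    @property
    def corrected(self) -> bool:
        return self.label is not None


def correct_adduct(model: CorrectorModel, s: str,
                   confidence_floor: float = CONFIDENCE_FLOOR) -> CorrectionResult:
    """Rule-first correction: grammar when parsable, classifier otherwise.

    The classifier can never contradict the deterministic grammar on
    parsable input; below the confidence floor the string is reported
    uncorrected.
    """
    pre = preprocess_adduct_text(s)
    try:
        form = parse_adduct(pre)
    except AdductParseError:
        form = None
    if form is not None:
        if is_missing_adduct(form):
            return CorrectionResult(s, None, 1.0, "missing")
        return CorrectionResult(s, canonical_string(form), 1.0, "grammar")
    label, confidence = model.predict(s)
    if confidence < confidence_floor or label == UNKNOWN_LABEL:
        return CorrectionResult(s, None, confidence, "uncorrected")
    return CorrectionResult(s, label, confidence, "model")


def save_model(model: CorrectorModel, path) -> None:
    joblib.dump({"version": model.version, "labels": model.labels,
                 "pipeline": model.pipeline}, path)


def load_model(path) -> CorrectorModel:
    blob = joblib.load(path)
    return CorrectorModel(pipeline=blob["pipeline"], labels=tuple(blob["labels"]),
                          version=str(blob.get("version", "1")))
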