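# Methods

This note documents the models and procedures implemented in
`speclib-repair`, the parameter choices that matter, what the synthetic
study conditions emulate, and the numerical conventions a maintainer needs
to know.

## The repair problem

An electrospray MS/MS spectrum is only reusable if its metadata says which
ion was fragmented: the adduct (e.g. `[M+H]+`, `[2M+Na]+`) and the
precursor m/z.  Public libraries disagree on how adducts are written and,
in the worst case, omit them entirely.  The package treats repair as two
separable problems:

1. **Normalization** — many strings, one species.  Solved
   deterministically by a grammar wherever possible, with a learned
   fallback.
2. **Prediction** — no string at all.  Solved by spectral matching against
   congruent reference spectra of the same compound, then copying the best
   match's canonical adduct.

## Adduct grammar

`AdductForm` is (multiplier k ≥ 1, multiset of gained fragments, multiset
of lost fragments, charge z ≠ 0).  Parsing is tolerant: whitespace,
missing/doubled brackets, charge written as `+`, `1+`, `+1`, `++` or
inside the bracket, unicode minus, and a `2M` multiplier prefix are all
accepted; unknown fragment tokens raise with the offending substring.
Placeholder strings (`UNKNOWN`, `?`, empty) map to a `MISSING_ADDUCT`
sentinel rather than an error, because the workflow must route them to
prediction, not reject them.

The canonical rendering is `[kM±ions]charge` with gains before losses,
H first then tokens alphabetically, repeated ions collapsed to a count
prefix (`2H`), and charge as `+`/`-`/`2+`/…  This ordering is a package
convention; any fixed order would do, what matters is that every
positional permutation of an adduct collapses to the same label.

Theoretical precursor m/z is
`(k·M + Σ gains − Σ losses − z·mₑ)/|z|` with neutral-fragment monoisotopic
masses from a shipped, user-extensible TSV (23 tokens covering the common
ESI adducts) and the electron mass (0.00054858 Da) charged per unit
charge.  Including the electron term keeps theoretical values well inside
the 0.25-Da coherence window used for observed-vs-theoretical precursor
checks.  The shipped adduct dictionary holds 60 canonical labels; it is a
superset of what any one library uses and is deliberately easy to extend.

## DP spectral alignment (OSA)

Peak lists sorted by m/z are aligned with the recurrence given in the
README over a zero-initialized (m+1)×(n+1) matrix.  Conventions that are
easy to get wrong:

* **Boundary semantics.**  Row 0 and column 0 stay zero, so leading gaps
  are free (semi-global flavor); the reported raw score is `dp[m,n]`, so
  trailing gaps are charged.  The brute-force oracle
  (`osa_brute_force`, sizes ≤ 8) enumerates every monotone alignment under
  exactly this convention: free skips of `min(i₁, j₁)` peaks before the
  first pair, `gap·(unmatched between/after)` elsewhere.  The DP equals it
  bit-for-bit (up to float associativity, tested at 1e-12) on hundreds of
  random instances in both intensity modes.
* **Intensity normalization.**  Intensities are scaled by each spectrum's
  maximum before `intensity_score = 1/(1+(Δ)²)`, making the score
  scale-free across libraries.  With intensities off, every in-tolerance
  match scores exactly 1.
* **Tie-breaking.**  Among score-optimal tracebacks the one minimizing
  Σ|Δm/z| over its aligned pairs wins; the accumulator ignores the match
  tolerance during traceback.  Residual ties resolve deterministically
  diagonal > up > left.  This is implemented as a second forward
  accumulator over the optimal-path subgraph, not by re-enumeration.
* **Normalization for reporting.**  `raw/max(m,n)` clipped to [0,1].  Raw
  and normalized are both emitted since either convention may be wanted
  downstream; ranking candidates for one query uses the normalized value.

Defaults: tolerance 0.005 Da, gap −0.1, mismatch −1 (fixed); the
constraint |gap| < |mismatch| is enforced, which also guarantees optimal
paths never take out-of-tolerance diagonal steps.

## Reference metrics

Greedy cosine follows the matchms contract (max-normalized intensities,
candidate pairs within tolerance taken in descending intensity-product
order, each peak used once, score `Σqᵢsⱼ/√(Σqᵢ²·Σsⱼ²)`) and is tested to
1e-9 against matchms itself.  Spectral-entropy similarity is
`1 − (2·S_mix − S_q − S_s)/ln 4` on tolerance-merged, sum-normalized
spectra with a half-weight mixture.  The ten generic vector distances are
SciPy's, applied to spectra binned at 0.01 Da over the pair's union m/z
range — the binning is this package's convention (the comparison needs
equal-length vectors somehow) and is recorded prominently because the
relative performance of the generic metrics depends on it.  Degenerate
inputs (all-zero vectors, zero variance for correlation) are defined as
maximal distance with a warning.  Minkowski order defaults to 3 so it is
distinct from city-block and Euclidean.

## Adduct corrector

Corpus: for each of the 60 dictionary labels, the label, every positional
permutation of its ion sequence, and ~10 textual corruptions of each
variant (spaces around signs, space before charge, dropped/doubled
brackets, charge inside bracket, unicode minus, lowercase `m`,
`1+`/`+1`/`++` charge spellings, surrounding whitespace) — 1181 labeled
examples, ≥ 10 per label.  Features: character 1–3-gram TF-IDF after the
same preprocessing applied at inference.  Model: one hidden layer of 200
units, 500 iteration cap, fixed seed; evaluated on a stratified 80/20
hold-out (labels with one example are excluded from the split with a
warning).

The corrector is rule-first: if the preprocessed string parses, the
grammar's canonical label is returned with confidence 1 and the model is
never consulted, so the classifier cannot contradict the grammar on
parsable input — this is tested exhaustively over the corpus.  The model
exists for unparsable strings; predictions under a 0.5 confidence floor
are reported uncorrected rather than silently relabeled.

## Matching workflow

Candidates must share the query's identifier (full 27-character InChIKey
by default; SMILES and formula supported, with formula documented as loose
for isomers) and its normalized ion mode; `unknown` never matches.
Candidates without a usable adduct are dropped for prediction.  Best match
is the extremal score; exact ties prefer the candidate with the smallest
|Δ precursor m/z|, then input order.  Match typing: both / adduct_only /
precursor_only / mismatch, with a missing field on either side making that
criterion non-concordant, and failure reserved for queries that never
reached scoring (no identifier, unknown mode, no congruent candidates, all
candidate adducts unknown) or whose own adduct is unidentifiable during
benchmarking.  Benchmark level 1 flattens intensities to one for every
metric; level 2 uses intensities and is restricted to the metrics designed
for them (osa, entropy, cosine_greedy).  No default score threshold is
applied for OSA; other metrics accept an optional `min_score`.

Reliability assessment: per repetition (seeds s, s+1, …), sample n spectra
from each library without replacement, all-vs-all greedy cosine, keep each
query's best subject at score ≥ 0.95, and report
`error_rate(G|F) = %` of kept pairs agreeing on field F but differing on
G, averaged over repetitions.  Sampling without replacement is a package
choice.

## Synthetic study conditions

The generator plants everything the workflows need to be measurable:

* pseudo-compounds with format-valid InChIKey-like ids, CHNO formulas
  (masses 80–900 Da, consistent with the formula), planted isomer pairs,
  and a non-canonical SMILES variant per compound;
* per-(compound, adduct) hash-derived fragmentation patterns of 8 peaks in
  [50, 490] Da.  Patterns depend on the adduct as well as the compound —
  real fragmentation does, and without this the best-match adduct of a
  compound would be unidentifiable in principle;
* replicates with additive m/z jitter (σ = 0.002 Da) and multiplicative
  log-normal intensity jitter (σ = 0.05), precursor m/z = theoretical +
  jitter;
* corruptions at exact counts (`round(fraction·n)` over a seeded
  permutation): blanked adduct+precursor, permuted adduct strings,
  malformed-but-parsable adduct strings, non-canonical SMILES.

The benchmark suite has four subject libraries sharing 25 compounds (plus
3 unique each; one library permutes half its adduct strings, another
malformats a third) and an HMDB-like library of the shared compounds with
exactly half its annotations blanked.  The reliability pair is 60
compounds × 2 adducts × 5 replicates per library (600 spectra), with a
10% non-canonical-SMILES fraction planted in one library.

What this does **not** emulate: chemically real fragmentation, collision
energy and instrument-type effects, cross-library intensity response,
wrong structure–spectrum assignments, and the sheer redundancy of real
libraries.  Passing tests therefore demonstrate that the algorithms are
implemented correctly and recover planted structure under realistic noise
— not that any particular match rate will be achieved on a given public
library.

## Problem sizes

The test suite and the acceptance script run the oracle comparison at 200
random pairs per intensity mode (lengths ≤ 6), the corrector on the full
1181-example corpus, recovery on 50 blanked queries against a 448-spectrum
merged subject, and reliability at n = 500, 5 repetitions.  These sizes
were chosen so the whole pipeline re-runs from scratch in about a minute
on one CPU while keeping every rate estimate's sampling error well inside
the asserted bands.

## Known limitations

* The grammar has no notion of isotopologues or in-source fragments, and
  charge states beyond ±3 are parsed but not specifically exercised.
* Adducts inconsistent with a spectrum's ion mode are flagged by the
  congruence filter, never rewritten.
* Cross-ion-mode adduct prediction is out of scope.
* Without brackets, charge-vs-count parses like `M+NH4+` are resolved by
  backtracking over candidate splits; pathological unbracketed strings can
  still parse differently than a human would read them.
* The O(m·n) alignment has no banding or vectorized batch mode; it is
  meant for library curation, not high-throughput search.
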