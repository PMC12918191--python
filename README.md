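# speclib-repair

Repair missing and malformed **adduct** and **precursor m/z** metadata in
MS/MS spectral libraries.

Open mass spectral libraries (GNPS, HMDB, MassBank, MoNA, MS-DIAL) are the
backbone of metabolite annotation in untargeted metabolomics, but their
metadata is uneven: adduct annotations are written in incompatible notations
(`[M+H2O+H]+` vs `[M + H + H2O] +`), and a large fraction of spectra —
close to half of HMDB's experimental MS/MS records — carry no adduct or
precursor m/z at all.  Cleaning pipelines usually discard such spectra;
this package repairs them instead.  It is written for library curators and
metabolomics bioinformaticians who want complete, queryable libraries
without throwing away data.

## What it does

* **Parse and canonicalize adduct strings.**  A tolerant grammar turns any
  reasonable rendering of an electrospray adduct into a structured form
  (multiplier, gained/lost fragments, charge) with one canonical label, and
  computes the theoretical precursor m/z
  `(k·M + Σ gains − Σ losses − z·mₑ)/|z|` from a neutral monoisotopic mass.
  A character n-gram TF-IDF + MLP corrector backs the grammar up for
  strings it cannot parse; the classifier never overrides the grammar on
  parsable input.

* **Score spectral similarity with a DP alignment (OSA).**  Two sorted peak
  lists are aligned by dynamic programming over a zero-initialized matrix,

      dp[i,j] = max( dp[i-1,j-1] + final_score,
                     dp[i-1,j]   + gap_penalty,
                     dp[i,j-1]   + gap_penalty )

  where `final_score = 1/(1 + (Δintensity)²)` when `|Δm/z| ≤ 0.005 Da`
  (or exactly 1 when intensities are switched off) and −1 otherwise, with
  `gap_penalty = −0.1`.  Ties among optimal tracebacks are broken by the
  minimal city-block distance Σ|Δm/z| over aligned pairs.  Greedy cosine,
  spectral-entropy similarity and ten generic vector distances (SciPy, on
  binned spectra) are provided behind the same metric registry for
  benchmarking.

* **Predict missing adducts.**  A query spectrum without an adduct is
  matched against subject spectra of the same compound (InChIKey, SMILES or
  formula) acquired in the same ionization mode; the best-scoring subject's
  canonical adduct is copied over, optionally with the theoretical
  precursor m/z.  Queries with known adducts double as ground truth for
  benchmarking metrics (match = same canonical adduct or precursor m/z
  within 0.5 Da).

* **Build and slice libraries.**  HMDB-style spectrum XML + compound CSV →
  MSP; conjunctive metadata subsetting (exact values / closed numeric
  ranges); annotation-completeness statistics; pairwise-exclusion
  comparisons (each library vs the merger of the rest); metadata-field
  reliability assessment via random high-confidence pairs.

* **Generate synthetic study data.**  Deterministic pseudo-compounds and
  libraries with planted ground truth (jitter, blanked/permuted/malformed
  adducts, non-canonical SMILES at exact fractions) make every workflow
  testable offline.

## Worked example

```python
from speclib_repair import canonicalize, parse_adduct, theoretical_precursor_mz
from speclib_repair.synth import make_benchmark_suite
from speclib_repair.libops import merge_libraries
from speclib_repair.workflow import predict_adduct

print(canonicalize("[M + H2O + H] +"))
print(round(theoretical_precursor_mz(parse_adduct("[M+H]+"), 180.063388), 6))

suite = make_benchmark_suite(seed=1)                    # synthetic libraries
subject = merge_libraries(suite.libraries, "integrated")
query = next(sp for sp in suite.hmdb_like if "adduct" not in sp.metadata)
record = predict_adduct(query, subject, "osa")
print(record.predicted_adduct, round(record.score, 3), record.subject_id)
```

prints

```
[M+H+H2O]+
181.070664
[M+H-H2O]+ 1.0 libC:compound_0000:[M+H-H2O]+:0
```

The spaced adduct collapses to its canonical label; the protonated hexose
precursor lands at 181.070664 Da; and the annotation-deficient query (its
planted truth is `[M+H-H2O]+`) is repaired by its best alignment
(normalized score 1.0) against a congruent-mode spectrum of the same
compound in another library.

The same operations are available from a shell:

```bash
repair adduct canon "[M + H2O + H] +"
repair synth --preset benchmark --seed 1 --out-dir fixtures/
repair match --query fixtures/hmdb_like.msp --subject fixtures/libA.msp \
      --metric osa --out report.tsv
repair stats --library fixtures/hmdb_like.msp --as-json
```

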