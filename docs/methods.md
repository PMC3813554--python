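# Methods

## Problem and model

Given a somatic mutation catalog for a cancer type and a table of
precomputed per-mutation features, the package (i) derives labeled
driver/passenger examples from recurrence patterns in the catalog itself,
(ii) selects a feature subset by a wrapper search under cross-validated
AUC, and (iii) trains a class-weighted support vector machine whose decision
value is the mutation score. Calls are made against empirical percentiles of
the training-score distributions, and each call carries an empirical
class-wise tail probability as its confidence.

The central assumption is that recurrence is evidence of selection:
variants seen independently in several tumors, or clustered in narrow
hotspots, are enriched for drivers, while isolated singletons — especially
in hypermutated, repair-deficient tumors — are almost all passengers. The
labels produced this way are noisy by construction; the classifier is asked
to generalize from prevalence-defined examples to the prevalence-independent
notion of driverness encoded in the features.

## Curation rules and their parameters

All rules operate on variant identity (chrom, pos, ref, alt); each
qualifying variant is reported once, keyed by the lexicographically
smallest record id. Defaults (all configurable in `CurationConfig`):

| parameter | default | meaning |
|---|---|---|
| `stringent_min_samples` | 2 | distinct samples for a stringent driver |
| `expanded_driver_min_samples` | 3 | distinct primary-tumor samples, any cancer type |
| `site_intersect_min` | 4 | records of any class sharing the exact site |
| `hotspot_window_bp` | 25 | centered window (± 12 bp) for the hotspot rule |
| `hotspot_min_mutations` | 5 | records inside the hotspot window |
| `passenger_isolation_window_bp` | 31 | centered window (± 15 bp); any other record disqualifies |
| `hypermutated_min_missense` | 55 | strictly-greater missense count marking a hypermutated sample |

Window widths must be odd and are read as centered: a "25 bp region"
around a site means site ± 12 bp. The site-intersection rule counts
records, not samples (a site hit by one missense and three indel records
qualifies); this choice is configurable in spirit but fixed in code, and
recurrence rule 1 counts distinct primary-tumor samples only, while the
window rules 2–3 count all records including cell lines. The hypermutated
cutoff is dataset-specific (e.g. 55 for one cohort, 130 for a more mutable
one) and uses strict inequality. Expanded sets subtract stringent variants
so the training and test material stay independent.

Because the catalog spans cancer types, `MutationRecord` carries a
`cancer_type` field; "a gene mutated in this cancer type" means the gene
has at least one record of any class among the target type's records.

## Imputation

Missing feature cells are filled from the ≤ k nearest same-gene mutations
(genomic bp distance; ties broken by lower position, then id) with the
feature observed — median for continuous features, mode for binary with
0/1 ties resolving to 0 (no annotation). Defaults k = 5. When a gene has
no donor the gene-wide, then table-wide central value is used; a feature
missing everywhere is an error. The nearest-neighbor choice reflects that
adjacent residues in the same protein share domain and conservation
context. The full table is imputed once, before selection; strictly this
lets test folds influence imputed training cells, a leakage we accept
because the donor pool is within-gene and the alternative (per-fold
imputation) makes the selection trace depend on fold membership.

## Screening and the two-step search

Single-feature screening uses a two-sided Mann–Whitney U test
(Bonferroni-corrected by the number of features actually screened, after
removing any configured exclusion list of population-biased features) and
an AUC margin |AUC − 0.5| > m. The margin is two-sided because features may
be protective or deleterious; features enter the model unflipped and the
SVM learns direction. The Mann–Whitney engine is scipy's, exact when both
groups have ≤ 20 tie-free observations, otherwise the tie- and
continuity-corrected normal approximation. The margin is data-set specific
(0.08 and 0.05 were used for the two cohorts the method was developed on);
the package default is 0.05.

Combination quality is the mean ROC AUC over repeated stratified k-fold
cross-validation (defaults 10 folds × 5 repeats; fold AUCs come from the
same rank-sum implementation used everywhere else). The model inside the
search is identical to the final classifier, with standardization fit per
training fold. "Fewer than 4 features" is read as subset sizes {1, 2, 3};
ties in the enumeration favor the smaller, then lexicographically earlier
subset. Hill climbing runs to exhaustion of the screened features rather
than stopping at the first decline, recording the full path so the AUC
curve can be plotted; the optimal set is the shortest path prefix attaining
the maximum CV AUC. The whole search is bit-reproducible for a fixed seed.

## Classifier, calls, confidence

The SVM defaults to an RBF kernel (C = 1, gamma scaled), standardized
inputs, and class weights N/(2·N_c) — sklearn's "balanced" mode, mean 1
over samples — because curated passengers outnumber drivers several-fold.
A linear kernel is available by flag. Percentiles use linear interpolation
between order statistics (numpy default) and are stored with the model.
Call rules are applied in order — driver (score strictly above the
passenger 90th percentile), then passenger (strictly below the driver 10th
percentile), else no-call — so when the two thresholds cross (well-separated
classes), scores between them are drivers by precedence and an
informational message is logged. Confidence counts strictly more extreme
same-class training scores; ties are not more extreme; no-calls have null
confidence. Sorted training scores ship inside the serialized model
(a joblib archive with a plain metadata dict) so confidence is reproducible
without retraining.

## Synthetic data

The generator serves two roles. `make_feature_table` draws continuous
informative features from Normal(d, 1) for drivers vs Normal(0, 1) for
passengers — a single such feature has expected AUC Φ(d/√2), which the
tests use as a closed-form check — plus Bernoulli(0.5 + δ) vs
Bernoulli(0.5) binary features and uniformly random missingness (a
block-missing mode emulates portal-wise dropout, where a whole feature
block is absent for a run of mutations). `make_catalog` plants driver
variants via the recurrence rule (3 primary-tumor samples) and via 5-record
hotspots laid out at offsets {−12, −6, 0, +6, +12} so that exactly the
centered record's window holds all five, plus isolated singletons spaced
200 bp apart as passengers; the planted truth is returned, and curation
must recover it exactly (a round-trip property tested directly).

What the generator does **not** emulate: realistic mutation spectra,
trinucleotide signatures, gene length variation, correlated features, or
label noise in the curated sets. Passing tests therefore demonstrate the
correctness of the rules, search, and calling machinery under known
conditions — not the field performance of the approach on real cohorts,
which depends on external feature portals and catalogs that are out of
scope here.

## Problem sizes and numerical choices

The test suite runs the statistical checks at sizes chosen to give stable
Monte-Carlo behavior while keeping a full run around three minutes:
enumeration optimality on twenty 8-feature fixtures (92 subsets each,
5 folds × 2 repeats), screening type-I control on 200 replicates of 95
noise features at n = 100 + 100, recovery of 3 informative of 30 features
at n = 300 + 300 over 20 seeds, and the Gaussian separation limit at
n = 1000 + 1000 per class split. Curation window rules are verified against
a brute-force O(n²) pairwise-distance oracle on 200 random catalogs of up
to 500 records. Degenerate inputs fail loudly: single-class labels, empty
score groups, constant correlation axes, features missing everywhere, and
class counts smaller than the fold count all raise errors naming the
problem.

## Known limitations

- Curated labels are prevalence-derived; in very high mutation-rate
  cancers the singleton-passenger assumption weakens.
- Whole-table imputation before selection (leakage noted above).
- No probability calibration of SVM scores; confidence is an empirical
  rank statistic, not a calibrated posterior.
- No-call mutations get no confidence by design.
- Gene symbols are upper-cased but not alias-resolved; mutations are keyed
  genomically, with protein change as annotation only.
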