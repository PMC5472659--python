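# Methods

## Model and assumptions

The package implements local, similarity-weighted read-across regression.
The core assumption is the read-across postulate itself: particles that are
similar — structurally, physico-chemically or in their biological
interactions — have similar toxicities.  Nothing global is estimated; a
fresh local model is fitted for every query from its neighbors, which makes
the approach applicable to heterogeneous datasets containing several modes
of action, at the price of refusing predictions for queries without
neighbors.

Endpoints are modelled on log2 scale throughout.  Raw-scale endpoint input
is converted exactly once at import (values ≤ 0 are rejected with the
offending substance named); whether a source file is already log2-scaled is
declared in the dataset schema, since it cannot be inferred reliably from
the numbers themselves.

### Representations

* **Composite fingerprints (MP2D class).**  Every heavy atom of a molecule
  contributes one atom-environment key: its own type plus the sorted types
  at topological distances 1 and 2 (hydrogens suppressed).  Atom type is the
  element symbol, lowercased for aromatic atoms — the simplest typing that
  separates aromatic from aliphatic chemistry and is reproducible from
  SMILES alone; equivalence with any particular toolkit's atom typing is not
  claimed, only self-consistency (key sets are invariant to atom input order
  by construction).  A nanoparticle's fingerprint is the set union over its
  core and coating compounds.  A bare metal core ([Au], [Ag]) contributes a
  single-atom key, intentionally separating particle families.  Fingerprints
  are binary; no feature selection is applied to them (filtering binary
  environment keys degrades fingerprint read-across).
* **Quantitative descriptors (P-CHEM / Proteomics / combined).**  Features
  are filtered per endpoint: Pearson correlation over pairwise-complete
  training observations, keep p < alpha (default 0.05).  No multiple-testing
  correction is applied — a deliberately liberal filter; with ~200 noise
  features, ~10 spurious ones are retained, which the downweighting by |r|
  and the local models tolerate.  The retained features' training means and
  standard deviations are frozen for scaling, so later queries and CV test
  folds never contribute to scaling statistics.

### Similarity and neighbors

Binary: Tanimoto index, neighbor threshold 0.1.  Quantitative: weighted
cosine of scaled/centered relevant-feature vectors with weights w_f = |r_f|,
threshold 0.5.  The absolute correlation is used because signed weights make
the weighted norms ill-defined; the measure is invariant to rescaling the
weight vector.  Only features measured on both substances contribute; a pair
with fewer than 2 shared features (or a zero-norm restricted vector) is
*incomparable* rather than imputed, and feeds the applicability domain.
Negative cosines are kept but always fall below the 0.5 threshold.

Training particles identical to the query — equal fingerprint, or equal
descriptor vector (same missing pattern, values equal to numerical
precision, rtol 1e-9) — are eliminated from the neighbor set, so duplicated
particles cannot leak their own measurement into the prediction.  Neighbors
are sorted by descending similarity with ties broken by substance id, making
predictions independent of training-row order.

### Local models

Per-sample weights are the similarities.  Defaults:

| parameter | default | meaning |
|---|---|---|
| alpha | 0.05 | feature-selection significance threshold |
| binary / quantitative threshold | 0.1 / 0.5 | neighbor similarity cutoffs |
| min_neighbors | 1 (WA), 5 (PLS/RF) | below: WA fallback |
| bootstrap_reps | 25 | PLS tuning/RMSE resamples |
| rf_trees | 50 | trees per forest |
| max_pls_components | 5 | PLS tuning grid upper bound |
| pi_z | 1.96 | 95% interval multiplier |

* **WA** needs one neighbor, performs no internal validation and therefore
  reports no interval.
* **PLS** tunes the number of components (1 … min(5, p, n−2)) on 25
  bootstrap resamples shared across candidates, scoring by out-of-bootstrap
  RMSE.  scikit-learn's PLS has no sample weights, so weighting uses the
  standard row-scaling reduction: center at the weighted means, scale rows
  by √w, fit, then apply the coefficient map to the raw centered query with
  the weighted mean as intercept.  On noise-free linear data this recovers
  the generating function exactly (property-tested).
* **RF** tunes the variables-per-split grid {2, (p+2)/2, p} and takes its
  resampled RMSE from the forest's out-of-bag predictions — each tree is
  already grown on a bootstrap resample, so OOB error *is* the bootstrap
  error estimate, at one fit per candidate instead of an explicit
  resampling loop.  Missing cells in the local design matrix are filled with
  0 (the training mean in scaled space) for the fit only; missingness has
  already been accounted for by the similarity stage.

The 95% prediction interval is ŷ ± 1.96·RMSE with the tuned configuration's
resampled RMSE.  Any failure — fewer than min_neighbors, constant neighbor
activities, empty design matrix, non-finite tuning RMSE, exceptions during
fit or predict — resolves to a WA fallback with an explanatory warning,
never a crash; such records carry no interval.

### Applicability domain

A query is refused (record with no value, warnings only) when it lacks the
representation (no parseable structures for MP2D; fewer than two measured
relevant features for quantitative classes) or has no neighbors above the
threshold.  Every returned prediction includes the neighbor ids and
similarities as its inspectable rationale.

## Validation protocol

5 repeats of 10-fold crossvalidation with fresh random partitions per
repeat.  Feature selection and scaling are recomputed inside every fold on
its training 9/10; by default no seed is fixed, so the spread across repeats
estimates split-induced variability (a seed can be supplied for
reproducibility in tests and scripted runs).  A diagnostic
`leak_feature_selection` switch performs selection once on the full data —
it exists only to demonstrate the optimism this causes (on a pure-noise
endpoint it inflates mean CV r² from ≈0.00 to ≈0.13 in the test suite) and
is never a default.

Metrics per run: RMSE; r² defined as the squared Pearson correlation of
predictions with measurements (the convention this model family reports —
note it is location/scale-invariant; a 1−SSE/SST coefficient of
determination is emitted alongside for comparison); and the percentage of
measurements inside the 95% interval.  Substances without predictions are
excluded from the metrics but counted and reported — dropping them silently
would inflate apparent performance.  WA-fallback records have no interval
and are excluded from coverage, also counted.  Experiments are compared by
one-way ANOVA over per-run values and Tukey HSD (family-wise 0.05); for
"interval correctness" the compared quantity is |coverage − 95|.  Identical
groups short-circuit to F = 0, p = 1 rather than a 0/0 NaN.

## Synthetic data generator

The generator emulates the statistical shape of a ~120-particle gold/silver
corona dataset: metal core plus 1–2 small organic coatings (thiols, acids,
amines — 16-compound pool), 20 P-CHEM features of which 8 carry signal, 200
proteomics features in 10 blocks of 20 (within-block correlation 0.7, first
block tied to the endpoint), 5% missing cells, endpoint noise sd 1.0 in log2
units.

Two deliberate realism choices: the signal features share a latent factor
(pairwise correlation 0.5) and their effect weights are all positive
(0.48–0.60).  Measured particle properties are strongly inter-correlated in
reality (the hydrodynamic-diameter family, surface area, zeta potential),
and this correlation is what gives the quantitative similarity its neighbor
structure — with isotropic independent features, cosine similarities
concentrate near zero in ~9 selected dimensions and almost no pair exceeds
the 0.5 threshold, a regime the method is explicitly not designed for.
Structure (core identity) enters the endpoint only through a ±1.0 core
effect, so fingerprint models are close to uninformative on synthetic data;
this is a property of the generator, not of the fingerprint method, and the
fingerprint machinery is validated through its own invariance and oracle
tests instead.

What passing tests on this generator do **not** show: behaviour under
systematic measurement bias, non-Gaussian or heteroscedastic endpoint noise,
assay-specific artefacts (ICP-AES, DLS), or real corona composition
patterns.  Results on the synthetic benchmark characterize the machinery,
not any laboratory dataset.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the full 5×10 CV protocol at
n = 120 (the design scale of the method); the noise-robustness sweep uses 2
repeats per noise level and the CLI smoke tests use 40–60 substances.  All
randomness flows from explicit seeds (`numpy.random.default_rng`); RF tree
seeds derive from the per-prediction generator, so predictions are
reproducible given (data, config, seed) and invariant to training-row order.

## Known limitations

* The Pearson filter sees only linear marginal associations; a feature
  relevant purely through interactions will be dropped.
* |r| weighting discards the correlation sign; two features with opposite
  effects contribute symmetrically to similarity.
* OOB/bootstrap RMSE is a local, model-internal error estimate; intervals
  are approximate and their empirical coverage (92–97% across synthetic
  experiments) should be monitored per dataset.
* With wide correlated blocks the liberal filter admits correlated spurious
  features; the no-leakage protocol measures, but does not remove, the
  resulting variance.
* Exact-duplicate elimination uses numerical identity; near-duplicates
  (e.g. re-measured particles) are legitimately retained as neighbors.
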