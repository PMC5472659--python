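# nanoreadacross

Read-across predictions of quantitative nanoparticle toxicity endpoints.

Most nanoparticles have no single well-defined chemical structure, so the
structural similarity measures of classical QSAR do not apply directly.  This
package predicts a continuous toxicity endpoint (e.g. net cell association of
gold/silver particles with A549 cells, log2 scale) for a query particle by

1. representing each particle either **structurally** — the union of
   atom-environment (MOLPRINT-2D-style) fingerprints of its core and coating
   compounds — or **quantitatively**, through measured physico-chemical
   (P-CHEM) or serum-protein interaction (Proteomics) descriptors;
2. finding **neighbors**: training particles whose similarity to the query
   exceeds a threshold (Tanimoto > 0.1 for binary fingerprints;
   correlation-weighted cosine > 0.5 for quantitative descriptors);
3. fitting a **local model** on those neighbors only — a similarity-weighted
   average (WA), weighted partial least squares (PLS) or weighted random
   forest (RF) — and predicting the query with a 95% prediction interval.

It is aimed at computational toxicologists who want automated, inspectable
and *validatable* read-across: every prediction carries its neighbor list and
similarities, queries without neighbors are explicitly refused (applicability
domain), and the crossvalidation protocol keeps feature selection strictly
inside each fold.

## Method

For quantitative descriptors, *activity-specific similarity* is used: only
features whose Pearson correlation with the endpoint is significant
(p < 0.05 over the training substances) enter the similarity.  For two
scaled, centered feature vectors x, y the similarity is the weighted cosine

    sim(x, y) = Σ_f w_f x_f y_f / ( √(Σ_f w_f x_f²) · √(Σ_f w_f y_f²) ),
    w_f = |r_f|,

computed over the features measured on both substances.  For binary
fingerprints it is the Tanimoto index |A∩B| / |A∪B|.  Particles identical to
the query are eliminated from the neighbor set, so duplicates cannot predict
themselves.

Given neighbors i with similarities s_i and activities y_i, the local models
are

* **WA**: ŷ = Σ s_i y_i / Σ s_i (benchmark; no prediction interval),
* **PLS / RF**: fitted on the neighbor descriptor matrix with per-sample
  weights s_i; the single hyperparameter (PLS components / RF variables per
  split) is tuned by bootstrap resampling and the selected configuration's
  out-of-bootstrap RMSE gives the 95% prediction interval ŷ ± 1.96·RMSE.
  On any failure (too few neighbors, constant activities, numerical error)
  the model falls back to WA with a warning.

Validation is 5 repeated 10-fold crossvalidations with independent random
splits; feature selection and scaling are recomputed per fold on the training
part only.  Experiments (descriptor class × algorithm) are compared by
one-way ANOVA followed by Tukey HSD on per-run RMSE, r² (squared Pearson
correlation) and interval coverage.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Hold out ten particles of a synthetic 120-particle dataset and predict them
from measured properties with local random forests:

```python
import numpy as np
from nanoreadacross import SyntheticConfig, generate_dataset, build_model, predict

dataset, truth = generate_dataset(SyntheticConfig(seed=7))
train = dataset.subset(dataset.ids[:110])
queries = [dataset.substance(i) for i in dataset.ids[110:]]

bundle = build_model(train, "net_cell_association", "P-CHEM", algorithm="RF")
print(f"relevant features: {len(bundle.relevant)} of "
      f"{len(train.features_for_class('P-CHEM'))}")
rng = np.random.default_rng(0)
for q in queries[:4]:
    rec = predict(bundle, q, rng=rng)
    measured = q.endpoints["net_cell_association"]
    print(f"{q.id}: predicted {rec.value:+.2f} "
          f"[{rec.interval_low:+.2f}, {rec.interval_high:+.2f}] "
          f"measured {measured:+.2f} "
          f"({len(rec.neighbors)} neighbors, {rec.algorithm_used})")
```

prints

```
relevant features: 9 of 20
G111.SA@MPA: predicted +1.97 [-0.51, +4.44] measured +5.01 (23 neighbors, RF)
G112.CIT: predicted +3.96 [+1.20, +6.73] measured +4.35 (21 neighbors, RF)
G113.MES@AUT: predicted +5.35 [+2.33, +8.38] measured +6.06 (26 neighbors, RF)
S114.HDA: predicted +0.99 [-2.46, +4.45] measured +0.18 (6 neighbors, RF)
```

Endpoint-specific filtering kept 9 of 20 measured properties.  Each
prediction is a log2 endpoint value with its 95% interval and the neighbors
it was read across from; three of the four measurements fall inside their
interval, and the first query shows the expected behaviour of a hard case —
its interval is the evidence a reviewing toxicologist would use to reject or
accept the extrapolation.

The same workflow is available from the shell:

```sh
nanoreadacross simulate --n 120 --seed 7 --out particles.csv
nanoreadacross crossvalidate --dataset particles.csv --descriptor-class P-CHEM \
    --algorithm RF --seed 1 --out cv_rf
nanoreadacross crossvalidate --dataset particles.csv --descriptor-class P-CHEM \
    --algorithm WA --seed 1 --out cv_wa
nanoreadacross compare cv_rf/cv_runs.csv cv_wa/cv_runs.csv --metric rmse
```

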