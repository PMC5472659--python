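"""Repeated crossvalidation without feature-selection leakage, and model comparison.

Validation uses repeated k-fold crossvalidation (default 5 repeats of 10
folds) with independent random training/test splits per repeat.  Feature
selection and scaling statistics are recomputed for every fold on its
training 9/10 exclusively — selecting features on the full dataset before
splitting leaks test information into the model and inflates apparent
performance.  A ``leak_feature_selection`` switch exists solely so tests can
demonstrate that the guard matters; it is never the default.

Per run we report RMSE, r² (squared Pearson correlation of predictions with
measurements; a coefficient-of-determination column is also provided) and the
percentage of measurements inside the 95% prediction interval.  Substances
that receive no prediction (outside the applicability domain) are excluded
from the metrics but counted and reported.  Experiments are compared by
one-way ANOVA over per-run metric values followed by Tukey HSD pairwise
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datamodel import Dataset, DescriptorClass, PredictionRecord
from .feature_selection import select_relevant_features
from .local_models import LocalModelConfig, build_model, predict

__all__ = [
    "CVRun",
    "ComparisonReport",
    "rmse",
    "r_squared",
    "pi_coverage",
    "repeated_kfold_cv",
    "cv_runs_frame",
    "compare_experiments",
]


def rmse(pred: Sequence[float], meas: Sequence[float]) -> float:
    """Root mean squared error of predictions against measurements."""
    p = np.asarray(pred, dtype=float)
    m = np.asarray(meas, dtype=float)
    if p.shape != m.shape or p.size == 0:
        raise ValueError("pred and meas must be nonempty and of equal length")
    return float(np.sqrt(np.mean((p - m) ** 2)))


def r_squared(pred: Sequence[float], meas: Sequence[float]) -> float | None:
    """Squared Pearson correlation between predictions and measurements.

    Returns None (undefined) when fewer than 3 pairs or either vector is
    constant.  Note this is explained-correlation, not 1 - SSE/SST; see
    :func:`coefficient_of_determination` for the latter.
    """
    p = np.asarray(pred, dtype=float)
    m = np.asarray(meas, dtype=float)
    if p.shape != m.shape:
        raise ValueError("pred and meas must have equal length")
    if p.size < 3 or np.ptp(p) == 0 or np.ptp(m) == 0:
        return None
    r = sstats.pearsonr(p, m).statistic
    return float(r * r)


def coefficient_of_determination(pred: Sequence[float], meas: Sequence[float]) -> float:
    """1 - SSE/SST; the alternate r² definition, offered for comparison."""
    p = np.asarray(pred, dtype=float)
    m = np.asarray(meas, dtype=float)
    sst = float(np.sum((m - m.mean()) ** 2))
    if sst == 0:
        raise ValueError("measurements are constant")
    return 1.0 - float(np.sum((p - m) ** 2)) / sst


def pi_coverage(records: Sequence[PredictionRecord], meas: Mapping[str, float]) -> float:
    """Percentage of measurements falling within the 95% prediction interval."""
    if not records:
        raise ValueError("no records")
    inside = 0
    for rec in records:
        if not rec.has_interval:
            raise ValueError(f"record {rec.query_id!r} has no prediction interval")
        if rec.interval_low <= meas[rec.query_id] <= rec.interval_high:
            inside += 1
    return 100.0 * inside / len(records)


@dataclass
class CVRun:
    """One repeat of a k-fold crossvalidation for one descriptor/algorithm pair."""

    descriptor_class: str
    algorithm: str
    repeat_index: int
    fold_assignments: dict[str, int]
    predictions: list[PredictionRecord]
    rmse: float | None
    r2: float | None
    r2_determination: float | None
    pi_coverage: float | None  # None for WA (and when every record fell back)
    n_predicted: int
    n_out_of_domain: int
    n_with_interval: int


def _partition(ids: list[str], k: int, rng: np.random.Generator) -> dict[str, int]:
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, k)
    assignment = {}
    for f, idxs in enumerate(folds):
        for i in idxs:
            assignment[ids[int(i)]] = f
    return assignment


def repeated_kfold_cv(
    dataset: Dataset,
    endpoint: str,
    descriptor_class: str,
    algorithm: str,
    k: int = 10,
    repeats: int = 5,
    seed: int | None = None,
    alpha: float = 0.05,
    sim_threshold: float | None = None,
    model_config: LocalModelConfig | None = None,
    leak_feature_selection: bool = False,
) -> list[CVRun]:
    """Repeated k-fold crossvalidation with fold-wise feature selection.

    For each repeat, the substances with the endpoint measured are randomly
    partitioned into ``k`` near-equal folds.  For each fold, feature
    selection and scaling (quantitative classes) are computed on the training
    part only, then every test substance is predicted with the local-model
    workflow.  Metrics are computed over substances that received a numeric
    prediction; out-of-domain substances are counted separately.

    ``seed`` controls fold assignment and all model resampling; by default no
    seed is fixed, so repeats estimate the split-induced variability.
    ``leak_feature_selection=True`` deliberately performs feature selection
    once on the full dataset (test folds included) — a diagnostic mode that
    exists to demonstrate the resulting optimism, never for real validation.
    """
    measured = [s.id for s in dataset.substances if endpoint in s.endpoints]
    if not measured:
        raise ValueError(f"endpoint {endpoint!r} has no measured substances")
    if k > len(measured):
        raise ValueError(f"k={k} exceeds the {len(measured)} substances with {endpoint!r}")

    rng = np.random.default_rng(seed)
    leaky_relevant = None
    if leak_feature_selection and descriptor_class != DescriptorClass.MP2D:
        leaky_relevant = select_relevant_features(
            dataset,
            endpoint,
            alpha=alpha,
            features=dataset.features_for_class(descriptor_class),
        )

    runs: list[CVRun] = []
    for rep in range(repeats):
        assignment = _partition(measured, k, rng)
        records: list[PredictionRecord] = []
        for fold in range(k):
            test_ids = [i for i in measured if assignment[i] == fold]
            train_ids = [i for i in measured if assignment[i] != fold]
            training = dataset.subset(train_ids)
            bundle = build_model(
                training,
                endpoint,
                descriptor_class,
                algorithm=algorithm,
                alpha=alpha,
                sim_threshold=sim_threshold,
                model_config=model_config,
                relevant=leaky_relevant,
            )
            for sid in test_ids:
                records.append(predict(bundle, dataset.substance(sid), rng=rng))

        meas = {s.id: s.endpoints[endpoint] for s in dataset.substances if endpoint in s.endpoints}
        predicted = [r for r in records if r.value is not None]
        with_pi = [r for r in predicted if r.has_interval]
        if predicted:
            p = [r.value for r in predicted]
            m = [meas[r.query_id] for r in predicted]
            run_rmse = rmse(p, m)
            run_r2 = r_squared(p, m)
            run_det = coefficient_of_determination(p, m) if np.ptp(m) > 0 else None
        else:
            run_rmse = run_r2 = run_det = None
        coverage = (
            pi_coverage(with_pi, meas) if (algorithm != "WA" and with_pi) else None
        )
        runs.append(
            CVRun(
                descriptor_class=descriptor_class,
                algorithm=algorithm,
                repeat_index=rep,
                fold_assignments=assignment,
                predictions=records,
                rmse=run_rmse,
                r2=run_r2,
                r2_determination=run_det,
                pi_coverage=coverage,
                n_predicted=len(predicted),
                n_out_of_domain=len(records) - len(predicted),
                n_with_interval=len(with_pi),
            )
        )
    return runs


def cv_runs_frame(runs: Sequence[CVRun]) -> pd.DataFrame:
    """Tidy per-repeat metric table (one row per repeat x experiment)."""
    return pd.DataFrame(
        {
            "descriptors": [r.descriptor_class for r in runs],
            "algorithm": [r.algorithm for r in runs],
            "repeat": [r.repeat_index for r in runs],
            "rmse": [r.rmse for r in runs],
            "r2": [r.r2 for r in runs],
            "r2_determination": [r.r2_determination for r in runs],
            "pi_coverage": [r.pi_coverage for r in runs],
            "n_predicted": [r.n_predicted for r in runs],
            "n_out_of_domain": [r.n_out_of_domain for r in runs],
            "n_with_interval": [r.n_with_interval for r in runs],
        }
    )


@dataclass
class ComparisonReport:
    """ANOVA + Tukey HSD comparison of per-run metric values across experiments."""

    metric: str
    groups: list[str]
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, significant
    group_means: dict[str, float] = field(default_factory=dict)

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [
            (row.group1, row.group2)
            for row in self.tukey.itertuples()
            if row.significant
        ]

    def to_text(self) -> str:
        lines = [
            f"metric: {self.metric}",
            f"ANOVA: F = {self.anova_f:.4g}, p = {self.anova_p:.4g}",
            "group means: "
            + ", ".join(f"{g}={v:.4g}" for g, v in self.group_means.items()),
            "Tukey HSD pairwise comparisons (alpha = 0.05):",
        ]
        for row in self.tukey.itertuples():
            flag = "*" if row.significant else " "
            lines.append(
                f"  {flag} {row.group1} vs {row.group2}: "
                f"diff = {row.meandiff:+.4g}, p_adj = {row.p_adj:.4g}"
            )
        return "\n".join(lines)


def compare_experiments(
    values_by_group: Mapping[str, Sequence[float]],
    metric: str = "metric",
    alpha: float = 0.05,
) -> ComparisonReport:
    """One-way ANOVA and Tukey HSD over per-run metric values.

    ``values_by_group`` maps an experiment label (e.g. "P-CHEM/RF") to its
    per-repeat metric values.  At least two groups with two runs each are
    required.  Identical groups (zero between-group variance) yield F = 0,
    p = 1 and no significant pairs.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two experiment groups to compare")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 runs")

    labels = list(groups)
    arrays = [groups[g] for g in labels]
    grand = np.concatenate(arrays)
    group_means = {g: float(v.mean()) for g, v in groups.items()}

    between = sum(v.size * (v.mean() - grand.mean()) ** 2 for v in arrays)
    if between == 0 or np.ptp(grand) == 0:
        f_stat, p_val = 0.0, 1.0
    else:
        res = sstats.f_oneway(*arrays)
        f_stat, p_val = float(res.statistic), float(res.pvalue)

    data = np.concatenate(arrays)
    tags = np.concatenate([[g] * groups[g].size for g in labels])
    if np.ptp(data) == 0:
        pairs = [
            (labels[i], labels[j], 0.0, 1.0, False)
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        tukey_df = pd.DataFrame(
            pairs, columns=["group1", "group2", "meandiff", "p_adj", "significant"]
        )
    else:
        res = pairwise_tukeyhsd(data, tags, alpha=alpha)
        # rebuild the summary table from result attributes
        i1, i2 = res._multicomp.pairindices
        g1 = [res.groupsunique[i] for i in i1]
        g2 = [res.groupsunique[i] for i in i2]
        tukey_df = pd.DataFrame(
            {
                "group1": [str(g) for g in g1],
                "group2": [str(g) for g in g2],
                "meandiff": res.meandiffs,
                "p_adj": res.pvalues,
                "significant": res.reject,
            }
        )
    return ComparisonReport(
        metric=metric,
        groups=labels,
        anova_f=f_stat,
        anova_p=p_val,
        tukey=tukey_df,
        group_means=group_means,
    )


def metric_values(runs: Sequence[CVRun], metric: str) -> list[float]:
    """Extract per-run values for a metric name used in comparisons.

    ``pi_error`` is the absolute deviation of interval coverage from the
    nominal 95% — the operationalization of "correct 95% prediction interval".
    """
    if metric == "rmse":
        vals = [r.rmse for r in runs]
    elif metric == "r2":
        vals = [r.r2 for r in runs]
    elif metric == "pi_coverage":
        vals = [r.pi_coverage for r in runs]
    elif metric == "pi_error":
        vals = [abs(r.pi_coverage - 95.0) if r.pi_coverage is not None else None for r in runs]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return [v for v in vals if v is not None]
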