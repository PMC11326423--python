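"""Agreement statistics and method-comparison machinery.

Predicted composite IHI scores are compared to manual ones with intraclass
correlations; per-criterion predictions with Cohen's kappa (quadratically
weighted for the 0.5-step criteria C1-C3, unweighted for C5, whose scale
is not treated as ordinal).  Uncertainty comes from a subject-level
bootstrap (100 redraws with replacement by default); two methods are
compared by differencing the metric on the *same* bootstrap replicates and
feeding the replicate differences into a Student's t-test, Bonferroni
corrected across the hypothesis family.

The ICC and kappa kernels are implemented here from the ANOVA mean-squares
decomposition and the contingency-table closed form; both are vectorized
over bootstrap replicates, and the test suite checks them against
independent brute-force computations and against the reference
implementations in pingouin and scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ratings import IHI_THRESHOLD, Criterion, criterion_grid

__all__ = [
    "UndefinedMetricError",
    "icc",
    "cohen_kappa",
    "MetricResult",
    "bootstrap_metric",
    "ComparisonResult",
    "compare_methods",
    "MetricReport",
    "evaluate_run",
    "icc_metric",
    "kappa_metric",
]


class UndefinedMetricError(ValueError):
    """Raised when an agreement statistic is undefined on the given data."""


def _icc_batch(a: np.ndarray, b: np.ndarray, variant: str) -> np.ndarray:
    """ICC over paired ratings; batched over leading axes.

    ``a`` and ``b`` have shape (..., n); returns shape (...) with NaN where
    the statistic is undefined (no between- or within-subject variance).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"paired ratings must share a shape: {a.shape} vs {b.shape}")
    n = a.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    k = 2  # two raters/methods
    data = np.stack([a, b], axis=-1)  # (..., n, k)
    grand = data.mean(axis=(-1, -2), keepdims=True)
    row_means = data.mean(axis=-1, keepdims=True)  # per subject
    col_means = data.mean(axis=-2, keepdims=True)  # per rater
    ss_total = ((data - grand) ** 2).sum(axis=(-1, -2))
    ss_rows = k * ((row_means - grand) ** 2).sum(axis=(-1, -2))
    ss_cols = n * ((col_means - grand) ** 2).sum(axis=(-1, -2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "icc2":
            denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        elif variant == "icc3":
            denom = msr + (k - 1) * mse
        else:
            raise ValueError(f"unknown ICC variant {variant!r}; use 'icc2' or 'icc3'")
        out = (msr - mse) / denom
    return np.where(np.abs(denom) < 1e-300, np.nan, out)


def icc(
    ratings_a: Sequence[float],
    ratings_b: Sequence[float],
    variant: str = "icc2",
) -> float:
    """Intraclass correlation between two paired rating vectors.

    The default ``icc2`` is the two-way random-effects, single-rater,
    absolute-agreement coefficient ICC(2,1) — the natural choice when the
    question is whether single automatic ratings can replace single manual
    ones, systematic offsets included.  ``icc3`` gives the consistency
    variant ICC(3,1), insensitive to a constant shift between methods.
    """
    a = np.asarray(ratings_a, dtype=np.float64)
    b = np.asarray(ratings_b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("ratings must be 1D vectors")
    if len(a) < 5:
        raise ValueError("need at least 5 paired ratings for a stable ICC")
    value = float(_icc_batch(a, b, variant))
    if np.isnan(value):
        raise UndefinedMetricError("ICC undefined: no rating variance")
    return value


def _to_category_indices(values: np.ndarray, categories: np.ndarray) -> np.ndarray:
    idx = np.abs(values[:, None] - categories[None, :]).argmin(axis=1)
    if not np.allclose(values, categories[idx], atol=1e-9):
        offgrid = values[~np.isclose(values, categories[idx], atol=1e-9)]
        raise ValueError(
            f"ratings not on the declared category grid {categories.tolist()}: "
            f"e.g. {offgrid[:3].tolist()} — round predictions first"
        )
    return idx


def cohen_kappa(
    a: Sequence[float],
    b: Sequence[float],
    weighting: str = "none",
    categories: Sequence[float] | None = None,
) -> float:
    """Cohen's kappa over a declared finite category grid.

    kappa = 1 - sum(w * O) / sum(w * E) with observed table O, chance table
    E from the marginal products, and disagreement weights w_ij = 1 - delta
    (unweighted) or (i - j)^2 / (k - 1)^2 (quadratic).  Categories are
    declared rather than inferred so that unobserved grid points still
    weight correctly.
    """
    if categories is None:
        raise ValueError("declare the category grid explicitly")
    cats = np.asarray(sorted(set(float(c) for c in categories)))
    if len(cats) < 2:
        raise ValueError("need at least two categories")
    va = np.asarray(a, dtype=np.float64)
    vb = np.asarray(b, dtype=np.float64)
    if va.shape != vb.shape or va.ndim != 1 or len(va) == 0:
        raise ValueError("paired non-empty 1D rating vectors required")
    ia = _to_category_indices(va, cats)
    ib = _to_category_indices(vb, cats)
    m = len(cats)
    observed = np.zeros((m, m))
    np.add.at(observed, (ia, ib), 1.0)
    observed /= len(va)
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    grid = np.arange(m)
    if weighting == "none":
        w = (grid[:, None] != grid[None, :]).astype(float)
    elif weighting == "quadratic":
        w = ((grid[:, None] - grid[None, :]) ** 2) / (m - 1) ** 2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    denom = float((w * expected).sum())
    if denom <= 0:
        raise UndefinedMetricError(
            "kappa undefined: both raters degenerate on a single category"
        )
    return 1.0 - float((w * observed).sum()) / denom


def icc_metric(variant: str = "icc2") -> Callable[[np.ndarray, np.ndarray], float]:
    """Metric function (truth, pred) -> ICC for use with the bootstrap."""

    def metric(truth: np.ndarray, pred: np.ndarray) -> float:
        value = float(_icc_batch(np.asarray(truth, float), np.asarray(pred, float), variant))
        if np.isnan(value):
            raise UndefinedMetricError("ICC undefined on replicate")
        return value

    metric.__name__ = variant
    return metric


def kappa_metric(criterion: Criterion) -> Callable[[np.ndarray, np.ndarray], float]:
    """Quadratic kappa for C1-C3, unweighted for C5, on the criterion grid."""
    weighting = "none" if criterion is Criterion.C5 else "quadratic"
    cats = criterion_grid(criterion)

    def metric(truth: np.ndarray, pred: np.ndarray) -> float:
        return cohen_kappa(truth, pred, weighting=weighting, categories=cats)

    metric.__name__ = f"kappa_{criterion.value}"
    return metric


@dataclass
class MetricResult:
    """Point estimate with bootstrap uncertainty."""

    metric: str
    point: float
    boot_mean: float
    boot_se: float
    ci_lower: float
    ci_upper: float
    n: int
    n_boot: int
    seed: int
    replicates: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    indices: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _bootstrap_indices(n: int, n_boot: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(n_boot, n))


def _metric_over_replicates(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    truth: np.ndarray,
    pred: np.ndarray,
    indices: np.ndarray,
) -> np.ndarray:
    values = np.empty(len(indices))
    for b, idx in enumerate(indices):
        try:
            values[b] = metric_fn(truth[idx], pred[idx])
        except UndefinedMetricError:
            values[b] = np.nan
    return values


def bootstrap_metric(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    truth: Sequence[float],
    predictions: Sequence[float],
    n_boot: int = 100,
    seed: int = 0,
) -> MetricResult:
    """Subject-level bootstrap of an agreement metric.

    Each replicate redraws N subjects with replacement and recomputes the
    metric on the redrawn (truth, prediction) pairs.  The replicate index
    sets are retained so paired method comparisons can reuse them.
    """
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(predictions, dtype=np.float64)
    if truth.shape != pred.shape or truth.ndim != 1 or len(truth) < 2:
        raise ValueError("paired vectors with at least 2 subjects required")
    indices = _bootstrap_indices(len(truth), n_boot, seed)
    reps = _metric_over_replicates(metric_fn, truth, pred, indices)
    n_bad = int(np.isnan(reps).sum())
    if n_bad > n_boot / 2:
        raise UndefinedMetricError(
            f"metric undefined on {n_bad}/{n_boot} bootstrap replicates"
        )
    good = reps[~np.isnan(reps)]
    lo, hi = np.percentile(good, [2.5, 97.5])
    return MetricResult(
        metric=getattr(metric_fn, "__name__", "metric"),
        point=float(metric_fn(truth, pred)),
        boot_mean=float(good.mean()),
        boot_se=float(good.std(ddof=1)) if len(good) > 1 else 0.0,
        ci_lower=float(lo),
        ci_upper=float(hi),
        n=len(truth),
        n_boot=n_boot,
        seed=seed,
        replicates=reps,
        indices=indices,
    )


@dataclass
class ComparisonResult:
    """Paired-bootstrap comparison of two methods on one metric."""

    label_a: str
    label_b: str
    metric: str
    differences: np.ndarray = field(repr=False)
    mean_difference: float = 0.0
    se_difference: float = 0.0
    t: float = 0.0
    p: float = 1.0
    p_adjusted: float = 1.0
    m_tests: int = 1
    significant: bool = False


def compare_methods(
    truth: Sequence[float],
    preds_a: Sequence[float],
    preds_b: Sequence[float],
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int = 100,
    seed: int = 0,
    m_tests: int = 1,
    label_a: str = "A",
    label_b: str = "B",
) -> ComparisonResult:
    """Bootstrap the metric difference between two methods and t-test it.

    Both methods are evaluated on bitwise-identical resampled index sets,
    so the replicate differences isolate the method effect from sampling.
    The replicate standard deviation is the bootstrap standard error of
    the difference; t = mean / SE with n_boot - 1 degrees of freedom,
    two-sided, Bonferroni-corrected over ``m_tests`` simultaneous tests.
    """
    truth = np.asarray(truth, dtype=np.float64)
    pa = np.asarray(preds_a, dtype=np.float64)
    pb = np.asarray(preds_b, dtype=np.float64)
    if not (truth.shape == pa.shape == pb.shape):
        raise ValueError("truth and both prediction vectors must be aligned")
    indices = _bootstrap_indices(len(truth), n_boot, seed)
    reps_a = _metric_over_replicates(metric_fn, truth, pa, indices)
    reps_b = _metric_over_replicates(metric_fn, truth, pb, indices)
    d = reps_a - reps_b
    good = d[~np.isnan(d)]
    if len(good) < 2:
        raise UndefinedMetricError("too few defined replicates to compare methods")
    mean_d = float(good.mean())
    se_d = float(good.std(ddof=1))
    if se_d == 0.0:
        t_stat, p = (0.0, 1.0)
    else:
        t_stat = mean_d / se_d
        p = 2.0 * float(stats.t.sf(abs(t_stat), df=n_boot - 1))
    p_adj = min(1.0, m_tests * p)
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        metric=getattr(metric_fn, "__name__", "metric"),
        differences=d,
        mean_difference=mean_d,
        se_difference=se_d,
        t=t_stat,
        p=p,
        p_adjusted=p_adj,
        m_tests=m_tests,
        significant=bool(p_adj < 0.05),
    )


@dataclass
class MetricReport:
    """Tabular report: one row per hemisphere x group x metric."""

    rows: pd.DataFrame
    confusion: pd.DataFrame
    n_boot: int
    seed: int
    icc_variant: str

    def to_json_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "seed": self.seed,
            "icc_variant": self.icc_variant,
            "metrics": self.rows.to_dict(orient="records"),
            "confusion": self.confusion.to_dict(orient="records"),
        }


_CRIT_COLUMNS = {Criterion.C1: "c1", Criterion.C2: "c2", Criterion.C3: "c3", Criterion.C5: "c5"}


def _validate_on_grid(frame: pd.DataFrame) -> None:
    for criterion, col in _CRIT_COLUMNS.items():
        grid = np.asarray(criterion_grid(criterion))
        vals = frame[col].to_numpy(dtype=float)
        if not np.all(np.isclose(vals[:, None], grid[None, :], atol=1e-9).any(axis=1)):
            raise ValueError(
                f"prediction column {col!r} contains off-grid values; "
                "round predictions with ratings.round_prediction before evaluation"
            )


def evaluate_run(
    truth: pd.DataFrame,
    predictions: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
    icc_variant: str = "icc2",
) -> MetricReport:
    """Full agreement report of a prediction table against a truth table.

    Both tables use the ratings TSV dialect and are joined on
    (subject_id, hemisphere).  Predictions must already be rounded onto
    the criterion grids.  Per hemisphere and per group (pooled plus each
    cohort): composite ICC with bootstrap CI, per-criterion kappas with
    bootstrap CI, and IHI confusion counts at the composite threshold 4.
    """
    _validate_on_grid(predictions)
    merged = truth.merge(
        predictions,
        on=["subject_id", "hemisphere"],
        suffixes=("_true", "_pred"),
        validate="one_to_one",
    )
    if merged.empty:
        raise ValueError("truth and prediction tables share no (subject, hemisphere)")
    cohort_col = "cohort_true" if "cohort_true" in merged.columns else "cohort"

    rows = []
    confusion_rows = []
    for hemisphere in sorted(merged["hemisphere"].unique()):
        hemi = merged[merged["hemisphere"] == hemisphere]
        groups: list[tuple[str, pd.DataFrame]] = [("pooled", hemi)]
        cohorts = [c for c in hemi[cohort_col].dropna().unique()]
        if len(cohorts) > 1:
            groups += [(str(c), hemi[hemi[cohort_col] == c]) for c in sorted(cohorts)]
        for group_name, sub in groups:
            if len(sub) < 5:
                continue  # too small for stable agreement statistics
            truth_comp = sub["composite_true"].to_numpy(float)
            pred_comp = sub["composite_pred"].to_numpy(float)
            specs: list[tuple[str, Callable, np.ndarray, np.ndarray]] = [
                (
                    "icc_composite",
                    icc_metric(icc_variant),
                    truth_comp,
                    pred_comp,
                )
            ]
            for criterion, col in _CRIT_COLUMNS.items():
                specs.append(
                    (
                        f"kappa_{criterion.value}",
                        kappa_metric(criterion),
                        sub[f"{col}_true"].to_numpy(float),
                        sub[f"{col}_pred"].to_numpy(float),
                    )
                )
            for name, metric_fn, t_vec, p_vec in specs:
                try:
                    res = bootstrap_metric(metric_fn, t_vec, p_vec, n_boot=n_boot, seed=seed)
                except UndefinedMetricError:
                    continue
                rows.append(
                    {
                        "hemisphere": hemisphere,
                        "group": group_name,
                        "metric": name,
                        "point": res.point,
                        "boot_mean": res.boot_mean,
                        "boot_se": res.boot_se,
                        "ci_lower": res.ci_lower,
                        "ci_upper": res.ci_upper,
                        "n": res.n,
                    }
                )
            true_flag = truth_comp >= IHI_THRESHOLD
            pred_flag = pred_comp >= IHI_THRESHOLD
            confusion_rows.append(
                {
                    "hemisphere": hemisphere,
                    "group": group_name,
                    "tp": int(np.sum(true_flag & pred_flag)),
                    "fp": int(np.sum(~true_flag & pred_flag)),
                    "fn": int(np.sum(true_flag & ~pred_flag)),
                    "tn": int(np.sum(~true_flag & ~pred_flag)),
                }
            )
    return MetricReport(
        rows=pd.DataFrame(rows),
        confusion=pd.DataFrame(confusion_rows),
        n_boot=n_boot,
        seed=seed,
        icc_variant=icc_variant,
    )
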