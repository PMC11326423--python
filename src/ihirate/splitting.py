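"""Stratified train/validation/test split search.

A quarter of each cohort is isolated as a test set before any modelling;
the remainder is re-split 80/20 into training and validation.  Because a
single random draw can be unbalanced, many candidate splits are drawn
(200 by default) and the one minimizing distributional differences across
the stratification variables — all IHI criteria plus age, weight, height,
sex, handedness and imaging centre — is kept.  Numeric variables are
compared with the two-sample Kolmogorov-Smirnov statistic, categorical
ones with the total-variation distance between category proportions (a KS
test is not meaningful for unordered categories); candidate badness is the
worst variable by default.

Splitting operates on one row per *subject*: a subject's two hemispheres
always land in the same set, so no subject can leak across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SplitConfig",
    "SplitAssignment",
    "ks_statistic",
    "total_variation_distance",
    "split_sizes",
    "subject_table",
    "candidate_split",
    "split_badness",
    "select_stratified_split",
    "StrategyAssembly",
    "assemble_strategy",
]

#: Default stratification variables on the subject-level table.
DEFAULT_NUMERIC_VARS = (
    "c1_left", "c2_left", "c3_left", "c5_left",
    "c1_right", "c2_right", "c3_right", "c5_right",
    "age", "weight", "height",
)
DEFAULT_CATEGORICAL_VARS = ("sex", "handedness", "centre")


@dataclass(frozen=True)
class SplitConfig:
    test_fraction: float = 0.25
    val_fraction_of_remainder: float = 0.20
    n_candidates: int = 200
    numeric_vars: tuple[str, ...] = DEFAULT_NUMERIC_VARS
    categorical_vars: tuple[str, ...] = DEFAULT_CATEGORICAL_VARS
    aggregate: str = "max"  # "max" (worst variable) or "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.test_fraction, self.val_fraction_of_remainder):
            if not 0.0 < frac < 1.0:
                raise ValueError(f"fractions must lie in (0, 1), got {frac}")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.aggregate not in ("max", "mean"):
            raise ValueError("aggregate must be 'max' or 'mean'")


def ks_statistic(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (sup-distance of ECDFs)."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS statistic needs two non-empty samples")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def total_variation_distance(sample_a: Sequence, sample_b: Sequence) -> float:
    """Half the L1 distance between the category proportions of two samples."""
    a = pd.Series(list(sample_a))
    b = pd.Series(list(sample_b))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("total-variation distance needs two non-empty samples")
    pa = a.value_counts(normalize=True)
    pb = b.value_counts(normalize=True)
    cats = pa.index.union(pb.index)
    return float(
        0.5 * np.abs(pa.reindex(cats, fill_value=0.0) - pb.reindex(cats, fill_value=0.0)).sum()
    )


def split_sizes(n: int, cfg: SplitConfig | None = None) -> tuple[int, int, int]:
    """(n_train, n_val, n_test) under the floor-rounded fraction rules.

    Test first: floor(test_fraction * n); then validation takes
    floor(val_fraction * remainder); training keeps the rest.
    """
    cfg = cfg or SplitConfig()
    if n < 3:
        raise ValueError(f"cannot split {n} subjects into three non-empty sets")
    n_test = int(np.floor(cfg.test_fraction * n))
    n_val = int(np.floor(cfg.val_fraction_of_remainder * (n - n_test)))
    n_train = n - n_test - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"degenerate split sizes (train={n_train}, val={n_val}, test={n_test}) "
            f"for n={n}"
        )
    return n_train, n_val, n_test


def subject_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-hemisphere ratings table to one row per subject.

    Criterion columns become ``c*_left`` / ``c*_right``; covariates are
    taken from the first row of each subject.
    """
    crit_cols = ["c1", "c2", "c3", "c5"]
    wide = ratings.pivot_table(
        index="subject_id", columns="hemisphere", values=crit_cols, aggfunc="first"
    )
    wide.columns = [f"{col}_{hemi}" for col, hemi in wide.columns]
    covar_cols = [
        c
        for c in ("age", "sex", "weight", "height", "handedness", "centre", "cohort")
        if c in ratings.columns
    ]
    covars = ratings.groupby("subject_id")[covar_cols].first()
    return wide.join(covars).reset_index()


@dataclass
class SplitAssignment:
    """subject_id -> {train, validation, test} with selection diagnostics."""

    assignment: dict[str, str]
    badness: dict[str, float] = field(default_factory=dict)
    aggregate_badness: float = float("nan")
    inner_badness: dict[str, float] = field(default_factory=dict)
    candidate_index: int = -1
    inner_candidate_index: int = -1
    seed: int = 0

    def subjects(self, which: str) -> list[str]:
        return [s for s, w in self.assignment.items() if w == which]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (
            len(self.subjects("train")),
            len(self.subjects("validation")),
            len(self.subjects("test")),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": list(self.assignment), "set": list(self.assignment.values())}
        )


def _candidate_rng(seed: int, candidate_index: int, stage: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage, candidate_index]))


def candidate_split(
    subjects: pd.DataFrame,
    cfg: SplitConfig,
    candidate_index: int,
) -> SplitAssignment:
    """One uniformly random three-way partition, deterministic in (seed, index)."""
    _require_complete(subjects, cfg)
    ids = subjects["subject_id"].astype(str).tolist()
    n_train, n_val, n_test = split_sizes(len(ids), cfg)
    order = _candidate_rng(cfg.seed, candidate_index).permutation(len(ids))
    assignment: dict[str, str] = {}
    for rank, pos in enumerate(order):
        if rank < n_test:
            which = "test"
        elif rank < n_test + n_val:
            which = "validation"
        else:
            which = "train"
        assignment[ids[pos]] = which
    return SplitAssignment(
        assignment=assignment, candidate_index=candidate_index, seed=cfg.seed
    )


def _require_complete(subjects: pd.DataFrame, cfg: SplitConfig) -> None:
    used = [v for v in (*cfg.numeric_vars, *cfg.categorical_vars) if v in subjects.columns]
    nulls = subjects[used].isna()
    if nulls.to_numpy().any():
        bad = subjects.loc[nulls.any(axis=1), "subject_id"].iloc[0]
        raise ValueError(f"missing stratification covariates for subject {bad!r}")


def split_badness(
    assignment: SplitAssignment | Mapping[str, str],
    subjects: pd.DataFrame,
    cfg: SplitConfig,
    groups: tuple[tuple[str, ...], tuple[str, ...]] = (("train", "validation"), ("test",)),
) -> tuple[dict[str, float], float]:
    """Per-variable and aggregate discrepancy between two subject groups.

    By default compares {train + validation} against test.  Numeric
    variables use the KS statistic, categorical ones the total-variation
    distance; both live on [0, 1].
    """
    mapping = assignment.assignment if isinstance(assignment, SplitAssignment) else dict(assignment)
    sets = pd.Series([mapping[str(s)] for s in subjects["subject_id"]], index=subjects.index)
    mask_a = sets.isin(groups[0])
    mask_b = sets.isin(groups[1])
    per_var: dict[str, float] = {}
    for var in cfg.numeric_vars:
        if var not in subjects.columns:
            continue
        a = subjects.loc[mask_a, var].to_numpy(dtype=float)
        b = subjects.loc[mask_b, var].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            logger.warning("stratification variable %r is constant; discrepancy 0", var)
            per_var[var] = 0.0
        else:
            per_var[var] = ks_statistic(a, b)
    for var in cfg.categorical_vars:
        if var not in subjects.columns:
            continue
        per_var[var] = total_variation_distance(
            subjects.loc[mask_a, var], subjects.loc[mask_b, var]
        )
    if not per_var:
        raise ValueError("no stratification variables present in the subject table")
    values = np.array(list(per_var.values()))
    aggregate = float(values.max() if cfg.aggregate == "max" else values.mean())
    return per_var, aggregate


def select_stratified_split(
    subjects: pd.DataFrame,
    cfg: SplitConfig | None = None,
) -> SplitAssignment:
    """Two-stage candidate search for a balanced train/validation/test split.

    Stage 1 draws ``n_candidates`` random partitions and keeps the one with
    the smallest {train + validation}-vs-test discrepancy (ties go to the
    lowest candidate index).  Stage 2 re-splits the retained remainder into
    train and validation with the same selection rule.
    """
    cfg = cfg or SplitConfig()
    best: SplitAssignment | None = None
    for index in range(cfg.n_candidates):
        cand = candidate_split(subjects, cfg, index)
        per_var, aggregate = split_badness(cand, subjects, cfg)
        if best is None or aggregate < best.aggregate_badness:
            cand.badness, cand.aggregate_badness = per_var, aggregate
            best = cand
    assert best is not None
    test_ids = set(best.subjects("test"))

    rest = subjects[~subjects["subject_id"].astype(str).isin(test_ids)].reset_index(drop=True)
    rest_ids = rest["subject_id"].astype(str).tolist()
    _, n_val, _ = split_sizes(len(subjects), cfg)
    best_inner: tuple[float, int, dict, dict[str, str]] | None = None
    for index in range(cfg.n_candidates):
        order = _candidate_rng(cfg.seed, index, stage=1).permutation(len(rest_ids))
        inner = {
            rest_ids[pos]: ("validation" if rank < n_val else "train")
            for rank, pos in enumerate(order)
        }
        per_var, aggregate = split_badness(
            inner, rest, cfg, groups=(("train",), ("validation",))
        )
        if best_inner is None or aggregate < best_inner[0]:
            best_inner = (aggregate, index, per_var, inner)
    assert best_inner is not None
    inner_aggregate, inner_index, inner_per_var, inner_map = best_inner

    assignment = {s: "test" for s in test_ids}
    assignment.update(inner_map)
    return SplitAssignment(
        assignment=assignment,
        badness=best.badness,
        aggregate_badness=best.aggregate_badness,
        inner_badness={"aggregate": inner_aggregate, **inner_per_var},
        candidate_index=best.candidate_index,
        inner_candidate_index=inner_index,
        seed=cfg.seed,
    )


@dataclass
class StrategyAssembly:
    """Pooled train/val subject ids plus untouched per-cohort test sets."""

    name: str
    train_cohorts: tuple[str, ...]
    train_subjects: dict[str, list[str]]
    val_subjects: dict[str, list[str]]
    test_subjects: dict[str, list[str]]

    @property
    def pooled_train(self) -> list[str]:
        return [s for cohort in self.train_cohorts for s in self.train_subjects[cohort]]

    @property
    def pooled_val(self) -> list[str]:
        return [s for cohort in self.train_cohorts for s in self.val_subjects[cohort]]

    @property
    def pooled_test(self) -> list[str]:
        return [s for ids in self.test_subjects.values() for s in ids]

    def assert_no_leakage(self) -> None:
        test = set(self.pooled_test)
        overlap = test & (set(self.pooled_train) | set(self.pooled_val))
        if overlap:
            raise AssertionError(f"test subjects leaked into training: {sorted(overlap)[:5]}")


def assemble_strategy(
    name: str,
    train_cohorts: Sequence[str],
    assignments: Mapping[str, SplitAssignment],
) -> StrategyAssembly:
    """Pool the chosen cohorts' train/val subsets; keep every test set intact.

    Test subjects of *all* cohorts (training cohorts or not) remain
    available for evaluation, pooled and per cohort.
    """
    missing = [c for c in train_cohorts if c not in assignments]
    if missing:
        raise ValueError(f"strategy {name!r} names cohorts without splits: {missing}")
    assembly = StrategyAssembly(
        name=name,
        train_cohorts=tuple(train_cohorts),
        train_subjects={c: a.subjects("train") for c, a in assignments.items()},
        val_subjects={c: a.subjects("validation") for c, a in assignments.items()},
        test_subjects={c: a.subjects("test") for c, a in assignments.items()},
    )
    assembly.assert_no_leakage()
    return assembly
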