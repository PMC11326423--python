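"""Shared fixtures.

The heavyweight fixtures (trained networks for the phantom-recovery and
saliency checks) are session-scoped and shared across test modules so
each model is trained exactly once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from ihirate.evaluation import icc
from ihirate.models import (
    ArchitectureSpec,
    TrainConfig,
    build_conv5fc3,
    predict_criterion,
    ridge_nested_cv,
    train_regressor,
)
from ihirate.phantom import CohortSpec, generate_cohort
from ihirate.ratings import CRITERIA, round_prediction

#: Reduced problem size used for CPU-scale phantom-recovery checks.
TRAIN_GRID = (30, 22, 14)
RECOVERY_SEEDS = (0, 1, 2)


def recovery_cohort_spec(
    name: str, prevalence_left: float, n_subjects: int = 400
) -> CohortSpec:
    """Low-noise phantom cohort used by the recovery experiments.

    Image noise is low and rater noise off, so recovery is measured
    against noiseless truth; anatomical jitter is raised above the
    generator default so that reading the body angle is a genuinely
    nonlinear problem.
    """
    return CohortSpec(
        name=name,
        n_subjects=n_subjects,
        grid_shape=TRAIN_GRID,
        noise_sd=0.02,
        blur_fwhm=1.0,
        target_prevalence_left=prevalence_left,
        target_prevalence_right=0.08,
        rater_flip_prob=0.0,  # evaluate against noiseless truth
        position_jitter_sd=0.07,
        size_jitter_sd=0.15,
    )


def train_recovery_models(seed: int):
    """Train conv5fc3 per criterion on one 400-subject low-noise cohort.

    Returns (trained_models, test_crops, test_labels, composite ICC data).
    Split 240/60/100 by permutation; reduced-width nets, raised learning
    rate and 10 epochs — the scaled-down training preset.
    """
    spec = recovery_cohort_spec(f"recovery{seed}", prevalence_left=0.20)
    dataset = generate_cohort(spec, seed=1000 + seed)
    crops = dataset.crops("left")
    labels = dataset.labels("left", which="truth")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(crops))
    tr, va, te = order[:240], order[240:300], order[300:]

    trained = {}
    rounded_preds = {}
    for criterion in CRITERIA:
        y = labels[criterion.value.lower()].to_numpy(float)
        model = build_conv5fc3(TRAIN_GRID, ArchitectureSpec.tiny(), seed=seed)
        cfg = TrainConfig(max_epochs=15, learning_rate=1e-3, seed=seed)
        fit = train_regressor(
            model, (crops[tr], y[tr]), (crops[va], y[va]), cfg,
            criterion=criterion.value,
        )
        raw = predict_criterion(fit, crops[te])
        trained[criterion] = fit
        rounded_preds[criterion] = np.array(
            [round_prediction(v, criterion) for v in raw]
        )
    composite_pred = sum(rounded_preds[c] for c in CRITERIA)
    composite_true = labels["composite"].to_numpy(float)[te]
    return {
        "dataset": dataset,
        "models": trained,
        "train_idx": tr,
        "val_idx": va,
        "test_idx": te,
        "crops": crops,
        "labels": labels,
        "composite_icc": icc(composite_true, composite_pred),
    }


@pytest.fixture(scope="session")
def recovery_runs():
    """Phantom-recovery training runs for each seed (the expensive fixture)."""
    return {seed: train_recovery_models(seed) for seed in RECOVERY_SEEDS}


@pytest.fixture(scope="session")
def prevalence_eval(recovery_runs):
    """Composite ICC of each seed's models on 20%- vs 8%-prevalence cohorts."""
    out = {}
    for seed, run in recovery_runs.items():
        iccs = {}
        for prevalence in (0.20, 0.08):
            spec = recovery_cohort_spec(
                f"ev{prevalence}", prevalence_left=prevalence, n_subjects=200
            )
            dataset = generate_cohort(spec, seed=2000 + seed)
            crops = dataset.crops("left")
            labels = dataset.labels("left", which="truth")
            rounded = {}
            for criterion in CRITERIA:
                raw = predict_criterion(run["models"][criterion], crops)
                rounded[criterion] = np.array(
                    [round_prediction(v, criterion) for v in raw]
                )
            iccs[prevalence] = icc(
                labels["composite"].to_numpy(float),
                sum(rounded[c] for c in CRITERIA),
            )
        out[seed] = iccs
    return out


@pytest.fixture(scope="session")
def ridge_c1_runs(recovery_runs):
    """Ridge nested-CV fits of the angle criterion C1 per recovery seed."""
    out = {}
    for seed, run in recovery_runs.items():
        crops, labels = run["crops"], run["labels"]
        flat = crops.reshape(len(crops), -1)
        y = labels["c1"].to_numpy(float)
        fit_idx = np.concatenate([run["train_idx"], run["val_idx"]])
        result = ridge_nested_cv(
            flat[fit_idx], y[fit_idx], input_extents=crops.shape[1:]
        )
        te = run["test_idx"]
        out[seed] = {
            "result": result,
            "test_icc": icc(y[te], result.model.predict(flat[te])),
        }
    return out
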