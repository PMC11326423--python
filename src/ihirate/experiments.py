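"""End-to-end experiment orchestration at phantom scale.

One :class:`ExperimentSpec` describes a full study: which synthetic
cohorts to generate, which multi-cohort training strategies to run
(single-cohort, three-cohort, all-cohort), which model families, criteria
and hemispheres, and a master seed from which every stage's seed is
derived.  :func:`run_experiment` materializes a self-describing output
directory — datasets, split assignments, model checkpoints, prediction
tables and agreement reports — with a manifest recording every artifact,
its seed and the config hash.  Completed stages are detected on disk and
skipped, so a partially failed run is resumable.

The default spec is roughly one tenth of a realistic multi-cohort study
with reduced-width networks, sized for a single CPU.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import evaluate_run
from .models import (
    ArchitectureSpec,
    TrainConfig,
    load_checkpoint,
    predict_criterion,
    ridge_nested_cv,
    save_checkpoint,
    train_regressor,
    build_model,
)
from .phantom import CohortSpec, PhantomDataset, default_cohorts, generate_cohort
from .ratings import CRITERIA, Criterion, round_prediction, write_ratings_tsv
from .splitting import (
    SplitAssignment,
    SplitConfig,
    assemble_strategy,
    select_stratified_split,
    subject_table,
)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentSpec", "ExperimentResult", "run_experiment", "derive_seed"]


def derive_seed(master_seed: int, *stage: object) -> int:
    """Deterministic per-stage seed: SHA-256 of (master seed, stage name)."""
    key = json.dumps([int(master_seed), *[str(s) for s in stage]])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


_DEFAULT_STRATEGIES = {
    "imagen": ("imagen",),
    "imagen_qtim_qtab": ("imagen", "qtim", "qtab"),
    "all": ("imagen", "qtim", "qtab", "ukb"),
}


@dataclass
class ExperimentSpec:
    cohorts: list[CohortSpec] = field(default_factory=lambda: default_cohorts(0.1))
    strategies: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_STRATEGIES)
    )
    architectures: tuple[str, ...] = ("conv5fc3",)
    criteria: tuple[str, ...] = ("C1", "C2", "C3", "C5")
    hemispheres: tuple[str, ...] = ("left", "right")
    arch_spec: ArchitectureSpec | None = None  # per-family tiny preset if None
    train_config: TrainConfig = field(default_factory=TrainConfig)
    split_config: SplitConfig = field(default_factory=SplitConfig)
    n_boot: int = 100
    master_seed: int = 0
    out_dir: str = "experiment_out"

    def validate(self) -> None:
        names = {c.name for c in self.cohorts}
        for strategy, members in self.strategies.items():
            missing = set(members) - names
            if missing:
                raise ValueError(
                    f"strategy {strategy!r} references unknown cohorts {sorted(missing)}"
                )
        for family in self.architectures:
            if family not in ("conv5fc3", "resnet3d", "secnn", "ridge"):
                raise ValueError(f"unknown architecture {family!r}")
        for crit in self.criteria:
            Criterion(crit)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "cohorts": [asdict(c) for c in self.cohorts],
                "strategies": {k: list(v) for k, v in self.strategies.items()},
                "architectures": list(self.architectures),
                "criteria": list(self.criteria),
                "hemispheres": list(self.hemispheres),
                "arch_spec": asdict(self.arch_spec) if self.arch_spec else None,
                "train_config": asdict(self.train_config),
                "split_config": {
                    "test_fraction": self.split_config.test_fraction,
                    "val_fraction_of_remainder": self.split_config.val_fraction_of_remainder,
                    "n_candidates": self.split_config.n_candidates,
                    "aggregate": self.split_config.aggregate,
                },
                "n_boot": self.n_boot,
                "master_seed": self.master_seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    out_dir: Path
    manifest: dict
    datasets: dict[str, PhantomDataset]
    assignments: dict[str, SplitAssignment]
    reports: dict[str, dict]


def _dataset_subframe(frame: pd.DataFrame, subject_ids: list[str]) -> pd.DataFrame:
    return frame[frame["subject_id"].isin(subject_ids)].reset_index(drop=True)


def _crops_and_labels(
    dataset: PhantomDataset,
    hemisphere: str,
    subject_ids: list[str],
) -> tuple[np.ndarray, pd.DataFrame]:
    crops = dataset.crops(hemisphere)  # mirrored right -> left frame
    labels = dataset.labels(hemisphere, which="observed")
    mask = labels["subject_id"].isin(subject_ids).to_numpy()
    return crops[mask], labels[mask].reset_index(drop=True)


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Generate, split, train, predict and evaluate one experiment grid."""
    spec.validate()
    out = Path(spec.out_dir)
    for sub in ("cohorts", "splits", "models", "predictions", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": spec.config_hash(),
        "master_seed": spec.master_seed,
        "stages": [],
        "checkpoints": [],
    }

    def stage_done(name: str, seconds: float, **extra) -> None:
        entry = {"stage": name, "seconds": round(seconds, 2), **extra}
        manifest["stages"].append(entry)
        logger.info("stage %s done in %.1fs", name, seconds)

    # 1. cohorts -----------------------------------------------------------
    datasets: dict[str, PhantomDataset] = {}
    for cohort in spec.cohorts:
        t0 = time.time()
        seed = derive_seed(spec.master_seed, "phantom", cohort.name)
        datasets[cohort.name] = generate_cohort(cohort, seed=seed)
        write_ratings_tsv(
            datasets[cohort.name].observed_frame(),
            out / "cohorts" / f"{cohort.name}_observed.tsv",
        )
        write_ratings_tsv(
            datasets[cohort.name].truth_frame(),
            out / "cohorts" / f"{cohort.name}_truth.tsv",
        )
        stage_done(f"generate:{cohort.name}", time.time() - t0, seed=seed)

    # 2. stratified splits -------------------------------------------------
    assignments: dict[str, SplitAssignment] = {}
    for cohort in spec.cohorts:
        t0 = time.time()
        seed = derive_seed(spec.master_seed, "split", cohort.name)
        cfg = SplitConfig(
            test_fraction=spec.split_config.test_fraction,
            val_fraction_of_remainder=spec.split_config.val_fraction_of_remainder,
            n_candidates=spec.split_config.n_candidates,
            numeric_vars=spec.split_config.numeric_vars,
            categorical_vars=spec.split_config.categorical_vars,
            aggregate=spec.split_config.aggregate,
            seed=seed,
        )
        subjects = subject_table(datasets[cohort.name].observed_frame())
        assignment = select_stratified_split(subjects, cfg)
        assignments[cohort.name] = assignment
        assignment.to_frame().assign(cohort=cohort.name).to_csv(
            out / "splits" / f"{cohort.name}.tsv", sep="\t", index=False
        )
        with open(out / "splits" / f"{cohort.name}_diagnostics.json", "w") as fh:
            json.dump(
                {
                    "badness": assignment.badness,
                    "aggregate_badness": assignment.aggregate_badness,
                    "inner_badness": assignment.inner_badness,
                    "candidate_index": assignment.candidate_index,
                    "seed": seed,
                },
                fh,
                indent=2,
            )
        stage_done(f"split:{cohort.name}", time.time() - t0, seed=seed)

    # 3. train + predict ---------------------------------------------------
    reports: dict[str, dict] = {}
    for strategy, members in spec.strategies.items():
        assembly = assemble_strategy(strategy, members, assignments)
        assembly.assert_no_leakage()
        for family in spec.architectures:
            for hemisphere in spec.hemispheres:
                pred_frames: list[pd.DataFrame] = []
                # test crops/labels per cohort, canonical frame
                test_parts = {
                    name: _crops_and_labels(
                        datasets[name], hemisphere, assembly.test_subjects[name]
                    )
                    for name in datasets
                }
                criterion_preds: dict[str, np.ndarray] = {}
                for crit_name in spec.criteria:
                    criterion = Criterion(crit_name)
                    t0 = time.time()
                    tag = f"{strategy}_{family}_{hemisphere}_{crit_name}"
                    ckpt = out / "models" / f"{tag}.npz"
                    raw_parts: list[np.ndarray] = []
                    if family == "ridge":
                        x_fit, y_fit = _pooled_ridge_inputs(
                            datasets, assembly, hemisphere, criterion
                        )
                        result = ridge_nested_cv(x_fit, y_fit)
                        for name in datasets:
                            crops, _ = test_parts[name]
                            raw_parts.append(
                                result.model.predict(crops.reshape(len(crops), -1))
                            )
                    else:
                        trained = _train_or_load(
                            spec, datasets, assembly, hemisphere, criterion,
                            family, ckpt, strategy,
                        )
                        manifest["checkpoints"].append(str(ckpt))
                        for name in datasets:
                            crops, _ = test_parts[name]
                            raw_parts.append(predict_criterion(trained, crops))
                    raw = np.concatenate(raw_parts)
                    criterion_preds[crit_name] = np.array(
                        [round_prediction(v, criterion) for v in raw]
                    )
                    stage_done(f"train:{tag}", time.time() - t0)
                pred_table = _prediction_table(
                    test_parts, criterion_preds, list(datasets)
                )
                pred_path = (
                    out / "predictions" / f"{strategy}_{family}_{hemisphere}.tsv"
                )
                pred_table.to_csv(pred_path, sep="\t", index=False)
                pred_frames.append(pred_table)

                if set(spec.criteria) == {c.value for c in CRITERIA}:
                    truth = pd.concat(
                        [part[1] for part in test_parts.values()], ignore_index=True
                    )
                    report = evaluate_run(
                        truth,
                        pred_table,
                        n_boot=spec.n_boot,
                        seed=derive_seed(spec.master_seed, "eval", strategy, family),
                    )
                    key = f"{strategy}_{family}_{hemisphere}"
                    reports[key] = report.to_json_dict()
                    with open(out / "reports" / f"{key}.json", "w") as fh:
                        json.dump(reports[key], fh, indent=2)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return ExperimentResult(
        out_dir=out,
        manifest=manifest,
        datasets=datasets,
        assignments=assignments,
        reports=reports,
    )


def _pooled_ridge_inputs(datasets, assembly, hemisphere, criterion):
    xs, ys = [], []
    for name in assembly.train_cohorts:
        ids = assembly.train_subjects[name] + assembly.val_subjects[name]
        crops, labels = _crops_and_labels(datasets[name], hemisphere, ids)
        xs.append(crops.reshape(len(crops), -1))
        ys.append(labels[criterion.value.lower()].to_numpy(float))
    return np.concatenate(xs), np.concatenate(ys)


def _train_or_load(
    spec: ExperimentSpec,
    datasets,
    assembly,
    hemisphere: str,
    criterion: Criterion,
    family: str,
    ckpt: Path,
    strategy: str,
):
    if ckpt.exists():
        logger.info("resuming from checkpoint %s", ckpt)
        return load_checkpoint(ckpt)
    x_tr, y_tr, x_va, y_va = [], [], [], []
    for name in assembly.train_cohorts:
        crops, labels = _crops_and_labels(
            datasets[name], hemisphere, assembly.train_subjects[name]
        )
        x_tr.append(crops)
        y_tr.append(labels[criterion.value.lower()].to_numpy(float))
        crops, labels = _crops_and_labels(
            datasets[name], hemisphere, assembly.val_subjects[name]
        )
        x_va.append(crops)
        y_va.append(labels[criterion.value.lower()].to_numpy(float))
    x_train = np.concatenate(x_tr)
    grid = x_train.shape[1:]
    arch = spec.arch_spec or ArchitectureSpec.tiny(family)
    seed = derive_seed(spec.master_seed, "train", strategy, family, hemisphere, criterion.value)
    model = build_model(family, grid, arch, seed=seed)
    cfg = TrainConfig(
        learning_rate=spec.train_config.learning_rate,
        weight_decay=spec.train_config.weight_decay,
        batch_size=spec.train_config.batch_size,
        max_epochs=spec.train_config.max_epochs,
        early_stop_tolerance=spec.train_config.early_stop_tolerance,
        seed=seed,
    )
    trained = train_regressor(
        model,
        (x_train, np.concatenate(y_tr)),
        (np.concatenate(x_va), np.concatenate(y_va)),
        cfg,
        criterion=criterion.value,
        hemisphere=hemisphere,
        strategy=strategy,
    )
    save_checkpoint(trained, ckpt)
    return trained


def _prediction_table(test_parts, criterion_preds, cohort_order) -> pd.DataFrame:
    truth = pd.concat([test_parts[name][1] for name in cohort_order], ignore_index=True)
    table = truth[["subject_id", "hemisphere", "cohort"]].copy()
    for crit_name, values in criterion_preds.items():
        table[crit_name.lower()] = values
    if set(criterion_preds) == {c.value for c in CRITERIA}:
        table["composite"] = sum(
            criterion_preds[c.value] for c in CRITERIA
        )
        table["ihi_flag"] = (table["composite"] >= 4).astype(int)
    table["rater_id"] = "model"
    return table
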