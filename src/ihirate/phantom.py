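"""Synthetic hippocampus phantoms with known ground-truth IHI criteria.

The generator emits grey-matter-like 3D crops whose geometry varies
monotonically with four latent traits in [0, 1], one per rated criterion:

* ``t1`` rotates the ellipsoidal "hippocampal body" from horizontal
  (t1 = 0) to vertical (t1 = 1) and makes it rounder — the verticality /
  roundness criterion C1;
* ``t2`` deepens a medial wedge-shaped dark groove — the collateral
  sulcus criterion C2;
* ``t3`` translates the body medially — the medial-position criterion C3;
* ``t5`` deepens a second, lateral groove — the fusiform-sulci
  criterion C5.

Latent t maps to criterion score round(2 t) on the criterion's grid, so
the latent-image-score relationship is monotone and learnable by
construction.  The geometry is deliberately simple — an ellipsoid plus
carved wedges — because the goal is a controlled test bed for the rating
pipeline, not anatomical realism; scanner physics, segmentation artefacts
and real anatomical covariance are absent, and results on phantoms bound
what the pipeline can do, not what it achieves on real cohorts.

Cohorts differ in size, age structure, image blur/noise/contrast, rater
and IHI prevalence (higher on the left than the right hemisphere, as in
real populations).  Prevalence is controlled through a two-component
latent prior — a "typical" Beta concentrated near 0 and an "inverted"
Beta concentrated near 1 — whose mixture weight is solved exactly from
the induced composite-score distribution.  Rater label noise perturbs
each criterion one grid step with a calibrated probability, emulating
realistic inter-rater disagreement on the composite score.

All generation is a pure function of (spec, seed); per-subject generators
are derived by counter from the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, stats

from .preprocess import GreyMatterCrop, RoiBox, mirror_hemisphere
from .ratings import (
    CRITERIA,
    Criterion,
    RatingRecord,
    records_to_frame,
    round_prediction,
    write_ratings_tsv,
)

__all__ = [
    "PhantomLatents",
    "CohortSpec",
    "PhantomSubject",
    "PhantomDataset",
    "render_crop",
    "latents_to_scores",
    "simulate_rater",
    "generate_cohort",
    "geometry_masks",
    "composite_exceedance",
    "solve_mixture_weight",
    "default_cohorts",
    "DEFAULT_GRID_SHAPE",
    "DEFAULT_FLIP_PROB",
    "BETA_TYPICAL",
    "BETA_INVERTED",
    "write_cohort",
    "load_cohort_specs",
]

#: Default crop extents; matches the hippocampal ROI of the preprocess module.
DEFAULT_GRID_SHAPE: tuple[int, int, int] = (72, 53, 33)

#: Latent priors of the two subject types (Beta shape parameters).
BETA_TYPICAL: tuple[float, float] = (1.2, 5.0)
BETA_INVERTED: tuple[float, float] = (5.0, 1.5)

#: Rater ±1-step perturbation probability per criterion, calibrated so the
#: truth-vs-observed composite ICC lands in the realistic inter-rater band
#: (roughly 0.70-0.85) on a 20%-prevalence cohort.
DEFAULT_FLIP_PROB: float = 0.65

_MIN_EXTENT = 12


@dataclass(frozen=True)
class PhantomLatents:
    """Latent criterion traits, each in [0, 1]."""

    t1: float
    t2: float
    t3: float
    t5: float

    def __post_init__(self) -> None:
        for name in ("t1", "t2", "t3", "t5"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"latent {name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.t1, self.t2, self.t3, self.t5])


# ---------------------------------------------------------------------------
# geometry

def _normalized_grid(shape: tuple[int, int, int]):
    nx, ny, nz = shape
    x = (np.arange(nx) + 0.5) / nx
    y = (np.arange(ny) + 0.5) / ny
    z = (np.arange(nz) + 0.5) / nz
    return np.meshgrid(x, y, z, indexing="ij")

# geometric constants (normalized coordinates)
_BODY_CX0, _BODY_SHIFT = 0.40, 0.18   # lateral position and medial travel (t3)
_BODY_CZ = 0.55
_BODY_A, _BODY_B0, _BODY_C = 0.20, 0.095, 0.30
_SULCUS_DX, _SULCUS_W, _SULCUS_H = 0.22, 0.060, 0.55   # collateral sulcus (t2)
_GROOVE_DX, _GROOVE_W, _GROOVE_H = -0.25, 0.045, 0.45  # fusiform groove (t5)
_Z_BASE = 0.04
_BASE_INTENSITY, _BODY_INTENSITY, _CARVE_INTENSITY = 0.30, 0.92, 0.04


#: per-subject anatomical nuisance: (dx, dy, dz, log-size); zero = canonical.
_NO_JITTER = (0.0, 0.0, 0.0, 0.0)


def _body_membership(
    xg, yg, zg, t1: float, t3: float, jitter=_NO_JITTER
) -> np.ndarray:
    dx_j, dy_j, dz_j, log_s = jitter
    s = float(np.exp(log_s))
    cx = _BODY_CX0 + _BODY_SHIFT * t3 + dx_j
    theta = t1 * np.pi / 2.0
    b = _BODY_B0 * (1.0 + 0.5 * t1) * s  # rounder as it turns vertical
    dx, dz = xg - cx, zg - (_BODY_CZ + dz_j)
    xr = np.cos(theta) * dx + np.sin(theta) * dz
    zr = -np.sin(theta) * dx + np.cos(theta) * dz
    r2 = (
        (xr / (_BODY_A * s)) ** 2
        + (zr / b) ** 2
        + ((yg - (0.5 + dy_j)) / (_BODY_C * s)) ** 2
    )
    return r2 <= 1.0


_WEDGE_Y_HALF = 0.40  # sulci are segments, not full-length slots


def _wedge(xg, yg, zg, x_centre: float, width: float, height: float, depth: float):
    """Tapered vertical slot rising from the crop base up to *depth*."""
    rel = (zg - _Z_BASE) / height
    taper = width * np.clip(1.0 - rel, 0.0, None)
    return (
        (np.abs(xg - x_centre) < taper)
        & (np.abs(yg - 0.5) <= _WEDGE_Y_HALF)
        & (zg >= _Z_BASE)
        & (zg <= _Z_BASE + depth * height)
    )


def render_crop(
    latents: PhantomLatents,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    seed: int = 0,
    noise_sd: float = 0.0,
    blur_fwhm: float = 0.0,
    intensity_scale: float = 1.0,
    hemisphere: str = "left",
    subject_id: str = "",
    cohort: str = "",
    jitter: tuple[float, float, float, float] = _NO_JITTER,
) -> GreyMatterCrop:
    """Render one grey-matter-like crop; deterministic given (latents, seed).

    The noiseless geometry: base tissue at 0.30, the body ellipsoid at
    0.92, grooves carved down to 0.04; then Gaussian blur (FWHM in
    voxels), a multiplicative contrast factor, additive Gaussian noise,
    and a clip back to [0, 1].  ``jitter`` = (dx, dy, dz, log-size) shifts
    and rescales the whole geometry — per-subject anatomical variability
    that carries no information about the criteria.
    """
    if min(grid_shape) < _MIN_EXTENT:
        raise ValueError(
            f"grid {grid_shape} too small to contain the phantom geometry "
            f"(min extent {_MIN_EXTENT})"
        )
    xg, yg, zg = _normalized_grid(grid_shape)
    vol = np.full(grid_shape, _BASE_INTENSITY)
    vol[_body_membership(xg, yg, zg, latents.t1, latents.t3, jitter)] = _BODY_INTENSITY
    cx = _BODY_CX0 + _BODY_SHIFT * latents.t3 + jitter[0]
    if latents.t2 > 0:
        vol[
            _wedge(xg, yg, zg, cx + _SULCUS_DX, _SULCUS_W, _SULCUS_H, latents.t2)
        ] = _CARVE_INTENSITY
    if latents.t5 > 0:
        vol[
            _wedge(xg, yg, zg, cx + _GROOVE_DX, _GROOVE_W, _GROOVE_H, latents.t5)
        ] = _CARVE_INTENSITY
    if blur_fwhm > 0:
        vol = ndimage.gaussian_filter(vol, sigma=blur_fwhm / 2.3548)
    vol = vol * intensity_scale
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, size=grid_shape)
    vol = np.clip(vol, 0.0, 1.0)
    roi = RoiBox((0, grid_shape[0]), (0, grid_shape[1]), (0, grid_shape[2]))
    return GreyMatterCrop(
        voxels=vol, roi=roi, hemisphere=hemisphere, subject_id=subject_id, cohort=cohort
    )


def geometry_masks(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    dilate: int = 2,
) -> dict[str, np.ndarray]:
    """Voxel supports of the generative geometry over the full latent range.

    ``body`` is the union of the ellipsoid across rotation and medial
    shift, ``sulcus`` and ``groove`` the wedges at maximal depth across
    the medial shift; each is dilated by *dilate* voxels to account for
    blur.  ``union`` is their union — the region where image information
    about the criteria lives.
    """
    xg, yg, zg = _normalized_grid(grid_shape)
    body = np.zeros(grid_shape, dtype=bool)
    for t1 in np.linspace(0, 1, 5):
        for t3 in (0.0, 0.5, 1.0):
            for jx in (-0.05, 0.0, 0.05):
                body |= _body_membership(
                    xg, yg, zg, t1, t3, jitter=(jx, 0.0, 0.0, 0.1)
                )
    sulcus = np.zeros(grid_shape, dtype=bool)
    groove = np.zeros(grid_shape, dtype=bool)
    for t3 in (0.0, 0.5, 1.0):
        cx = _BODY_CX0 + _BODY_SHIFT * t3
        sulcus |= _wedge(xg, yg, zg, cx + _SULCUS_DX, _SULCUS_W, _SULCUS_H, 1.0)
        groove |= _wedge(xg, yg, zg, cx + _GROOVE_DX, _GROOVE_W, _GROOVE_H, 1.0)
    masks = {"body": body, "sulcus": sulcus, "groove": groove}
    if dilate > 0:
        masks = {
            k: ndimage.binary_dilation(v, iterations=dilate) for k, v in masks.items()
        }
    masks["union"] = masks["body"] | masks["sulcus"] | masks["groove"]
    return masks


def body_vertical_spread(voxels: np.ndarray, threshold: float = 0.6) -> float:
    """Standard deviation of the normalized z-coordinate of bright voxels.

    A probe for the verticality latent t1: as the body rotates upright its
    bright voxels spread over more of the z axis.  Intended for noiseless
    renders, where "bright" cleanly selects the body.
    """
    nx, ny, nz = voxels.shape
    zg = np.broadcast_to((np.arange(nz) + 0.5) / nz, (nx, ny, nz))
    sel = voxels > threshold
    if not sel.any():
        raise ValueError("no voxels above threshold; is this a noiseless render?")
    return float(zg[sel].std())


# ---------------------------------------------------------------------------
# latents -> labels

_LATENT_TO_CRIT = {
    "t1": Criterion.C1,
    "t2": Criterion.C2,
    "t3": Criterion.C3,
    "t5": Criterion.C5,
}


def latents_to_scores(latents: PhantomLatents) -> dict[Criterion, float]:
    """Ground-truth criterion scores: round(2 * latent) on each grid."""
    return {
        crit: round_prediction(2.0 * getattr(latents, name), crit)
        for name, crit in _LATENT_TO_CRIT.items()
    }


def _score_distribution(criterion: Criterion, beta_ab: tuple[float, float]):
    """Exact pmf of the criterion score when the latent is Beta(a, b).

    Scores are returned on the half-unit integer grid (score * 2), so
    composite-score convolutions stay exact.
    """
    a, b = beta_ab
    step = criterion.step
    levels = np.arange(0, 2.0 + step / 2, step)
    # latent boundaries between adjacent score levels: midpoints of 2*latent
    cuts = (levels[:-1] + step / 2.0) / 2.0
    cdf = stats.beta.cdf(cuts, a, b)
    pmf = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    half_units = (levels * 2).astype(int)
    out = np.zeros(half_units.max() + 1)
    out[half_units] = pmf
    return out


def composite_exceedance(beta_ab: tuple[float, float], threshold: float = 4.0) -> float:
    """P(composite >= threshold) when all four latents are iid Beta(a, b)."""
    pmf = np.array([1.0])
    for criterion in CRITERIA:
        pmf = np.convolve(pmf, _score_distribution(criterion, beta_ab))
    half_threshold = int(round(threshold * 2))
    return float(pmf[half_threshold:].sum())


def solve_mixture_weight(
    target_prevalence: float,
    beta_typical: tuple[float, float] = BETA_TYPICAL,
    beta_inverted: tuple[float, float] = BETA_INVERTED,
) -> float:
    """Mixture weight of the inverted component hitting the target prevalence."""
    if not 0.0 <= target_prevalence <= 1.0:
        raise ValueError(f"target prevalence {target_prevalence} outside [0, 1]")
    p_lo = composite_exceedance(beta_typical)
    p_hi = composite_exceedance(beta_inverted)
    w = (target_prevalence - p_lo) / (p_hi - p_lo)
    if not 0.0 <= w <= 1.0:
        raise ValueError(
            f"prevalence {target_prevalence} unattainable with priors "
            f"(reachable range [{p_lo:.4f}, {p_hi:.4f}])"
        )
    return float(w)


# ---------------------------------------------------------------------------
# rater noise

def simulate_rater(
    truth: RatingRecord,
    flip_prob: float,
    seed: int | np.random.Generator = 0,
    rater_id: str = "sim",
) -> RatingRecord:
    """Perturb each criterion one grid step up/down with probability flip_prob.

    At a scale boundary the only legal direction is taken, so a flip always
    changes the score.  The composite is recomputed from the perturbed
    criteria.
    """
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError(f"flip_prob {flip_prob} outside [0, 1]")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    scores: dict[Criterion, float] = {}
    for criterion in CRITERIA:
        value = truth.scores[criterion]
        if rng.random() < flip_prob:
            if value <= 0.0:
                direction = 1.0
            elif value >= 2.0:
                direction = -1.0
            else:
                direction = 1.0 if rng.random() < 0.5 else -1.0
            value = float(np.clip(value + direction * criterion.step, 0.0, 2.0))
        scores[criterion] = value
    return RatingRecord.from_scores(
        subject_id=truth.subject_id,
        hemisphere=truth.hemisphere,
        scores=scores,
        rater_id=rater_id,
        covariates=truth.covariates,
    )


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Everything that defines one synthetic cohort."""

    name: str
    n_subjects: int
    target_prevalence_left: float = 0.20
    target_prevalence_right: float = 0.08
    noise_sd: float = 0.05
    blur_fwhm: float = 1.5
    intensity_scale: float = 1.0
    age_mean: float = 20.0
    age_sd: float = 3.0
    rater_id: str = "sim"
    rater_flip_prob: float = DEFAULT_FLIP_PROB
    sex_p_female: float = 0.5
    n_centres: int = 2
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    # per-subject anatomical nuisance (normalized-coordinate / log units)
    position_jitter_sd: float = 0.05
    size_jitter_sd: float = 0.12

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for p in (self.target_prevalence_left, self.target_prevalence_right):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {p} outside [0, 1]")


@dataclass
class PhantomSubject:
    subject_id: str
    crop_left: GreyMatterCrop
    crop_right: GreyMatterCrop
    truth_left: RatingRecord
    truth_right: RatingRecord
    observed_left: RatingRecord
    observed_right: RatingRecord
    latents_left: PhantomLatents
    latents_right: PhantomLatents
    covariates: dict[str, object]


@dataclass
class PhantomDataset:
    spec: CohortSpec
    seed: int
    subjects: list[PhantomSubject]

    def truth_frame(self) -> pd.DataFrame:
        recs = [s.truth_left for s in self.subjects] + [
            s.truth_right for s in self.subjects
        ]
        return records_to_frame(recs)

    def observed_frame(self) -> pd.DataFrame:
        recs = [s.observed_left for s in self.subjects] + [
            s.observed_right for s in self.subjects
        ]
        return records_to_frame(recs)

    def crops(self, hemisphere: str, mirror_right: bool = True) -> np.ndarray:
        """Stacked (N, nx, ny, nz) crop array in a canonical left frame.

        Right-hemisphere crops are mirrored into the left frame when
        ``mirror_right`` (the default), so one model serves both sides.
        """
        out = []
        for s in self.subjects:
            crop = s.crop_left if hemisphere == "left" else s.crop_right
            if hemisphere == "right" and mirror_right:
                crop = mirror_hemisphere(crop)
            out.append(crop.voxels)
        return np.stack(out)

    def labels(self, hemisphere: str, which: str = "observed") -> pd.DataFrame:
        frame = self.observed_frame() if which == "observed" else self.truth_frame()
        return frame[frame["hemisphere"] == hemisphere].reset_index(drop=True)


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> dict[str, object]:
    sex = "F" if rng.random() < spec.sex_p_female else "M"
    height = rng.normal(168.0 if sex == "F" else 178.0, 7.0)
    weight = 0.5 * (height - 100.0) + rng.normal(0.0, 7.0)
    return {
        "age": float(np.round(rng.normal(spec.age_mean, spec.age_sd), 2)),
        "sex": sex,
        "weight": float(np.round(weight, 1)),
        "height": float(np.round(height, 1)),
        "handedness": "right" if rng.random() < 0.9 else "left",
        "centre": f"centre_{int(rng.integers(spec.n_centres))}",
        "cohort": spec.name,
    }


def _draw_latents(rng: np.random.Generator, inverted: bool) -> PhantomLatents:
    a, b = BETA_INVERTED if inverted else BETA_TYPICAL
    t = rng.beta(a, b, size=4)
    return PhantomLatents(t1=t[0], t2=t[1], t3=t[2], t5=t[3])


def generate_cohort(spec: CohortSpec, seed: int = 0) -> PhantomDataset:
    """Generate a fully reproducible synthetic cohort.

    Each subject gets independent left/right latents drawn from the
    typical/inverted mixture (weights solved per hemisphere from the
    target prevalences), a rendered crop per hemisphere with the cohort's
    blur/noise/contrast, covariates, and noiseless plus rater-perturbed
    rating records.
    """
    w_left = solve_mixture_weight(spec.target_prevalence_left)
    w_right = solve_mixture_weight(spec.target_prevalence_right)
    subjects: list[PhantomSubject] = []
    for index in range(spec.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 1000 + index])
        )
        subject_id = f"{spec.name}_{index:05d}"
        covariates = _draw_covariates(spec, rng)
        halves: dict[str, tuple] = {}
        for hemisphere, w in (("left", w_left), ("right", w_right)):
            latents = _draw_latents(rng, inverted=bool(rng.random() < w))
            truth = RatingRecord.from_scores(
                subject_id,
                hemisphere,
                latents_to_scores(latents),
                rater_id="truth",
                covariates=covariates,
            )
            observed = simulate_rater(
                truth, spec.rater_flip_prob, seed=rng, rater_id=spec.rater_id
            )
            jitter = (
                float(rng.normal(0.0, spec.position_jitter_sd)),
                float(rng.normal(0.0, spec.position_jitter_sd)),
                float(rng.normal(0.0, spec.position_jitter_sd)),
                float(rng.normal(0.0, spec.size_jitter_sd)),
            )
            crop = render_crop(
                latents,
                grid_shape=spec.grid_shape,
                seed=int(rng.integers(2**31)),
                noise_sd=spec.noise_sd,
                blur_fwhm=spec.blur_fwhm,
                intensity_scale=spec.intensity_scale,
                hemisphere=hemisphere,
                subject_id=subject_id,
                cohort=spec.name,
                jitter=jitter,
            )
            halves[hemisphere] = (latents, truth, observed, crop)
        subjects.append(
            PhantomSubject(
                subject_id=subject_id,
                crop_left=halves["left"][3],
                crop_right=halves["right"][3],
                truth_left=halves["left"][1],
                truth_right=halves["right"][1],
                observed_left=halves["left"][2],
                observed_right=halves["right"][2],
                latents_left=halves["left"][0],
                latents_right=halves["right"][0],
                covariates=covariates,
            )
        )
    return PhantomDataset(spec=spec, seed=seed, subjects=subjects)


def default_cohorts(
    scale: float = 0.1,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
) -> list[CohortSpec]:
    """Four cohorts echoing the IMAGEN / QTIM / QTAB / UKBiobank structure.

    Sizes are ``scale`` times the real cohorts (default one tenth); ages,
    per-hemisphere prevalences and raters follow the published cohort
    descriptions, and acquisition differences are emulated by distinct
    blur / noise / contrast settings.
    """
    def n(full: int) -> int:
        return max(int(round(full * scale)), 20)

    return [
        CohortSpec(
            name="imagen", n_subjects=n(2008), age_mean=14.5, age_sd=1.3,
            target_prevalence_left=0.21, target_prevalence_right=0.08,
            noise_sd=0.04, blur_fwhm=1.2, intensity_scale=1.0,
            rater_id="CC", n_centres=8, grid_shape=grid_shape,
        ),
        CohortSpec(
            name="qtim", n_subjects=n(993), age_mean=22.9, age_sd=2.8,
            target_prevalence_left=0.24, target_prevalence_right=0.10,
            noise_sd=0.06, blur_fwhm=1.6, intensity_scale=0.90,
            rater_id="KDM", n_centres=1, grid_shape=grid_shape,
        ),
        CohortSpec(
            name="qtab", n_subjects=n(400), age_mean=11.3, age_sd=1.3,
            target_prevalence_left=0.27, target_prevalence_right=0.17,
            noise_sd=0.03, blur_fwhm=1.0, intensity_scale=1.10,
            rater_id="KDM", n_centres=1, grid_shape=grid_shape,
        ),
        CohortSpec(
            name="ukb", n_subjects=n(985), age_mean=63.5, age_sd=7.6,
            target_prevalence_left=0.21, target_prevalence_right=0.06,
            noise_sd=0.05, blur_fwhm=1.4, intensity_scale=0.95,
            rater_id="KDM", n_centres=3, grid_shape=grid_shape,
        ),
    ]


# ---------------------------------------------------------------------------
# on-disk format

def write_cohort(dataset: PhantomDataset, out_dir: str | Path) -> None:
    """Write crops as NIfTI plus truth/observed rating TSVs."""
    out = Path(out_dir)
    (out / "crops").mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for subject in dataset.subjects:
        for hemisphere, crop in (
            ("left", subject.crop_left),
            ("right", subject.crop_right),
        ):
            img = nib.Nifti1Image(crop.voxels.astype(np.float32), affine)
            nib.save(img, out / "crops" / f"{subject.subject_id}_{hemisphere}.nii.gz")
    write_ratings_tsv(dataset.truth_frame(), out / "ratings_truth.tsv")
    write_ratings_tsv(dataset.observed_frame(), out / "ratings_observed.tsv")


def load_cohort_specs(path: str | Path) -> list[CohortSpec]:
    """Read cohort specs from a YAML file (a list of mappings)."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if isinstance(raw, dict):
        raw = raw.get("cohorts", [raw])
    specs = []
    for entry in raw:
        if "grid_shape" in entry:
            entry["grid_shape"] = tuple(entry["grid_shape"])
        specs.append(CohortSpec(**entry))
    return specs
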