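"""Synthetic multimodal cohorts with known ground truth.

Generates tabular clinical/cognitive features, voxelwise volume-like data
built from planted spatial components with site and covariate effects, and
binary outcome labels, all deterministic given a seed.  A matched control
sample sharing the site/covariate structure (but carrying no outcome
signal) is available for fitting reference transforms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .tabprep import FeatureMatrix


class ConfigError(ValueError):
    pass


def _default_site_weights(n_sites: int) -> np.ndarray:
    # one dominant site holding ~half the cohort, the rest spread evenly
    if n_sites == 1:
        return np.array([1.0])
    w = np.full(n_sites, 0.5 / (n_sites - 1))
    w[0] = 0.5
    return w


@dataclass
class SynthConfig:
    n_subjects: int = 109
    n_sites: int = 10
    site_weights: np.ndarray | None = None
    prevalence: float = 0.5
    n_clinical: int = 30
    n_cognitive: int = 10
    n_informative: int = 3
    effect_vector: np.ndarray | None = None
    informative_indices: np.ndarray | None = None
    n_binary_clinical: int = 0
    missing_rate: float | np.ndarray = 0.0
    n_voxels: int = 500
    n_components: int = 9
    site_shift: np.ndarray | None = None
    site_scale: np.ndarray | None = None
    age_range: tuple[float, float] = (15.0, 40.0)
    sex_ratio: float = 0.4
    age_slope: float = 0.0
    sex_effect: float = 0.0
    tiv_mean: float = 1500.0
    tiv_sd: float = 120.0
    loading_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_weights is None:
            self.site_weights = _default_site_weights(self.n_sites)
        self.site_weights = np.asarray(self.site_weights, dtype=float)
        if self.effect_vector is None:
            self.effect_vector = np.zeros(self.n_informative)
        self.effect_vector = np.asarray(self.effect_vector, dtype=float)
        if self.site_shift is None:
            self.site_shift = np.zeros(self.n_sites)
        self.site_shift = np.asarray(self.site_shift, dtype=float)
        if self.site_scale is None:
            self.site_scale = np.ones(self.n_sites)
        self.site_scale = np.asarray(self.site_scale, dtype=float)
        if self.informative_indices is None:
            # evenly spread, independent of the seed so that companion cohorts
            # (validation, controls) plant their signal on the same columns
            self.informative_indices = np.unique(
                np.linspace(0, max(self.n_clinical - 1, 0), self.n_informative).round().astype(int)
            ) if self.n_informative else np.array([], dtype=int)
        self.informative_indices = np.asarray(self.informative_indices, dtype=int)
        self.validate()

    def validate(self) -> None:
        if abs(self.site_weights.sum() - 1.0) > 1e-12:
            raise ConfigError("site_weights must sum to 1")
        if np.any(self.site_weights < 0):
            raise ConfigError("site_weights must be non-negative")
        if len(self.site_weights) != self.n_sites:
            raise ConfigError("site_weights length must equal n_sites")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigError("prevalence must lie in (0, 1)")
        if self.n_informative > self.n_clinical:
            raise ConfigError("n_informative cannot exceed n_clinical")
        if len(self.effect_vector) != self.n_informative:
            raise ConfigError("effect_vector length must equal n_informative")
        if len(self.informative_indices) != self.n_informative:
            raise ConfigError("informative_indices length must equal n_informative")
        if self.n_informative and self.informative_indices.max() >= self.n_clinical:
            raise ConfigError("informative index out of range")
        if len(self.site_shift) != self.n_sites or len(self.site_scale) != self.n_sites:
            raise ConfigError("site effect vectors must have n_sites entries")
        if self.n_components > self.n_voxels:
            raise ConfigError("n_components cannot exceed n_voxels")


@dataclass
class SyntheticTruth:
    informative_feature_indices: np.ndarray
    component_maps: np.ndarray  # voxels x K, unit-norm columns
    subject_loadings: np.ndarray  # subjects x K
    bayes_accuracy: float
    planted_site_params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "informative_feature_indices": self.informative_feature_indices.tolist(),
                    "component_maps": self.component_maps.tolist(),
                    "subject_loadings": self.subject_loadings.tolist(),
                    "bayes_accuracy": self.bayes_accuracy,
                    "planted_site_params": {
                        k: np.asarray(v).tolist() for k, v in self.planted_site_params.items()
                    },
                },
                fh,
            )


def bayes_accuracy(effect_vector: np.ndarray) -> float:
    """Bayes accuracy of the equal-covariance two-class Gaussian model."""
    return float(norm.cdf(np.linalg.norm(effect_vector) / 2.0))


def optimal_linear_rule(truth: SyntheticTruth, config: SynthConfig, clinical: FeatureMatrix) -> np.ndarray:
    """Predictions (+1/-1) of the known-optimal linear rule on informative features."""
    idx = truth.informative_feature_indices
    scores = clinical.values[:, idx] @ config.effect_vector
    return np.where(scores > 0, 1, -1)


def _draw_covariates(rng: np.random.Generator, n: int, config: SynthConfig):
    sites = rng.choice(config.n_sites, size=n, p=config.site_weights)
    age = rng.uniform(*config.age_range, size=n)
    sex = (rng.random(n) < config.sex_ratio).astype(int)
    tiv = np.abs(rng.normal(config.tiv_mean, config.tiv_sd, size=n))
    return sites, age, sex, tiv


def _voxel_data(
    rng: np.random.Generator,
    config: SynthConfig,
    n: int,
    sites: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    component_maps: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    loadings = rng.normal(0.0, config.loading_sd, size=(n, config.n_components))
    signal = loadings @ component_maps.T
    age_c = age - np.mean(config.age_range)
    trend = config.age_slope * age_c[:, None] + config.sex_effect * sex[:, None]
    noise = rng.normal(0.0, config.noise_sd, size=(n, config.n_voxels))
    voxels = (signal + trend + noise) * config.site_scale[sites][:, None] + config.site_shift[sites][:, None]
    return voxels, loadings


def _component_maps(rng: np.random.Generator, config: SynthConfig) -> np.ndarray:
    raw = rng.standard_normal((config.n_voxels, config.n_components))
    q, _ = np.linalg.qr(raw)
    maps = q[:, : config.n_components]
    return maps / np.linalg.norm(maps, axis=0, keepdims=True)


def generate_cohort(config: SynthConfig):
    """Generate a full multimodal cohort.

    Returns ``(clinical, cognitive, voxels, labels, sites, covariates, truth)``
    where labels are +1 (positive outcome class) / -1, sites are integer
    labels, and covariates is a DataFrame with id/site/age/sex/tiv/label.
    """
    from .imgprep import VoxelMatrix  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    labels = np.where(rng.random(n) < config.prevalence, 1, -1)
    sites, age, sex, tiv = _draw_covariates(rng, n, config)

    informative = config.informative_indices
    clinical_vals = rng.standard_normal((n, config.n_clinical))
    shift = np.zeros((n, config.n_informative))
    shift[labels == 1] = 0.5 * config.effect_vector
    shift[labels == -1] = -0.5 * config.effect_vector
    clinical_vals[:, informative] += shift
    if config.n_binary_clinical:
        nb = min(config.n_binary_clinical, config.n_clinical)
        binary_cols = np.arange(config.n_clinical - nb, config.n_clinical)
        binary_cols = np.setdiff1d(binary_cols, informative)
        clinical_vals[:, binary_cols] = (clinical_vals[:, binary_cols] > 0).astype(float)

    cognitive_vals = rng.standard_normal((n, config.n_cognitive))

    component_maps = _component_maps(rng, config)
    voxel_vals, loadings = _voxel_data(rng, config, n, sites, age, sex, component_maps)

    clinical = FeatureMatrix.from_values(
        clinical_vals, [f"clin_{j}" for j in range(config.n_clinical)], "clinical"
    )
    cognitive = FeatureMatrix.from_values(
        cognitive_vals, [f"cog_{j}" for j in range(config.n_cognitive)], "cognitive"
    )
    voxels = VoxelMatrix(values=voxel_vals, subjects=[f"s{i}" for i in range(n)])
    covariates = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "site": sites,
            "age": age,
            "sex": sex,
            "tiv": tiv,
            "label": labels,
        }
    )
    truth = SyntheticTruth(
        informative_feature_indices=informative,
        component_maps=component_maps,
        subject_loadings=loadings,
        bayes_accuracy=bayes_accuracy(config.effect_vector),
        planted_site_params={"shift": config.site_shift, "scale": config.site_scale},
    )
    return clinical, cognitive, voxels, labels, sites, covariates, truth


def generate_validation_cohort(config: SynthConfig, n_subjects: int, effect_multiplier: float = 0.5, seed: int | None = None):
    """A second cohort with attenuated planted effects (generalization drop)."""
    cfg = dataclasses.replace(
        config,
        n_subjects=n_subjects,
        effect_vector=config.effect_vector * effect_multiplier,
        seed=config.seed + 104729 if seed is None else seed,
    )
    return generate_cohort(cfg)


def generate_reference_controls(config: SynthConfig, n_controls: int, seed: int | None = None):
    """Control sample sharing site effects and covariate trends, no outcome signal.

    Site allocation is deterministic-ish: expected counts per site rounded,
    with a floor of 2 controls per site so that per-site variances are
    estimable.  Components reuse the cohort's planted maps (same generator
    stream layout as :func:`generate_cohort`).
    """
    from .imgprep import VoxelMatrix

    config.validate()
    if n_controls < 2 * config.n_sites:
        raise ConfigError("need at least 2 controls per site")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    counts = np.maximum(2, np.round(config.site_weights * n_controls).astype(int))
    while counts.sum() > n_controls:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_controls:
        counts[np.argmax(config.site_weights)] += 1
    if counts.min() < 2:
        raise ConfigError("site allocation left a site with fewer than 2 controls")
    sites = np.repeat(np.arange(config.n_sites), counts)

    n = int(counts.sum())
    age = rng.uniform(*config.age_range, size=n)
    sex = (rng.random(n) < config.sex_ratio).astype(int)
    tiv = np.abs(rng.normal(config.tiv_mean, config.tiv_sd, size=n))

    # same component maps as the patient cohort: replay the cohort stream
    cohort_rng = np.random.default_rng(config.seed)
    cohort_rng.random(config.n_subjects)  # labels draw
    _draw_covariates(cohort_rng, config.n_subjects, config)
    cohort_rng.standard_normal((config.n_subjects, config.n_clinical))
    cohort_rng.standard_normal((config.n_subjects, config.n_cognitive))
    component_maps = _component_maps(cohort_rng, config)

    voxel_vals, _ = _voxel_data(rng, config, n, sites, age, sex, component_maps)
    voxels = VoxelMatrix(values=voxel_vals, subjects=[f"hc{i}" for i in range(n)])
    covariates = pd.DataFrame(
        {"id": voxels.subjects, "site": sites, "age": age, "sex": sex, "tiv": tiv}
    )
    return voxels, sites, covariates


def inject_missingness(matrix: FeatureMatrix, rates, seed: int) -> FeatureMatrix:
    """Set entries missing completely at random, per-feature probability ``rates``."""
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (matrix.n_features,))
    if np.any(rates < 0) or np.any(rates >= 1):
        raise ConfigError("missingness rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    drop = rng.random(matrix.values.shape) < rates[None, :]
    values = matrix.values.copy()
    values[drop] = np.nan
    return FeatureMatrix(
        values=values,
        mask=matrix.mask & ~drop,
        feature_names=list(matrix.feature_names),
        modality=matrix.modality,
    )


def write_cohort(outdir, clinical, cognitive, voxels, covariates, truth) -> None:
    """Persist a cohort: CSV tables, 4-D NIfTI voxel stack, JSON truth."""
    import pathlib

    import nibabel as nib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(outdir / "clinical.csv")
    cognitive.to_csv(outdir / "cognitive.csv")
    covariates.to_csv(outdir / "subjects.csv", index=False)
    truth.to_json(outdir / "truth.json")
    vols = voxels.values.T[:, None, None, :]  # voxels arranged on a line
    nib.save(nib.Nifti1Image(vols.astype(np.float32), np.eye(4)), str(outdir / "voxels.nii"))
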