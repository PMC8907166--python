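"""Fold-wise preprocessing of tabular feature matrices.

The pipeline applied to every training fold is, in order:

1. robust standardization around the per-feature median,
2. 7-nearest-neighbour imputation of missing entries,
3. pruning of non-informative features (zero variance, non-finite values),
4. min-max scaling of the surviving features to [0, 1].

All statistics are estimated from the training fold only; ``apply_preproc``
pushes any other matrix through the frozen transform.  Out-of-range test
values are clamped into [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MODALITIES = ("clinical", "cognitive", "image_components", "stacked_scores")


class PreprocError(ValueError):
    """Raised for degenerate folds or contract violations."""


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with an explicit observedness mask.

    ``mask`` is True where a value was observed.  Unobserved entries hold
    NaN.  Observed entries may be non-finite (e.g. inf); such features are
    discarded by pruning.
    """

    values: np.ndarray
    mask: np.ndarray
    feature_names: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise PreprocError("values must be 2-D (subjects x features)")
        if self.values.shape != self.mask.shape:
            raise PreprocError("mask shape must match values shape")
        if len(self.feature_names) != self.values.shape[1]:
            raise PreprocError("feature_names length must match column count")
        if self.modality not in MODALITIES:
            raise PreprocError(f"unknown modality {self.modality!r}")

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        feature_names: Sequence[str] | None = None,
        modality: str = "clinical",
    ) -> "FeatureMatrix":
        values = np.asarray(values, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(values.shape[1])]
        mask = ~np.isnan(values)
        return cls(values=values, mask=mask, feature_names=list(feature_names), modality=modality)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[rows],
            mask=self.mask[rows],
            feature_names=list(self.feature_names),
            modality=self.modality,
        )

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[~self.mask] = np.nan
        return pd.DataFrame(vals, columns=self.feature_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, modality: str = "clinical") -> "FeatureMatrix":
        df = pd.read_csv(path)
        return cls.from_values(df.to_numpy(dtype=float), list(df.columns), modality)


@dataclass
class PreprocModel:
    """Frozen fold-wise preprocessing transform."""

    center: np.ndarray
    spread: np.ndarray
    keep_mask: np.ndarray
    minmax_lo: np.ndarray
    minmax_hi: np.ndarray
    feature_names: list[str]
    modality: str
    knn_k: int = 7
    # standardized training matrix with NaN at unobserved entries; neighbour
    # lookups for imputation run against this reference
    training_reference: np.ndarray = field(default=None, repr=False)

    @property
    def kept_feature_names(self) -> list[str]:
        return [n for n, k in zip(self.feature_names, self.keep_mask) if k]

    def to_json(self, path) -> None:
        payload = {
            "center": self.center.tolist(),
            "spread": self.spread.tolist(),
            "keep_mask": self.keep_mask.tolist(),
            "minmax_lo": self.minmax_lo.tolist(),
            "minmax_hi": self.minmax_hi.tolist(),
            "feature_names": self.feature_names,
            "modality": self.modality,
            "knn_k": self.knn_k,
            "training_reference": np.where(
                np.isnan(self.training_reference), None, self.training_reference
            ).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PreprocModel":
        with open(path) as fh:
            payload = json.load(fh)
        ref = np.array(
            [[np.nan if v is None else v for v in row] for row in payload["training_reference"]],
            dtype=float,
        )
        return cls(
            center=np.asarray(payload["center"], dtype=float),
            spread=np.asarray(payload["spread"], dtype=float),
            keep_mask=np.asarray(payload["keep_mask"], dtype=bool),
            minmax_lo=np.asarray(payload["minmax_lo"], dtype=float),
            minmax_hi=np.asarray(payload["minmax_hi"], dtype=float),
            feature_names=list(payload["feature_names"]),
            modality=payload["modality"],
            knn_k=int(payload["knn_k"]),
            training_reference=ref,
        )


def _robust_location_scale(values: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median and IQR per feature; IQR falls back to MAD, then to 1.0."""
    n, d = values.shape
    center = np.zeros(d)
    spread = np.ones(d)
    for j in range(d):
        col = values[observed[:, j], j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            continue
        center[j] = np.median(col)
        iqr = np.percentile(col, 75) - np.percentile(col, 25)
        if iqr > 0:
            spread[j] = iqr
        else:
            mad = np.median(np.abs(col - center[j]))
            spread[j] = mad if mad > 0 else 1.0
    return center, spread


def _knn_impute(reference: np.ndarray, target: np.ndarray, k: int) -> np.ndarray:
    """Impute NaN entries of ``target`` from the ``reference`` rows.

    Distance between a target row and a reference row is the mean squared
    difference over features observed in both (non-finite entries count as
    unobserved).  For each missing entry the value is the mean of that
    feature over the k nearest reference rows observing it; ties break by
    reference row index.  A row sharing no observed feature with any
    candidate falls back to the standardized median (zero).
    """
    ref_obs = np.isfinite(reference)
    tgt_obs = np.isfinite(target)
    out = target.copy()
    n_ref = reference.shape[0]
    ref_filled = np.where(ref_obs, reference, 0.0)

    for i in range(target.shape[0]):
        missing = np.flatnonzero(~tgt_obs[i])
        if missing.size == 0:
            continue
        t_obs = tgt_obs[i]
        t_filled = np.where(t_obs, target[i], 0.0)
        shared = ref_obs & t_obs[None, :]
        n_shared = shared.sum(axis=1)
        diff = (ref_filled - t_filled[None, :]) ** 2
        sq = np.where(shared, diff, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(n_shared > 0, sq / np.maximum(n_shared, 1), np.inf)
        for j in missing:
            cand = np.flatnonzero(ref_obs[:, j] & np.isfinite(dist))
            if cand.size == 0:
                out[i, j] = 0.0
                continue
            order = cand[np.lexsort((cand, dist[cand]))]
            chosen = order[: min(k, order.size)]
            out[i, j] = reference[chosen, j].mean()
    return out


def fit_preproc(train: FeatureMatrix, knn_k: int = 7) -> PreprocModel:
    """Fit the standardize -> impute -> prune -> scale pipeline on a training fold."""
    if train.n_subjects < 2:
        raise PreprocError("need at least 2 training subjects")
    values, observed = train.values, train.mask & np.isfinite(train.values)

    center, spread = _robust_location_scale(values, observed)
    z = np.where(train.mask, (values - center) / spread, np.nan)

    z_imp = _knn_impute(z, z, knn_k)

    keep = np.zeros(train.n_features, dtype=bool)
    for j in range(train.n_features):
        col_raw = values[train.mask[:, j], j]
        if col_raw.size == 0:
            continue
        if not np.all(np.isfinite(col_raw)):
            continue  # "infinity" pruning rule
        if np.nanvar(col_raw) == 0:
            continue  # zero-variance pruning rule
        keep[j] = True
    if not keep.any():
        raise PreprocError("degenerate fold: all features pruned")

    lo = np.nanmin(np.where(np.isfinite(z_imp), z_imp, np.nan), axis=0)
    hi = np.nanmax(np.where(np.isfinite(z_imp), z_imp, np.nan), axis=0)
    lo = np.where(np.isfinite(lo), lo, 0.0)
    hi = np.where(np.isfinite(hi), hi, 1.0)
    bad = keep & ~(hi > lo)
    keep[bad] = False
    if not keep.any():
        raise PreprocError("degenerate fold: all features pruned")

    return PreprocModel(
        center=center,
        spread=spread,
        keep_mask=keep,
        minmax_lo=lo,
        minmax_hi=hi,
        feature_names=list(train.feature_names),
        modality=train.modality,
        knn_k=knn_k,
        training_reference=z,
    )


def apply_preproc(model: PreprocModel, data: FeatureMatrix) -> FeatureMatrix:
    """Apply a frozen preprocessing model; output values all lie in [0, 1]."""
    if list(data.feature_names) != list(model.feature_names):
        raise PreprocError("feature names do not match the fitted model")
    z = np.where(data.mask, (data.values - model.center) / model.spread, np.nan)
    z = np.where(np.isfinite(z) | np.isnan(z), z, np.nan)  # inf -> treated as missing
    z_imp = _knn_impute(model.training_reference, z, model.knn_k)

    keep = model.keep_mask
    lo, hi = model.minmax_lo[keep], model.minmax_hi[keep]
    scaled = (z_imp[:, keep] - lo) / (hi - lo)
    scaled = np.clip(scaled, 0.0, 1.0)
    return FeatureMatrix(
        values=scaled,
        mask=np.ones_like(scaled, dtype=bool),
        feature_names=model.kept_feature_names,
        modality=data.modality,
    )
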