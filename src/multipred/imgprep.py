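"""Imaging branch: voxel-level corrections and reference-guided ICA.

Order of operations for a patient cohort, each transform fitted on a
separate control sample and frozen before it touches patients:

1. proportional scaling by total intracranial volume,
2. reliability mask discarding voxels whose variance is site-only,
3. empirical-Bayes location/scale site harmonization,
4. age/sex residualization using control-derived betas,
5. reference-guided ICA producing per-subject component loadings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tabprep import FeatureMatrix


class ImagePrepError(ValueError):
    pass


@dataclass
class VoxelMatrix:
    """Subjects x voxels matrix of volume-like values."""

    values: np.ndarray
    subjects: list[str] | None = None
    voxel_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] == 0:
            raise ImagePrepError("values must be 2-D with at least one voxel")
        if not np.all(np.isfinite(self.values)):
            raise ImagePrepError("voxel values must be finite")
        if self.subjects is None:
            self.subjects = [f"s{i}" for i in range(self.values.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_nifti(cls, path) -> "VoxelMatrix":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ImagePrepError("expected a 4-D image (one volume per subject)")
        n = data.shape[3]
        return cls(values=data.reshape(-1, n).T)


@dataclass
class ReliabilityMask:
    g_coefficient: np.ndarray
    keep: np.ndarray
    threshold: float

    def apply(self, voxels: VoxelMatrix) -> VoxelMatrix:
        return VoxelMatrix(values=voxels.values[:, self.keep], subjects=list(voxels.subjects))


@dataclass
class HarmonizationModel:
    site_labels: np.ndarray
    feature_grand_mean: np.ndarray  # per-voxel alpha
    feature_scale: np.ndarray  # per-voxel pooled sd
    covariate_names: list[str]
    design_betas: np.ndarray  # covariates x voxels
    covariate_means: np.ndarray
    gamma_star: np.ndarray  # sites x voxels
    delta_star: np.ndarray  # sites x voxels, variances
    prior_hyperparams: dict = field(default_factory=dict)


@dataclass
class ReferenceComponents:
    maps: np.ndarray  # voxels x K, unit-norm columns
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[1] < 1:
            raise ImagePrepError("reference maps must be voxels x K with K >= 1")
        norms = np.linalg.norm(self.maps, axis=0)
        if np.any(norms == 0):
            raise ImagePrepError("reference maps must be nonzero")
        self.maps = self.maps / norms
        if self.names is None:
            self.names = [f"ic_{k}" for k in range(self.maps.shape[1])]


class GigIcaError(RuntimeError):
    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# TIV scaling


def scale_tiv(voxels: VoxelMatrix, tiv: np.ndarray, reference: float | None = None) -> VoxelMatrix:
    """Divide each subject's voxels by its TIV, rescaled to the cohort mean TIV."""
    tiv = np.asarray(tiv, dtype=float)
    if np.any(tiv <= 0):
        raise ImagePrepError("TIV must be positive for every subject")
    if tiv.shape[0] != voxels.n_subjects:
        raise ImagePrepError("one TIV per subject required")
    ref = float(np.mean(tiv)) if reference is None else float(reference)
    return VoxelMatrix(values=voxels.values / tiv[:, None] * ref, subjects=list(voxels.subjects))


# ---------------------------------------------------------------------------
# g-theory reliability mask


def _site_counts(sites: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, counts = np.unique(sites, return_counts=True)
    return labels, counts


def fit_gtheory_mask(controls: VoxelMatrix, sites: np.ndarray, threshold: float = 0.8) -> ReliabilityMask:
    """One-way random-effects variance decomposition per voxel.

    g = sigma2_subject / (sigma2_subject + sigma2_site); voxels with
    g <= threshold are discarded (site-only variance gives g = 0).
    """
    sites = np.asarray(sites)
    labels, counts = _site_counts(sites)
    if len(labels) < 2:
        raise ImagePrepError("need at least 2 sites")
    if counts.min() < 2:
        raise ImagePrepError("every site needs at least 2 subjects")
    X = controls.values
    N, k = X.shape[0], len(labels)

    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for lab, n_i in zip(labels, counts):
        rows = X[sites == lab]
        m_i = rows.mean(axis=0)
        ssb += n_i * (m_i - grand) ** 2
        ssw += ((rows - m_i) ** 2).sum(axis=0)
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - (counts**2).sum() / N) / (k - 1)
    sigma2_site = np.maximum(0.0, (msb - msw) / n0)
    sigma2_subj = msw
    denom = sigma2_subj + sigma2_site
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(denom > 0, sigma2_subj / denom, 0.0)
    return ReliabilityMask(g_coefficient=g, keep=g > threshold, threshold=threshold)


# ---------------------------------------------------------------------------
# empirical-Bayes site harmonization (parametric priors)


def _design_matrices(sites: np.ndarray, covariates: pd.DataFrame, site_labels: np.ndarray, covariate_names):
    onehot = (sites[:, None] == site_labels[None, :]).astype(float)
    cov = covariates[list(covariate_names)].to_numpy(dtype=float)
    return onehot, cov


def fit_combat(
    controls: VoxelMatrix,
    sites: np.ndarray,
    covariates: pd.DataFrame,
    covariate_names=("age", "sex"),
    max_iter: int = 500,
    tol: float = 1e-6,
) -> HarmonizationModel:
    """Fit parametric empirical-Bayes harmonization on a control sample.

    Per-voxel model: x = alpha + covariates.beta + gamma_site + delta_site * eps.
    Site parameters are shrunk toward normal / inverse-gamma priors with the
    standard iterative conditional update.
    """
    sites = np.asarray(sites)
    labels, counts = _site_counts(sites)
    if counts.min() < 2:
        raise ImagePrepError("every site needs at least 2 control subjects")
    X = controls.values
    N, V = X.shape
    onehot, cov = _design_matrices(sites, covariates, labels, covariate_names)
    cov_means = cov.mean(axis=0)
    covc = cov - cov_means
    design = np.hstack([onehot, covc])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ImagePrepError("singular design (collinear covariates or empty site)")

    beta_full, *_ = np.linalg.lstsq(design, X, rcond=None)
    site_effects = beta_full[: len(labels)]  # sites x V (include intercepts)
    cov_betas = beta_full[len(labels):]  # covariates x V

    alpha = (counts / N) @ site_effects
    fitted = design @ beta_full
    var_pooled = ((X - fitted) ** 2).mean(axis=0)
    if np.any(var_pooled <= 0):
        raise ImagePrepError("zero residual variance voxel; prune before harmonizing")
    scale = np.sqrt(var_pooled)

    stand = (X - alpha[None, :] - covc @ cov_betas) / scale[None, :]

    k = len(labels)
    gamma_hat = np.zeros((k, V))
    delta_hat = np.zeros((k, V))
    for idx, lab in enumerate(labels):
        rows = stand[sites == lab]
        gamma_hat[idx] = rows.mean(axis=0)
        delta_hat[idx] = ((rows - gamma_hat[idx]) ** 2).mean(axis=0)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1)
    d_mean = delta_hat.mean(axis=1)
    d_var = delta_hat.var(axis=1)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    priors = {"gamma_bar": gamma_bar, "tau2": tau2, "lambda": np.zeros(k), "theta": np.zeros(k)}
    for i, (lab, n_i) in enumerate(zip(labels, counts)):
        g_hat, d_hat = gamma_hat[i], delta_hat[i]
        if tau2[i] <= 1e-12 and d_var[i] <= 1e-12:
            # degenerate priors (e.g. single site): no shrinkage possible
            gamma_star[i], delta_star[i] = g_hat, d_hat
            continue
        lam = (2 * d_var[i] + d_mean[i] ** 2) / d_var[i] if d_var[i] > 1e-12 else np.inf
        theta = (d_mean[i] * d_var[i] + d_mean[i] ** 3) / d_var[i] if d_var[i] > 1e-12 else 0.0
        priors["lambda"][i], priors["theta"][i] = lam, theta
        g_star, d_star = g_hat.copy(), d_hat.copy()
        rows = stand[sites == lab]
        for _ in range(max_iter):
            if tau2[i] > 1e-12:
                g_new = (n_i * tau2[i] * g_hat + d_star * gamma_bar[i]) / (n_i * tau2[i] + d_star)
            else:
                g_new = np.full(V, gamma_bar[i])
            sse = ((rows - g_new[None, :]) ** 2).sum(axis=0)
            if np.isfinite(lam):
                d_new = (theta + 0.5 * sse) / (n_i / 2.0 + lam - 1.0)
            else:
                d_new = d_hat
            change = max(np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max())
            g_star, d_star = g_new, d_new
            if change < tol:
                break
        gamma_star[i], delta_star[i] = g_star, d_star
    if np.any(delta_star <= 0):
        raise ImagePrepError("non-positive harmonization scale estimate")

    return HarmonizationModel(
        site_labels=labels,
        feature_grand_mean=alpha,
        feature_scale=scale,
        covariate_names=list(covariate_names),
        design_betas=cov_betas,
        covariate_means=cov_means,
        gamma_star=gamma_star,
        delta_star=delta_star,
        prior_hyperparams=priors,
    )


def apply_combat(
    model: HarmonizationModel,
    data: VoxelMatrix,
    sites: np.ndarray,
    covariates: pd.DataFrame,
) -> VoxelMatrix:
    """Out-of-sample harmonization with frozen site adjustments."""
    sites = np.asarray(sites)
    unseen = np.setdiff1d(np.unique(sites), model.site_labels)
    if unseen.size:
        raise ImagePrepError(f"no harmonization parameters for site(s) {unseen.tolist()}")
    cov = covariates[model.covariate_names].to_numpy(dtype=float) - model.covariate_means
    X = data.values
    biological = model.feature_grand_mean[None, :] + cov @ model.design_betas
    stand = (X - biological) / model.feature_scale[None, :]
    site_idx = np.searchsorted(model.site_labels, sites)
    adjusted = (stand - model.gamma_star[site_idx]) / np.sqrt(model.delta_star[site_idx])
    out = adjusted * model.feature_scale[None, :] + biological
    return VoxelMatrix(values=out, subjects=list(data.subjects))


# ---------------------------------------------------------------------------
# covariate residualization from control betas


@dataclass
class ResidualizeModel:
    betas: np.ndarray  # covariates x voxels
    covariate_names: list[str]
    covariate_means: np.ndarray


def fit_covariate_betas(
    controls: VoxelMatrix, covariates: pd.DataFrame, covariate_names=("age", "sex")
) -> ResidualizeModel:
    """Per-voxel OLS betas of the covariates, fitted on controls."""
    cov = covariates[list(covariate_names)].to_numpy(dtype=float)
    means = cov.mean(axis=0)
    design = np.hstack([np.ones((cov.shape[0], 1)), cov - means])
    beta, *_ = np.linalg.lstsq(design, controls.values, rcond=None)
    return ResidualizeModel(
        betas=beta[1:], covariate_names=list(covariate_names), covariate_means=means
    )


def residualize_age_sex(model: ResidualizeModel, data: VoxelMatrix, covariates: pd.DataFrame) -> VoxelMatrix:
    """Subtract control-derived covariate effects; the mean level is retained."""
    for name in model.covariate_names:
        if covariates[name].isna().any():
            raise ImagePrepError(f"missing covariate {name!r} for some subject")
    cov = covariates[model.covariate_names].to_numpy(dtype=float) - model.covariate_means
    return VoxelMatrix(values=data.values - cov @ model.betas, subjects=list(data.subjects))


# ---------------------------------------------------------------------------
# reference-guided ICA

_NEGENTROPY_CONST = 0.3745672075244098  # E[log cosh(Z)], Z standard normal


def _logcosh_negentropy(y: np.ndarray) -> tuple[float, np.ndarray]:
    g = np.log(np.cosh(y))
    diff = g.mean() - _NEGENTROPY_CONST
    return diff**2, 2.0 * diff * np.tanh(y) / y.size


def gig_ica(
    data: VoxelMatrix,
    refs: ReferenceComponents,
    similarity_weight: float = 0.5,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract one component per reference by projected gradient ascent.

    Objective for unit unmixing vector w in the whitened subject space:
    ``a * corr(component, ref)^2 + (1 - a) * negentropy_proxy(component)``,
    with deflation against previously extracted components.  Component signs
    are fixed so that corr(component, ref) >= 0.

    Returns ``(components, loadings)``: components is voxels x K with
    unit-norm columns; loadings (subjects x K) are least-squares mixing
    weights and serve as the ``image_components`` feature matrix.
    """
    if not (0.0 < similarity_weight < 1.0):
        raise ImagePrepError("similarity_weight must lie in (0, 1)")
    K = refs.maps.shape[1]
    X = data.values
    n, V = X.shape
    if refs.maps.shape[0] != V:
        raise ImagePrepError("reference maps and data voxel counts differ")
    if K > min(n - 1, V):
        raise ImagePrepError("more references than extractable components")

    Xc = X - X.mean(axis=0, keepdims=True)  # center per voxel
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    r = min(n - 1, 5 * K, int((s > s[0] * 1e-10).sum()))
    Y = Vt[:r]  # r x V, orthonormal spatial basis
    sqrtV = np.sqrt(V)

    a = similarity_weight
    W = np.zeros((K, r))
    comps = np.zeros((V, K))
    trace = []

    for kk in range(K):
        ref = refs.maps[:, kk]
        refc = ref - ref.mean()
        refc = refc / np.linalg.norm(refc)
        Yr = Y @ refc  # gradient direction of similarity
        row_means = Y.mean(axis=1)

        def project(w):
            if kk:
                w = w - W[:kk].T @ (W[:kk] @ w)
            nrm = np.linalg.norm(w)
            if nrm == 0:
                raise GigIcaError("deflation collapsed the unmixing vector", trace)
            return w / nrm

        def objective_grad(w):
            y = w @ Y  # unit-norm V-vector
            mu = y.mean()
            yc = y - mu
            nyc = np.linalg.norm(yc)
            corr = float(yc @ refc / nyc)
            # d corr / dw
            g_corr = (Yr - row_means * (refc.sum() / V)) / nyc - corr * (Y @ yc) / nyc**2
            neg, g_y = _logcosh_negentropy(y * sqrtV)
            g_neg = (Y * sqrtV) @ g_y
            obj = a * corr**2 + (1 - a) * neg
            grad = a * 2 * corr * g_corr + (1 - a) * g_neg
            return obj, grad, corr

        w = project(Yr.copy())
        obj, grad, corr = objective_grad(w)
        step = 1.0
        converged = False
        for it in range(max_iter):
            cand = project(w + step * grad)
            obj_new, grad_new, corr_new = objective_grad(cand)
            if obj_new < obj - 1e-14:
                step *= 0.5
                if step < 1e-12:
                    converged = True
                    break
                continue
            delta = 1.0 - abs(float(w @ cand))
            w, obj, grad, corr = cand, obj_new, grad_new, corr_new
            step = min(step * 1.5, 10.0)
            trace.append({"component": kk, "iter": it, "objective": obj})
            if delta < tol:
                converged = True
                break
        if not converged:
            raise GigIcaError(f"component {kk} did not converge in {max_iter} iterations", trace)
        y = w @ Y
        if (y - y.mean()) @ refc < 0:
            w, y = -w, -y
        W[kk] = w
        comps[:, kk] = y / np.linalg.norm(y)

    loadings, *_ = np.linalg.lstsq(comps, Xc.T, rcond=None)
    return comps, loadings.T


def loadings_to_features(loadings: np.ndarray, names=None) -> FeatureMatrix:
    if names is None:
        names = [f"ic_{k}" for k in range(loadings.shape[1])]
    return FeatureMatrix.from_values(loadings, names, "image_components")


def export_mask_nifti(mask: ReliabilityMask, shape, path) -> None:
    import nibabel as nib

    vol = np.zeros(int(np.prod(shape)), dtype=np.float32)
    vol[: mask.g_coefficient.size] = mask.g_coefficient
    nib.save(nib.Nifti1Image(vol.reshape(shape), np.eye(4)), str(path))


def harmonization_to_json(model: HarmonizationModel, path) -> None:
    payload = {
        "site_labels": model.site_labels.tolist(),
        "feature_grand_mean": model.feature_grand_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "covariate_names": model.covariate_names,
        "design_betas": model.design_betas.tolist(),
        "covariate_means": model.covariate_means.tolist(),
        "gamma_star": model.gamma_star.tolist(),
        "delta_star": model.delta_star.tolist(),
        "prior_hyperparams": {k: np.asarray(v).tolist() for k, v in model.prior_hyperparams.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
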