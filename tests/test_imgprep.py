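import numpy as np
import pandas as pd
import pytest

from multipred import imgprep as ip
from multipred import synthcohort as sc
from multipred.imgprep import (
    ImagePrepError,
    ReferenceComponents,
    VoxelMatrix,
    apply_combat,
    fit_combat,
    fit_covariate_betas,
    fit_gtheory_mask,
    gig_ica,
    residualize_age_sex,
    scale_tiv,
)


def _covariates(rng, n, age=None, sex=None):
    return pd.DataFrame(
        {
            "age": rng.uniform(18, 40, n) if age is None else age,
            "sex": (rng.random(n) < 0.5).astype(int) if sex is None else sex,
        }
    )


class TestScaleTiv:
    def test_equal_tivs_identity(self, rng):
        v = VoxelMatrix(values=rng.normal(size=(10, 20)))
        out = scale_tiv(v, np.full(10, 1500.0))
        np.testing.assert_allclose(out.values, v.values)

    def test_double_mean_tiv_halves(self, rng):
        vals = rng.normal(size=(3, 5))
        tiv = np.array([1.0, 1.0, 4.0])  # mean 2.0 -> subject 2 has tiv = 2x mean
        out = scale_tiv(VoxelMatrix(values=vals), tiv)
        np.testing.assert_allclose(out.values[2], vals[2] / 2.0)

    def test_invariant_under_common_tiv_rescaling(self, rng):
        vals = rng.normal(size=(6, 10))
        tiv = rng.uniform(1200, 1800, 6)
        a = scale_tiv(VoxelMatrix(values=vals), tiv)
        b = scale_tiv(VoxelMatrix(values=vals), 2.0 * tiv)
        np.testing.assert_allclose(a.values, b.values)

    def test_nonpositive_tiv_rejected(self, rng):
        with pytest.raises(ImagePrepError):
            scale_tiv(VoxelMatrix(values=rng.normal(size=(2, 3))), np.array([1.0, 0.0]))


class TestGTheoryMask:
    def test_site_only_variance_excluded(self, rng):
        sites = np.repeat([0, 1, 2], 40)
        vals = rng.normal(size=(120, 3))
        vals[:, 0] = np.array([0.0, 5.0, -3.0])[sites]  # identical within site
        mask = fit_gtheory_mask(VoxelMatrix(values=vals), sites, threshold=0.8)
        assert mask.g_coefficient[0] == 0.0
        assert not mask.keep[0]
        assert mask.keep[1] and mask.keep[2]

    def test_iid_voxel_approaches_one(self, rng):
        sites = np.repeat([0, 1, 2], 100)
        vals = rng.normal(size=(300, 20))
        mask = fit_gtheory_mask(VoxelMatrix(values=vals), sites, threshold=0.8)
        assert np.all(mask.g_coefficient >= 0.9)

    def test_sums_of_squares_oracle(self, rng):
        # brute-force two-loop ANOVA on a 3-site, 5-subject-per-site toy
        sites = np.repeat([0, 1, 2], 5)
        vals = rng.normal(size=(15, 4)) + np.array([0.0, 1.0, -1.0])[sites][:, None]
        mask = fit_gtheory_mask(VoxelMatrix(values=vals), sites, threshold=0.5)
        N, k = 15, 3
        for v in range(4):
            x = vals[:, v]
            grand = x.mean()
            ssb = ssw = 0.0
            for s in range(3):
                grp = x[sites == s]
                ssb += len(grp) * (grp.mean() - grand) ** 2
                for val in grp:
                    ssw += (val - grp.mean()) ** 2
            msb, msw = ssb / (k - 1), ssw / (N - k)
            n0 = (N - (3 * 5**2) / N) / (k - 1)
            s2site = max(0.0, (msb - msw) / n0)
            g = msw / (msw + s2site)
            assert mask.g_coefficient[v] == pytest.approx(g)

    def test_singleton_site_errors(self, rng):
        sites = np.array([0, 0, 1])
        with pytest.raises(ImagePrepError):
            fit_gtheory_mask(VoxelMatrix(values=rng.normal(size=(3, 2))), sites)


def _two_site_controls(rng, n_per_site=100, n_vox=500, shift=0.8, scale=1.5, age_slope=0.0):
    sites = np.repeat([0, 1], n_per_site)
    cov = _covariates(rng, 2 * n_per_site)
    base = rng.normal(size=(2 * n_per_site, n_vox))
    base += age_slope * (cov["age"].to_numpy()[:, None] - 29.0)
    vals = base.copy()
    vals[sites == 1] = vals[sites == 1] * scale + shift
    return VoxelMatrix(values=vals), sites, cov


class TestCombat:
    def test_single_site_identity(self, rng):
        sites = np.zeros(50, dtype=int)
        cov = _covariates(rng, 50)
        v = VoxelMatrix(values=rng.normal(size=(50, 40)))
        model = fit_combat(v, sites, cov)
        out = apply_combat(model, v, sites, cov)
        np.testing.assert_allclose(out.values, v.values, atol=1e-8)

    def test_planted_shift_and_scale_recovered(self, rng):
        v, sites, cov = _two_site_controls(rng)
        model = fit_combat(v, sites, cov)
        harmonized = apply_combat(model, v, sites, cov)
        raw_gap = v.values[sites == 1].mean() - v.values[sites == 0].mean()
        est_shift = (
            model.gamma_star[1] * model.feature_scale
        ).mean() - (model.gamma_star[0] * model.feature_scale).mean()
        assert abs(raw_gap - 0.8) < 0.1  # planted shift present in raw data
        assert abs(est_shift - raw_gap) < 0.1
        sd0 = harmonized.values[sites == 0].std()
        sd1 = harmonized.values[sites == 1].std()
        raw_ratio = v.values[sites == 1].std() / v.values[sites == 0].std()
        assert abs(raw_ratio - 1.5) < 0.15
        assert abs(sd1 / sd0 - 1.0) < 0.1  # scale effect removed

    def test_site_mean_gap_reduced_fivefold(self, rng):
        v, sites, cov = _two_site_controls(rng)
        model = fit_combat(v, sites, cov)
        harmonized = apply_combat(model, v, sites, cov)
        gap_before = abs(v.values[sites == 1].mean() - v.values[sites == 0].mean())
        gap_after = abs(
            harmonized.values[sites == 1].mean() - harmonized.values[sites == 0].mean()
        )
        assert gap_after < gap_before / 5.0

    def test_no_site_effect_minimal_alteration(self, rng):
        v, sites, cov = _two_site_controls(rng, shift=0.0, scale=1.0)
        model = fit_combat(v, sites, cov)
        out = apply_combat(model, v, sites, cov)
        rms = np.sqrt(((out.values - v.values) ** 2).mean())
        assert rms < 0.1

    def test_age_slope_preserved(self, rng):
        # scale=1 so the planted covariate trend is identical across sites
        v, sites, cov = _two_site_controls(rng, shift=0.8, scale=1.0, age_slope=0.05)
        model = fit_combat(v, sites, cov)
        out = apply_combat(model, v, sites, cov)
        age = cov["age"].to_numpy()
        agec = age - age.mean()
        slope = (agec @ out.values).mean() / (agec @ agec)
        assert abs(slope - 0.05) < 0.005  # within 10%

    def test_deterministic_and_unseen_site(self, rng):
        v, sites, cov = _two_site_controls(rng, n_per_site=30, n_vox=50)
        model = fit_combat(v, sites, cov)
        a = apply_combat(model, v, sites, cov)
        b = apply_combat(model, v, sites, cov)
        np.testing.assert_array_equal(a.values, b.values)
        with pytest.raises(ImagePrepError):
            apply_combat(model, v, np.full_like(sites, 9), cov)

    def test_singular_design_errors(self, rng):
        sites = np.repeat([0, 1], 10)
        cov = _covariates(rng, 20)
        cov["sex"] = cov["age"]  # collinear
        with pytest.raises(ImagePrepError):
            fit_combat(VoxelMatrix(values=rng.normal(size=(20, 5))), sites, cov)

    def test_site_classifier_at_chance_after_harmonization(self, rng):
        from sklearn.model_selection import cross_val_score
        from sklearn.svm import LinearSVC

        v, sites, cov = _two_site_controls(rng, n_per_site=60, n_vox=100, shift=0.5, scale=1.2)
        model = fit_combat(v, sites, cov)
        out = apply_combat(model, v, sites, cov)
        acc = cross_val_score(LinearSVC(C=1.0), out.values, sites, cv=5).mean()
        # 2 balanced classes: chance 0.5, binomial 95% band half-width ~0.09 at n=120
        assert acc < 0.62


class TestResidualize:
    def test_zero_betas_identity(self, rng):
        controls = VoxelMatrix(values=np.tile(rng.normal(size=(1, 10)), (30, 1)))
        cov = _covariates(rng, 30)
        model = fit_covariate_betas(controls, cov)
        data = VoxelMatrix(values=rng.normal(size=(5, 10)))
        out = residualize_age_sex(model, data, _covariates(rng, 5))
        np.testing.assert_allclose(out.values, data.values, atol=1e-9)

    def test_planted_slope_recovered(self, rng):
        n = 200
        cov = _covariates(rng, n)
        age = cov["age"].to_numpy()
        vals = rng.normal(size=(n, 50), scale=0.1) + 0.02 * age[:, None]
        controls = VoxelMatrix(values=vals)
        model = fit_covariate_betas(controls, cov)
        out = residualize_age_sex(model, controls, cov)
        agec = age - age.mean()
        slope = (agec @ out.values).mean() / (agec @ agec)
        assert abs(slope) < 0.005

    def test_idempotent_after_refit(self, rng):
        n = 100
        cov = _covariates(rng, n)
        vals = rng.normal(size=(n, 20)) + 0.03 * cov["age"].to_numpy()[:, None]
        controls = VoxelMatrix(values=vals)
        model = fit_covariate_betas(controls, cov)
        once = residualize_age_sex(model, controls, cov)
        refit = fit_covariate_betas(once, cov)
        assert np.abs(refit.betas).max() < 1e-9
        twice = residualize_age_sex(refit, once, cov)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-7)

    def test_missing_covariate_errors(self, rng):
        cov = _covariates(rng, 10)
        model = fit_covariate_betas(VoxelMatrix(values=rng.normal(size=(10, 5))), cov)
        bad = cov.copy()
        bad.loc[3, "age"] = np.nan
        with pytest.raises(ImagePrepError):
            residualize_age_sex(model, VoxelMatrix(values=rng.normal(size=(10, 5))), bad)


def _planted_ica_data(rng, n=80, V=400, K=5, noise=0.0):
    raw = rng.standard_normal((V, K))
    q, _ = np.linalg.qr(raw)
    comps = q / np.linalg.norm(q, axis=0)
    loadings = rng.normal(size=(n, K))
    data = loadings @ comps.T
    if noise:
        data = data + rng.normal(scale=noise, size=data.shape)
    return VoxelMatrix(values=data), comps, loadings


class TestGigIca:
    def test_exact_model_recovery(self, rng):
        data, comps, loadings = _planted_ica_data(rng)
        refs = ReferenceComponents(maps=comps)
        est_comps, est_load = gig_ica(data, refs, similarity_weight=0.5)
        for k in range(5):
            r = np.corrcoef(est_comps[:, k], comps[:, k])[0, 1]
            assert r >= 0.999
            # loadings match planted weights up to a positive per-component scale
            lc = np.corrcoef(est_load[:, k], loadings[:, k])[0, 1]
            assert lc >= 0.999

    def test_noisy_recovery_with_perturbed_refs(self, rng):
        # SNR 5 in variance; refs correlate ~0.9 with the truth
        K = 5
        data, comps, _ = _planted_ica_data(rng, n=100, V=500, K=K)
        sig_sd = data.values.std()
        data = VoxelMatrix(values=data.values + rng.normal(scale=sig_sd / np.sqrt(5), size=data.values.shape))
        pert = comps + rng.normal(scale=0.022, size=comps.shape)
        pert /= np.linalg.norm(pert, axis=0)
        for k in range(K):
            assert np.corrcoef(pert[:, k], comps[:, k])[0, 1] > 0.85
        est_comps, _ = gig_ica(data, ReferenceComponents(maps=pert), similarity_weight=0.5)
        for k in range(K):
            r = abs(np.corrcoef(est_comps[:, k], comps[:, k])[0, 1])
            assert r >= 0.95

    def test_subject_permutation_equivariance(self, rng):
        data, comps, _ = _planted_ica_data(rng, n=40, V=200, K=3, noise=0.1)
        refs = ReferenceComponents(maps=comps)
        _, load = gig_ica(data, refs)
        perm = rng.permutation(40)
        _, load_p = gig_ica(VoxelMatrix(values=data.values[perm]), refs)
        np.testing.assert_allclose(load_p, load[perm], atol=1e-6)

    def test_deflation_decorrelates_components(self, rng):
        data, comps, _ = _planted_ica_data(rng, n=60, V=300, K=4, noise=0.2)
        est, _ = gig_ica(data, ReferenceComponents(maps=comps))
        cc = np.corrcoef(est.T)
        off = cc[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_sign_convention(self, rng):
        data, comps, _ = _planted_ica_data(rng, n=40, V=200, K=3)
        est, _ = gig_ica(data, ReferenceComponents(maps=comps))
        for k in range(3):
            c = est[:, k] - est[:, k].mean()
            r = comps[:, k] - comps[:, k].mean()
            assert c @ r >= 0

    def test_too_many_refs_rejected(self, rng):
        data, comps, _ = _planted_ica_data(rng, n=4, V=50, K=3)
        with pytest.raises(ImagePrepError):
            gig_ica(data, ReferenceComponents(maps=np.eye(50)[:, :10]))

    def test_similarity_weight_validated(self, rng):
        data, comps, _ = _planted_ica_data(rng, n=20, V=100, K=2)
        with pytest.raises(ImagePrepError):
            gig_ica(data, ReferenceComponents(maps=comps), similarity_weight=1.5)


class TestLeakageContract:
    def test_patient_values_never_affect_control_fits(self, rng):
        cfg = sc.SynthConfig(n_subjects=30, n_sites=3, site_weights=np.ones(3) / 3,
                             n_voxels=60, seed=21)
        ctrl_vox, ctrl_sites, ctrl_cov = sc.generate_reference_controls(cfg, 60, seed=5)
        mask1 = fit_gtheory_mask(ctrl_vox, ctrl_sites, 0.5)
        cm1 = fit_combat(mask1.apply(ctrl_vox), ctrl_sites, ctrl_cov)
        # "touching" arbitrary patient data in between must not change refits
        _ = VoxelMatrix(values=rng.normal(size=(30, 60)))
        mask2 = fit_gtheory_mask(ctrl_vox, ctrl_sites, 0.5)
        cm2 = fit_combat(mask2.apply(ctrl_vox), ctrl_sites, ctrl_cov)
        np.testing.assert_array_equal(mask1.g_coefficient, mask2.g_coefficient)
        np.testing.assert_array_equal(cm1.gamma_star, cm2.gamma_star)
        np.testing.assert_array_equal(cm1.delta_star, cm2.delta_star)
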