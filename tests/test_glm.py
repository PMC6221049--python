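import numpy as np
import pytest
from scipy import stats

import tmsfmri as tf
from tmsfmri import glm
from tmsfmri.core import HIGH, LOW, PulseTrain, VolumeSeries


def _design(n=120, tr=2.0, seed=0, cutoff=80.0):
    pulses = tf.generate_pulse_train(n, tr, (5, 8), seed=seed)
    rng = np.random.default_rng(seed + 1)
    return glm.build_design(pulses, n, tr,
                            wm_signal=rng.normal(900, 2, n),
                            csf_signal=rng.normal(500, 3, n),
                            highpass_cutoff=cutoff), pulses


class TestCanonicalHRF:
    def test_peak_near_five_seconds(self):
        h, dt = glm.canonical_hrf()
        assert np.argmax(h) * dt == pytest.approx(5.0, abs=0.2)
        assert h.max() == pytest.approx(1.0)

    def test_tail_below_one_percent_of_peak(self):
        h, _ = glm.canonical_hrf()
        assert abs(h[-1]) < 0.01

    def test_large_ratio_limit_is_single_gamma(self):
        params = glm.HRFParams(peak_undershoot_ratio=1e9)
        h, dt = glm.canonical_hrf(params)
        t = np.arange(0, params.duration, dt)
        g = stats.gamma.pdf(t, a=6.0, scale=1.0)
        assert np.allclose(h, g / g.max(), atol=1e-6)

    def test_matches_nilearn_spm_hrf_shape(self):
        """Independent oracle: shape agrees with nilearn's SPM HRF."""
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf
        tr = 2.0
        h, _ = glm.canonical_hrf(glm.HRFParams(), tr)
        ref = spm_hrf(tr, oversampling=16, time_length=32.0)
        n = min(h.size, ref.size)
        r = np.corrcoef(h[:n], ref[:n])[0, 1]
        assert r > 0.999

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            glm.HRFParams(peak_delay=-1.0)
        with pytest.raises(ValueError):
            glm.HRFParams(duration=10.0)   # shorter than undershoot delay


class TestBuildDesign:
    def test_no_pulses_gives_nuisance_drift_intercept_only(self):
        empty = PulseTrain(np.array([]), np.array([], dtype=object))
        rng = np.random.default_rng(0)
        d = glm.build_design(empty, 100, 2.0, rng.normal(900, 2, 100),
                             rng.normal(500, 3, 100), 80.0)
        assert not any(c.startswith(("high", "low")) for c in d.columns)
        assert d.columns[-1] == "intercept"
        assert "wm_nuisance" in d.columns and "csf_nuisance" in d.columns

    def test_single_pulse_column_is_shifted_hrf(self):
        """Direct-convolution oracle: one high pulse at t0 makes the
        canonical column the HRF sampled at frame times minus t0."""
        t0 = 20.0
        pulses = PulseTrain(np.array([t0]), np.array([HIGH], dtype=object))
        d = glm.build_design(pulses, 60, 2.0, highpass_cutoff=None)
        col = d.frame["high_canon"].to_numpy()
        h, dt = glm.canonical_hrf(glm.HRFParams(), 2.0)
        expect = np.zeros(60)
        for i, t in enumerate(np.arange(60) * 2.0):
            k = int(round((t - t0) / dt))
            if 0 <= k < h.size:
                expect[i] = h[k]
        assert np.allclose(col, expect, atol=1e-12)

    def test_drift_columns_orthonormal(self):
        d, _ = _design()
        cols = [c for c in d.columns if c.startswith("drift_")]
        assert len(cols) == int(np.floor(2 * 120 * 2.0 / 80.0))
        D = d.frame[cols].to_numpy()
        assert np.allclose(D.T @ D, np.eye(len(cols)), atol=1e-10)

    def test_nuisance_columns_mean_centred(self):
        d, _ = _design()
        assert d.frame["wm_nuisance"].mean() == pytest.approx(0.0, abs=1e-10)
        assert d.frame["csf_nuisance"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_collinear_design_rejected_with_names(self):
        pulses = tf.generate_pulse_train(60, 2.0, (5, 8), seed=0)
        wm = np.ones(60)  # centred -> zero column, collinear with anything
        with pytest.raises(ValueError, match="wm_nuisance"):
            glm.build_design(pulses, 60, 2.0, wm_signal=wm)

    def test_onsets_outside_acquisition_rejected(self):
        pulses = PulseTrain(np.array([500.0]), np.array([HIGH], dtype=object))
        with pytest.raises(ValueError, match="within the acquisition"):
            glm.build_design(pulses, 100, 2.0)


def _series_from_matrix(Y, tr=2.0):
    """(T, nvox) matrix as a 1-voxel-thick VolumeSeries + all-true mask."""
    T, nvox = Y.shape
    data = Y.T.reshape(nvox, 1, 1, T)
    return (VolumeSeries(data, np.diag([4.0, 4, 4, 1]), tr),
            np.ones((nvox, 1, 1), dtype=bool))


class TestFitGLM:
    def test_noiseless_recovery_is_exact(self):
        d, _ = _design(n=80)
        X = d.matrix
        rng = np.random.default_rng(3)
        beta = rng.normal(0, 2, (X.shape[1], 7))
        series, mask = _series_from_matrix(X @ beta)
        res = glm.fit_glm(series, d, mask)
        assert np.allclose(res.betas, beta, atol=1e-8)
        assert np.allclose(res.sigma2, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        d, _ = _design(n=100)
        X = d.matrix
        rng = np.random.default_rng(4)
        Y = rng.normal(0, 1, (100, 10))
        series, mask = _series_from_matrix(Y)
        res = glm.fit_glm(series, d, mask)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.allclose(res.betas, beta_oracle, atol=1e-9)
        resid = Y - X @ beta_oracle
        df = 100 - np.linalg.matrix_rank(X)
        assert np.allclose(res.sigma2, (resid ** 2).sum(0) / df, atol=1e-9)
        assert res.df == df

    def test_sigma2_estimates_noise_variance(self):
        """Mean residual variance ~ true variance over 50 seeds."""
        d, _ = _design(n=100)
        X = d.matrix
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            Y = rng.normal(0, 3.0, (100, 20))
            series, mask = _series_from_matrix(Y)
            vals.append(glm.fit_glm(series, d, mask).sigma2.mean())
        assert np.mean(vals) == pytest.approx(9.0, rel=0.05)

    def test_df_exhaustion_rejected(self):
        d, _ = _design(n=80)
        series, mask = _series_from_matrix(np.zeros((60, 2)))
        with pytest.raises(ValueError, match="rows"):
            glm.fit_glm(series, d, mask)

    def test_against_nilearn_first_level(self):
        """Cross-check betas against nilearn's OLS on the same design."""
        from nilearn.glm.first_level import run_glm
        d, _ = _design(n=90)
        rng = np.random.default_rng(5)
        Y = rng.normal(100, 5, (90, 12))
        series, mask = _series_from_matrix(Y)
        res = glm.fit_glm(series, d, mask)
        labels, estimates = run_glm(Y, d.matrix, noise_model="ols")
        theta = estimates[labels[0]].theta      # single OLS label
        assert np.allclose(res.betas, theta, atol=1e-8)


class TestFContrast:
    def test_zero_effect_gives_zero_f_unit_p(self):
        d, _ = _design(n=80)
        X = d.matrix
        beta = np.zeros((X.shape[1], 3))
        beta[d.columns.index("intercept")] = 100.0
        rng = np.random.default_rng(6)
        series, mask = _series_from_matrix(X @ beta)
        res = glm.fit_glm(series, d, mask)
        res.sigma2[:] = 1.0  # zero-residual fit: fix the scale to test cb=0
        stat = glm.f_contrast(res)
        assert np.allclose(stat.f[mask], 0.0, atol=1e-12)
        assert np.allclose(stat.p[mask], 1.0)

    def test_single_row_f_equals_squared_t(self):
        d, _ = _design(n=100)
        X = d.matrix
        rng = np.random.default_rng(7)
        Y = rng.normal(0, 1, (100, 8)) + np.outer(X[:, 0], rng.normal(1, 0.1, 8))
        series, mask = _series_from_matrix(Y)
        res = glm.fit_glm(series, d, mask)
        c = np.zeros(X.shape[1]); c[0] = 1.0
        stat = glm.f_contrast(res, c)
        se = np.sqrt(res.sigma2 * (c @ res.xtx_inv @ c))
        tvals = (c @ res.betas) / se
        assert np.allclose(stat.f[mask], tvals ** 2, atol=1e-9)
        assert stat.q == 1

    def test_invariant_to_contrast_reparameterisation(self):
        d, _ = _design(n=100)
        rng = np.random.default_rng(8)
        Y = rng.normal(0, 1, (100, 6))
        series, mask = _series_from_matrix(Y)
        res = glm.fit_glm(series, d, mask)
        C = glm.default_contrast(d)
        M = np.array([[2.0, 1.0], [0.5, -1.0]])   # invertible remix
        f1 = glm.f_contrast(res, C).f
        f2 = glm.f_contrast(res, M @ C).f
        assert np.allclose(f1[mask], f2[mask], atol=1e-8)

    def test_invariant_to_intercept_added_to_regressor(self):
        """Adding the intercept column to a task regressor leaves the
        default contrast's F unchanged (nuisance invariance)."""
        d, _ = _design(n=100)
        rng = np.random.default_rng(9)
        Y = rng.normal(50, 1, (100, 5))
        series, mask = _series_from_matrix(Y)
        f1 = glm.f_contrast(glm.fit_glm(series, d, mask)).f
        d2 = glm.DesignMatrix(d.frame.copy(), d.frame_times, d.hrf_params)
        d2.frame["high_canon"] = d2.frame["high_canon"] + d2.frame["intercept"]
        f2 = glm.f_contrast(glm.fit_glm(series, d2, mask)).f
        assert np.allclose(f1[mask], f2[mask], atol=1e-6)


class TestFWE:
    def test_bonferroni_threshold_arithmetic(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        f = np.full(mask.shape, 1.0); p = np.full(mask.shape, 0.5)
        stat = glm.StatMap(f, p, 2, 100, mask)
        out = glm.fwe_threshold(stat, alpha=0.05, method="bonferroni")
        assert out.n_tests == 1000
        # per-voxel threshold p < 5e-5
        assert stats.f.sf(out.f_threshold, 2, 100) == pytest.approx(5e-5, rel=1e-6)
        assert not out.suprathreshold.any()

    def test_permutation_needs_enough_pulses(self):
        pulses = tf.generate_pulse_train(100, 2.0, (5, 8), seed=0)  # ~7/level
        spec = tf.PhantomSpec(grid_shape=(8, 8, 8), n_dynamics=100, seed=0)
        s, masks, _ = tf.generate_phantom(spec)
        with pytest.raises(ValueError, match="20 pulses"):
            glm.permutation_max_f(s, pulses, masks["gm"], 100, 2.0, n_perm=10)

    def test_permutation_and_bonferroni_agree_on_null(self):
        """Both FWE methods keep a null phantom clean at alpha 0.05."""
        spec = tf.PhantomSpec(grid_shape=(10, 10, 10), n_dynamics=320,
                              ar1_coef=0.0, effect_pct=0.0, seed=77)
        s, masks, truth = tf.generate_phantom(spec)
        wm = s.data[masks["wm"]].mean(axis=0)
        csf = s.data[masks["csf"]].mean(axis=0)
        d = glm.build_design(truth.pulse_train, 320, 2.0, wm, csf, 80.0)
        res = glm.fit_glm(s, d, masks["gm"])
        stat = glm.f_contrast(res)
        bonf = glm.fwe_threshold(stat, 0.05, "bonferroni")
        null = glm.permutation_max_f(s, truth.pulse_train, masks["gm"],
                                     320, 2.0, wm, csf, 80.0,
                                     n_perm=200, seed=1)
        perm = glm.fwe_threshold(stat, 0.05, "permutation", perm_null=null)
        assert not bonf.suprathreshold.any()
        assert not perm.suprathreshold.any()
        assert perm.f_threshold > 0

    def test_unknown_method_rejected(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        stat = glm.StatMap(np.ones(mask.shape), np.full(mask.shape, 0.5),
                           2, 50, mask)
        with pytest.raises(ValueError, match="unknown FWE"):
            glm.fwe_threshold(stat, method="fdr")
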