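"""fMRI pipeline tests: smoothing, ROI statistics, drift removal, the
incremental GLM against a batch oracle, and activation-map ROI selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hybridnf.core import CalibrationError, NoActiveClusterError, VolumeSeries
from hybridnf.fmri import (GlmState, activation_roi, background_mask, detrend,
                           fmri_feature, gaussian_smooth, glm_over_series,
                           iglm_estimates, iglm_update, roi_mean)
from hybridnf.hemo import design_matrix
from hybridnf.protocol import Block, ProtocolSpec, validate_protocol
from hybridnf.synthetic import (BoldSynth, SimConfig, gen_fmri,
                                gen_task_design)


@pytest.fixture(scope="module")
def design40(proto_20_20x2):
    design, _ = gen_task_design(proto_20_20x2, 2.0)
    return design


class TestSmoothing:
    def test_fwhm_zero_identity(self):
        v = np.random.default_rng(0).normal(size=(8, 8, 4))
        assert np.array_equal(gaussian_smooth(v, 0.0), v)

    def test_constant_field_preserved(self):
        v = np.full((8, 8, 4), 3.5)
        assert np.allclose(gaussian_smooth(v, 6.0), 3.5)

    def test_impulse_peak_matches_sampled_kernel(self):
        # isotropic 2 mm voxels, fwhm = 2 x 2.3548 mm -> sigma = 1 voxel;
        # oracle: closed-form evaluation of the sampled, normalized kernel
        from hybridnf.fmri import FWHM_TO_SIGMA
        v = np.zeros((9, 9, 9))
        v[4, 4, 4] = 1.0
        out = gaussian_smooth(v, 2.0 * FWHM_TO_SIGMA,
                              voxel_sizes=(2.0, 2.0, 2.0))
        radius = 4  # truncate 4 sigma at sigma=1
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * x ** 2)
        k /= k.sum()
        assert out[4, 4, 4] == pytest.approx(k[radius] ** 3, rel=1e-6)


class TestRoiMean:
    def test_constant_and_hand_mean(self):
        v = np.zeros((4, 4, 2))
        mask = np.zeros_like(v, dtype=bool)
        mask[0, 0, 0] = mask[1, 0, 0] = True
        v[0, 0, 0], v[1, 0, 0] = 1.0, 3.0
        assert roi_mean(v, mask) == 2.0
        assert roi_mean(np.full((3, 3, 3), 7.0), np.ones((3, 3, 3), bool)) == 7.0

    def test_empty_mask_rejected(self):
        with pytest.raises(CalibrationError):
            roi_mean(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool))

    def test_full_grid_on_null_generator_gives_baseline(self):
        cfg = SimConfig(seed=1, n_volumes=5, noise_sd_bold=0.0,
                        drift_slope=0.0, bold_beta=0.0)
        series, truth = gen_fmri(cfg)
        assert roi_mean(series.data[3], np.ones(cfg.grid_shape, bool)) == \
            pytest.approx(truth.baseline)


class TestDetrend:
    def test_exact_line_removed(self):
        y = 3.0 + 0.5 * np.arange(30)
        assert np.abs(detrend(y, "linear")).max() < 1e-10

    def test_constant_series_ema(self):
        y = np.full(50, 4.2)
        r = detrend(y, "ema", alpha=0.3)
        assert r[0] == 0.0
        assert np.abs(r).max() < 1e-12

    def test_causal_linear_on_generator_drift(self):
        cfg = SimConfig(seed=1, n_volumes=40, noise_sd_bold=0.0,
                        drift_slope=0.5, bold_beta=0.0)
        series, _ = gen_fmri(cfg)
        tc = series.data[:, 2, 2, 2]
        resid = detrend(tc, "linear", causal=True)
        assert np.abs(resid[10:]).max() < 1e-6

    def test_bad_args(self):
        with pytest.raises(ValueError):
            detrend(np.zeros(1), "linear")
        with pytest.raises(ValueError):
            detrend(np.zeros(5), "ema", alpha=0.0)


class TestIncrementalGlm:
    def test_single_update_algebra(self):
        state = GlmState(design_columns=["a", "b"])
        iglm_update(state, [1.0, 2.0], 3.0)
        assert state.n == 1
        assert np.array_equal(state.xtx, np.array([[1.0, 2.0], [2.0, 4.0]]))
        assert np.array_equal(state.xty.ravel(), [3.0, 6.0])

    def test_update_order_commutes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        s1 = GlmState(design_columns=list("abc"))
        s2 = GlmState(design_columns=list("abc"))
        for k in range(20):
            iglm_update(s1, X[k], y[k])
        for k in np.random.default_rng(1).permutation(20):
            iglm_update(s2, X[k], y[k])
        assert np.allclose(s1.xtx, s2.xtx, atol=1e-10)
        assert np.allclose(s1.xty, s2.xty, atol=1e-10)

    @given(st.integers(0, 1000))
    def test_prefix_estimates_match_batch_ols(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(8, 40), rng.integers(2, 6)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        state = GlmState(design_columns=[f"c{i}" for i in range(p)])
        for k in range(n):
            iglm_update(state, X[k], y[k])
            if k + 1 > p + 1:
                beta_b, *_ = np.linalg.lstsq(X[: k + 1], y[: k + 1],
                                             rcond=None)
                est = iglm_estimates(state)
                denom = max(1.0, np.abs(beta_b).max())
                assert np.abs(est.betas.ravel() - beta_b).max() / denom < 1e-8

    def test_exact_fit_zero_variance(self):
        x = np.arange(1.0, 11.0)
        state = GlmState(design_columns=["x"])
        for xi in x:
            iglm_update(state, [xi], 2.0 * xi)
        est = iglm_estimates(state)
        assert est.betas.ravel()[0] == pytest.approx(2.0)
        assert est.sigma2[0] == pytest.approx(0.0, abs=1e-12)

    def test_singular_design_names_columns(self):
        state = GlmState(design_columns=["a", "a_copy", "b"])
        rng = np.random.default_rng(0)
        for _ in range(10):
            u, b = rng.normal(size=2)
            iglm_update(state, [u, u, b], rng.normal())
        with pytest.raises(np.linalg.LinAlgError, match="a"):
            iglm_estimates(state, ridge_fallback=False)

    def test_beta_recovery(self, design40):
        # beta=1, noise sd 0.1, 80 scans x 20 seeds: unbiased recovery
        X, cols = design_matrix(np.tile(design40, 2), 2.0)
        betas = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_volumes=80, noise_sd_bold=0.1)
            series, truth = gen_fmri(cfg, np.tile(design40, 2),
                                     np.ones(80))
            state = glm_over_series(series, np.tile(design40, 2))
            est = iglm_estimates(state)
            bmap = est.betas[cols.index("task")].reshape(series.grid_shape)
            betas.append(bmap[truth.active_mask].mean())
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - 1.0) <= 3 * se

    def test_null_contrast_t_centered(self, design40):
        # drift column absent from the generative model: t ~ centered on 0
        tvals = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_volumes=40, noise_sd_bold=0.1,
                            drift_slope=0.0, bold_beta=0.0)
            series, _ = gen_fmri(cfg, design40, np.ones(40))
            state = glm_over_series(series, design40)
            est = iglm_estimates(state, contrasts={"drift": [0, 1, 0]})
            tvals.append(est.tstats["drift"][0])
        assert abs(np.mean(tvals)) < 0.75


def _series_from_masks(design, betas, noise_sd, seed, grid=(12, 12, 6)):
    cfg = SimConfig(seed=seed, n_volumes=design.size, noise_sd_bold=noise_sd,
                    grid_shape=grid)
    synth = BoldSynth(cfg, np.random.default_rng(seed),
                      active_mask=betas > 0, betas=betas)
    data = np.stack([synth.generate(k, design[k], 1.0)
                     for k in range(design.size)])
    return VolumeSeries(data, tr=cfg.tr), synth


class TestActivationRoi:
    def test_recovery_at_snr10(self, design40):
        # SNR = beta / noise = 10: Jaccard >= 0.8 against the true mask
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_volumes=40, noise_sd_bold=0.1)
            series, truth = gen_fmri(cfg, design40, np.ones(40))
            _, roi = activation_roi(series, design40)
            inter = (roi.mask & truth.active_mask).sum()
            union = (roi.mask | truth.active_mask).sum()
            assert inter / union >= 0.8

    def test_null_raises_no_cluster(self, design40):
        failures = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_volumes=40, noise_sd_bold=0.1,
                            bold_beta=0.0)
            series, _ = gen_fmri(cfg, design40, np.ones(40))
            try:
                activation_roi(series, design40, z_threshold=3.0)
            except NoActiveClusterError:
                failures += 1
        assert failures >= 9

    def test_two_blobs_higher_beta_wins(self, design40):
        grid = (12, 12, 6)
        betas = np.zeros(grid)
        betas[2:4, 2:4, 2] = 0.5
        betas[8:10, 8:10, 2] = 1.0
        series, _ = _series_from_masks(design40, betas, 0.05, seed=0)
        _, roi = activation_roi(series, design40)
        assert roi.mask[8:10, 8:10, 2].all()
        assert not roi.mask[2:4, 2:4, 2].any()

    def test_translation_equivariance(self, design40):
        grid = (12, 12, 6)
        rois = []
        for shift in (0, 3):
            betas = np.zeros(grid)
            betas[2 + shift: 5 + shift, 2: 5, 2] = 1.0
            series, _ = _series_from_masks(design40, betas, 0.0, seed=0)
            _, roi = activation_roi(series, design40)
            rois.append(roi.mask)
        assert np.array_equal(np.roll(rois[0], 3, axis=0), rois[1])


class TestFmriFeature:
    def test_modes(self):
        assert fmri_feature(5.0, 5.0, "background_subtracted") == 0.0
        assert fmri_feature(5.0, 99.0, "raw") == 5.0

    def test_global_drift_cancels_in_background_mode(self, design40):
        # multiplicative global drift hits ROI and background alike
        cfg = SimConfig(seed=0, n_volumes=40, noise_sd_bold=0.0,
                        bold_beta=0.0, drift_slope=0.0)
        series, _ = gen_fmri(cfg)
        drift = 1.0 + 0.002 * np.arange(40)
        data = series.data * drift[:, None, None, None]
        roi = np.zeros(cfg.grid_shape, bool)
        roi[5:7, 5:7, 2] = True
        bg = background_mask(cfg.grid_shape)
        feats = [fmri_feature(roi_mean(v, roi), roi_mean(v, bg))
                 for v in data]
        assert np.ptp(feats) < 1e-9
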