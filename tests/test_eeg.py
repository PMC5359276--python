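"""EEG pipeline tests: R-peak detection, average artifact subtraction,
filtering, windowing, CSP and band-power features."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hybridnf.core import DesyncError, EegStream
from hybridnf.eeg import (CspModel, TemplateBuffer, bandpass, detect_r_peaks,
                          eeg_feature, csp_separation, segment_windows,
                          template_correct, train_csp)
from hybridnf.synthetic import SimConfig, gen_eeg

FS = 250.0


def _stream(data, fs=FS, markers=()):
    labels = [f"ch{i}" for i in range(data.shape[0])]
    return EegStream(np.asarray(data, float), fs, labels, list(markers))


def _pulse_train(positions, n, width=9, amp=100.0):
    x = np.zeros(n)
    t = np.linspace(-1, 1, width)
    bump = amp * np.exp(-t ** 2 / 0.045)
    half = width // 2
    for p in positions:
        x[p - half: p - half + width] += bump
    return x


class TestRPeakDetection:
    def test_synthetic_ecg_recall(self):
        cfg = SimConfig(seed=4, n_volumes=30, heart_rate=60.0,
                        heart_jitter_sd=0.0, artifact_gain=0.0)
        _, truth = gen_eeg(cfg)
        ecg = truth.clean_eeg[cfg.n_channels]
        peaks = detect_r_peaks(ecg, cfg.fs_eeg)
        assert np.all(np.diff(peaks) == 250)
        assert len(peaks) == len(truth.r_peak_samples)
        assert np.abs(peaks - truth.r_peak_samples).max() <= 2

    def test_flatline_returns_empty_with_warning(self):
        with pytest.warns(UserWarning):
            peaks = detect_r_peaks(np.zeros(2000), FS)
        assert peaks.size == 0

    def test_refractory_keeps_first(self):
        # two pulses 0.2 s apart: closer than the 0.3 s refractory
        n = 2000
        ecg = _pulse_train([500, 550, 1500], n)
        peaks = detect_r_peaks(ecg, FS)
        assert len(peaks) == 2
        assert abs(peaks[0] - 500) <= 2 and abs(peaks[1] - 1500) <= 2


class TestTemplateCorrection:
    def test_constant_artifact_annihilated(self):
        spt = 100
        artifact = np.tile(np.sin(np.arange(spt)), 8)
        data = np.tile(artifact, (3, 1))
        stream = _stream(data)
        anchors = np.arange(8) * spt
        res = template_correct(stream, anchors, TemplateBuffer(10, spt))
        assert res.passthrough_epochs == [0]
        assert np.abs(res.stream.data[:, spt:]).max() < 1e-12

    def test_periodic_artifact_exact_for_any_buffer_size(self):
        # strictly epoch-periodic artifact on zero EEG: exact cancellation
        # after the first epoch regardless of buffer capacity
        spt, n_ep = 80, 10
        rng = np.random.default_rng(0)
        template = rng.normal(size=(4, spt))
        data = np.tile(template, (1, n_ep))
        for cap in (1, 3, 10):
            res = template_correct(_stream(data), np.arange(n_ep) * spt,
                                   TemplateBuffer(cap, spt))
            assert np.abs(res.stream.data[:, spt:]).max() < 1e-12

    def test_linearity(self):
        spt, n_ep = 60, 8
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, spt * n_ep))
        y = rng.normal(size=(3, spt * n_ep))
        anchors = np.arange(n_ep) * spt
        cx = template_correct(_stream(x), anchors, TemplateBuffer(5, spt))
        cy = template_correct(_stream(y), anchors, TemplateBuffer(5, spt))
        cxy = template_correct(_stream(x + y), anchors, TemplateBuffer(5, spt))
        assert np.allclose(cxy.stream.data,
                           cx.stream.data + cy.stream.data, atol=1e-12)

    def test_gradient_suppression_on_defaults(self, contaminated_run):
        cfg, _, stream, truth = contaminated_run
        ttl = stream.marker_samples("TTL")
        res = template_correct(stream, ttl,
                               TemplateBuffer(10, cfg.samples_per_tr))
        nch = cfg.n_channels
        resid = (res.stream.data - truth.clean_eeg
                 - truth.bcg_component)[:nch, cfg.samples_per_tr:]
        pre = np.mean(truth.gradient_component[:nch] ** 2)
        post = np.mean(resid ** 2)
        assert 10 * np.log10(pre / post) >= 30.0

    def test_bcg_correction_correlation(self):
        cfg = SimConfig(seed=6, n_volumes=40, artifact_gain=0.0,
                        heart_rate=60.0, heart_jitter_sd=0.0)
        stream, truth = gen_eeg(cfg)
        ecg = stream.data[cfg.n_channels]
        peaks = detect_r_peaks(ecg, cfg.fs_eeg)
        epoch = int(np.median(np.diff(peaks)))
        res = template_correct(stream, peaks, TemplateBuffer(15, epoch),
                               mode="bcg")
        warm = 16 * epoch
        for ch in range(cfg.n_channels):
            c = np.corrcoef(res.stream.data[ch, warm:],
                            truth.clean_eeg[ch, warm:])[0, 1]
            assert c >= 0.95

    def test_uneven_gradient_anchors_raise_desync(self):
        data = np.zeros((2, 1000))
        anchors = np.array([0, 100, 230, 300])
        with pytest.raises(DesyncError):
            template_correct(_stream(data), anchors, TemplateBuffer(5, 100))


class TestBandpass:
    def test_passband_and_stopband(self):
        t = np.arange(int(10 * FS)) / FS
        keep = np.sin(2 * np.pi * 20 * t)
        kill = np.sin(2 * np.pi * 2 * t)
        out = bandpass(_stream(np.vstack([keep, kill])), 8.0, 30.0)
        mid = np.s_[int(2 * FS): int(8 * FS)]
        assert np.abs(out.data[0, mid]).max() >= 0.95
        assert np.abs(out.data[1, mid]).max() <= 0.05

    def test_zero_in_zero_out(self):
        out = bandpass(_stream(np.zeros((2, 1000))), 8.0, 30.0)
        assert not out.data.any()

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_stream(np.zeros((1, 1000))), 30.0, 8.0)
        with pytest.raises(ValueError):
            bandpass(_stream(np.zeros((1, 1000))), 8.0, 200.0)


class TestSegmentWindows:
    def test_calibration_segmentation_yields_181(self):
        stream = _stream(np.zeros((2, int(20 * FS))))
        wins = segment_windows(stream, 2.0, 0.95)
        assert len(wins) == 181
        assert wins[0].start_time == 0.0
        assert wins[-1].start_time == pytest.approx(18.0)

    def test_disjoint_tiling(self):
        wins = segment_windows(_stream(np.zeros((1, int(4 * FS)))), 2.0, 0.0)
        assert len(wins) == 2

    def test_too_short_is_empty(self):
        wins = segment_windows(_stream(np.zeros((1, int(1.9 * FS)))), 2.0, 0.5)
        assert wins == []

    @pytest.mark.parametrize("overlap", [0.0, 0.5, 0.9, 0.95])
    @pytest.mark.parametrize("dur", [2.0, 5.2, 20.0, 33.4])
    def test_count_matches_closed_form(self, overlap, dur):
        n = int(round(dur * FS))
        wins = segment_windows(_stream(np.zeros((1, n))), 2.0, overlap)
        L = int(2.0 * FS)
        step = int(round(L * (1 - overlap)))
        expected = (n - L) // step + 1 if n >= L else 0
        assert len(wins) == expected


def _planted_windows(rng, v, n, amp, nch=8, nsamp=400):
    out = []
    for _ in range(n):
        x = rng.normal(size=(nch, nsamp))
        out.append(x + np.outer(v, rng.normal(size=nsamp) * amp))
    return out


class TestCsp:
    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=8)
        v /= np.linalg.norm(v)
        task = _planted_windows(rng, v, 30, 3.0)
        rest = _planted_windows(rng, v, 30, 0.2)
        model = train_csp(task, rest, n_pairs=2)
        pat = model.patterns[:, 0] / np.linalg.norm(model.patterns[:, 0])
        assert abs(pat @ v) >= 0.95

    def test_null_case_no_separation(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=8)
        v /= np.linalg.norm(v)
        a = _planted_windows(rng, v, 60, 1.0)
        b = _planted_windows(rng, v, 60, 1.0)
        model = train_csp(a, b)
        assert np.abs(model.eigenvalues - 0.5).max() < 0.1
        assert csp_separation(model, a, b) < 0.7

    def test_label_swap_reverses_filter_ends(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        task = _planted_windows(rng, v, 20, 2.0, nch=6)
        rest = _planted_windows(rng, v, 20, 0.3, nch=6)
        m1 = train_csp(task, rest, n_pairs=2)
        m2 = train_csp(rest, task, n_pairs=2)
        f1 = m1.filters[0] / np.linalg.norm(m1.filters[0])
        f2 = m2.filters[2] / np.linalg.norm(m2.filters[2])  # opposite end
        assert abs(f1 @ f2) > 0.999

    def test_channel_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        task = _planted_windows(rng, v, 20, 2.0, nch=6)
        rest = _planted_windows(rng, v, 20, 0.3, nch=6)
        perm = np.random.default_rng(4).permutation(6)
        m1 = train_csp(task, rest, n_pairs=1)
        m2 = train_csp([w[perm] for w in task], [w[perm] for w in rest],
                       n_pairs=1)
        f1 = m1.filters[0] / np.linalg.norm(m1.filters[0])
        f2 = np.empty(6)
        f2[perm] = m2.filters[0]
        f2 /= np.linalg.norm(f2)
        assert abs(f1 @ f2) > 0.999


class TestEegFeature:
    def _identity_model(self, nch=1):
        return CspModel(filters=np.eye(nch), patterns=np.eye(nch),
                        n_pairs=1, band=(8.0, 30.0),
                        eigenvalues=np.full(nch, 0.5))

    def test_amplitude_doubling_adds_log4(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(3, 500))
        model = self._identity_model(3)
        assert eeg_feature(2 * w, model) - eeg_feature(w, model) == \
            pytest.approx(np.log(4.0), abs=1e-12)

    def test_unit_variance_noise_feature_near_zero(self):
        # Monte-Carlo over 100 seeds: log variance of unit noise ~ 0
        model = self._identity_model(1)
        feats = [eeg_feature(np.random.default_rng(s).normal(size=(1, 2000)),
                             model) for s in range(100)]
        assert abs(np.mean(feats)) < 0.02

    def test_zero_variance_floors_with_warning(self):
        model = self._identity_model(2)
        with pytest.warns(UserWarning):
            val = eeg_feature(np.zeros((2, 100)), model)
        assert np.isfinite(val)

    def test_erd_contrast_end_to_end(self, proto_20_20x2):
        from hybridnf.loop import calibrate
        cfg = SimConfig(seed=12, n_volumes=40, erd_depth=0.5)
        calib = calibrate(cfg, proto_20_20x2)
        # ERD: band power (hence log-power feature) lower during Task
        assert calib.eeg_sign == -1.0


@given(st.integers(1, 30))
def test_template_buffer_capacity_invariant(cap):
    buf = TemplateBuffer(cap, 10)
    for i in range(2 * cap):
        buf.push(np.full((2, 10), float(i)))
        assert len(buf) <= cap
    assert len(buf) == cap
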