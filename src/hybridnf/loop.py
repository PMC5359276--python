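"""End-to-end session runners: calibration and the closed feedback loop.

``calibrate`` replays the platform's non-feedback session: a block-design
run is simulated, artifacts are removed offline, CSP filters are trained
on 2 s / 95 %-overlap windows, the GLM activation map selects the feedback
ROI, and per-modality Rest baselines and display targets are established.

``run_closed_loop`` then runs the feedback session proper on the virtual
clock: signals are generated tick-by-tick from the subject's current
regulation state, cleaned online, turned into band-power and ROI features,
normalized against the calibration targets, combined, displayed, and fed
back to the subject model -- closing the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import EegStream, VolumeSeries
from .eeg import (OnlineEegCleaner, TemplateBuffer, bandpass, detect_r_peaks,
                  eeg_feature, segment_windows, template_correct, train_csp)
from .fmri import (activation_roi, background_mask, fmri_feature,
                   gaussian_smooth, roi_mean)
from .nfb import (BaselineState, combine, normalize_for_display,
                  update_baseline, zscore_feedback)
from .presentation import map_nfb
from .protocol import ProtocolSpec
from .sync import Latencies, Scheduler
from .synthetic import (BoldSynth, EegSynth, SimConfig, Subject,
                        gen_eeg, gen_fmri, gen_task_design, open_loop_trace)


@dataclass
class Calibration:
    """Initialization state extracted from the non-feedback session."""

    csp: object            # full CSP filter bank (both eigenvalue ends)
    feature_csp: object    # discriminative-end sub-bank feeding the feature
    band: tuple
    eeg_baseline_value: float
    eeg_rest_sd: float
    eeg_sign: float
    eeg_target: float
    roi: object
    activation: object
    bg_mask: np.ndarray
    fmri_baseline_value: float
    fmri_rest_sd: float
    fmri_target: float
    fwhm: float
    n_rest_windows: int
    n_task_windows: int


def _strip_ecg(stream: EegStream, ecg_label: str = "ECG") -> EegStream:
    rows = [i for i, l in enumerate(stream.channel_labels) if l != ecg_label]
    return EegStream(stream.data[rows], stream.fs,
                     [stream.channel_labels[i] for i in rows],
                     list(stream.markers))


def clean_offline(stream: EegStream, samples_per_tr: int,
                  gradient_capacity: int = 10, bcg_capacity: int = 15,
                  ecg_label: str = "ECG") -> EegStream:
    """Offline gradient + BCG average-artifact subtraction."""
    ttl = stream.marker_samples("TTL")
    res = template_correct(stream, ttl,
                           TemplateBuffer(gradient_capacity, samples_per_tr))
    out = res.stream
    if ecg_label in stream.channel_labels:
        ecg = out.data[stream.channel_labels.index(ecg_label)]
        peaks = detect_r_peaks(ecg, stream.fs)
        # the first TR passed through uncorrected: peaks found there anchor
        # gradient-contaminated epochs and must not feed the pulse template
        peaks = peaks[peaks >= samples_per_tr]
        if peaks.size >= 2:
            epoch = int(np.median(np.diff(peaks)))
            res = template_correct(out, peaks,
                                   TemplateBuffer(bcg_capacity, epoch),
                                   mode="bcg")
            out = res.stream
    return out


def calibrate(
    config: SimConfig,
    protocol: ProtocolSpec,
    fwhm: float = 4.0,
    z_threshold: float = 3.0,
    min_cluster: int = 4,
    n_pairs: int = 3,
    band: tuple = (8.0, 30.0),
    win: float = 2.0,
    overlap: float = 0.95,
) -> Calibration:
    """Run the simulated calibration session and extract initialization."""
    design, events = gen_task_design(protocol, config.tr)
    cfg = replace(config, n_volumes=design.size)
    trace = open_loop_trace(design, dt=cfg.tr)
    stream, _ = gen_eeg(cfg, trace, design)
    series, _ = gen_fmri(cfg, design, trace)

    # ----- EEG: clean, filter, window, CSP, baselines
    cleaned = clean_offline(stream, cfg.samples_per_tr)
    filtered = _strip_ecg(bandpass(cleaned, *band))
    fs = cfg.fs_eeg
    task_wins, rest_wins = [], []
    warm = cfg.samples_per_tr  # the first TR passed through uncorrected
    for onset, kind, dur in events:
        if kind == "BEGIN":
            continue
        a = max(int(round(onset * fs)), warm)
        b = int(round(onset * fs)) + int(round(dur * fs))
        if b - a < int(round(win * fs)):
            continue
        sub = EegStream(filtered.data[:, a:b], fs, filtered.channel_labels)
        wins = segment_windows(sub, win, overlap)
        (task_wins if kind == "TASK" else rest_wins).extend(wins)
    csp = train_csp(task_wins, rest_wins, n_pairs=n_pairs, band=band)
    feat_csp = _discriminative_end(csp, task_wins, rest_wins)
    f_task = np.array([eeg_feature(w, feat_csp) for w in task_wins])
    f_rest = np.array([eeg_feature(w, feat_csp) for w in rest_wins])
    eeg_sign = -1.0 if f_task.mean() < f_rest.mean() else 1.0
    eeg_baseline = float(f_rest.mean())
    eeg_rest_sd = float(f_rest.std(ddof=1))
    eeg_target = float(np.mean(eeg_sign * 100.0 * (f_task - eeg_baseline)))
    if eeg_target <= 0:
        eeg_target = max(200.0 * eeg_rest_sd, 1e-6)

    # ----- fMRI: smooth, activation map, ROI, baselines
    vx = series.voxel_sizes()
    smoothed = np.stack([gaussian_smooth(v, fwhm, vx) for v in series.data])
    sm_series = VolumeSeries(smoothed, tr=series.tr,
                             timestamps=series.timestamps, affine=series.affine)
    amap, roi = activation_roi(sm_series, design, z_threshold, min_cluster)
    bg = background_mask(series.grid_shape)
    feats = np.array([
        fmri_feature(roi_mean(v, roi.mask), roi_mean(v, bg))
        for v in smoothed
    ])
    kinds = _volume_kinds(events, series.n_volumes, series.tr)
    rest_v = feats[kinds == "REST"]
    task_v = feats[kinds == "TASK"]
    fmri_baseline = float(rest_v.mean())
    fmri_rest_sd = float(rest_v.std(ddof=1))
    fmri_target = float(np.mean(task_v - fmri_baseline))
    if fmri_target <= 0:
        fmri_target = max(2.0 * fmri_rest_sd, 1e-6)

    return Calibration(
        csp=csp, feature_csp=feat_csp, band=tuple(band),
        eeg_baseline_value=eeg_baseline, eeg_rest_sd=eeg_rest_sd,
        eeg_sign=eeg_sign, eeg_target=eeg_target,
        roi=roi, activation=amap, bg_mask=bg,
        fmri_baseline_value=fmri_baseline, fmri_rest_sd=fmri_rest_sd,
        fmri_target=fmri_target, fwhm=fwhm,
        n_rest_windows=len(rest_wins), n_task_windows=len(task_wins),
    )


def _discriminative_end(csp, task_wins, rest_wins) -> object:
    """Sub-bank of the CSP model holding the eigenvalue end whose absolute
    log band power separates Task from Rest best.

    CSP eigenvalues rank *relative* (trace-normalized) variance, but the
    feedback feature is absolute log variance of the projections; under
    ERD the Task-variance-minimizing end carries the absolute contrast, so
    the two ends are compared on the calibration windows themselves.
    """
    from hybridnf.eeg import CspModel
    n = csp.n_pairs
    best, best_delta = None, -1.0
    for sel in (slice(0, n), slice(n, 2 * n)):
        sub = CspModel(filters=csp.filters[sel],
                       patterns=csp.patterns[:, sel],
                       n_pairs=n, band=csp.band,
                       eigenvalues=csp.eigenvalues[sel])
        ft = np.mean([eeg_feature(w, sub) for w in task_wins])
        fr = np.mean([eeg_feature(w, sub) for w in rest_wins])
        if abs(ft - fr) > best_delta:
            best, best_delta = sub, abs(ft - fr)
    return best


def _volume_kinds(events, n_volumes: int, tr: float) -> np.ndarray:
    kinds = np.array(["REST"] * n_volumes, dtype=object)
    for onset, kind, dur in events:
        a = int(round(onset / tr))
        b = min(n_volumes, a + int(round(dur / tr)))
        kinds[a:b] = kind
    return kinds


@dataclass
class RunResult:
    """Everything one closed-loop session produced."""

    samples: list
    frames: list
    nfb_log: pd.DataFrame
    event_log: list
    tick_rows: list            # (tick, time_s, block_kind, task_block_no, combined)
    subject_trace: list        # (tick, effective regulation state)
    calibration: Calibration
    aborted: bool
    reports: list

    def task_block_means(self) -> list:
        """Mean combined feedback per Task-block occurrence, in order."""
        by_block: dict = {}
        for _, _, kind, no, val in self.tick_rows:
            if kind == "TASK" and val is not None:
                by_block.setdefault(no, []).append(val)
        return [float(np.mean(by_block[k])) for k in sorted(by_block)]


def run_closed_loop(
    config: SimConfig,
    protocol: ProtocolSpec,
    calibration: Calibration | None = None,
    gain: float = 0.0,
    seed: int | None = None,
    combine_mode: str = "mean",
    metaphor: str = "DISK",
    latencies: Latencies | None = None,
    eeg_z_target: float = 2.0,
    eeg_rest_lag: float = 2.0,
    fmri_rest_lag: float = 6.0,
) -> RunResult:
    """Run one feedback session on the virtual clock.

    The subject model receives every emitted feedback sample; its
    regulation state shapes the signals generated for the *next* tick, so
    causality is strict.  ``seed`` defaults to ``config.seed``; the
    calibration (if not supplied) is run on an independent seed offset.

    EEG feedback is the rest-referenced z-score of the CSP log band power
    (self-calibrating: the rest mean and sd are replaced at every
    Rest-block end, which absorbs any scale offset between the offline
    calibration cleaning and the online cleaner), displayed against
    ``eeg_z_target``.  fMRI feedback is the background-subtracted ROI
    signal change against its rest baseline, displayed against the
    calibration task response.  Rest features gathered during the first
    ``*_rest_lag`` seconds of a Rest block are excluded from baseline
    updates (ERD recovery and the hemodynamic tail of the preceding Task
    block would otherwise bias the reference).
    """
    seed = config.seed if seed is None else int(seed)
    design, events = gen_task_design(protocol, config.tr)
    nv = design.size
    cfg = replace(config, seed=seed, n_volumes=nv)
    if calibration is None:
        calibration = calibrate(replace(cfg, seed=seed + 90001), protocol)
    lat = latencies or Latencies()

    esynth = EegSynth(cfg, np.random.default_rng(seed))
    bsynth = BoldSynth(cfg, np.random.default_rng(seed + 1))
    fs = cfg.fs_eeg
    spt = cfg.samples_per_tr
    ecg_idx = cfg.n_channels  # ECG appended last
    cleaner = OnlineEegCleaner(cfg.n_channels + 1, esynth.n_samples, fs, spt,
                               ecg_idx)
    sos_band = sps.butter(4, calibration.band, btype="bandpass", fs=fs,
                          output="sos")
    win_len = int(round(2.0 * fs))

    sched = Scheduler(protocol, cfg.tr, fs, latencies=lat)
    state = sched.start_session(0.0)
    subject = Subject(gain=gain, dt=protocol.update_period)
    eeg_base = BaselineState(calibration.eeg_baseline_value, "EEG")
    eeg_sd = {"value": max(calibration.eeg_rest_sd, 1e-9)}
    fmri_base = BaselineState(calibration.fmri_baseline_value, "FMRI")
    vx = (2.0, 2.0, 4.0)

    eff = {"state": 0.0}
    gen = {"samples": 0, "volumes": 0}
    latest = {"fmri_feat": None}
    rest_feats = {"EEG": [], "FMRI": []}
    frames, log_rows, tick_rows, subj_rows = [], [], [], []

    kinds_by_vol = _volume_kinds(events, nv, cfg.tr)
    vol_block_elapsed = np.zeros(nv)
    for onset, _, dur in events:
        a = int(round(onset / cfg.tr))
        b = min(nv, a + int(round(dur / cfg.tr)))
        vol_block_elapsed[a:b] = np.arange(b - a) * cfg.tr

    def block_kind_at(t: float) -> str:
        for onset, kind, dur in events:
            if onset <= t < onset + dur:
                return kind
        return events[-1][1] if events else "REST"

    def generate_up_to(clock: float) -> None:
        target = min(esynth.n_samples, int(np.floor(clock * fs)))
        if target > gen["samples"]:
            t_chunk = gen["samples"] / fs
            kind = block_kind_at(t_chunk)
            contaminated, *_ = esynth.chunk(gen["samples"], target,
                                            eff["state"], kind == "TASK")
            cleaner.append(contaminated)
            gen["samples"] = target
        while gen["volumes"] < nv and (gen["volumes"] + 1) * cfg.tr <= clock:
            k = gen["volumes"]
            vol = bsynth.generate(k, design[k], eff["state"])
            sm = gaussian_smooth(vol, calibration.fwhm, vx)
            feat = fmri_feature(roi_mean(sm, calibration.roi.mask),
                                roi_mean(sm, calibration.bg_mask))
            latest["fmri_feat"] = feat
            if (kinds_by_vol[k] == "REST"
                    and vol_block_elapsed[k] >= fmri_rest_lag):
                rest_feats["FMRI"].append(feat)
            gen["volumes"] += 1

    def compute_nfb(st, k, t, task_on):
        end = int(np.floor((t - lat.eeg) * fs))
        window = cleaner.window(end, win_len)
        if window is None or latest["fmri_feat"] is None:
            return None
        filt = sps.sosfiltfilt(sos_band, window, axis=1)
        f_e = eeg_feature(filt, calibration.feature_csp)
        kind = sched.blocks[st.block_index].kind
        elapsed = (k - st.block_start_tick) * sched.u
        if kind == "REST" and elapsed >= eeg_rest_lag:
            rest_feats["EEG"].append(f_e)
        raw_e = calibration.eeg_sign * zscore_feedback(
            f_e, eeg_base.value, eeg_sd["value"])
        norm_e = normalize_for_display(raw_e, eeg_z_target, 0.0)
        raw_f = latest["fmri_feat"] - fmri_base.value
        norm_f = normalize_for_display(raw_f, calibration.fmri_target, 0.0)
        sample = combine(norm_e, norm_f, combine_mode, timestamp=t)
        frames.append(map_nfb(sample, metaphor, tick=k))
        for modality, raw, base, norm in (
            ("EEG", raw_e, eeg_base.value, norm_e),
            ("FMRI", raw_f, fmri_base.value, norm_f),
        ):
            log_rows.append((t, kind, modality, raw, base, norm, sample.scalar))
        return sample

    def on_tick(st, k, t, task_on, nfb_sample):
        value = nfb_sample.scalar if nfb_sample is not None else 0.0
        eff["state"] = subject.step(task_on, value)
        subj_rows.append((k, eff["state"]))
        kind = sched.blocks[st.block_index].kind
        task_no = sum(1 for b in sched.blocks[: st.block_index + 1]
                      if b.kind == "TASK") if kind == "TASK" else 0
        tick_rows.append((k, t, kind, task_no,
                          nfb_sample.scalar if nfb_sample else None))

    def on_transition(old_kind, new_kind, k):
        if old_kind == "REST":
            if len(rest_feats["EEG"]) >= 3:
                eeg_sd["value"] = max(
                    float(np.std(rest_feats["EEG"], ddof=1)), 1e-9)
            update_baseline(eeg_base, rest_feats["EEG"])
            update_baseline(fmri_base, rest_feats["FMRI"])
            rest_feats["EEG"], rest_feats["FMRI"] = [], []

    total = sched.begin + sum(
        b.duration if b.duration is not None else b.duration_range[1]
        for b in sched.blocks
    )
    eeg_view = SimpleNamespace(n_samples=0)
    vol_view = SimpleNamespace(n_volumes=0)
    n_steps = int(np.ceil(total / sched.u)) + 2
    for m in range(1, n_steps + 1):
        clock = m * sched.u
        generate_up_to(clock)
        eeg_view.n_samples = gen["samples"]
        vol_view.n_volumes = gen["volumes"]
        sched.step(state, clock, eeg_view, vol_view,
                   compute_nfb=compute_nfb, on_tick=on_tick,
                   on_transition=on_transition)
        if state.finished or state.aborted:
            break

    nfb_log = pd.DataFrame(
        log_rows,
        columns=["time_s", "block", "modality", "raw", "baseline",
                 "normalized", "combined"],
    )
    return RunResult(
        samples=list(state.emitted), frames=frames, nfb_log=nfb_log,
        event_log=list(state.event_log), tick_rows=tick_rows,
        subject_trace=subj_rows, calibration=calibration,
        aborted=state.aborted, reports=list(state.reports),
    )
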