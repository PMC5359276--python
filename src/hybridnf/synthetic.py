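"""Ground-truthed bimodal signal simulator.

Everything downstream (artifact correction, CSP, incremental GLM, the
closed-loop scheduler) is exercised against data produced here, where the
clean EEG, the two scanner-borne artifact components, the BOLD activation
pattern and the subject's regulation state are all known exactly.

The EEG model is broadband Gaussian noise plus 8-30 Hz oscillators on two
"motor" channels whose amplitude drops during Task in proportion to
``erd_depth`` times the subject's regulation state (event-related
desynchronization).  The gradient artifact is one fixed band-limited
waveform repeated identically every TR, scaled to ``artifact_gain`` times
the clean-EEG RMS; the ballistocardiogram artifact is a damped-sinusoid
pulse placed at each R peak of a synthetic ECG.  The contaminated signal is
*exactly* clean + gradient + BCG, so template-subtraction residuals can be
measured to machine precision.

The BOLD model is baseline + beta x (HRF * design, modulated by the subject
state) on a small active block, plus linear scanner drift and Gaussian
noise; the top slice never carries task signal and serves as the background
region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import EegStream, MarkerEvent, VolumeSeries
from .hemo import double_gamma_hrf
from .protocol import ProtocolSpec, validate_protocol
from .core import ProtocolError

_CHANNEL_POOL = [
    "C3", "C4", "Cz", "F3", "F4", "P3", "P4", "O1", "O2", "Fz", "Pz", "Oz",
    "T7", "T8", "F7", "F8", "P7", "P8", "FC1", "FC2", "CP1", "CP2", "FC5",
    "FC6", "CP5", "CP6", "TP9", "TP10", "FT9", "FT10", "AF3", "AF4",
]

MOTOR_CHANNELS = (0, 1)  # C3, C4 carry the task-modulated oscillators
ECG_LABEL = "ECG"


@dataclass
class SimConfig:
    """Study conditions for one simulated session.

    Defaults follow the acquisition regime the platform targets: EEG
    digitized at 250 Hz, EPI with TR = 2 s, gradient artifact two orders of
    magnitude above clean EEG, 20 s Task/Rest blocks handled by the
    protocol layer.  The 12x12x6 grid is a scaled-down EPI matrix so a full
    session simulates in seconds; all sizes are configurable upward.
    """

    seed: int = 0
    n_channels: int = 8
    fs_eeg: float = 250.0
    tr: float = 2.0
    n_volumes: int = 80
    grid_shape: tuple = (12, 12, 6)
    artifact_gain: float = 100.0
    heart_rate: float = 66.0  # incommensurate with TR: beats not TR-locked
    heart_jitter_sd: float = 0.0
    erd_depth: float = 0.5
    drift_slope: float = 0.0
    noise_sd_eeg: float = 1.0
    noise_sd_bold: float = 0.1
    osc_amp: float = 2.0
    bcg_amp: float = 5.0
    bold_beta: float = 1.0
    bold_baseline: float = 100.0

    def __post_init__(self):
        spt = self.fs_eeg * self.tr
        if abs(spt - round(spt)) > 1e-9:
            raise ValueError(
                f"fs_eeg x tr = {spt} must be an integer number of samples per TR"
            )
        if self.artifact_gain < 0:
            raise ValueError("artifact_gain must be >= 0")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if len(self.grid_shape) != 3 or any(g <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape must be three positive extents")
        if self.n_channels < 2 or self.n_channels > len(_CHANNEL_POOL):
            raise ValueError(
                f"n_channels must be in [2, {len(_CHANNEL_POOL)}]"
            )
        if self.n_volumes < 0:
            raise ValueError("n_volumes must be >= 0")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")

    @property
    def samples_per_tr(self) -> int:
        return int(round(self.fs_eeg * self.tr))

    @property
    def n_samples(self) -> int:
        return self.samples_per_tr * self.n_volumes

    def channel_labels(self, with_ecg: bool = True) -> list:
        labels = _CHANNEL_POOL[: self.n_channels]
        return labels + [ECG_LABEL] if with_ecg else list(labels)


@dataclass
class GroundTruth:
    """Exact decomposition of a simulated run, for tests and scoring.

    EEG matrices include the appended ECG row; ``contaminated = clean_eeg +
    gradient_component + bcg_component`` holds to machine precision.
    """

    clean_eeg: np.ndarray = None
    gradient_component: np.ndarray = None
    bcg_component: np.ndarray = None
    r_peak_samples: np.ndarray = None
    true_betas: np.ndarray = None
    active_mask: np.ndarray = None
    baseline: float = None
    subject_trace: np.ndarray = None


# ---------------------------------------------------------------------------
# task design


def gen_task_design(protocol: ProtocolSpec, tr: float) -> tuple:
    """Per-volume boxcar (1 = Task) plus a block event list.

    Fixed protocols only: every block duration must be a positive multiple
    of the TR so block edges fall on volume boundaries.  Events are
    ``(onset_s, kind, duration_s)`` tuples with onsets measured from t0.
    """
    spec = validate_protocol(protocol)
    if spec.mode != "fixed":
        raise ProtocolError(
            "gen_task_design requires a fixed protocol; flexible block "
            "durations are decided at run time by the scheduler"
        )
    boxcar = []
    events = []
    t = 0.0
    for b in spec.expanded_blocks():
        ratio = b.duration / tr
        n_vol = int(round(ratio))
        if abs(ratio - n_vol) > 1e-9 or n_vol == 0:
            raise ProtocolError(
                f"{b.kind} duration {b.duration} s is not a positive multiple "
                f"of TR={tr} s; fixed blocks must span whole volumes"
            )
        boxcar.extend([1.0 if b.kind == "TASK" else 0.0] * n_vol)
        events.append((t, b.kind, float(b.duration)))
        t += b.duration
    return np.asarray(boxcar, dtype=float), events


# ---------------------------------------------------------------------------
# subject model


def subject_step(
    state: float,
    task_on: bool,
    nfb: float = 0.0,
    gain: float = 0.0,
    dt: float = 0.5,
    tau_task: float = 6.0,
    tau_rest: float = 4.0,
) -> float:
    """One tick of the first-order regulation dynamics.

    During Task the state relaxes toward 1 with rate (1 + gain x positive
    NFB) / tau_task; during Rest it decays toward 0 with time constant
    tau_rest.  Output clamped to [0, 1].
    """
    state = float(np.clip(state, 0.0, 1.0))
    pos = max(0.0, float(nfb))
    if task_on:
        rate = (1.0 + gain * pos) / tau_task
        state = state + (1.0 - state) * (1.0 - math.exp(-rate * dt))
    else:
        state = state * math.exp(-dt / tau_rest)
    return float(np.clip(state, 0.0, 1.0))


@dataclass
class Subject:
    """Feedback-responsive regulator with a slow learning component.

    The fast state ``x`` follows :func:`subject_step`.  A non-decaying
    ``skill`` term accumulates with gain x positive feedback during Task,
    modelling across-block learning; the effective regulation presented to
    the signal generators is ``min(1, x + skill)`` during Task and ``x``
    during Rest, so resting activity stays stationary while task-evoked
    responses grow with training when gain > 0.
    """

    gain: float = 0.0
    dt: float = 0.5
    learning_rate: float = 0.02
    skill_cap: float = 0.6
    x: float = 0.0
    skill: float = 0.0

    def step(self, task_on: bool, nfb: float = 0.0) -> float:
        self.x = subject_step(self.x, task_on, nfb, self.gain, dt=self.dt)
        if task_on:
            self.skill = min(
                self.skill_cap,
                self.skill + self.learning_rate * self.gain * max(0.0, nfb) * self.dt,
            )
            return min(1.0, self.x + self.skill)
        return self.x


def open_loop_trace(design: np.ndarray, dt: float) -> np.ndarray:
    """Regulation trace of a gain-0 subject driven by the task design,
    sampled once per design entry (spacing ``dt`` seconds)."""
    subj = Subject(gain=0.0, dt=dt)
    return np.array([subj.step(bool(d)) for d in design])


# ---------------------------------------------------------------------------
# EEG synthesis


class EegSynth:
    """Chunkwise EEG generator with exact artifact bookkeeping.

    All random draws happen at construction in a fixed order from a single
    generator, so output is bitwise-deterministic and independent of the
    chunking used to read it (the closed loop reads tick-sized chunks, the
    batch API volume-sized ones).
    """

    def __init__(self, config: SimConfig, rng: np.random.Generator,
                 n_volumes: int | None = None):
        self.config = config
        nv = config.n_volumes if n_volumes is None else n_volumes
        self.n_volumes = nv
        fs = config.fs_eeg
        spt = config.samples_per_tr
        n = spt * nv
        self.n_samples = n
        nch = config.n_channels

        # clean model: broadband noise + motor-channel oscillators
        self.noise = rng.normal(0.0, config.noise_sd_eeg, size=(nch, n))
        t = np.arange(n) / fs
        self.osc = np.zeros((nch, n))
        for ch in MOTOR_CHANNELS:
            if ch < nch:
                p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
                # non-integer Hz: oscillations are not periodic in the TR
                # or the inter-beat interval, so artifact templates cannot
                # coherently absorb them
                self.osc[ch] = config.osc_amp * (
                    np.sin(2 * np.pi * 9.7 * t + p1)
                    + 0.7 * np.sin(2 * np.pi * 21.4 * t + p2)
                )

        # gradient artifact: one fixed band-limited template repeated per TR
        raw = rng.normal(size=(nch + 1, spt))
        if spt > 30:
            sos = sps.butter(4, min(100.0, 0.45 * fs), btype="low", fs=fs,
                             output="sos")
            raw = sps.sosfiltfilt(sos, raw, axis=1)
        rest_rms = float(np.sqrt(np.mean((self.noise + self.osc) ** 2)))
        tpl_rms = float(np.sqrt(np.mean(raw[:nch] ** 2)))
        scale = (config.artifact_gain * rest_rms / tpl_rms) if tpl_rms > 0 else 0.0
        self.gradient_template = raw * scale

        # heartbeat schedule and BCG pulse
        self.r_peaks = self._beat_schedule(rng)
        lb = int(round(0.3 * fs))
        tp = np.arange(lb) / fs
        pulse = np.exp(-tp / 0.12) * np.sin(2 * np.pi * 7.0 * tp)
        weights = config.bcg_amp * rng.uniform(0.5, 1.5, size=nch)
        self.bcg = np.zeros((nch, n))
        for k, p in enumerate(self.r_peaks):
            shift = 0
            if config.heart_jitter_sd > 0:
                shift = int(round(rng.normal(0.0, config.heart_jitter_sd) * fs))
            a = p + shift
            if a < 0:
                continue
            b = min(n, a + lb)
            if a < n:
                self.bcg[:, a:b] += weights[:, None] * pulse[: b - a]

        # ECG channel: small noise + sharp biphasic R spikes
        self.ecg = rng.normal(0.0, 0.05 * config.bcg_amp, size=n)
        lq = max(3, int(round(0.08 * fs)) | 1)  # odd length, centered
        tq = np.linspace(-1.0, 1.0, lq)
        qrs = np.exp(-(tq ** 2) / 0.045)  # monophasic R wave
        qrs *= 800.0 / qrs.max()
        half = lq // 2
        for p in self.r_peaks:
            a, b = p - half, p - half + lq
            sa, sb = max(a, 0), min(b, n)
            if sa < sb:
                self.ecg[sa:sb] += qrs[sa - a: sb - a]

    def _beat_schedule(self, rng: np.random.Generator) -> np.ndarray:
        cfg = self.config
        mean_ibi = 60.0 / cfg.heart_rate
        peaks = []
        t = 0.4 * mean_ibi
        while t * cfg.fs_eeg < self.n_samples:
            peaks.append(int(round(t * cfg.fs_eeg)))
            ibi = mean_ibi
            if cfg.heart_jitter_sd > 0:
                ibi = ibi + rng.normal(0.0, cfg.heart_jitter_sd)
            t += max(0.35, ibi)  # refractory floor
        return np.asarray(peaks, dtype=int)

    def chunk(self, start: int, stop: int, state: float, task_on: bool):
        """Samples [start, stop): returns (contaminated, clean, gradient,
        bcg) matrices with the ECG row appended last."""
        cfg = self.config
        stop = min(stop, self.n_samples)
        nch = cfg.n_channels
        mod = 1.0 - cfg.erd_depth * float(state) * (1.0 if task_on else 0.0)
        clean = self.noise[:, start:stop].copy()
        for ch in MOTOR_CHANNELS:
            if ch < nch:
                clean[ch] += mod * self.osc[ch, start:stop]
        clean = np.vstack([clean, self.ecg[start:stop]])
        spt = cfg.samples_per_tr
        idx = (np.arange(start, stop)) % spt
        gradient = self.gradient_template[:, idx]
        bcg = np.vstack(
            [self.bcg[:, start:stop], np.zeros(stop - start)]
        )
        return clean + gradient + bcg, clean, gradient, bcg


def gen_eeg(
    config: SimConfig,
    subject_trace: np.ndarray | None = None,
    design: np.ndarray | None = None,
) -> tuple:
    """Full-session contaminated EEG stream plus its exact ground truth.

    ``subject_trace`` and ``design`` are per-volume vectors (defaults: full
    regulation, all-Rest).  TTL markers are placed at every TR boundary.
    """
    nv = config.n_volumes
    design = np.zeros(nv) if design is None else np.asarray(design, float)
    trace = np.ones(nv) if subject_trace is None else np.asarray(subject_trace, float)
    if design.size != nv or trace.size != nv:
        raise ValueError("design and subject_trace must have one entry per volume")
    rng = np.random.default_rng(config.seed)
    synth = EegSynth(config, rng)
    spt = config.samples_per_tr
    parts = [synth.chunk(k * spt, (k + 1) * spt, trace[k], bool(design[k]))
             for k in range(nv)]
    if nv:
        cont = np.hstack([p[0] for p in parts])
        clean = np.hstack([p[1] for p in parts])
        grad = np.hstack([p[2] for p in parts])
        bcg = np.hstack([p[3] for p in parts])
    else:
        cont = clean = grad = bcg = np.zeros((config.n_channels + 1, 0))
    markers = [MarkerEvent("TTL", k * spt, f"V{k + 1}") for k in range(nv)]
    stream = EegStream(cont, config.fs_eeg, config.channel_labels(), markers)
    truth = GroundTruth(
        clean_eeg=clean,
        gradient_component=grad,
        bcg_component=bcg,
        r_peak_samples=synth.r_peaks,
        subject_trace=trace,
    )
    return stream, truth


# ---------------------------------------------------------------------------
# BOLD synthesis


def default_active_mask(grid_shape: tuple) -> np.ndarray:
    """3x3x1 active block centered in-plane, mid slice, never the top slice."""
    nx, ny, nz = grid_shape
    mask = np.zeros(grid_shape, dtype=bool)
    cx, cy = nx // 2, ny // 2
    cz = min(nz // 2, max(0, nz - 2))
    mask[max(0, cx - 1): cx + 2, max(0, cy - 1): cy + 2, cz] = True
    return mask


class BoldSynth:
    """Volume-by-volume BOLD generator with causal HRF convolution."""

    def __init__(self, config: SimConfig, rng: np.random.Generator,
                 n_volumes: int | None = None,
                 active_mask: np.ndarray | None = None,
                 betas: np.ndarray | None = None):
        self.config = config
        nv = config.n_volumes if n_volumes is None else n_volumes
        self.n_volumes = nv
        self.noise = (
            rng.normal(0.0, config.noise_sd_bold, size=(nv,) + tuple(config.grid_shape))
            if config.noise_sd_bold > 0
            else np.zeros((nv,) + tuple(config.grid_shape))
        )
        self.active_mask = (
            default_active_mask(config.grid_shape)
            if active_mask is None else np.asarray(active_mask, bool)
        )
        if betas is None:
            betas = np.where(self.active_mask, config.bold_beta, 0.0)
        self.betas = np.asarray(betas, float)
        # top slice is the background region: no task modulation there
        self.betas[..., -1] = 0.0
        self.hrf = double_gamma_hrf(config.tr)
        self._d_eff = np.zeros(nv)

    def generate(self, k: int, design_val: float, state: float) -> np.ndarray:
        """Volume ``k`` given the design value and subject state during it."""
        cfg = self.config
        self._d_eff[k] = float(design_val) * float(state)
        j0 = max(0, k - self.hrf.size + 1)
        conv = float(np.dot(self._d_eff[j0: k + 1][::-1], self.hrf[: k - j0 + 1]))
        return (
            cfg.bold_baseline
            + self.betas * conv
            + cfg.drift_slope * k
            + self.noise[k]
        )


def gen_fmri(
    config: SimConfig,
    design: np.ndarray | None = None,
    subject_trace: np.ndarray | None = None,
) -> tuple:
    """Full-session BOLD volume series plus ground truth."""
    nv = config.n_volumes
    design = np.zeros(nv) if design is None else np.asarray(design, float)
    trace = np.ones(nv) if subject_trace is None else np.asarray(subject_trace, float)
    if design.size != nv or trace.size != nv:
        raise ValueError("design and subject_trace must have one entry per volume")
    rng = np.random.default_rng(config.seed + 1)
    synth = BoldSynth(config, rng)
    vols = np.stack(
        [synth.generate(k, design[k], trace[k]) for k in range(nv)]
    ) if nv else np.zeros((0,) + tuple(config.grid_shape))
    series = VolumeSeries(vols, tr=config.tr,
                          timestamps=np.arange(nv) * config.tr)
    truth = GroundTruth(
        true_betas=synth.betas,
        active_mask=synth.active_mask,
        baseline=config.bold_baseline,
        subject_trace=trace,
    )
    return series, truth
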