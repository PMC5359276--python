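"""Real-time EEG processing: artifact template subtraction, band-pass
filtering, CSP spatial filtering and band-power feature extraction.

Both MR-induced artifacts are handled by average artifact subtraction (AAS):
the mean of the last N equally shaped epochs (anchored at TR boundaries for
the gradient artifact, at detected R peaks for the ballistocardiogram) is
subtracted from each incoming epoch.  The sliding template uses 5-15 TRs for
the gradient and 10-20 pulse intervals for the BCG.  Epochs arriving before
the buffer holds anything pass through unmodified and are flagged; once at
least one epoch is stored, partial-mean correction applies.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .core import DesyncError, EegStream

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# R-peak detection


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    refractory: float = 0.3,
    band: tuple = (5.0, 15.0),
    k_mad: float = 4.0,
) -> np.ndarray:
    """Detect R peaks on a single ECG channel.

    Band-pass (default 5-15 Hz) then threshold the rectified signal at
    ``k_mad`` times the MAD-based robust scale; peaks closer than the
    refractory period to the previously kept peak are dropped (the first of
    a too-close pair survives).  A flat or empty trace yields an empty
    array with a warning rather than an exception.
    """
    ecg = np.asarray(ecg, dtype=float).ravel()
    if ecg.size < int(refractory * fs) + 1 or np.ptp(ecg) == 0.0:
        warnings.warn("ECG trace flat or too short: no R peaks detected")
        return np.array([], dtype=int)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, ecg)
    env = np.abs(filt)
    scale = 1.4826 * np.median(np.abs(env - np.median(env)))
    if scale == 0.0:
        warnings.warn("degenerate ECG amplitude distribution: no R peaks")
        return np.array([], dtype=int)
    # MAD floor plus an amplitude-aware term (median of per-second envelope
    # maxima ~ typical beat amplitude) so QRS side lobes stay subthreshold
    blk = max(1, int(round(fs)))
    nblk = env.size // blk
    beat_amp = float(np.median(env[: nblk * blk].reshape(nblk, blk).max(axis=1))) \
        if nblk else float(env.max())
    thr = max(k_mad * scale, 0.4 * beat_amp)
    cand, _ = sps.find_peaks(env, height=thr)
    gap = int(round(refractory * fs))
    refine = max(1, int(round(0.08 * fs)))
    kept = []
    for p in cand:
        if not kept or p - kept[-1] >= gap:
            q = int(p + np.argmax(env[p: p + refine]))  # snap to the R apex
            kept.append(q)
    return np.asarray(kept, dtype=int)


# ---------------------------------------------------------------------------
# average artifact subtraction


@dataclass
class TemplateBuffer:
    """FIFO of the most recent artifact epochs (channels x epoch_length)."""

    capacity: int
    epoch_length: int | None = None
    epochs: deque = field(default_factory=deque)

    def __post_init__(self):
        if self.capacity < 1:
            raise ValueError("buffer capacity must be >= 1")

    def push(self, epoch: np.ndarray) -> None:
        if self.epoch_length is None:
            self.epoch_length = epoch.shape[1]
        if epoch.shape[1] != self.epoch_length:
            raise ValueError("all buffered epochs must share one shape")
        self.epochs.append(np.array(epoch, dtype=float))
        while len(self.epochs) > self.capacity:
            self.epochs.popleft()

    def template(self) -> np.ndarray | None:
        if not self.epochs:
            return None
        return np.mean(np.stack(list(self.epochs)), axis=0)

    def __len__(self) -> int:
        return len(self.epochs)


@dataclass
class CorrectionResult:
    stream: EegStream
    buffer: TemplateBuffer
    passthrough_epochs: list


def template_correct(
    stream: EegStream,
    anchors: np.ndarray,
    buffer: TemplateBuffer,
    mode: str = "gradient",
    spacing_tol: float = 0.05,
) -> CorrectionResult:
    """Sliding average-artifact subtraction anchored at ``anchors``.

    Each epoch ``[a_i, a_i + L)`` is corrected with the mean of the epochs
    currently in ``buffer`` (however many are stored, >= 1), then pushed
    into the buffer.  Epochs arriving while the buffer is empty pass
    through unmodified and are listed in ``passthrough_epochs``.  In
    gradient mode the anchors must be equally spaced (the TR grid): spacing
    deviating by more than ``spacing_tol`` of the nominal raises
    :class:`DesyncError` for the synchronization layer to handle.  The
    epoch length is ``buffer.epoch_length`` if set, else the median anchor
    spacing.
    """
    anchors = np.asarray(anchors, dtype=int)
    data = stream.data.copy()
    if anchors.size == 0:
        return CorrectionResult(stream.with_data(data), buffer, [])
    if anchors.size > 1:
        spacing = np.diff(anchors)
        nominal = float(np.median(spacing))
        if mode == "gradient" and np.any(
            np.abs(spacing - nominal) > spacing_tol * nominal
        ):
            worst = int(np.argmax(np.abs(spacing - nominal)))
            raise DesyncError(
                f"gradient anchors not equally spaced: gap {spacing[worst]} at "
                f"anchor {worst + 1} vs nominal {nominal:.1f} samples"
            )
    else:
        nominal = float(stream.n_samples - anchors[0])
    length = buffer.epoch_length or int(round(nominal))
    passthrough = []
    for i, a in enumerate(anchors):
        b = min(a + length, stream.n_samples)
        avail = b - a
        if avail <= 0:
            continue
        tpl = buffer.template()
        if tpl is None:
            passthrough.append(i)
        else:
            data[:, a:b] = data[:, a:b] - tpl[:, :avail]
        if avail == length:  # only whole epochs enter the template
            buffer.push(stream.data[:, a:b])
    return CorrectionResult(stream.with_data(data), buffer, passthrough)


# ---------------------------------------------------------------------------
# temporal filtering and windowing


def bandpass(stream: EegStream, low: float, high: float, order: int = 4) -> EegStream:
    """Zero-phase (forward-backward) Butterworth band-pass per channel."""
    if not 0 < low < high < stream.fs / 2:
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for fs={stream.fs} Hz"
        )
    sos = sps.butter(order, (low, high), btype="bandpass", fs=stream.fs,
                     output="sos")
    return stream.with_data(sps.sosfiltfilt(sos, stream.data, axis=1))


@dataclass(frozen=True)
class Window:
    start_sample: int
    start_time: float
    data: np.ndarray


def segment_windows(stream: EegStream, win: float, overlap: float) -> list:
    """Sliding windows of ``win`` seconds with fractional ``overlap``.

    Step = win x (1 - overlap); windows are emitted only while fully inside
    the stream, with start times at exact multiples of the step.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    nwin = win * stream.fs
    if abs(nwin - round(nwin)) > 1e-9:
        raise ValueError("win x fs must be an integer number of samples")
    nwin = int(round(nwin))
    step_s = win * (1.0 - overlap)
    out = []
    i = 0
    while True:
        start = int(round(i * step_s * stream.fs))
        if start + nwin > stream.n_samples:
            break
        out.append(Window(start, start / stream.fs,
                          stream.data[:, start: start + nwin]))
        i += 1
    return out


# ---------------------------------------------------------------------------
# common spatial patterns


@dataclass
class CspModel:
    """CSP filter bank: rows of ``filters`` project channels onto
    components; ``patterns`` columns are the corresponding scalp patterns
    (pseudo-inverse of the filters).  ``eigenvalues`` are the Task-class
    variance ratios of the kept components (near 1: Task-dominant, near 0:
    Rest-dominant)."""

    filters: np.ndarray
    patterns: np.ndarray
    n_pairs: int
    band: tuple
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.filters.shape[0]


def _class_covariance(windows) -> np.ndarray:
    covs = []
    for w in windows:
        x = w.data if isinstance(w, Window) else np.asarray(w, float)
        c = x @ x.T
        tr = np.trace(c)
        if tr > 0:
            covs.append(c / tr)
    return np.mean(np.stack(covs), axis=0)


def train_csp(task_windows, rest_windows, n_pairs: int = 3,
              band: tuple = (8.0, 30.0)) -> CspModel:
    """Train CSP filters from band-passed Task and Rest windows.

    Solves the generalized eigenproblem C_task w = lambda (C_task + C_rest) w
    and keeps the ``n_pairs`` largest- and smallest-eigenvalue filters
    (Task-variance maximizers and minimizers).  Rank-deficient covariances
    get diagonal shrinkage, logged.  Eigenvalue ties break by eigenvector
    index; filter signs are fixed so each filter's largest-magnitude
    coefficient is positive.
    """
    if len(task_windows) < 2 or len(rest_windows) < 2:
        raise ValueError("need at least 2 windows per class")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    c1 = _class_covariance(task_windows)
    c2 = _class_covariance(rest_windows)
    comp = c1 + c2
    n_ch = comp.shape[0]
    if np.linalg.cond(comp) > 1e10:
        gamma = 1e-6
        shrink = gamma * np.trace(comp) / n_ch * np.eye(n_ch)
        c1, c2 = c1 + shrink / 2, c2 + shrink / 2
        comp = c1 + c2
        log.warning("rank-deficient class covariances: shrinkage applied")
    evals, evecs = sla.eigh(c1, comp)  # ascending eigenvalues in [0, 1]
    n_pairs = min(n_pairs, n_ch // 2) or 1
    sel = list(range(n_ch - 1, n_ch - 1 - n_pairs, -1)) + list(range(n_pairs))
    filters = evecs[:, sel].T
    sign = np.sign(filters[np.arange(filters.shape[0]),
                           np.argmax(np.abs(filters), axis=1)])
    sign[sign == 0] = 1.0
    filters = filters * sign[:, None]
    patterns = np.linalg.pinv(filters)
    return CspModel(filters=filters, patterns=patterns, n_pairs=n_pairs,
                    band=tuple(band), eigenvalues=evals[sel])


def eeg_feature(window, model: CspModel, eps: float = 1e-12) -> float:
    """Log band power of a window: mean over the CSP components of the log
    variance of the projected signal.  A zero-variance window floors at
    log(eps) with a warning."""
    x = window.data if isinstance(window, Window) else np.asarray(window, float)
    z = model.filters @ x
    v = z.var(axis=1)
    if np.any(v <= 0):
        warnings.warn("zero-variance window: feature floored at log(eps)")
    return float(np.mean(np.log(np.maximum(v, eps))))


# ---------------------------------------------------------------------------
# streaming cleaner for the closed loop


class OnlineEegCleaner:
    """Sample-streaming gradient + BCG correction for the feedback loop.

    Gradient correction is applied on arrival: every incoming sample is
    corrected with the current sliding-TR template (samples of the very
    first TR pass through, before any template exists); completed TR epochs
    of the raw signal feed the template buffer.  R peaks are detected
    causally on the gradient-corrected ECG (streaming band-pass, threshold
    learned during the second TR); completed pulse epochs are corrected
    with the sliding pulse template with at most one pulse length of
    delay, which is within the feedback window for any realistic heart
    rate.
    """

    def __init__(self, n_channels: int, n_samples: int, fs: float,
                 samples_per_tr: int, ecg_index: int,
                 gradient_capacity: int = 10, bcg_capacity: int = 15,
                 refractory: float = 0.3, k_mad: float = 4.0):
        self.fs = fs
        self.spt = samples_per_tr
        self.ecg_index = ecg_index
        self.n_total = n_channels
        self.raw = np.zeros((n_channels, n_samples))
        self.gcorr = np.zeros((n_channels, n_samples))   # gradient-corrected
        self.corrected = np.zeros((n_channels, n_samples))
        self.end = 0
        self.grad_buffer = TemplateBuffer(gradient_capacity, samples_per_tr)
        self.pulse_len = int(round(0.35 * fs))
        self.bcg_buffer = TemplateBuffer(bcg_capacity, self.pulse_len)
        self._tr_done = 0
        self._sos = sps.butter(4, (5.0, 15.0), btype="bandpass", fs=fs,
                               output="sos")
        self._zi = np.zeros((self._sos.shape[0], 2))
        self._env = np.zeros(n_samples)
        self._thr = None
        self._refractory = int(round(refractory * fs))
        self._refine = max(1, int(round(0.08 * fs)))
        self._k_mad = k_mad
        self.r_peaks: list = []
        self._scan = samples_per_tr  # skip TR 1 (uncorrected gradient)
        self._bcg_done = 0  # peaks whose epochs are fully corrected

    def append(self, chunk: np.ndarray) -> None:
        w = self.end
        e = w + chunk.shape[1]
        self.raw[:, w:e] = chunk
        tpl = self.grad_buffer.template()
        if tpl is None:
            self.gcorr[:, w:e] = chunk
        else:
            self.gcorr[:, w:e] = chunk - tpl[:, np.arange(w, e) % self.spt]
        self.end = e
        while (self._tr_done + 1) * self.spt <= e:
            a = self._tr_done * self.spt
            self.grad_buffer.push(self.raw[:, a: a + self.spt])
            self._tr_done += 1
        self.corrected[:, w:e] = self.gcorr[:, w:e]
        self._detect_peaks(w, e)
        self._apply_bcg(e)

    def _detect_peaks(self, w: int, e: int) -> None:
        filt, self._zi = sps.sosfilt(self._sos, self.gcorr[self.ecg_index, w:e],
                                     zi=self._zi)
        self._env[w:e] = np.abs(filt)
        if self._thr is None:
            if e >= 2 * self.spt:  # learn threshold once TR 2 is corrected
                seg = self._env[self.spt: 2 * self.spt]
                med = np.median(seg)
                scale = 1.4826 * np.median(np.abs(seg - med))
                peak = self._env[self.spt: e].max()
                self._thr = max(self._k_mad * scale, 0.4 * peak)
            else:
                return
        last = self.r_peaks[-1] if self.r_peaks else -self._refractory
        i = self._scan
        while i < e:
            if self._env[i] > self._thr and i - last >= self._refractory:
                if i + self._refine > e:
                    break  # apex may still be arriving; resume next chunk
                q = i + int(np.argmax(self._env[i: i + self._refine]))
                self.r_peaks.append(q)
                last = q
                i = q + self._refractory
            else:
                i += 1
        self._scan = i

    def _apply_bcg(self, e: int) -> None:
        while self._bcg_done < len(self.r_peaks):
            p = self.r_peaks[self._bcg_done]
            if p + self.pulse_len > e:
                break
            tpl = self.bcg_buffer.template()
            if tpl is not None:
                self.corrected[:, p: p + self.pulse_len] = (
                    self.gcorr[:, p: p + self.pulse_len] - tpl
                )
            self.bcg_buffer.push(self.gcorr[:, p: p + self.pulse_len])
            self._bcg_done += 1

    def window(self, end_sample: int, length: int) -> np.ndarray | None:
        """Corrected samples [end - length, end) without the ECG row."""
        if end_sample - length < 0 or end_sample > self.end:
            return None
        rows = [i for i in range(self.n_total) if i != self.ecg_index]
        return self.corrected[rows, end_sample - length: end_sample]


def _top_component_variance(w: np.ndarray, window) -> float:
    x = window.data if isinstance(window, Window) else np.asarray(window, float)
    c = x @ x.T
    return float(w @ c @ w / np.trace(c))


def csp_separation(model: CspModel, task_windows, rest_windows) -> float:
    """Fraction of windows correctly ranked by the top CSP component's
    normalized variance (0.5 = no separation)."""
    w = model.filters[0]
    tv = [_top_component_variance(w, x) for x in task_windows]
    rv = [_top_component_variance(w, x) for x in rest_windows]
    thr = float(np.median(tv + rv))
    correct = sum(v > thr for v in tv) + sum(v <= thr for v in rv)
    return correct / (len(tv) + len(rv))
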