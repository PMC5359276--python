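"""Core data containers and exceptions shared across the pipelines.

The two acquisition modalities flow through the system as :class:`EegStream`
(a channels x samples matrix in microvolts with time-stamped markers) and
:class:`VolumeSeries` (an ordered stack of 3-D BOLD volumes with a TR).
Feedback values travel as :class:`NfbSample`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MARKER_KINDS = frozenset({"TTL", "R_PEAK", "PROTOCOL", "NFB_UPDATE"})


class HybridNfError(Exception):
    """Base class for package errors."""


class DesyncError(HybridNfError):
    """Raised when acquisition anchors violate their timing contract."""


class CalibrationError(HybridNfError):
    """Raised when calibration produced unusable state (empty ROI, sd<=0...)."""


class ProtocolError(HybridNfError):
    """Raised for invalid protocol specifications or session misuse."""


class NoActiveClusterError(CalibrationError):
    """No supra-threshold cluster survived activation mapping."""


@dataclass(frozen=True)
class MarkerEvent:
    """A time-stamped event attached to an EEG stream."""

    kind: str
    sample: int
    label: str = ""

    def __post_init__(self):
        if self.kind not in MARKER_KINDS:
            raise ValueError(
                f"marker kind {self.kind!r} not in {sorted(MARKER_KINDS)}"
            )
        if self.sample < 0:
            raise ValueError("marker sample must be >= 0")


@dataclass
class EegStream:
    """Multichannel EEG segment.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names, one per row of ``data``.
    markers : list of MarkerEvent
        Events with sample indices inside ``[0, n_samples)``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list
    markers: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        for m in self.markers:
            if not 0 <= m.sample < self.data.shape[1]:
                raise ValueError(
                    f"marker at sample {m.sample} outside [0, {self.data.shape[1]})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "EegStream":
        """Copy of the stream with replaced sample matrix (markers kept)."""
        return replace(self, data=np.asarray(data, float), markers=list(self.markers))

    def marker_samples(self, kind: str) -> np.ndarray:
        return np.array([m.sample for m in self.markers if m.kind == kind], dtype=int)


@dataclass
class VolumeSeries:
    """Ordered series of 3-D BOLD volumes.

    ``data`` has shape (n_volumes, nx, ny, nz); ``timestamps`` are acquisition
    onsets in seconds from the session reference, strictly increasing by ~TR.
    """

    data: np.ndarray
    tr: float
    timestamps: np.ndarray = None
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("volume series must be 4-D (t, x, y, z)")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(self.data.shape[0]) * self.tr
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if self.timestamps.shape != (self.data.shape[0],):
            raise ValueError("one timestamp per volume required")
        if self.data.shape[0] > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.affine is None:
            self.affine = np.diag([2.0, 2.0, 4.0, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[1:]

    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class NfbSample:
    """A 1- or 2-dimensional feedback value with provenance.

    ``values`` is ordered [EEG, fMRI] in bimodal vector mode.  When
    ``normalized`` is set every component must lie in [0, 1].
    """

    values: np.ndarray
    modalities: tuple
    timestamp: float
    normalized: bool = False

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 1 or self.values.size not in (1, 2):
            raise ValueError("NFB value must be a 1- or 2-vector")
        self.modalities = tuple(self.modalities)
        if len(self.modalities) != self.values.size:
            raise ValueError("one modality tag per component required")
        if self.normalized and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            raise ValueError("normalized NFB components must lie in [0, 1]")

    @property
    def scalar(self) -> float:
        """Mean of the components (the display-ready scalar for 1-D metaphors)."""
        return float(self.values.mean())
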