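"""Feedback computation: percent signal change, z-scores, ROI-size change,
rest-block baselines and unimodal/bimodal combination.

The feedback statistic is the average percent signal change (APSC) of a
feature against its Rest baseline.  For ratio-scaled features (BOLD) the
usual 100 x (x - b) / |b| applies; log-power EEG features use a scaled
difference instead, since a ratio of logarithms has no meaningful scale.
Baselines start from the calibration average over all Rest intervals and
are replaced by the just-finished Rest block's mean at every Rest-block
end (a cumulative-average policy is available for drift-free protocols).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CalibrationError, NfbSample


def apsc(feature: float, baseline: float, mode: str = "ratio",
         scale: float = 100.0) -> float:
    """Average percent signal change of a feature against its baseline.

    ratio mode: 100 x (feature - baseline) / |baseline|; difference mode:
    scale x (feature - baseline), for log-domain features.  Increase maps
    to a positive value in both modes.
    """
    if mode == "ratio":
        if baseline == 0:
            raise CalibrationError(
                "baseline is 0: ratio-mode APSC undefined, use difference mode"
            )
        return 100.0 * (feature - baseline) / abs(baseline)
    if mode == "difference":
        return scale * (feature - baseline)
    raise ValueError(f"unknown APSC mode {mode!r}")


def zscore_feedback(feature: float, rest_mean: float, rest_sd: float) -> float:
    """Feature expressed in Rest-distribution standard deviations."""
    if rest_sd <= 0:
        raise CalibrationError("rest sd must be positive (degenerate calibration)")
    return (feature - rest_mean) / rest_sd


def roi_size_change(current_size: int, baseline_size: int) -> float:
    """Relative ROI-size change in percent."""
    if baseline_size <= 0:
        raise CalibrationError("baseline ROI size must be positive")
    return 100.0 * (current_size - baseline_size) / baseline_size


@dataclass
class BaselineState:
    """Per-modality Rest baseline with its update history."""

    value: float
    modality: str
    n_contributing: int = 1
    policy: str = "replace"  # or "cumulative"
    history: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_contributing < 1:
            raise CalibrationError(
                "baseline must be built from at least one rest feature"
            )
        if self.policy not in ("replace", "cumulative"):
            raise ValueError(f"unknown baseline policy {self.policy!r}")


def update_baseline(state: BaselineState, rest_block_features) -> BaselineState:
    """End-of-Rest-block baseline update.

    ``replace``: the baseline becomes the just-finished block's feature
    mean (tracks slow drift).  ``cumulative``: running average over all
    blocks seen so far.  An empty block leaves the state unchanged with a
    warning.
    """
    feats = np.asarray(list(rest_block_features), dtype=float)
    if feats.size == 0:
        warnings.warn("empty rest block: baseline left unchanged")
        return state
    block_mean = float(feats.mean())
    state.history.append(block_mean)
    if state.policy == "replace":
        state.value = block_mean
        state.n_contributing = feats.size
    else:
        total = state.n_contributing + feats.size
        state.value = (
            state.value * state.n_contributing + block_mean * feats.size
        ) / total
        state.n_contributing = total
    return state


def combine(eeg_nfb: float | None, fmri_nfb: float | None,
            mode: str = "vector2d", w: float = 0.5,
            timestamp: float = 0.0, normalized: bool = True) -> NfbSample:
    """Combine per-modality feedback values into an :class:`NfbSample`.

    ``vector2d`` keeps the two values as [EEG, fMRI]; ``mean`` averages
    them; ``weighted`` returns w x EEG + (1 - w) x fMRI; ``unimodal``
    passes the single provided value through.  A bimodal mode with a
    missing value raises an error naming the stalled pipeline.
    """
    have_eeg, have_fmri = eeg_nfb is not None, fmri_nfb is not None
    if not (have_eeg or have_fmri):
        raise ValueError("at least one modality value required")
    if mode == "unimodal":
        if have_eeg and have_fmri:
            raise ValueError("unimodal mode accepts exactly one value")
        if have_eeg:
            return NfbSample([eeg_nfb], ("EEG",), timestamp, normalized)
        return NfbSample([fmri_nfb], ("FMRI",), timestamp, normalized)
    if mode not in ("vector2d", "mean", "weighted"):
        raise ValueError(f"unknown combination mode {mode!r}")
    if not (have_eeg and have_fmri):
        missing = "EEG" if not have_eeg else "fMRI"
        raise ValueError(
            f"bimodal mode {mode!r} requires both values: the {missing} "
            "pipeline has not delivered a feature"
        )
    if mode == "vector2d":
        return NfbSample([eeg_nfb, fmri_nfb], ("EEG", "FMRI"),
                         timestamp, normalized)
    if mode == "mean":
        return NfbSample([(eeg_nfb + fmri_nfb) / 2.0], ("EEG+FMRI",),
                         timestamp, normalized)
    if not 0.0 <= w <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    return NfbSample([w * eeg_nfb + (1.0 - w) * fmri_nfb],
                     ("EEG+FMRI",), timestamp, normalized)


def normalize_for_display(raw: float, target: float, floor: float = 0.0) -> float:
    """Map a raw feedback value onto [0, 1] between floor and target."""
    if target <= floor:
        raise CalibrationError(
            f"display target ({target}) must exceed the floor ({floor})"
        )
    return float(np.clip((raw - floor) / (target - floor), 0.0, 1.0))
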