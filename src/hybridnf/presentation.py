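"""Deterministic mappings from normalized feedback values to visual
metaphors (pure geometry on the unit canvas; no rendering dependency).

SUN: brightness follows the EEG value, radius the fMRI value.  BAR: height
is the single value (or the mean of both for bimodal input).  DISK: the
disk sits at (x, y) = (EEG, fMRI) with the goal at the (1, 1) corner.
Unimodal input drives both parameters of a 2-D metaphor proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NfbSample

METAPHORS = ("SUN", "BAR", "DISK")

R_MIN = 0.05
R_MAX = 0.45


@dataclass(frozen=True)
class DisplayFrame:
    metaphor: str
    params: dict
    tick: int = 0


def _components(nfb: NfbSample) -> tuple:
    """(eeg_like, fmri_like) in [0,1]; unimodal input drives both."""
    if nfb.values.size == 2:
        return float(nfb.values[0]), float(nfb.values[1])
    v = float(nfb.values[0])
    return v, v


def map_nfb(nfb: NfbSample, metaphor: str = "DISK", tick: int = 0,
            r_min: float = R_MIN, r_max: float = R_MAX) -> DisplayFrame:
    """Map a normalized feedback sample to one display frame."""
    if metaphor not in METAPHORS:
        raise ValueError(f"unknown metaphor {metaphor!r}")
    if not nfb.normalized:
        raise ValueError("display mapping requires normalized feedback values")
    eeg, fmri = _components(nfb)
    if metaphor == "SUN":
        params = {"brightness": eeg, "radius": r_min + (r_max - r_min) * fmri}
    elif metaphor == "BAR":
        params = {"height": float(np.mean(nfb.values))}
    else:  # DISK
        params = {"x": eeg, "y": fmri}
    return DisplayFrame(metaphor=metaphor, params=params, tick=tick)


def frames_to_rows(frames) -> list:
    """Flatten frames into (tick, metaphor, param, value) rows for CSV export."""
    rows = []
    for f in frames:
        for k, v in sorted(f.params.items()):
            rows.append((f.tick, f.metaphor, k, v))
    return rows
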