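"""Hemodynamic response model shared by the BOLD simulator and the GLM.

The canonical double-gamma HRF (response peak ~6 s, undershoot ~16 s,
undershoot ratio 1/6) is used, sampled on the TR grid and normalized to unit
peak so regression coefficients carry the amplitude of the simulated effect.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr`` seconds, peak 1."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration + 1e-9, tr)
    peak = gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    m = h.max()
    if m > 0:
        h = h / m
    return h


def convolve_design(design: np.ndarray, hrf: np.ndarray) -> np.ndarray:
    """Causal discrete convolution of a per-volume design with the HRF,
    truncated to the design length."""
    design = np.asarray(design, dtype=float)
    return np.convolve(design, hrf)[: design.size]


def design_matrix(design: np.ndarray, tr: float) -> tuple:
    """Online GLM design: intercept + linear drift + HRF-convolved task.

    Returns (X, column_labels) with X of shape (n_volumes, 3).  The drift
    column is a centered unit-slope ramp so the task column stays
    interpretable as response amplitude.
    """
    design = np.asarray(design, dtype=float)
    n = design.size
    k = np.arange(n, dtype=float)
    reg = convolve_design(design, double_gamma_hrf(tr))
    X = np.column_stack([np.ones(n), k - k.mean() if n else k, reg])
    return X, ["intercept", "drift", "task"]
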