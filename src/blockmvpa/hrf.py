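"""Canonical hemodynamic response function and block regressors.

A single double-gamma HRF (SPM convention: peak at 6 s, undershoot at
16 s, unit dispersions, peak:undershoot ratio 6, 32-s support) is shared
by the synthetic-data generator and the GLM design builder, so that
noise-free parameter recovery is exact.  The kernel is normalized to unit
sum, which makes the plateau of a long boxcar response equal to 1: pattern
amplitudes are therefore expressed directly in sustained-signal units.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma

HRF_DURATION_S = 32.0


def canonical_hrf(
    tr: float,
    duration_s: float = HRF_DURATION_S,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    peak_dispersion_s: float = 1.0,
    undershoot_dispersion_s: float = 1.0,
    peak_undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Sample the double-gamma HRF at scan resolution.

    Returns an array of ``duration_s / tr`` samples normalized to unit sum.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration_s, tr)
    peak = gamma.pdf(t, peak_delay_s / peak_dispersion_s, scale=peak_dispersion_s)
    undershoot = gamma.pdf(
        t, undershoot_delay_s / undershoot_dispersion_s, scale=undershoot_dispersion_s
    )
    h = peak - undershoot / peak_undershoot_ratio
    return h / h.sum()


def boxcar(onsets_scan: np.ndarray, n_scans: np.ndarray, t_total: int) -> np.ndarray:
    """Indicator time course of the given blocks, in scan units."""
    box = np.zeros(t_total)
    for onset, n in zip(np.atleast_1d(onsets_scan), np.atleast_1d(n_scans)):
        if onset < 0 or onset + n > t_total:
            raise ValueError(f"block [{onset}, {onset + n}) outside session of {t_total} scans")
        box[int(onset) : int(onset) + int(n)] = 1.0
    return box


def block_regressor(
    onsets_scan: np.ndarray, n_scans: np.ndarray, t_total: int, tr: float
) -> np.ndarray:
    """Boxcar of the given blocks convolved with the canonical HRF."""
    box = boxcar(onsets_scan, n_scans, t_total)
    return np.convolve(box, canonical_hrf(tr))[:t_total]
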