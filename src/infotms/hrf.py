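"""Canonical double-gamma hemodynamic response function and event regressors.

The BOLD response to a brief neural event is modeled as a difference of two
gamma densities: a positive lobe peaking ~6 s after the event and a slower
undershoot peaking ~16 s, weighted by ``undershoot_ratio``.  The kernel is
parameterized by its *peak times* (gamma modes), so the default kernel attains
its maximum at exactly ``peak_delay`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = ["HRFParams", "hrf_double_gamma", "event_regressor"]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF shape parameters (seconds unless noted)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "kernel_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 <= self.undershoot_ratio < 1:
            raise ValueError("undershoot_ratio must lie in [0, 1)")


def hrf_double_gamma(
    params: HRFParams = HRFParams(), tr: float = 2.0, oversampling: int = 20
) -> np.ndarray:
    """Sample the double-gamma impulse response on a ``tr / oversampling`` grid.

    Each lobe is a gamma density with mode at its delay (shape =
    1 + delay/dispersion, scale = dispersion).  The kernel is normalized to a
    peak value of 1 and spans ``params.kernel_length`` seconds.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    dt = tr / oversampling
    t = np.arange(0.0, params.kernel_length, dt)
    peak = _gamma.pdf(
        t, a=1.0 + params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = _gamma.pdf(
        t,
        a=1.0 + params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    kernel = peak - params.undershoot_ratio * under
    return kernel / kernel.max()


def event_regressor(
    onsets: np.ndarray,
    duration: float,
    n_timepoints: int,
    tr: float,
    params: HRFParams = HRFParams(),
    oversampling: int = 20,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the volume grid.

    Boxcars of the given duration are placed at each onset on a fine grid
    (``tr / oversampling``, i.e. 0.1 s at the default TR of 2 s), convolved
    with the double-gamma kernel, and decimated to volume acquisition times
    ``0, tr, 2*tr, ...``.  Onsets are not rounded to the TR grid.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    else:
        amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
        if amplitudes.shape != onsets.shape:
            raise ValueError("amplitudes must match onsets in length")
    dt = tr / oversampling
    n_fine = n_timepoints * oversampling
    box = np.zeros(n_fine)
    n_box = max(1, int(round(duration / dt)))
    for onset, amp in zip(onsets, amplitudes):
        if onset < 0:
            raise ValueError(f"negative onset {onset}")
        start = int(round(onset / dt))
        if start >= n_fine:
            continue
        box[start : min(start + n_box, n_fine)] += amp
    kernel = hrf_double_gamma(params, tr=tr, oversampling=oversampling)
    conv = np.convolve(box, kernel)[:n_fine]
    return conv[::oversampling]
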