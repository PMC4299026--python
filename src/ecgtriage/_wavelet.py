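"""Undecimated quadratic-spline wavelet transform (algorithme a trous).

The filter bank is the classic Mallat quadratic-spline pair used by ECG
delineators: lowpass h = (1/8, 3/8, 3/8, 1/8) and highpass g = (2, -2).
The detail coefficient at scale 2^j behaves like the smoothed derivative of
the signal, so a wave peak shows up as a (+max, -min) modulus-maxima pair
with a zero crossing at the peak.

Each stage is realigned to the input grid by its integer-rounded group
delay; the residual half-sample offsets are below the localization
tolerances used downstream.
"""

from __future__ import annotations

import numpy as np

_H = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0
_G = np.array([2.0, -2.0])


def _upsample(filt: np.ndarray, level: int) -> np.ndarray:
    """Insert 2**(level-1) - 1 zeros between taps (a trous dilation)."""
    if level == 1:
        return filt
    step = 2 ** (level - 1)
    out = np.zeros((len(filt) - 1) * step + 1)
    out[::step] = filt
    return out


def _conv_aligned(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    full = np.convolve(x, filt)
    delay = (len(filt) - 1) // 2
    return full[delay:delay + len(x)]


def swt_details(x: np.ndarray, levels: int = 4) -> list[np.ndarray]:
    """Detail coefficients w_1..w_levels (scales 2^1..2^levels), input-aligned."""
    x = np.asarray(x, dtype=float)
    approx = x
    details = []
    for j in range(1, levels + 1):
        details.append(_conv_aligned(approx, _upsample(_G, j)))
        approx = _conv_aligned(approx, _upsample(_H, j))
    return details


def modulus_maxima(w: np.ndarray, threshold: float | np.ndarray) -> np.ndarray:
    """Indices of local extrema of w whose magnitude exceeds the threshold."""
    mag = np.abs(w)
    interior = np.zeros(len(w), dtype=bool)
    if len(w) >= 3:
        interior[1:-1] = (mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:])
    return np.flatnonzero(interior & (mag > threshold))
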