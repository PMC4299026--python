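"""Signal conditioning: baseline removal, R-peak detection, beat windowing.

These are the on-node stages that precede feature extraction: a
morphological-operator baseline filter, a quadratic-spline wavelet R-peak
detector, and fixed-length window segmentation centered on each R peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import grey_closing, grey_opening, maximum_filter1d

from ecgtriage._wavelet import modulus_maxima, swt_details

logger = logging.getLogger(__name__)

#: window length d: the R sample itself plus 100 samples before and after
DEFAULT_WINDOW = 201

#: structuring-element durations (s) for the opening / closing baseline pass;
#: chosen to bracket the QRS and T-wave durations
OPENING_S = 0.2
CLOSING_S = 0.28

REFRACTORY_S = 0.2       # minimum R-R separation enforced by the detector
THRESHOLD_FACTOR = 0.3   # adaptive threshold = 0.3 x trailing RMS
RMS_WINDOW_S = 2.0


@dataclass(frozen=True)
class EcgRecord:
    """A sampled single-lead ECG (mV) at a fixed rate."""

    samples: np.ndarray
    fs: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(samples)):
            raise ValueError("record contains non-finite samples")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Beat:
    """A fixed-length sample window centered on an R peak."""

    window: np.ndarray
    r_index: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        if not np.all(np.isfinite(self.window)):
            raise ValueError("beat window contains non-finite samples")


def baseline_filter(record: EcgRecord) -> EcgRecord:
    """Remove baseline wander with morphological opening-then-closing.

    The baseline estimate is a grey-scale opening (flat structuring element
    of 0.2 s) followed by a closing (0.28 s); the estimate is subtracted
    from the signal.  Sub-1-Hz drift is suppressed while QRS complexes,
    narrower than the structuring elements, pass through.
    """
    n_open = max(int(round(OPENING_S * record.fs)), 3)
    n_close = max(int(round(CLOSING_S * record.fs)), 3)
    if len(record) < max(n_open, n_close):
        raise ValueError(
            f"record of {len(record)} samples is shorter than the "
            f"{max(n_open, n_close)}-sample structuring element"
        )
    baseline = grey_closing(grey_opening(record.samples, size=n_open), size=n_close)
    return EcgRecord(record.samples - baseline, record.fs, record.source_id)


def _trailing_rms(w: np.ndarray, win: int) -> np.ndarray:
    """Causal (trailing-window) RMS; expanding window during start-up."""
    sq = w**2
    csum = np.cumsum(sq)
    out = np.empty_like(w)
    idx = np.arange(len(w))
    lo = np.maximum(idx - win + 1, 0)
    totals = csum - np.where(lo > 0, csum[lo - 1], 0.0)
    counts = idx - lo + 1
    np.sqrt(totals / counts, out=out)
    return out


def detect_r_peaks(record: EcgRecord) -> np.ndarray:
    """Detect R peaks with the quadratic-spline wavelet modulus-maxima scheme.

    Opposite-sign modulus-maxima pairs of the scale-2^3 detail coefficients
    exceeding an adaptive threshold — 0.3 x the larger of the trailing 2-s
    RMS and the 2-s peak envelope, so T waves and noise extrema well below
    the running QRS amplitude are rejected — mark QRS complexes.
    Candidates are confirmed at scale 2^2, localized at the zero crossing
    between the pair, refined to the local signal-magnitude maximum, and
    de-duplicated with a 200 ms refractory period that keeps the larger
    peak.
    """
    x = record.samples
    fs = record.fs
    n = len(x)
    if n < 16 or np.max(np.abs(x)) == 0.0:
        return np.empty(0, dtype=int)

    w2, w3 = swt_details(x, levels=3)[1:3]
    win = max(int(round(RMS_WINDOW_S * fs)), 8)
    envelope3 = maximum_filter1d(np.abs(w3), size=win, mode="nearest")
    envelope2 = maximum_filter1d(np.abs(w2), size=win, mode="nearest")
    thr3 = np.maximum(THRESHOLD_FACTOR * np.maximum(_trailing_rms(w3, win), envelope3),
                      1e-12)
    thr2 = np.maximum(THRESHOLD_FACTOR * np.maximum(_trailing_rms(w2, win), envelope2),
                      1e-12)

    mm = modulus_maxima(w3, thr3)
    pair_span = int(round(0.15 * fs))
    confirm_half = max(int(round(0.036 * fs)), 2)
    refine_half = max(int(round(0.04 * fs)), 2)

    candidates: list[int] = []
    for a, b in zip(mm[:-1], mm[1:]):
        if b - a > pair_span or np.sign(w3[a]) == np.sign(w3[b]):
            continue
        seg = w3[a:b + 1]
        crossings = np.flatnonzero(np.diff(np.sign(seg)) != 0)
        zc = a + (int(crossings[0]) if len(crossings) else (b - a) // 2)
        lo, hi = max(zc - confirm_half, 0), min(zc + confirm_half + 1, n)
        if np.max(np.abs(w2[lo:hi])) <= thr2[zc]:
            continue  # no support at the finer scale
        lo, hi = max(zc - refine_half, 0), min(zc + refine_half + 1, n)
        candidates.append(lo + int(np.argmax(np.abs(x[lo:hi]))))

    if not candidates:
        return np.empty(0, dtype=int)

    refractory = int(round(REFRACTORY_S * fs))
    peaks: list[int] = []
    for c in sorted(set(candidates)):
        if peaks and c - peaks[-1] < refractory:
            if np.abs(x[c]) > np.abs(x[peaks[-1]]):
                peaks[-1] = c
        else:
            peaks.append(c)
    return np.asarray(peaks, dtype=int)


def segment_beats(record: EcgRecord, peaks, d: int = DEFAULT_WINDOW,
                  labels=None) -> list[Beat]:
    """Cut one d-sample window per peak; edge peaks whose window would leave
    the record are skipped and counted in the log."""
    half = (d - 1) // 2
    n = len(record)
    beats: list[Beat] = []
    skipped = 0
    for i, p in enumerate(np.asarray(peaks, dtype=int)):
        if p - half < 0 or p + half >= n:
            skipped += 1
            continue
        label = None if labels is None else labels[i]
        beats.append(Beat(record.samples[p - half:p + half + 1], int(p), label))
    if skipped:
        logger.info("segment_beats: skipped %d edge peak(s) of %d", skipped, len(peaks))
    return beats
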