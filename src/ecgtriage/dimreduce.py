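"""Dimensionality reduction: sparse random projections, PCA, fiducial points.

A beat window of d samples is reduced to a k-coefficient feature vector u
by one of three front-ends (or a concatenation of a projection with the
fiducial points):

* ``sample_achlioptas`` / ``project_rp`` — a sparse ternary random
  projection u = P v with entries +1 (p=1/6), -1 (p=1/6), 0 (p=2/3),
  evaluated by signed accumulation only (no multiplications).
* ``fit_pca`` / ``project_pca`` — the k leading eigenvectors of the sample
  covariance, extracted by power iteration with deflation.
* ``delineate_fpd`` — wavelet delineation of the 8 fiducial points (onset,
  peak, end of P and T; onset and end of the QRS), as signed sample
  offsets relative to the R peak.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field

import numpy as np

from ecgtriage._wavelet import modulus_maxima, swt_details

_PACK_MAGIC = b"AP"
#: 2-bit code per ternary entry, row-major, first entry in the low bits
_CODE = {0: 0b00, 1: 0b01, -1: 0b10}
_DECODE = np.array([0, 1, -1, 0], dtype=np.int8)

FIDUCIAL_NAMES = ("P_on", "P_peak", "P_end", "QRS_on",
                  "QRS_end", "T_on", "T_peak", "T_end")


# ---------------------------------------------------------------------------
# random projections

@dataclass(frozen=True)
class AchlioptasMatrix:
    """A k x d ternary projection matrix with entries in {-1, 0, +1}."""

    entries: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.int8)
        if entries.ndim != 2:
            raise ValueError("entries must be a 2-D matrix")
        k, d = entries.shape
        if not 1 <= k < d:
            raise ValueError(f"require 1 <= k < d, got k={k}, d={d}")
        if not np.isin(entries, (-1, 0, 1)).all():
            raise ValueError("entries must be ternary (-1, 0, +1)")
        object.__setattr__(self, "entries", entries)

    @property
    def k(self) -> int:
        return self.entries.shape[0]

    @property
    def d(self) -> int:
        return self.entries.shape[1]


def sample_achlioptas(k: int, d: int, seed: int) -> AchlioptasMatrix:
    """Draw i.i.d. entries: +1 w.p. 1/6, -1 w.p. 1/6, 0 w.p. 2/3."""
    if k >= d:
        raise ValueError(f"require k < d, got k={k}, d={d}")
    rng = np.random.default_rng(seed)
    entries = rng.choice(np.array([-1, 0, 1], dtype=np.int8), size=(k, d),
                         p=[1 / 6, 2 / 3, 1 / 6])
    return AchlioptasMatrix(entries, seed=seed)


def project_rp(P: AchlioptasMatrix, v: np.ndarray) -> np.ndarray:
    """u = P v by signed accumulation: add the +1 columns, subtract the -1."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != P.d:
        raise ValueError(f"window length {v.shape[-1]} does not match d={P.d}")
    plus = (P.entries == 1)
    minus = (P.entries == -1)
    return v @ plus.T.astype(float) - v @ minus.T.astype(float)


def pack_achlioptas(P: AchlioptasMatrix) -> bytes:
    """Pack to 2 bits/entry ({0: 00, +1: 01, -1: 10}, row-major): ceil(kd/4) bytes."""
    flat = P.entries.ravel()
    codes = np.zeros(len(flat), dtype=np.uint8)
    codes[flat == 1] = _CODE[1]
    codes[flat == -1] = _CODE[-1]
    pad = (-len(codes)) % 4
    codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)]).reshape(-1, 4)
    packed = codes[:, 0] | (codes[:, 1] << 2) | (codes[:, 2] << 4) | (codes[:, 3] << 6)
    return packed.tobytes()


def unpack_achlioptas(buffer: bytes, k: int, d: int) -> AchlioptasMatrix:
    """Inverse of :func:`pack_achlioptas` (lossless round trip)."""
    expected = -(-(k * d) // 4)
    if len(buffer) != expected:
        raise ValueError(f"buffer of {len(buffer)} bytes; expected {expected} for {k}x{d}")
    packed = np.frombuffer(buffer, dtype=np.uint8)
    codes = np.empty((len(packed), 4), dtype=np.uint8)
    for i in range(4):
        codes[:, i] = (packed >> (2 * i)) & 0b11
    entries = _DECODE[codes.ravel()[:k * d]].reshape(k, d)
    return AchlioptasMatrix(entries)


def save_achlioptas(P: AchlioptasMatrix, path) -> None:
    """Binary format: 8-byte header (magic 'AP', uint16 k, uint32 d, LE) + payload."""
    with open(path, "wb") as fh:
        fh.write(_PACK_MAGIC + struct.pack("<HI", P.k, P.d))
        fh.write(pack_achlioptas(P))


def load_achlioptas(path) -> AchlioptasMatrix:
    with open(path, "rb") as fh:
        header = fh.read(8)
        if header[:2] != _PACK_MAGIC:
            raise ValueError("not an Achlioptas matrix file")
        k, d = struct.unpack("<HI", header[2:])
        return unpack_achlioptas(fh.read(), k, d)


# ---------------------------------------------------------------------------
# principal component analysis

@dataclass(frozen=True)
class PcaMatrix:
    """k leading covariance eigenvectors (rows) plus the training mean."""

    components: np.ndarray    # (k, d), rows orthonormal, eigenvalue-ordered
    mean_vector: np.ndarray   # (d,)
    eigenvalues: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def d(self) -> int:
        return self.components.shape[1]


def fit_pca(windows: np.ndarray, k: int, tol: float = 1e-9,
            max_iter: int = 1000) -> PcaMatrix:
    """Extract the k leading covariance eigenvectors by power iteration.

    Uses the sample covariance (1/N) sum (v_i - E[v])(v_i - E[v])^T of the
    mean-centered windows.  Components are deflated one at a time and
    re-orthogonalized each sweep; the sign convention makes the
    largest-magnitude element of each component positive.
    """
    X = np.asarray(windows, dtype=float)
    n, d = X.shape
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} windows, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    C = (Xc.T @ Xc) / n
    if np.trace(C) < 1e-12:
        raise ValueError("degenerate (constant) input: covariance is zero")

    components = np.zeros((k, d))
    eigenvalues = np.zeros(k)
    for j in range(k):
        v = C[:, int(np.argmax(np.diag(C)))].copy()
        norm = np.linalg.norm(v)
        v = np.ones(d) / np.sqrt(d) if norm < 1e-12 else v / norm
        for _ in range(max_iter):
            w = C @ v
            if j:  # keep strictly orthogonal to previous components
                w -= components[:j].T @ (components[:j] @ w)
            norm = np.linalg.norm(w)
            if norm < 1e-15:
                break
            w /= norm
            if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
                v = w
                break
            v = w
        lam = float(v @ C @ v)
        if v[int(np.argmax(np.abs(v)))] < 0:
            v = -v
        components[j] = v
        eigenvalues[j] = lam
        C = C - lam * np.outer(v, v)
    return PcaMatrix(components, mean, eigenvalues)


def save_pca(T: PcaMatrix, path) -> None:
    """JSON header (k, d, dtype) + '\\n' + little-endian float64 rows:
    mean vector first, then the k component rows."""
    header = json.dumps({"format": "ecgtriage-pca", "k": T.k, "d": T.d,
                         "dtype": "<f8"}).encode()
    with open(path, "wb") as fh:
        fh.write(header + b"\n")
        fh.write(T.mean_vector.astype("<f8").tobytes())
        fh.write(T.components.astype("<f8").tobytes())


def load_pca(path) -> PcaMatrix:
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        if header.get("format") != "ecgtriage-pca":
            raise ValueError("not an ecgtriage PCA matrix file")
        k, d = header["k"], header["d"]
        mean = np.frombuffer(fh.read(8 * d), dtype="<f8").copy()
        comps = np.frombuffer(fh.read(8 * k * d), dtype="<f8").reshape(k, d).copy()
    return PcaMatrix(comps, mean)


def project_pca(T: PcaMatrix, v: np.ndarray) -> np.ndarray:
    """u = T (v - E[v])."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != T.d:
        raise ValueError(f"window length {v.shape[-1]} does not match d={T.d}")
    return (v - T.mean_vector) @ T.components.T


# ---------------------------------------------------------------------------
# fiducial point delineation

@dataclass
class FiducialSet:
    """8 signed sample offsets relative to the R peak, with a detection mask.

    Order: P_on, P_peak, P_end, QRS_on, QRS_end, T_on, T_peak, T_end.
    Undetected points are substituted by the detected neighbor closer to
    the R peak (falling back to the R peak itself at offset 0), after which
    the ordering P_on <= P_peak <= P_end <= QRS_on <= 0 <= QRS_end <= T_on
    <= T_peak <= T_end always holds.
    """

    offsets: np.ndarray        # (8,) int, samples relative to R
    detected_mask: np.ndarray  # (8,) bool


def _delineate_wave(w: np.ndarray, lo: int, hi: int,
                    min_modulus: float) -> tuple[int, int, int] | None:
    """Locate a P/T-like wave inside [lo, hi] from the scale-2^4 details.

    A wave requires an adjacent opposite-sign modulus-maxima pair with an
    interior zero crossing (the monotone flank a neighboring QRS leaks into
    the window cannot produce one); the peak sits at the zero crossing and
    the onset/end where the detail magnitude decays below 25% of the
    bounding maxima.  Returns None when no pair reaches ``min_modulus``.
    """
    seg = w[lo:hi + 1]
    mm = modulus_maxima(seg, 0.0)
    max_span = len(seg)  # pair extrema must both lie inside the window
    best = None
    for i, a in enumerate(mm[:-1]):
        for b in mm[i + 1:]:
            if b - a > max_span or np.sign(seg[a]) == np.sign(seg[b]):
                continue
            score = max(abs(seg[a]), abs(seg[b]))
            if best is None or score > best[0]:
                best = (score, int(a), int(b))
    if best is None or best[0] < min_modulus:
        return None
    _, a, b = best
    crossings = np.flatnonzero(np.diff(np.sign(seg[a:b + 1])) != 0)
    peak = a + (int(crossings[0]) if len(crossings) else (b - a) // 2)
    onset = a
    while onset > 0 and abs(seg[onset - 1]) >= 0.25 * abs(seg[a]):
        onset -= 1
    end = b
    while end < len(seg) - 1 and abs(seg[end + 1]) >= 0.25 * abs(seg[b]):
        end += 1
    return lo + onset, lo + peak, lo + end


def delineate_fpd(window: np.ndarray, fs: float) -> FiducialSet:
    """Delineate the 8 fiducial points of a beat window centered on its R peak.

    The QRS onset/end are located at scales 2^1-2^2 within +-60 ms of the R
    peak; the P wave is searched in [-200, -60] ms and the T wave in
    [+80, +400] ms at scale 2^4.  A wave whose scale-appropriate modulus
    maximum is below 0.1 x the QRS modulus maximum (at the same scale) is
    declared undetected and substituted per the neighbor-closer-to-R rule.
    """
    window = np.asarray(window, dtype=float)
    d = len(window)
    center = (d - 1) // 2
    w1, w2, w3, w4 = swt_details(window, levels=4)
    ms = fs / 1000.0

    offsets = np.zeros(8, dtype=int)
    detected = np.zeros(8, dtype=bool)

    qrs_half = int(round(60 * ms))
    q_lo, q_hi = max(center - qrs_half, 0), min(center + qrs_half, d - 1)
    wq = np.abs(w1[q_lo:q_hi + 1]) + np.abs(w2[q_lo:q_hi + 1])
    m_qrs = wq.max()
    m_qrs4 = np.abs(w4[q_lo:q_hi + 1]).max()
    if m_qrs > 1e-12:
        sig = np.flatnonzero(wq >= 0.1 * m_qrs)
        offsets[3] = q_lo + int(sig[0]) - center    # QRS_on
        offsets[4] = q_lo + int(sig[-1]) - center   # QRS_end
        detected[3] = detected[4] = True

        # P wave: [-200, -60] ms at scale 2^4
        p_lo, p_hi = max(center - int(round(200 * ms)), 0), center - int(round(60 * ms))
        if p_hi > p_lo:
            hit = _delineate_wave(w4, p_lo, p_hi, 0.1 * m_qrs4)
            if hit is not None:
                offsets[0:3] = np.asarray(hit) - center
                detected[0] = detected[1] = detected[2] = True

        # T wave: [+80, +400] ms at scale 2^4 (clipped to the window)
        t_lo = center + int(round(80 * ms))
        t_hi = min(center + int(round(400 * ms)), d - 2)
        if t_hi > t_lo:
            hit = _delineate_wave(w4, t_lo, t_hi, 0.1 * m_qrs4)
            if hit is not None:
                offsets[5:8] = np.asarray(hit) - center
                detected[5] = detected[6] = detected[7] = True

    # substitution: undetected point -> detected neighbor closer to R (or R itself)
    if not detected[3]:
        offsets[3] = 0
    if not detected[4]:
        offsets[4] = 0
    for i in (2, 1, 0):       # P_end, P_peak, P_on inherit inward neighbor
        if not detected[i]:
            offsets[i] = offsets[i + 1]
    for i in (5, 6, 7):       # T_on, T_peak, T_end inherit inward neighbor
        if not detected[i]:
            offsets[i] = offsets[i - 1]

    # enforce the ordering invariant by monotone clamping toward R
    offsets[3] = min(offsets[3], 0)
    offsets[4] = max(offsets[4], 0)
    for i in (2, 1, 0):
        offsets[i] = min(offsets[i], offsets[i + 1])
    for i in (5, 6, 7):
        offsets[i] = max(offsets[i], offsets[i - 1])

    return FiducialSet(offsets=offsets, detected_mask=detected)


def fpd_features(windows: np.ndarray, fs: float) -> np.ndarray:
    """Delineate every window; returns the (n, 8) offsets matrix."""
    return np.asarray([delineate_fpd(w, fs).offsets for w in np.atleast_2d(windows)],
                      dtype=float)


def combine_features(u8: np.ndarray, fpd: FiducialSet | np.ndarray) -> np.ndarray:
    """Concatenate 8 projection coefficients with the 8 fiducial offsets."""
    u8 = np.asarray(u8, dtype=float)
    if u8.shape[-1] != 8:
        raise ValueError(f"expected 8 projection coefficients, got {u8.shape[-1]}")
    offs = fpd.offsets if isinstance(fpd, FiducialSet) else np.asarray(fpd)
    if offs.shape[-1] != 8:
        raise ValueError(f"expected 8 fiducial offsets, got {offs.shape[-1]}")
    return np.concatenate([u8, offs.astype(float)], axis=-1)
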