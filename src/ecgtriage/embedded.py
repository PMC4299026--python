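"""Integer-only inference path mirroring a fixed-point microcontroller port.

The floating-point classifier is transformed after training:

* each gaussian membership function is mapped onto the 16-bit range
  [0, 65535] and replaced by a piecewise-linear curve with breakpoints at
  S = 2.35 sigma: value 65535 at the center, chords through the scaled
  gaussian at |c - x| = S and 2S, the plateau value 1 on [2S, 4S) and 0
  beyond 4S;
* fuzzification multiplies 16-bit grades into 32-bit accumulators; after
  every product the three class accumulators are left-shifted by the
  largest common amount that avoids overflow and the low 16 bits are
  dropped (only the ratio of the fuzzy values matters to the decision);
* defuzzification evaluates (M1 - M2) * 2^16 >= alpha_q16 * S_sum in
  double-width integer arithmetic — no division.

Worst-case deviation of the chord approximation from the scaled gaussian
is ~5,675 counts (8.7% of full scale, attained where the inner chord passes
under the gaussian tail at |c - x| ~ 1.71 sigma); the documented bound of
5,750 adds slack for slope and grid rounding.  See the methods note for
the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ecgtriage.nfc import (
    CLASSES,
    PATHOLOGICAL,
    ClassificationResult,
    MembershipFunction,
    NfcModel,
    _labels_from_fuzzy,
    fuzzify_batch,
)

FULL_SCALE = 2**16 - 1                      # top of the 16-bit grade range
S_OVER_SIGMA = 2.35                         # breakpoint width S = 2.35 sigma
#: scaled gaussian value at |c - x| = S: round(65535 * exp(-2.35^2 / 2))
G_S = int(round(FULL_SCALE * np.exp(-(S_OVER_SIGMA**2) / 2.0)))
#: feature quantizer spans +-4.7 sigma, i.e. the full MF support 4S
QUANT_COVERAGE = 4.7
#: max |chord - scaled gaussian| over the 16-bit axis (derivation: methods note)
LINEARIZATION_MAX_ERROR = 5750

_MASK32 = (1 << 32) - 1


@dataclass(frozen=True)
class FeatureQuantizer:
    """Per-coefficient affine map from normalized features to the 16-bit grid."""

    lo: np.ndarray    # (k,) normalized-feature value mapped to 0
    step: np.ndarray  # (k,) grid step; value 65535 maps to lo + 65535*step

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.step) <= 0):
            raise ValueError("degenerate quantizer: step must be positive")

    def quantize(self, Z: np.ndarray) -> np.ndarray:
        q = np.round((np.asarray(Z, dtype=float) - self.lo) / self.step)
        return np.clip(q, 0, FULL_SCALE).astype(np.int64)


@dataclass(frozen=True)
class LinearizedMf:
    """Piecewise-linear integer membership function on the 16-bit axis.

    Slopes are Q16 fixed point; segment 2 covers |c - x| in [0, S) and
    segment 1 covers [S, 2S).
    """

    center_int: int
    s_int: int
    seg1_slope: int      # Q16; grade = G_S - ((slope * (delta - S)) >> 16)
    seg1_intercept: int  # = G_S
    seg2_slope: int      # Q16; grade = 65535 - ((slope * delta) >> 16)
    seg2_intercept: int  # = 65535


def linearize_mf(mf: MembershipFunction, quantizer: FeatureQuantizer,
                 coefficient: int) -> LinearizedMf:
    """Chord-based linearization of one gaussian MF on the quantized axis."""
    step = float(np.asarray(quantizer.step).ravel()[coefficient])
    lo = float(np.asarray(quantizer.lo).ravel()[coefficient])
    center_int = int(np.clip(round((mf.center - lo) / step), 0, FULL_SCALE))
    s_int = max(int(round(S_OVER_SIGMA * mf.sigma / step)), 1)
    seg2_slope = int(round((FULL_SCALE - G_S) * 2**16 / s_int))
    seg1_slope = int(round((G_S - 1) * 2**16 / s_int))
    return LinearizedMf(center_int, s_int, seg1_slope, G_S, seg2_slope, FULL_SCALE)


def eval_linearized(lmf: LinearizedMf, x_int) -> np.ndarray | int:
    """Evaluate the piecewise-linear MF with integer add/shift/multiply only."""
    x = np.asarray(x_int, dtype=np.int64)
    delta = np.abs(x - lmf.center_int)
    s = lmf.s_int
    grade = np.zeros_like(delta)
    plateau = (delta >= 2 * s) & (delta < 4 * s)
    grade[plateau] = 1
    seg1 = (delta >= s) & (delta < 2 * s)
    grade[seg1] = lmf.seg1_intercept - ((lmf.seg1_slope * (delta[seg1] - s)) >> 16)
    seg2 = delta < s
    grade[seg2] = lmf.seg2_intercept - ((lmf.seg2_slope * delta[seg2]) >> 16)
    grade = np.clip(grade, 0, FULL_SCALE)
    return int(grade) if np.isscalar(x_int) else grade


@dataclass
class QuantizedNfc:
    """Integer-domain mirror of a trained NfcModel."""

    lmfs: list            # k x 3 nested list of LinearizedMf
    alpha_q16: int        # alpha as Q0.16: alpha ~ alpha_q16 / 2^16
    quantizer: FeatureQuantizer
    scale_mean: np.ndarray
    scale_std: np.ndarray
    # dense mirrors of the per-MF parameters for vectorized evaluation
    centers_int: np.ndarray = None    # type: ignore[assignment]
    s_int: np.ndarray = None          # type: ignore[assignment]
    slopes1: np.ndarray = None        # type: ignore[assignment]
    slopes2: np.ndarray = None        # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 <= self.alpha_q16 <= FULL_SCALE:
            raise ValueError("alpha_q16 must fit in 16 bits")
        k = len(self.lmfs)
        self.centers_int = np.array([[m.center_int for m in row] for row in self.lmfs],
                                    dtype=np.int64).reshape(k, 3)
        self.s_int = np.array([[m.s_int for m in row] for row in self.lmfs],
                              dtype=np.int64).reshape(k, 3)
        self.slopes1 = np.array([[m.seg1_slope for m in row] for row in self.lmfs],
                                dtype=np.int64).reshape(k, 3)
        self.slopes2 = np.array([[m.seg2_slope for m in row] for row in self.lmfs],
                                dtype=np.int64).reshape(k, 3)

    @property
    def k(self) -> int:
        return len(self.lmfs)

    def quantize_features(self, U: np.ndarray) -> np.ndarray:
        """Raw feature vector(s) -> normalized -> 16-bit grid."""
        Z = (np.asarray(U, dtype=float) - self.scale_mean) / self.scale_std
        return self.quantizer.quantize(Z)


@dataclass
class IntFuzzyState:
    """Per-class 32-bit accumulators plus the common shift log."""

    accumulators: np.ndarray   # (3,) unsigned, < 2^32
    applied_shift_log: int


def quantize_model(model: NfcModel) -> QuantizedNfc:
    """Transform a trained floating-point model into its integer mirror.

    The per-coefficient quantizer covers +-4.7 standard deviations of the
    normalized feature (the full 4S support of a unit-sigma MF); alpha is
    rounded to Q0.16 and clipped to 16 bits.
    """
    if not model.trained:
        raise ValueError("quantize_model requires a trained model")
    k = model.k
    lo = np.full(k, -QUANT_COVERAGE)
    step = np.full(k, 2.0 * QUANT_COVERAGE / FULL_SCALE)
    quantizer = FeatureQuantizer(lo=lo, step=step)
    lmfs = [[linearize_mf(model.membership(i, cls), quantizer, i) for cls in CLASSES]
            for i in range(k)]
    alpha_q16 = int(np.clip(round(model.alpha_train * 2**16), 0, FULL_SCALE))
    return QuantizedNfc(lmfs, alpha_q16, quantizer,
                        model.scale_mean.copy(), model.scale_std.copy())


def _grades_batch(qmodel: QuantizedNfc, X: np.ndarray) -> np.ndarray:
    """(n, k) quantized features -> (n, k, 3) integer grades, vectorized."""
    delta = np.abs(X[:, :, None] - qmodel.centers_int[None])
    s = qmodel.s_int[None]
    grade = np.zeros_like(delta)
    plateau = (delta >= 2 * s) & (delta < 4 * s)
    grade[plateau] = 1
    m1 = (delta >= s) & (delta < 2 * s)
    slopes1 = np.broadcast_to(qmodel.slopes1[None], delta.shape)
    sb = np.broadcast_to(s, delta.shape)
    grade[m1] = G_S - ((slopes1[m1] * (delta[m1] - sb[m1])) >> 16)
    m2 = delta < s
    slopes2 = np.broadcast_to(qmodel.slopes2[None], delta.shape)
    grade[m2] = FULL_SCALE - ((slopes2[m2] * delta[m2]) >> 16)
    return np.clip(grade, 0, FULL_SCALE)


def _shift_truncate(acc: np.ndarray) -> tuple[np.ndarray, int]:
    """Left-shift all accumulators by the largest common overflow-free amount,
    then drop the low 16 bits."""
    top = int(acc.max())
    if top == 0:
        return acc >> 16, 0
    shift = 32 - top.bit_length()
    shift = max(shift, 0)
    return (acc << shift) >> 16, shift


def int_fuzzify(qmodel: QuantizedNfc, x_int: np.ndarray) -> IntFuzzyState:
    """Overflow-safe integer fuzzification of one quantized feature vector.

    The grades of the first two coefficients are multiplied per class; the
    three products are left-shifted by the maximum common amount that keeps
    every accumulator below 2^32 and the least-significant 16 bits are
    discarded.  Every subsequent grade is processed the same way.
    """
    x = np.asarray(x_int, dtype=np.int64)
    if x.shape != (qmodel.k,):
        raise ValueError(f"expected a length-{qmodel.k} quantized vector")
    grades = _grades_batch(qmodel, x[None])[0]      # (k, 3)
    acc = grades[0].astype(np.int64)
    shift_log = 0
    for i in range(1, qmodel.k):
        acc = acc * grades[i]
        acc, shift = _shift_truncate(acc)
        shift_log += shift
    return IntFuzzyState(acc, shift_log)


def int_fuzzify_batch(qmodel: QuantizedNfc, X_int: np.ndarray) -> np.ndarray:
    """Vectorized integer fuzzy values for (n, k) quantized features -> (n, 3)."""
    grades = _grades_batch(qmodel, np.asarray(X_int, dtype=np.int64))
    acc = grades[:, 0, :].astype(np.int64)
    for i in range(1, qmodel.k):
        acc = acc * grades[:, i, :]
        top = acc.max(axis=1)
        # 32 - bit_length(top); frexp exponent equals bit length for ints < 2^53
        bits = np.frexp(top.astype(np.float64))[1]
        shift = np.clip(32 - bits, 0, None).astype(np.int64)
        shift[top == 0] = 0
        acc = (acc << shift[:, None]) >> 16
    return acc


def int_defuzzify(state: IntFuzzyState, alpha_q16: int) -> ClassificationResult:
    """Division-free integer decision: (M1 - M2) * 2^16 >= alpha_q16 * S_sum."""
    acc = np.asarray(state.accumulators, dtype=np.int64)
    order = np.argsort(acc)[::-1]
    m1, m2 = int(acc[order[0]]), int(acc[order[1]])
    s_sum = int(acc.sum())
    if s_sum == 0 or m1 == m2 or ((m1 - m2) << 16) < alpha_q16 * s_sum:
        label = "U"
    else:
        label = CLASSES[order[0]]
    return ClassificationResult(acc, label, label in PATHOLOGICAL,
                                float(m1), float(m2), float(s_sum))


def classify_int(qmodel: QuantizedNfc, u: np.ndarray,
                 alpha_q16: int | None = None) -> ClassificationResult:
    """Full integer pipeline for one raw feature vector."""
    alpha = qmodel.alpha_q16 if alpha_q16 is None else alpha_q16
    x = qmodel.quantize_features(np.asarray(u, dtype=float))
    return int_defuzzify(int_fuzzify(qmodel, x), alpha)


def classify_int_batch(qmodel: QuantizedNfc, U: np.ndarray,
                       alpha_q16: int | None = None) -> np.ndarray:
    alpha = qmodel.alpha_q16 if alpha_q16 is None else alpha_q16
    X = qmodel.quantize_features(np.atleast_2d(np.asarray(U, dtype=float)))
    acc = int_fuzzify_batch(qmodel, X)
    part = np.sort(acc, axis=1)
    m1, m2 = part[:, 2], part[:, 1]
    s_sum = acc.sum(axis=1)
    assigned = (s_sum > 0) & (m1 > m2) & (((m1 - m2) << 16) >= alpha * s_sum)
    labels = np.full(len(acc), "U", dtype="<U1")
    arg = np.argmax(acc, axis=1)
    labels[assigned] = np.asarray(CLASSES)[arg[assigned]]
    return labels


def parity_audit(model: NfcModel, qmodel: QuantizedNfc, features: np.ndarray,
                 labels=None, alpha_test: float | None = None) -> dict:
    """Per-beat float vs integer label comparison.

    Reports the agreement rate and, when true labels are given, the NDR and
    ARR of both paths and their deltas.
    """
    U = np.atleast_2d(np.asarray(features, dtype=float))
    alpha = model.alpha_train if alpha_test is None else alpha_test
    alpha_q16 = qmodel.alpha_q16 if alpha_test is None else \
        int(np.clip(round(alpha_test * 2**16), 0, FULL_SCALE))
    float_labels = _labels_from_fuzzy(fuzzify_batch(model, U), alpha)
    int_labels = classify_int_batch(qmodel, U, alpha_q16)
    agree = float(np.mean(float_labels == int_labels))
    report = {
        "n": len(U),
        "n_agree": int(np.sum(float_labels == int_labels)),
        "agreement": agree,
        "float_labels": float_labels,
        "int_labels": int_labels,
    }
    if labels is not None:
        from ecgtriage.evaluate import compute_ndr_arr

        rf = compute_ndr_arr(float_labels, labels)
        ri = compute_ndr_arr(int_labels, labels)
        report.update(ndr_float=rf.ndr, arr_float=rf.arr,
                      ndr_int=ri.ndr, arr_int=ri.arr,
                      ndr_delta=ri.ndr - rf.ndr, arr_delta=ri.arr - rf.arr)
    return report


# ---------------------------------------------------------------------------
# serialization: versioned little-endian blob suitable for firmware replay

_BLOB_MAGIC = b"QNFC"
_BLOB_VERSION = 1


def save_quantized(qmodel: QuantizedNfc, path) -> None:
    """Layout: magic 'QNFC', u16 version, u16 k, u16 alpha_q16, then per
    coefficient f64 lo/step/scale_mean/scale_std, then per (coefficient,
    class) u16 center, u32 s, u32 slope1, u32 slope2.  Little-endian."""
    import struct

    with open(path, "wb") as fh:
        fh.write(_BLOB_MAGIC + struct.pack("<HHH", _BLOB_VERSION, qmodel.k,
                                           qmodel.alpha_q16))
        for i in range(qmodel.k):
            fh.write(struct.pack("<dddd",
                                 float(np.asarray(qmodel.quantizer.lo)[i]),
                                 float(np.asarray(qmodel.quantizer.step)[i]),
                                 float(qmodel.scale_mean[i]),
                                 float(qmodel.scale_std[i])))
            for m in qmodel.lmfs[i]:
                fh.write(struct.pack("<HIII", m.center_int, m.s_int,
                                     m.seg1_slope, m.seg2_slope))


def load_quantized(path) -> QuantizedNfc:
    import struct

    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[:4] != _BLOB_MAGIC:
        raise ValueError("not an ecgtriage quantized model blob")
    version, k, alpha_q16 = struct.unpack("<HHH", blob[4:10])
    if version != _BLOB_VERSION:
        raise ValueError(f"unsupported blob version {version}")
    off = 10
    lo = np.empty(k)
    step = np.empty(k)
    scale_mean = np.empty(k)
    scale_std = np.empty(k)
    lmfs = []
    for i in range(k):
        lo[i], step[i], scale_mean[i], scale_std[i] = struct.unpack_from("<dddd", blob, off)
        off += 32
        row = []
        for _ in range(3):
            c, s, sl1, sl2 = struct.unpack_from("<HIII", blob, off)
            off += 14
            row.append(LinearizedMf(c, s, sl1, G_S, sl2, FULL_SCALE))
        lmfs.append(row)
    return QuantizedNfc(lmfs, alpha_q16, FeatureQuantizer(lo, step),
                        scale_mean, scale_std)
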