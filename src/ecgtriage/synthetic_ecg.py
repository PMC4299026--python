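"""Synthetic single-lead ECG records with labeled N / V / L beats.

Beats are sums of gaussian bumps for the P, Q, R, S and T waves — the
standard phantom-ECG construction.  Three morphologies are produced:

* ``N`` — normal sinus beat: narrow QRS, upright P and T.
* ``V`` — premature ventricular contraction: no P wave, QRS widened by a
  factor of 2.5, inverted T.
* ``L`` — left bundle branch block: QRS widened by 1.8 with a secondary
  (notch) bump on the R wave and a discordant (inverted) T.

The generator reproduces the class-separating morphological structure a
triage classifier exploits; it makes no claim of physiological fidelity
(see the methods note).  Records add RR jitter, white gaussian noise and
sinusoidal baseline wander on top of the clean beat train.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ecgtriage.preprocess import Beat

#: default window length: the R sample plus 100 samples on either side
DEFAULT_WINDOW = 201

CLASSES = ("N", "V", "L")

#: class mix of the reference arrhythmia corpus (74,064 N / 6,608 V / 8,032 L)
REFERENCE_CLASS_MIX = (74064 / 88704, 6608 / 88704, 8032 / 88704)


@dataclass(frozen=True)
class MorphologyParams:
    """Gaussian-bump description of one beat class.

    Amplitudes are in mV, centers in seconds relative to the R peak and
    widths are gaussian standard deviations in seconds.  ``qrs_width_scale``
    multiplies the widths of the Q, R, S (and notch) bumps; wide-QRS
    pathologies (V, L) require a scale >= 1.
    """

    class_label: str
    wave_amplitudes: dict[str, float]
    wave_centers: dict[str, float]
    wave_widths: dict[str, float]
    qrs_width_scale: float = 1.0
    p_present: bool = True
    t_polarity: int = 1

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(
                f"invalid class label {self.class_label!r}; expected one of {CLASSES}"
            )
        if any(w <= 0 for w in self.wave_widths.values()):
            raise ValueError("wave_widths must be positive")
        if self.class_label in ("V", "L") and self.qrs_width_scale < 1:
            raise ValueError("wide-QRS classes V and L require qrs_width_scale >= 1")
        if self.class_label == "V" and self.p_present:
            raise ValueError("class V beats have no P wave (p_present must be False)")


_QRS_WAVES = ("Q", "R", "S", "R2")  # R2 = notch bump of the L morphology


def default_morphology(class_label: str) -> MorphologyParams:
    """Reference morphology parameters for a beat class."""
    if class_label == "N":
        return MorphologyParams(
            class_label="N",
            wave_amplitudes={"P": 0.2, "Q": -0.12, "R": 1.0, "S": -0.25, "T": 0.35},
            wave_centers={"P": -0.14, "Q": -0.03, "R": 0.0, "S": 0.03, "T": 0.22},
            wave_widths={"P": 0.025, "Q": 0.012, "R": 0.012, "S": 0.014, "T": 0.06},
        )
    if class_label == "V":
        # ectopic beat: no P, no discrete Q, broad R/S, large inverted T
        return MorphologyParams(
            class_label="V",
            wave_amplitudes={"R": 1.1, "S": -0.4, "T": 0.5},
            wave_centers={"R": 0.0, "S": 0.07, "T": 0.24},
            wave_widths={"R": 0.012, "S": 0.02, "T": 0.07},
            qrs_width_scale=2.5,
            p_present=False,
            t_polarity=-1,
        )
    if class_label == "L":
        # widened, notched QRS (secondary R2 bump) with discordant T
        return MorphologyParams(
            class_label="L",
            wave_amplitudes={"P": 0.18, "Q": -0.08, "R": 1.0, "R2": 0.25,
                             "S": -0.3, "T": 0.4},
            wave_centers={"P": -0.15, "Q": -0.05, "R": 0.0, "R2": 0.04,
                          "S": 0.06, "T": 0.24},
            wave_widths={"P": 0.025, "Q": 0.015, "R": 0.012, "R2": 0.012,
                         "S": 0.02, "T": 0.065},
            qrs_width_scale=1.8,
            t_polarity=-1,
        )
    raise ValueError(f"invalid class label {class_label!r}; expected one of {CLASSES}")


@dataclass(frozen=True)
class RecordSpec:
    """Parameters of one synthetic record.

    Defaults are the package's reference study conditions: 360 Hz sampling,
    the reference corpus class mix, 0.05 mV RMS white noise and 0.15 mV
    baseline wander at 0.3 Hz (respiration band).
    """

    n_beats: int = 3000
    class_mix: tuple[float, float, float] = REFERENCE_CLASS_MIX
    fs: float = 360.0
    rr_mean: float = 0.8
    rr_jitter: float = 0.05
    noise_rms: float = 0.05
    baseline_amp: float = 0.15
    baseline_freq: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.size != 3 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
            raise ValueError("class_mix must be 3 nonnegative probabilities summing to 1")


def _beat_waveform(params: MorphologyParams, t: np.ndarray,
                   rng: np.random.Generator | None) -> np.ndarray:
    """Evaluate the sum-of-gaussians morphology on time axis ``t`` (s, R at 0).

    When ``rng`` is given, per-beat variability is applied: ~5% amplitude and
    width jitter per wave and up to 5 ms center jitter for the P and T waves.
    The R (and notch) bumps stay anchored at t = 0 so the annotation always
    points at the true R sample.
    """
    x = np.zeros_like(t)
    for wave, amp in params.wave_amplitudes.items():
        if wave == "P" and not params.p_present:
            continue
        center = params.wave_centers[wave]
        width = params.wave_widths[wave]
        if wave in _QRS_WAVES:
            width *= params.qrs_width_scale
        if wave == "T":
            amp = amp * params.t_polarity
        if rng is not None:
            amp *= 1.0 + 0.05 * rng.standard_normal()
            width *= 1.0 + 0.05 * rng.standard_normal()
            width = max(width, 1e-3)
            if wave in ("P", "T"):
                center += 0.005 * rng.standard_normal()
        x += amp * np.exp(-((t - center) ** 2) / (2.0 * width**2))
    return x


def generate_beat(params: MorphologyParams, fs: float = 360.0, seed: int | None = None,
                  d: int = DEFAULT_WINDOW) -> Beat:
    """Generate one clean beat window of ``d`` samples with R at the center.

    Deterministic given ``seed``; ``seed=None`` disables per-beat jitter.
    """
    if fs < 120:
        raise ValueError("fs must be >= 120 Hz to resolve the QRS complex")
    half = (d - 1) // 2
    t = (np.arange(d) - half) / fs
    rng = np.random.default_rng(seed) if seed is not None else None
    window = _beat_waveform(params, t, rng)
    return Beat(window=window, r_index=half, label=params.class_label)


def generate_record(spec: RecordSpec,
                    morphologies: dict[str, MorphologyParams] | None = None,
                    d: int = DEFAULT_WINDOW):
    """Generate a record as (signal mV array, annotations [(r_index, label), ...]).

    Beats are painted at jittered RR intervals (clipped so consecutive
    windows never overlap), then white noise and sinusoidal baseline wander
    are added.  Deterministic given ``spec`` (including its seed).
    """
    fs = spec.fs
    half = (d - 1) // 2
    if spec.rr_mean * fs <= d:
        raise ValueError(
            f"rr_mean {spec.rr_mean}s is shorter than the {d}-sample beat window at {fs} Hz"
        )
    if morphologies is None:
        morphologies = {c: default_morphology(c) for c in CLASSES}
    rng = np.random.default_rng(spec.seed)

    labels = rng.choice(np.array(CLASSES), size=spec.n_beats, p=np.asarray(spec.class_mix))
    rr = spec.rr_mean + spec.rr_jitter * rng.standard_normal(spec.n_beats - 1) \
        if spec.n_beats > 1 else np.empty(0)
    rr_samples = np.maximum(np.round(rr * fs).astype(int), d + 1)
    r_indices = d + np.concatenate([[0], np.cumsum(rr_samples)])

    n = int(r_indices[-1]) + d
    signal = np.zeros(n)
    beat_seeds = rng.integers(0, 2**31, size=spec.n_beats)
    for r, label, bseed in zip(r_indices, labels, beat_seeds):
        beat = generate_beat(morphologies[label], fs=fs, seed=int(bseed), d=d)
        signal[r - half:r + half + 1] += beat.window

    if spec.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(n) / fs
        signal += spec.baseline_amp * np.sin(2 * np.pi * spec.baseline_freq * tt + phase)
    if spec.noise_rms > 0:
        signal += spec.noise_rms * rng.standard_normal(n)

    annotations = [(int(r), str(label)) for r, label in zip(r_indices, labels)]
    return signal, annotations


@dataclass
class BeatDataset:
    """A labeled beat collection with stratified fold assignment."""

    windows: np.ndarray        # (n, d) mV
    labels: np.ndarray         # (n,) of 'N'/'V'/'L'
    folds: np.ndarray          # (n,) fold ids in [0, n_folds)
    r_indices: np.ndarray      # (n,) R positions in the source record
    fs: float
    n_folds: int

    def __len__(self) -> int:
        return len(self.labels)

    def fold_mask(self, fold: int) -> np.ndarray:
        return self.folds == fold


def assign_folds(labels: np.ndarray, folds: int, seed: int = 0) -> np.ndarray:
    """Stratified fold ids: per-class counts differ by at most 1 across folds.

    Remainder beats go to the lowest-numbered folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    out = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < folds:
            raise ValueError(f"class {cls!r} has {len(idx)} beats, fewer than {folds} folds")
        rng.shuffle(idx)
        base, rem = divmod(len(idx), folds)
        sizes = [base + (1 if f < rem else 0) for f in range(folds)]
        start = 0
        for f, size in enumerate(sizes):
            out[idx[start:start + size]] = f
            start += size
    return out


def generate_dataset(spec: RecordSpec, folds: int = 4,
                     d: int = DEFAULT_WINDOW) -> BeatDataset:
    """Generate a record and return its beats with stratified fold ids."""
    signal, annotations = generate_record(spec, d=d)
    half = (d - 1) // 2
    windows, labels, r_idx = [], [], []
    for r, label in annotations:
        windows.append(signal[r - half:r + half + 1])
        labels.append(label)
        r_idx.append(r)
    labels = np.asarray(labels)
    fold_ids = assign_folds(labels, folds, seed=spec.seed + 1)
    return BeatDataset(
        windows=np.asarray(windows),
        labels=labels,
        folds=fold_ids,
        r_indices=np.asarray(r_idx),
        fs=spec.fs,
        n_folds=folds,
    )


def write_record_csv(signal: np.ndarray, annotations, signal_path, ann_path) -> None:
    """Write a record as a single-column signal CSV plus a (sample_index, label) CSV."""
    np.savetxt(signal_path, np.asarray(signal), fmt="%.6f", header="mV", comments="")
    with open(ann_path, "w") as fh:
        fh.write("sample_index,label\n")
        for r, label in annotations:
            fh.write(f"{r},{label}\n")
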