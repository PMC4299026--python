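# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ecgtriage`, in the order the pipeline applies them.

## Synthetic ECG generator

Each beat is a sum of gaussian bumps, one per characteristic wave. The
defaults define the package's reference study conditions and are not meant
as a physiologically validated simulation:

| class | structure | QRS width scale | P wave | T wave |
|---|---|---|---|---|
| N | P, Q, R, S, T | 1.0 | 0.2 mV at −140 ms | +0.35 mV at +220 ms |
| V | wide R, deep S, no Q | 2.5 | absent | inverted, 0.5 mV |
| L | notched R (secondary 0.25 mV bump at +40 ms), wide QRS | 1.8 | 0.18 mV at −150 ms | inverted (discordant) |

Wave centers sit inside the standard delineation search windows (P in
[−200, −60] ms, T in [+80, +400] ms relative to R) with margin for the
per-beat jitter: every wave receives ~5% amplitude and width jitter and P/T
centers ±5 ms (1 s.d.), seeded per beat. The R bump stays anchored at the
window center, so the annotation index is the true R sample (argmax of the
clean beat within ±1 sample).

Records place beats at RR intervals of 0.8 ± 0.05 s (clipped so windows
never overlap), then add white noise of 0.05 mV RMS and a 0.15 mV, 0.3 Hz
sinusoidal baseline (respiration band). Class priors default to the
proportions of the reference arrhythmia corpus the evaluation protocol is
modeled on: 74,064 N / 6,608 V / 8,032 L (≈ 0.835 / 0.075 / 0.091).

**What passing tests do and do not show.** The generator reproduces the
*class-separating structure* (QRS width, P-wave presence, T polarity,
amplitudes) but none of the difficulty of real ambulatory ECG:
inter-patient morphology variability, electrode artifacts, rhythm changes,
fusion beats, or class overlap. Consequently the desk-scale pipeline
reaches NDR ≈ ARR ≈ 1.0, and passing the end-to-end bar (ARR ≥ 0.95 with
NDR ≥ 0.85) demonstrates the *plumbing and the optimization machinery*,
not clinical performance. On real recordings NDR in the low-to-mid 90s at
a 95% ARR floor is the realistic regime for this model class.

Stratified fold assignment shuffles each class (seeded) and deals
`n // folds` beats per fold, giving the remainder to the lowest-numbered
folds — deterministic and testable; per-class fold counts differ by ≤ 1.

## Conditioning

*Baseline removal* subtracts a morphological baseline estimate: grey-scale
opening with a flat 0.2 s structuring element followed by closing with
0.28 s (72 and 101 samples at 360 Hz). The element widths bracket the QRS
and T durations, so the estimate tracks sub-1-Hz drift but not the waves
themselves.

*R-peak detection* uses the à trous quadratic-spline filter bank
(lowpass (1,3,3,1)/8, highpass (2,−2)); a wave appears as an opposite-sign
modulus-maxima pair with a zero crossing at the peak. QRS candidates are
pairs at scale 2³ within 150 ms whose maxima exceed an adaptive threshold,
confirmed at scale 2², localized at the zero crossing, refined to the
local signal-magnitude maximum (±40 ms), and de-duplicated with a 200 ms
refractory period that keeps the larger peak.

The threshold is `0.3 × max(trailing 2-s RMS, centered 2-s peak envelope)`
of the per-scale coefficients. The RMS term alone proved insufficient:
QRS energy inflates a 2-s RMS while white-noise extrema (≈ 4 s.d.) still
clear 0.3 × RMS, producing spurious pairs; the peak-envelope term — the
standard amplitude-tracking component of wavelet QRS detectors — rejects
T waves and noise well below the running QRS amplitude. A consequence of
the centered envelope is that detection needs ≥ one QRS within ±1 s, which
holds for any plausible rhythm.

*Segmentation* cuts the d = 201-sample window (R ± 100 samples). The
wording "100 samples before and after" is ambiguous between d = 200 and
201; including the R sample keeps the window symmetric, and `d` remains a
parameter. Edge beats whose window would leave the record are dropped (and
logged), never padded, preserving the fixed-length classifier contract.

## Dimensionality reduction

*Random projections.* Entries are sampled i.i.d. from the sparse ternary
law (+1, −1 w.p. 1/6 each, 0 w.p. 2/3). Projection is implemented as
signed accumulation over the ±1 column masks; on integer-valued (ADC)
samples it is bit-identical to a dense matrix-vector product. Packing uses
2 bits per entry ({0→00, +1→01, −1→10}, row-major, first entry in the low
bits of each byte): a 16 × 201 matrix costs 804 bytes, a quarter of an
8-bit encoding.

*PCA.* Power iteration with deflation on the sample covariance
`(1/N) Σ (vᵢ − E[v])(vᵢ − E[v])ᵀ` (tolerance 1e−9, ≤ 1000 iterations per
component, re-orthogonalization against accepted components every sweep,
sign fixed by making the largest-magnitude element positive). Components
agree with a full eigendecomposition to |cos| > 0.999 on well-separated
spectra; closely spaced eigenvalues converge more slowly and are only
guaranteed up to the iteration cap.

*Fiducial points.* Eight signed sample offsets relative to R, in the fixed
order (P_on, P_peak, P_end, QRS_on, QRS_end, T_on, T_peak, T_end); sample
units keep the features integer-friendly for the embedded path. QRS
bounds are the outermost samples within ±60 ms whose combined scale-2¹/2²
magnitude exceeds 10% of the QRS modulus maximum. P and T waves are sought
at scale 2⁴ in [−200, −60] ms and [+80, +400] ms: a wave requires an
opposite-sign modulus-maxima pair with an interior zero crossing (the
monotone flank a neighboring QRS leaks into the window cannot produce
one) and a modulus maximum ≥ 10% of the QRS modulus maximum at that scale.
Onset/end are where the detail magnitude decays below 25% of the bounding
maxima. An undetected point inherits the position of its detected neighbor
closer to R (ultimately the R peak itself, offset 0) — so a V beat with no
P wave reports P_on = P_peak = P_end = QRS_on — and a final monotone clamp
guarantees the ordering invariant for arbitrary inputs.

## Neuro-fuzzy classifier

Features are normalized per coefficient to zero mean and unit variance
(fitted on the balanced training split and stored in the model) so that
membership initialization and a fixed learning rate are meaningful across
feature families of very different scales (projection sums vs sample
offsets).

Initialization sets each gaussian's center/width to the per-class sample
mean/standard deviation of the normalized coefficient, with σ floored at
1e−3 to prevent degenerate spikes. Training minimizes the mean squared
error between the normalized fuzzy vector `f_l / Σf` and the one-hot class
target by batch gradient descent (default 200 epochs, learning rate 0.05,
no momentum); gradients are exact derivatives through the
product-of-gaussians layers and match central finite differences to
< 1e−6. A nonlinear conjugate-gradient optimizer over the same loss is
available behind `optimizer="cg"`. Samples whose fuzzy sum underflows
contribute no gradient. The loss function, rate and epoch count are this
package's declared choices; MSE on normalized outputs is the classical
neuro-fuzzy training target and keeps the product-layer gradients simple.

The decision rule assigns the argmax class iff `M1 − M2 ≥ α·S`, else U.
Two degenerate cases are fixed deterministically: an exact tie M1 = M2 and
the all-zero fuzzy vector (possible only after quantization) both yield U
— the conservative, pathological call. The rule is scale-invariant
(multiplying all fuzzy values by λ > 0 changes nothing), which is what
licenses the integer shift-truncate scheme below.

`tune_alpha` returns the smallest α on the grid {0, 0.001, …, 1} with
ARR ≥ the floor on the tuning split; ARR is non-decreasing in α (raising α
only moves beats into U, which counts as recognized), so the result is
unique and can be found by sorting per-beat margin ratios. If even α = 1
fails (an abnormal beat whose non-winning fuzzy values are exactly zero),
(1.0, False) is returned.

## Integer inference path

The feature quantizer maps each normalized coefficient's range
[−4.7, +4.7] onto [0, 65535]; ±4.7σ spans the support `4S = 4·2.35σ` of a
unit-σ membership function. Each gaussian is scaled to peak 65535 and
replaced by:

- 0 for |c−x| ≥ 4S, the constant 1 on [2S, 4S) (the smallest nonzero
  grade, keeping products rarely zero),
- the chord from (2S, 1) to (S, G_S) on [S, 2S),
- the chord from (S, G_S) to (0, 65535) on [0, S),

with `G_S = round(65535·e^{−2.35²/2}) = 4143` and slopes precomputed in
Q16 fixed point, so evaluation uses only integer add/multiply/shift. The
chord construction interpolates exact scaled-gaussian values, making it
fully reproducible; the exact slopes of the reference two-segment
approximation are not published, so equivalence to any particular firmware
is not claimed. Worst-case deviation from the rounded scaled gaussian is
analytic: stationary points of `chord(t) − e^{−t²/2}` sit at
t ≈ 0.44 (gaussian above the chord, ≈ 5,448 counts) and t ≈ 1.71σ (chord
above the gaussian tail, ≈ 5,675 counts ≈ 8.7% of full scale). The
documented bound is 5,750 (slack for slope/grid rounding) and is asserted
by exhaustive 16-bit sweep. The plateau and the floor in the evaluation
keep the curve monotone non-increasing in |c−x|.

Fuzzification multiplies 16-bit grades into three 32-bit accumulators:
after each product, all three are left-shifted by the largest common
amount keeping every one below 2³², then the low 16 bits are dropped.
Because only ratios matter to the decision, this retains the maximum
common precision; a class whose accumulator underflows to zero stays
zero. For a single step whose shifted values all reach ≥ 2³¹ the
pairwise-ratio error is below ~2⁻¹⁴ (one floor of ≤ 1 count on outputs
≥ 2¹⁵ per operand).

Defuzzification compares `(M1 − M2)·2¹⁶ ≥ α_q16·S` in 64-bit integers —
exactly the real-valued rule with `α = α_q16/2¹⁶`, no division. α is
stored as Q0.16, clipped to 65535 (so α = 1 is represented with error
2⁻¹⁶).

The parity audit labels a beat set through both paths and reports
agreement and NDR/ARR deltas; the package's acceptance bar is ≥ 99% label
agreement on the default 10,000-beat synthetic set. Disagreements
concentrate on beats whose float margin is within the propagated
quantization error of the α threshold.

## Genetic optimization of the projection

Candidate matrices are scored by: project both training splits, initialize
and train the classifier on the balanced split, tune α on the larger
split, and read the NDR there. A candidate that cannot reach the ARR floor
even at α = 1 is penalized below every feasible one (score = NDR − 1),
keeping the constraint primary. The search uses tournament selection
(size 3), row-wise uniform crossover (rate 0.9), per-entry resampling
mutation from the ternary law (rate 0.02) and elitism 2, so best fitness
is monotone non-decreasing. Reference scale is a population of 20 for 30
generations; the desk-scale default used by the tests and the acceptance
script is 10 × 10, which converges on the synthetic conditions in well
under a minute per cross-validation round. Selection scheme and rates are
declared here, not taken from any publication.

## Evaluation protocol

4-fold cross-validation with class-stratified folds. Per round: the three
training folds form train_set_2; a balanced train_set_1 (150 beats per
class, 450 total, drawn seeded from the training folds) fits the
membership functions (and the PCA matrix when used); train_set_2 tunes α
and drives the GA; the held-out fold is scored. NDR counts only
true-normal beats *predicted N* as discarded (a normal beat predicted V, L
or U is sent to detailed analysis); ARR counts any abnormal beat predicted
V, L or U as recognized — confusing V with L is not a triage error.

Baselines (LDA, linear SVM, gaussian SVM via scikit-learn) solve the
binary normal-vs-abnormal problem on the same folds; their operating point
is the decision-axis threshold maximizing training NDR subject to the
training ARR floor. Run-time parameter counts are the hyperplane length
for linear models, the support-vector count for the RBF SVM, and k × 3
gaussians for the neuro-fuzzy classifier.

The transmission-savings estimator assumes a node sends 2 bytes for a beat
it calls normal (R-peak offset) and 18 bytes otherwise (8 fiducial points
× 2 bytes + header), against a reference that sends 18 bytes for every
beat; both costs are configurable:
`reduction = 1 − (n_N·b_N + n_A·b_A)/(n·b_A)`.

## Numerical choices and degenerate inputs

- σ floor 1e−3 (normalized units) everywhere a width is produced.
- α grid step 0.001 — below any rate change observable at desk-scale n.
- Flat or empty records yield no detections; flat beat windows yield an
  all-undetected fiducial set (all offsets 0).
- Constant feature matrices are rejected by PCA (zero covariance) and
  handled by the classifier via the σ floor.
- Power-iteration start vector: the covariance column of the largest
  diagonal entry, a deterministic choice.

## Known limitations

- The synthetic generator's realism limits (above) — full-scale claims
  require real annotated recordings, ingested via the CSV readers.
- Only single-lead processing; the three-lead detailed-analysis stage
  downstream of triage is out of scope.
- The wavelet delineator's thresholds (10% detection, 25% boundary decay)
  are pinned for reproducibility, not tuned against a reference
  delineation corpus.
- Three beat classes only; no patient-adaptive retraining.
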