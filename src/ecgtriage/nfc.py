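"""Three-layer neuro-fuzzy classifier for N / V / L heartbeat triage.

Layer 1 (membership): one gaussian membership function per (coefficient,
class) pair, mu_{k,l}(u_k) = exp(-(u_k - c_{k,l})^2 / (2 sigma_{k,l}^2)).

Layer 2 (fuzzification): per-class product of the k membership grades,
f_l = prod_k mu_{k,l}(u_k).

Layer 3 (defuzzification): with M1 >= M2 the two largest fuzzy values and
S their sum, the beat is assigned to the argmax class when
M1 - M2 >= alpha * S and otherwise marked unknown (U).  V, L and U are
treated as potentially pathological; only N beats are discarded from
detailed analysis.

Features are affinely normalized (per coefficient, fitted on the balanced
training split) before membership evaluation; the normalization is stored
in the model so quantization and inference see the same scale.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

CLASSES = ("N", "V", "L")
PATHOLOGICAL = frozenset({"V", "L", "U"})

SIGMA_FLOOR = 1e-3       # after normalization; prevents degenerate spikes
ALPHA_GRID_STEP = 1e-3
_TINY = 1e-300


@dataclass(frozen=True)
class MembershipFunction:
    """A gaussian membership curve with center c and width sigma."""

    center: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def membership_grade(mf: MembershipFunction, u_k: float) -> float:
    """mu(u) = exp(-(u - c)^2 / (2 sigma^2)), in (0, 1]."""
    return float(np.exp(-((u_k - mf.center) ** 2) / (2.0 * mf.sigma**2)))


@dataclass
class NfcModel:
    """Gaussian membership grid plus feature scaling and the tuned alpha."""

    centers: np.ndarray       # (k, 3) in normalized feature space
    sigmas: np.ndarray        # (k, 3), >= SIGMA_FLOOR
    scale_mean: np.ndarray    # (k,) per-coefficient affine normalization
    scale_std: np.ndarray     # (k,)
    alpha_train: float = 0.0
    trained: bool = False
    reducer_id: str = ""
    loss_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.centers.shape != self.sigmas.shape or self.centers.shape[1] != 3:
            raise ValueError("centers and sigmas must both be (k, 3)")
        if np.any(self.sigmas <= 0):
            raise ValueError("all sigmas must be positive")
        if not 0.0 <= self.alpha_train <= 1.0:
            raise ValueError("alpha_train must be in [0, 1]")

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def normalize(self, u: np.ndarray) -> np.ndarray:
        return (np.asarray(u, dtype=float) - self.scale_mean) / self.scale_std

    def membership(self, coefficient: int, class_label: str) -> MembershipFunction:
        l = CLASSES.index(class_label)
        return MembershipFunction(self.centers[coefficient, l],
                                  self.sigmas[coefficient, l])

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "format": "ecgtriage-nfc",
            "version": 1,
            "classes": list(CLASSES),
            "centers": self.centers.tolist(),
            "sigmas": self.sigmas.tolist(),
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
            "alpha_train": self.alpha_train,
            "trained": self.trained,
            "reducer_id": self.reducer_id,
        })

    @classmethod
    def from_json(cls, text: str) -> "NfcModel":
        obj = json.loads(text)
        if obj.get("format") != "ecgtriage-nfc":
            raise ValueError("not an ecgtriage NFC model")
        return cls(
            centers=np.asarray(obj["centers"]),
            sigmas=np.asarray(obj["sigmas"]),
            scale_mean=np.asarray(obj["scale_mean"]),
            scale_std=np.asarray(obj["scale_std"]),
            alpha_train=obj["alpha_train"],
            trained=obj["trained"],
            reducer_id=obj.get("reducer_id", ""),
        )


@dataclass
class ClassificationResult:
    """Fuzzy values and the triage decision for one beat."""

    fuzzy_values: np.ndarray
    label: str
    is_pathological: bool
    m1: float
    m2: float
    s: float


# ---------------------------------------------------------------------------
# inference

def fuzzify(model: NfcModel, u: np.ndarray) -> np.ndarray:
    """Per-class fuzzy values f_l = prod_k mu_{k,l}(u_k) for one beat."""
    u = np.asarray(u, dtype=float)
    if u.shape != (model.k,):
        raise ValueError(f"expected a length-{model.k} feature vector, got {u.shape}")
    return fuzzify_batch(model, u[None, :])[0]


def fuzzify_batch(model: NfcModel, U: np.ndarray) -> np.ndarray:
    """Vectorized fuzzification of an (n, k) feature matrix -> (n, 3)."""
    Z = model.normalize(np.atleast_2d(U))
    if Z.shape[1] != model.k:
        raise ValueError(f"expected k={model.k} coefficients, got {Z.shape[1]}")
    log_g = -((Z[:, :, None] - model.centers[None]) ** 2) / (2.0 * model.sigmas[None] ** 2)
    return np.exp(log_g.sum(axis=1))


def defuzzify(fuzzy_values: np.ndarray, alpha: float) -> ClassificationResult:
    """Assign the argmax class when M1 - M2 >= alpha * S, else unknown (U).

    Ties (M1 == M2) and the all-zero vector yield U, the conservative
    (pathological) call.
    """
    f = np.asarray(fuzzy_values, dtype=float)
    if f.shape != (3,) or np.any(f < 0) or not np.all(np.isfinite(f)):
        raise ValueError("fuzzy values must be 3 nonnegative finite numbers")
    order = np.argsort(f)[::-1]
    m1, m2 = float(f[order[0]]), float(f[order[1]])
    s = float(f.sum())
    if s <= 0.0 or m1 == m2 or (m1 - m2) < alpha * s:
        label = "U"
    else:
        label = CLASSES[order[0]]
    return ClassificationResult(f, label, label in PATHOLOGICAL, m1, m2, s)


def classify(model: NfcModel, u: np.ndarray,
             alpha_test: float | None = None) -> ClassificationResult:
    """Fuzzify then defuzzify; alpha_test defaults to the trained alpha."""
    alpha = model.alpha_train if alpha_test is None else alpha_test
    return defuzzify(fuzzify(model, u), alpha)


def classify_batch(model: NfcModel, U: np.ndarray,
                   alpha_test: float | None = None) -> np.ndarray:
    """Vectorized labels for an (n, k) feature matrix."""
    alpha = model.alpha_train if alpha_test is None else alpha_test
    F = fuzzify_batch(model, U)
    return _labels_from_fuzzy(F, alpha)


def _labels_from_fuzzy(F: np.ndarray, alpha: float) -> np.ndarray:
    part = np.sort(F, axis=1)
    m1, m2 = part[:, 2], part[:, 1]
    s = F.sum(axis=1)
    assigned = (s > 0) & (m1 > m2) & ((m1 - m2) >= alpha * s)
    labels = np.full(len(F), "U", dtype="<U1")
    arg = np.argmax(F, axis=1)
    labels[assigned] = np.asarray(CLASSES)[arg[assigned]]
    return labels


# ---------------------------------------------------------------------------
# training

def init_model(features: np.ndarray, labels: np.ndarray,
               reducer_id: str = "") -> NfcModel:
    """Warm-start the membership grid from per-class sample moments.

    Feature scaling (zero mean, unit variance per coefficient) is fitted on
    the given set; centers are per-class means and sigmas per-class standard
    deviations of the normalized features, floored at SIGMA_FLOOR.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be (n, k)")
    for cls in CLASSES:
        if np.sum(y == cls) < 2:
            raise ValueError(f"need at least 2 samples of class {cls!r}")
    scale_mean = X.mean(axis=0)
    scale_std = np.maximum(X.std(axis=0), 1e-9)
    Z = (X - scale_mean) / scale_std
    k = X.shape[1]
    centers = np.zeros((k, 3))
    sigmas = np.zeros((k, 3))
    for l, cls in enumerate(CLASSES):
        Zc = Z[y == cls]
        centers[:, l] = Zc.mean(axis=0)
        sigmas[:, l] = np.maximum(Zc.std(axis=0), SIGMA_FLOOR)
    return NfcModel(centers, sigmas, scale_mean, scale_std, reducer_id=reducer_id)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    y = np.zeros((len(labels), 3))
    for l, cls in enumerate(CLASSES):
        y[np.asarray(labels) == cls, l] = 1.0
    return y


def loss_and_gradients(centers: np.ndarray, sigmas: np.ndarray,
                       Z: np.ndarray, Y: np.ndarray):
    """MSE between the normalized fuzzy vector and the one-hot target.

    Returns (loss, dL/dcenters, dL/dsigmas); gradients are exact
    derivatives of the loss through the product-of-gaussians layers.
    Samples whose fuzzy sum underflows to ~0 contribute no gradient.
    """
    n = len(Z)
    diff = Z[:, :, None] - centers[None]                       # (n, k, 3)
    log_g = -(diff**2) / (2.0 * sigmas[None] ** 2)
    F = np.exp(log_g.sum(axis=1))                              # (n, 3)
    S = F.sum(axis=1)
    ok = S > _TINY
    P = np.full_like(F, 1.0 / 3.0)
    P[ok] = F[ok] / S[ok, None]
    R = P - Y
    loss = float(np.mean(np.sum(R**2, axis=1)))

    # dL/dF_m = (2/n) (R_m - sum_l R_l P_l) / S   (zero where S underflowed)
    rp = np.sum(R * P, axis=1, keepdims=True)
    A = np.zeros_like(F)
    A[ok] = (2.0 / n) * (R[ok] - rp[ok]) / S[ok, None]
    AF = A * F                                                  # (n, 3)
    d_centers = np.einsum("il,ikl->kl", AF, diff / sigmas[None] ** 2)
    d_sigmas = np.einsum("il,ikl->kl", AF, diff**2 / sigmas[None] ** 3)
    return loss, d_centers, d_sigmas


def train_model(model: NfcModel, features: np.ndarray, labels: np.ndarray,
                epochs: int = 200, learning_rate: float = 0.05,
                optimizer: str = "gd", seed: int | None = None) -> NfcModel:
    """Refine the membership grid by batch gradient descent (or nonlinear CG).

    The loss is the mean squared error between the normalized fuzzy vector
    f_l / sum f and the one-hot class target.  Sigmas are floored at
    SIGMA_FLOOR after every step.  Returns a trained copy; the input model
    is untouched.  ``epochs=0`` returns the (marked-trained) model unchanged.
    """
    out = copy.deepcopy(model)
    Z = out.normalize(np.asarray(features, dtype=float))
    Y = _one_hot(labels)
    centers, sigmas = out.centers.copy(), out.sigmas.copy()
    history: list[float] = []

    if optimizer == "gd":
        for _ in range(epochs):
            loss, dC, dS = loss_and_gradients(centers, sigmas, Z, Y)
            if not (np.isfinite(loss) and np.all(np.isfinite(dC)) and np.all(np.isfinite(dS))):
                raise RuntimeError("non-finite loss or gradients during NFC training")
            history.append(loss)
            centers -= learning_rate * dC
            sigmas = np.maximum(sigmas - learning_rate * dS, SIGMA_FLOOR)
    elif optimizer == "cg":
        from scipy.optimize import minimize

        shape = centers.shape

        def fun(theta):
            c = theta[:centers.size].reshape(shape)
            s = np.maximum(theta[centers.size:].reshape(shape), SIGMA_FLOOR)
            loss, dC, dS = loss_and_gradients(c, s, Z, Y)
            history.append(loss)
            return loss, np.concatenate([dC.ravel(), dS.ravel()])

        res = minimize(fun, np.concatenate([centers.ravel(), sigmas.ravel()]),
                       jac=True, method="CG", options={"maxiter": epochs})
        centers = res.x[:centers.size].reshape(shape)
        sigmas = np.maximum(res.x[centers.size:].reshape(shape), SIGMA_FLOOR)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}; use 'gd' or 'cg'")

    out.centers, out.sigmas = centers, sigmas
    out.trained = True
    out.loss_history = history
    return out


def tune_alpha(model: NfcModel, features: np.ndarray, labels: np.ndarray,
               arr_min: float = 0.95,
               grid_step: float = ALPHA_GRID_STEP) -> tuple[float, bool]:
    """Smallest grid alpha with ARR >= arr_min on the given set.

    ARR counts abnormal (V/L) beats labeled V, L or U as recognized; it is
    non-decreasing in alpha, so the returned alpha is unique.  Returns
    (alpha, reached); when even alpha=1 cannot meet the bound, returns
    (1.0, False).
    """
    y = np.asarray(labels)
    abnormal = np.isin(y, ("V", "L"))
    if not abnormal.any():
        raise ValueError("tuning set contains no abnormal (V/L) beats")
    F = fuzzify_batch(model, features)[abnormal]
    part = np.sort(F, axis=1)
    m1, m2 = part[:, 2], part[:, 1]
    s = F.sum(axis=1)
    arg_n = (np.argmax(F, axis=1) == 0) & (s > 0) & (m1 > m2)
    # an abnormal beat escapes recognition iff it is assigned class N:
    # margin ratio r >= alpha with r = (m1 - m2)/s
    r = np.where(s > 0, (m1 - m2) / np.maximum(s, _TINY), 0.0)[arg_n]
    n_abn = int(abnormal.sum())
    base = n_abn - len(r)  # abnormal beats never classified as N

    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 9)
    r_sorted = np.sort(r)
    # recognized(alpha) = base + #{r_i < alpha}
    recognized = base + np.searchsorted(r_sorted, grid, side="left")
    arr = recognized / n_abn
    hit = np.flatnonzero(arr >= arr_min)
    if len(hit):
        return float(grid[hit[0]]), True
    return 1.0, False
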