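"""Triage metrics, cross-validation, Pareto sweeps and baseline comparison.

Two headline rates summarize a triage run:

* NDR (normal discard rate) — the fraction of true-normal beats labeled N
  and hence discarded from detailed analysis;
* ARR (abnormal recognition rate) — the fraction of true-pathological
  (V or L) beats labeled V, L or U, i.e. flagged for detailed analysis.
  Class confusion among pathologies is not an error at the triage level.

Cross-validation follows the 4-fold protocol: a balanced train_set_1
(default 150 beats per class) drawn from the training folds fits the
membership functions, the full training folds (train_set_2) tune alpha —
and, for random projections, drive the genetic matrix search — and the
held-out fold is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecgtriage import dimreduce, nfc

CLASSES = ("N", "V", "L")
PRED_LABELS = ("N", "V", "L", "U")


@dataclass
class EvalReport:
    """Confusion counts plus the NDR/ARR pair for one evaluation."""

    confusion: pd.DataFrame   # rows: true N/V/L; columns: predicted N/V/L/U
    ndr: float
    arr: float
    alpha_used: float | None = None

    @property
    def n_total(self) -> int:
        return int(self.confusion.to_numpy().sum())

    @property
    def n_pred_normal(self) -> int:
        return int(self.confusion["N"].sum())

    @property
    def n_pred_abnormal(self) -> int:
        return self.n_total - self.n_pred_normal


def compute_ndr_arr(predictions, truths, alpha_used: float | None = None) -> EvalReport:
    """NDR/ARR and the full 3x4 confusion table.

    ``truths`` must contain at least one normal and one abnormal beat.
    """
    preds = np.asarray(predictions)
    y = np.asarray(truths)
    if len(preds) != len(y) or len(y) == 0:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    if not set(np.unique(y)) <= set(CLASSES):
        raise ValueError(f"truths may only contain {CLASSES}")
    if not set(np.unique(preds)) <= set(PRED_LABELS):
        raise ValueError(f"predictions may only contain {PRED_LABELS}")
    normal = y == "N"
    abnormal = ~normal
    if not normal.any() or not abnormal.any():
        raise ValueError("truths must contain both normal and abnormal beats")
    counts = np.zeros((3, 4), dtype=int)
    for i, t in enumerate(CLASSES):
        for j, p in enumerate(PRED_LABELS):
            counts[i, j] = int(np.sum((y == t) & (preds == p)))
    confusion = pd.DataFrame(counts, index=list(CLASSES), columns=list(PRED_LABELS))
    ndr = float(np.sum(normal & (preds == "N")) / normal.sum())
    arr = float(np.sum(abnormal & (preds != "N")) / abnormal.sum())
    return EvalReport(confusion, ndr, arr, alpha_used)


def mean_report(reports: list[EvalReport]) -> EvalReport:
    """Element-wise sum of confusions with mean NDR/ARR across folds."""
    confusion = sum(r.confusion for r in reports)
    return EvalReport(confusion,
                      float(np.mean([r.ndr for r in reports])),
                      float(np.mean([r.arr for r in reports])),
                      float(np.mean([r.alpha_used for r in reports]))
                      if all(r.alpha_used is not None for r in reports) else None)


# ---------------------------------------------------------------------------
# cross-validation

REDUCERS = ("rp8", "rp16", "pca8", "pca16", "fpd", "rp8+fpd", "pca8+fpd")


@dataclass
class CvResult:
    fold_reports: list
    mean: EvalReport
    reducer: str
    models: list = field(default_factory=list)


def _reduce_fold(reducer: str, train1_w, train2_w, test_w, fs,
                 train1_labels, train2_labels, ga_config, seed):
    """Fit the configured front-end on the training data and project all splits.

    Returns (u1, u2, u_test, trained_model_or_None, alpha_or_None, frontend)
    where frontend is the fitted AchlioptasMatrix / PcaMatrix (None for fpd).
    """
    from ecgtriage import ga_opt

    if reducer.startswith("rp"):
        k = 8 if reducer.startswith("rp8") else 16
        cfg = ga_config or ga_opt.DESK_GA
        if cfg.seed != seed:
            from dataclasses import replace
            cfg = replace(cfg, seed=seed)
        result = ga_opt.evolve(cfg, train1_w, train1_labels,
                               train2_w, train2_labels, k=k,
                               d=train1_w.shape[1])
        P = result.best_matrix
        u1 = dimreduce.project_rp(P, train1_w)
        u2 = dimreduce.project_rp(P, train2_w)
        ut = dimreduce.project_rp(P, test_w)
        return u1, u2, ut, result.best_model, result.best_alpha, P
    elif reducer.startswith("pca"):
        k = 8 if reducer.startswith("pca8") else 16
        T = dimreduce.fit_pca(train1_w, k)
        u1 = dimreduce.project_pca(T, train1_w)
        u2 = dimreduce.project_pca(T, train2_w)
        ut = dimreduce.project_pca(T, test_w)
        return u1, u2, ut, None, None, T
    elif reducer == "fpd":
        u1 = dimreduce.fpd_features(train1_w, fs)
        u2 = dimreduce.fpd_features(train2_w, fs)
        ut = dimreduce.fpd_features(test_w, fs)
        return u1, u2, ut, None, None, None
    raise ValueError(f"unknown reducer {reducer!r}; expected one of {REDUCERS}")


def cross_validate(dataset, reducer: str = "rp16", arr_min: float = 0.95,
                   train1_per_class: int = 150, ga_config=None,
                   nfc_epochs: int = 200, learning_rate: float = 0.05,
                   alpha_test: float | None = None, seed: int = 0) -> CvResult:
    """Round-robin evaluation over the dataset's fold assignment.

    Combined reducers ("rp8+fpd", "pca8+fpd") concatenate the 8 projection
    coefficients with the 8 fiducial offsets before training.
    """
    if reducer not in REDUCERS:
        raise ValueError(f"unknown reducer {reducer!r}; expected one of {REDUCERS}")
    windows, labels = dataset.windows, dataset.labels
    rng = np.random.default_rng(seed)
    reports, models = [], []

    base, fpd_extra = (reducer.split("+") + [None])[:2]
    for fold in range(dataset.n_folds):
        test_mask = dataset.fold_mask(fold)
        train_mask = ~test_mask
        tr_idx = np.flatnonzero(train_mask)
        tr_labels = labels[tr_idx]
        # balanced train_set_1 drawn from the training folds
        t1_idx = []
        for cls in CLASSES:
            cls_idx = tr_idx[tr_labels == cls]
            if len(cls_idx) < train1_per_class:
                raise ValueError(
                    f"class {cls!r} has only {len(cls_idx)} training beats; "
                    f"need {train1_per_class}")
            t1_idx.append(rng.choice(cls_idx, size=train1_per_class, replace=False))
        t1_idx = np.concatenate(t1_idx)

        t1_w, t1_y = windows[t1_idx], labels[t1_idx]
        t2_w, t2_y = windows[tr_idx], labels[tr_idx]
        te_w, te_y = windows[test_mask], labels[test_mask]

        u1, u2, ut, model, alpha, _frontend = _reduce_fold(
            base, t1_w, t2_w, te_w, dataset.fs, t1_y, t2_y, ga_config,
            seed=int(rng.integers(0, 2**31)))
        if fpd_extra:
            u1 = dimreduce.combine_features(u1, dimreduce.fpd_features(t1_w, dataset.fs))
            u2 = dimreduce.combine_features(u2, dimreduce.fpd_features(t2_w, dataset.fs))
            ut = dimreduce.combine_features(ut, dimreduce.fpd_features(te_w, dataset.fs))
            model = alpha = None  # NFC must be retrained on the widened features

        if model is None:
            model = nfc.init_model(u1, t1_y, reducer_id=reducer)
            model = nfc.train_model(model, u1, t1_y, epochs=nfc_epochs,
                                    learning_rate=learning_rate)
            alpha, _ = nfc.tune_alpha(model, u2, t2_y, arr_min=arr_min)
            model.alpha_train = alpha

        used_alpha = alpha if alpha_test is None else alpha_test
        preds = nfc.classify_batch(model, ut, used_alpha)
        reports.append(compute_ndr_arr(preds, te_y, alpha_used=used_alpha))
        models.append(model)

    return CvResult(reports, mean_report(reports), reducer, models)


# ---------------------------------------------------------------------------
# alpha_test sweeps

@dataclass
class ParetoCurve:
    """NDR/ARR trade-off points, alpha ascending."""

    points: pd.DataFrame  # columns: alpha, ndr, arr


def pareto_sweep(model: nfc.NfcModel, features: np.ndarray, truths,
                 alpha_grid) -> ParetoCurve:
    """Evaluate NDR/ARR at every alpha of the grid (run-time alpha scaling).

    Along the returned curve ARR is non-decreasing and NDR non-increasing:
    raising alpha only moves beats into the (pathological) unknown class.
    """
    grid = np.sort(np.asarray(alpha_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("alpha grid must be non-empty")
    F = nfc.fuzzify_batch(model, features)
    rows = []
    for alpha in grid:
        report = compute_ndr_arr(nfc._labels_from_fuzzy(F, alpha), truths, alpha)
        rows.append((float(alpha), report.ndr, report.arr))
    return ParetoCurve(pd.DataFrame(rows, columns=["alpha", "ndr", "arr"]))


# ---------------------------------------------------------------------------
# baseline classifiers

def _pick_threshold(scores: np.ndarray, y_bin: np.ndarray, arr_min: float) -> float:
    """Operating point on the decision axis meeting the training ARR floor.

    Scores are oriented so larger means more abnormal; a beat is flagged
    when its score exceeds the threshold.  Among the thresholds that miss
    at most floor((1 - arr_min) * n_abnormal) abnormal training beats, the
    one maximizing the training NDR is returned (ties go to the threshold
    missing fewer abnormals).
    """
    abn = np.sort(scores[y_bin == 1])
    nrm = scores[y_bin == 0]
    max_miss = int(np.floor((1.0 - arr_min) * len(abn)))
    best_ndr, best_thr = -1.0, -np.inf
    for miss in range(0, max_miss + 1):
        thr = float(np.nextafter(abn[miss], -np.inf)) if miss < len(abn) else np.inf
        ndr = float(np.mean(nrm <= thr)) if len(nrm) else 0.0
        if ndr > best_ndr + 1e-12:
            best_ndr, best_thr = ndr, thr
    return best_thr


def baseline_compare(features: np.ndarray, truths, folds,
                     arr_min: float = 0.95, nfc_epochs: int = 200,
                     seed: int = 0) -> pd.DataFrame:
    """Compare LDA, linear SVM, gaussian SVM and the NFC on identical folds.

    The reference classifiers solve the binary normal-vs-abnormal problem;
    their operating point is moved along the decision axis to the threshold
    that maximizes the training NDR subject to the training ARR floor (a
    low-enough threshold always satisfies the floor, so no relaxation of
    the constraint itself is needed).  Returns one row per classifier with
    NDR, ARR and the run-time parameter count (hyperplane elements, support
    vectors, or gaussian membership functions).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.svm import SVC

    X = np.asarray(features, dtype=float)
    y = np.asarray(truths)
    folds = np.asarray(folds)
    y_bin = (y != "N").astype(int)  # 1 = abnormal
    mu, sd = X.mean(axis=0), np.maximum(X.std(axis=0), 1e-9)
    Xs = (X - mu) / sd
    fold_ids = np.unique(folds)

    def run_binary(make_clf):
        preds_all = np.empty(len(y), dtype="<U1")
        param_count = 0
        for f in fold_ids:
            test = folds == f
            train = ~test
            if len(np.unique(y_bin[train])) < 2 or len(np.unique(y_bin[test])) < 2:
                raise ValueError("degenerate single-class fold")
            clf = make_clf()
            clf.fit(Xs[train], y_bin[train])
            thr = _pick_threshold(clf.decision_function(Xs[train]), y_bin[train],
                                  arr_min)
            flagged = clf.decision_function(Xs[test]) > thr
            preds_all[test] = np.where(flagged, "V", "N")
            n_sv = getattr(clf, "n_support_", None)
            param_count = max(param_count,
                              int(np.sum(n_sv)) if n_sv is not None else Xs.shape[1])
        report = compute_ndr_arr(preds_all, y)
        return report, param_count

    rows = []
    lda_report, _ = run_binary(lambda: LinearDiscriminantAnalysis())
    rows.append(("lda", lda_report.ndr, lda_report.arr, X.shape[1]))
    lin_report, _ = run_binary(lambda: SVC(kernel="linear"))
    rows.append(("svm_linear", lin_report.ndr, lin_report.arr, X.shape[1]))
    rbf_report, n_sv = run_binary(lambda: SVC(kernel="rbf", gamma="scale"))
    rows.append(("svm_gaussian", rbf_report.ndr, rbf_report.arr, n_sv))

    # the neuro-fuzzy classifier on the same folds (3-class, alpha-tuned)
    rng = np.random.default_rng(seed)
    nfc_preds = np.empty(len(y), dtype="<U1")
    for f in fold_ids:
        test = folds == f
        tr_idx = np.flatnonzero(~test)
        t1_idx = []
        for cls in CLASSES:
            cls_idx = tr_idx[y[tr_idx] == cls]
            take = min(len(cls_idx), 150)
            t1_idx.append(rng.choice(cls_idx, size=take, replace=False))
        t1_idx = np.concatenate(t1_idx)
        model = nfc.init_model(X[t1_idx], y[t1_idx], reducer_id="baseline")
        model = nfc.train_model(model, X[t1_idx], y[t1_idx], epochs=nfc_epochs)
        alpha, _ = nfc.tune_alpha(model, X[tr_idx], y[tr_idx], arr_min=arr_min)
        nfc_preds[test] = nfc.classify_batch(model, X[test], alpha)
    nfc_report = compute_ndr_arr(nfc_preds, y)
    rows.append(("nfc", nfc_report.ndr, nfc_report.arr, X.shape[1] * 3))

    return pd.DataFrame(rows, columns=["classifier", "ndr", "arr", "parameter_count"])


# ---------------------------------------------------------------------------
# transmission savings

def transmission_savings(report: EvalReport, bytes_normal: int = 2,
                         bytes_abnormal: int = 18) -> float:
    """Percent reduction in transmitted volume vs sending full fiducial data.

    A triaging node sends only the R-peak position for beats it calls
    normal and the full fiducial description otherwise; the reference
    sends the full description for every beat:

        reduction = 1 - (n_N * b_N + n_A * b_A) / (n_total * b_A)
    """
    if bytes_normal <= 0 or bytes_abnormal <= 0:
        raise ValueError("byte costs must be positive")
    if bytes_normal > bytes_abnormal:
        raise ValueError("bytes_normal must not exceed bytes_abnormal")
    n_total = report.n_total
    if n_total == 0:
        raise ValueError("empty report")
    sent = report.n_pred_normal * bytes_normal + report.n_pred_abnormal * bytes_abnormal
    return 100.0 * (1.0 - sent / (n_total * bytes_abnormal))
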