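"""Medication-state classifiers and their significance testing.

Individual models: a support-vector machine or random forest trained and
evaluated within one subject using a 41-fold sliding-block
cross-validation.  The subject's balanced windows form a concatenated
sequence (pre half then post half); fold i tests the two contiguous
blocks at total-data percentiles [i, i+10) and [i+50, i+60) (one block
per medication state, together 20% of the data), and trains on the
remaining ~80% minus 2% buffer blocks adjacent to each test block, which
are discarded to limit temporal leakage.

Group models: leave-one-subject-out over the cohort.

Significance: permutation tests that shuffle medication-state labels and
re-run the full train/test procedure; the 95th percentile of the null
AUCs is the significance threshold and per-subject p-values are
FDR-corrected across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from bradyflux.features import FEATURE_NAMES
from bradyflux.groupstats import fdr_bh

ModelKind = Literal["sv", "rf"]
N_FOLDS = 41
TEST_BLOCK_PCT = 10.0
BUFFER_FRACTION = 0.02


@dataclass(frozen=True)
class FoldSpec:
    """Index sets (into the concatenated balanced sequence) of one fold."""

    fold_index: int
    test_idx: np.ndarray
    buffer_idx: np.ndarray
    train_idx: np.ndarray


@dataclass
class ModelResult:
    subject_id: str
    model_kind: ModelKind
    training_mode: Literal["individual", "group"]
    auc: float
    accuracy: float
    fold_aucs: np.ndarray | None = None
    fold_accuracies: np.ndarray | None = None
    null_aucs: np.ndarray | None = None
    p_value: float = np.nan
    threshold: float = np.nan
    fdr_significant: bool = False
    extras: dict = field(default_factory=dict)


def _block(q_lo: float, q_hi: float, n_total: int) -> np.ndarray:
    lo = int(np.floor(q_lo * n_total / 100.0))
    hi = int(np.floor(q_hi * n_total / 100.0))
    return np.arange(lo, hi)


def make_individual_folds(n_pre: int, n_post: int) -> list[FoldSpec]:
    """The 41 sliding-percentile folds over a subject's balanced sequence.

    Buffers of ceil(2% of total) windows flank each test block on both
    open sides, clipped to the block's own session half (the two halves
    are separate recordings, so there is no temporal adjacency across
    the half boundary).
    """
    if n_pre != n_post:
        raise ValueError("folds require state-balanced window counts")
    n = n_pre
    n_total = 2 * n
    buffer_w = int(np.ceil(BUFFER_FRACTION * n_total))
    folds = []
    for i in range(N_FOLDS):
        pre_block = _block(i, i + TEST_BLOCK_PCT, n_total)
        post_block = _block(i + 50, i + 60, n_total)
        if pre_block.size == 0 or post_block.size == 0:
            raise ValueError(
                f"too few windows ({n} per state) for a two-state test set in every fold"
            )
        test = np.concatenate([pre_block, post_block])
        buffers = []
        for blk, half_lo, half_hi in ((pre_block, 0, n), (post_block, n, n_total)):
            left = np.arange(max(blk[0] - buffer_w, half_lo), blk[0])
            right = np.arange(blk[-1] + 1, min(blk[-1] + 1 + buffer_w, half_hi))
            buffers.extend([left, right])
        buffer_idx = np.concatenate(buffers) if buffers else np.empty(0, dtype=int)
        mask = np.ones(n_total, dtype=bool)
        mask[test] = False
        mask[buffer_idx] = False
        folds.append(
            FoldSpec(
                fold_index=i,
                test_idx=test,
                buffer_idx=buffer_idx,
                train_idx=np.flatnonzero(mask),
            )
        )
    return folds


def fit_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    model_kind: ModelKind,
    model_seed: int = 0,
) -> np.ndarray:
    """Train one classifier and return a continuous score per test
    window (higher = more post-medication-like)."""
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class")
    if model_kind == "sv":
        model = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=model_seed)
        model.fit(x_train, y_train)
        return model.decision_function(x_test)
    if model_kind == "rf":
        model = RandomForestClassifier(n_estimators=100, random_state=model_seed, n_jobs=1)
        model.fit(x_train, y_train)
        return model.predict_proba(x_test)[:, 1]
    raise ValueError(f"unknown model kind {model_kind!r}")


def evaluate(scores: np.ndarray, labels: np.ndarray, model_kind: ModelKind) -> tuple[float, float]:
    """(AUC, accuracy).  AUC is the rank-based Mann-Whitney statistic
    (ties counted one half); accuracy thresholds the score at 0 for the
    SVM decision value and at 0.5 for the forest probability."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined for single-class labels")
    auc = float(roc_auc_score(labels, scores))
    cut = 0.0 if model_kind == "sv" else 0.5
    accuracy = float(np.mean((np.asarray(scores) > cut).astype(int) == labels))
    return auc, accuracy


def _subject_matrix(windows: pd.DataFrame, subject_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and labels in concatenated balanced order
    (pre half then post half, each in temporal order)."""
    sub = windows[windows["subject_id"] == subject_id]
    pre = sub[sub["state"] == "pre"].sort_values("window_index")
    post = sub[sub["state"] == "post"].sort_values("window_index")
    x = np.vstack([pre[FEATURE_NAMES].to_numpy(), post[FEATURE_NAMES].to_numpy()])
    y = np.concatenate([np.zeros(len(pre), dtype=int), np.ones(len(post), dtype=int)])
    return x, y


def _cv_auc(
    x: np.ndarray,
    y: np.ndarray,
    folds: Sequence[FoldSpec],
    model_kind: ModelKind,
    model_seed: int,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Mean AUC/accuracy over folds; folds whose (possibly permuted)
    train or test sets degenerate to one class are skipped."""
    aucs = np.full(len(folds), np.nan)
    accs = np.full(len(folds), np.nan)
    for k, fold in enumerate(folds):
        y_tr = y[fold.train_idx]
        y_te = y[fold.test_idx]
        if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
            continue
        scores = fit_predict(
            x[fold.train_idx], y_tr, x[fold.test_idx], model_kind, model_seed
        )
        aucs[k], accs[k] = evaluate(scores, y_te, model_kind)
    return float(np.nanmean(aucs)), float(np.nanmean(accs)), aucs, accs


def run_individual_model(
    subject_windows: pd.DataFrame,
    model_kind: ModelKind = "sv",
    model_seed: int = 0,
) -> ModelResult:
    """41-fold sliding-block CV within one subject; metrics are means
    over the folds."""
    subject_id = subject_windows["subject_id"].iloc[0]
    x, y = _subject_matrix(subject_windows, subject_id)
    n = int(y.sum())
    folds = make_individual_folds(n, len(y) - n)
    auc, acc, fold_aucs, fold_accs = _cv_auc(x, y, folds, model_kind, model_seed)
    return ModelResult(
        subject_id=subject_id,
        model_kind=model_kind,
        training_mode="individual",
        auc=auc,
        accuracy=acc,
        fold_aucs=fold_aucs,
        fold_accuracies=fold_accs,
    )


def run_group_model(
    cohort_windows: pd.DataFrame,
    test_subject: str,
    model_kind: ModelKind = "sv",
    model_seed: int = 0,
    training_subjects: Sequence[str] | None = None,
) -> ModelResult:
    """Leave-one-subject-out group model: train on every other subject's
    balanced windows (or an explicit subset), test on all windows of
    ``test_subject``.  No window of the test subject enters training."""
    subjects = list(cohort_windows["subject_id"].unique())
    if test_subject not in subjects:
        raise KeyError(test_subject)
    if training_subjects is None:
        training_subjects = [s for s in subjects if s != test_subject]
    if test_subject in training_subjects:
        raise ValueError("test subject must not appear in training")
    if len(training_subjects) < 1:
        raise ValueError("need at least one training subject")
    train = cohort_windows[cohort_windows["subject_id"].isin(training_subjects)]
    x_tr = train[FEATURE_NAMES].to_numpy()
    y_tr = (train["state"] == "post").to_numpy().astype(int)
    x_te, y_te = _subject_matrix(cohort_windows, test_subject)
    scores = fit_predict(x_tr, y_tr, x_te, model_kind, model_seed)
    auc, acc = evaluate(scores, y_te, model_kind)
    return ModelResult(
        subject_id=test_subject,
        model_kind=model_kind,
        training_mode="group",
        auc=auc,
        accuracy=acc,
        extras={"scores": scores, "labels": y_te},
    )


def permutation_significance(
    auc_fn: Callable[[np.ndarray], float],
    labels: np.ndarray,
    observed_auc: float,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Label-shuffling permutation test of one model's AUC.

    ``auc_fn`` re-runs the train/test procedure for a permuted label
    vector and returns its AUC.  Returns (p, threshold, null AUCs) with
    p = (1 + #{null >= observed}) / (n_perm + 1) and threshold the 95th
    percentile of the null distribution.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = auc_fn(rng.permutation(labels))
    p = (1.0 + float(np.sum(null >= observed_auc))) / (n_perm + 1.0)
    threshold = float(np.percentile(null, 95))
    return p, threshold, null


def individual_significance(
    subject_windows: pd.DataFrame,
    result: ModelResult,
    n_perm: int = 5000,
    seed: int = 0,
) -> ModelResult:
    """Permutation test for an individual model: each permutation
    shuffles the subject's window labels and re-runs the full 41-fold CV."""
    subject_id = result.subject_id
    x, y = _subject_matrix(subject_windows, subject_id)
    n = int(y.sum())
    folds = make_individual_folds(n, len(y) - n)

    def auc_fn(perm_labels: np.ndarray) -> float:
        return _cv_auc(x, perm_labels, folds, result.model_kind, 0)[0]

    p, threshold, null = permutation_significance(auc_fn, y, result.auc, n_perm, seed)
    result.p_value, result.threshold, result.null_aucs = p, threshold, null
    return result


def group_significance(result: ModelResult, n_perm: int = 5000, seed: int = 0) -> ModelResult:
    """Permutation test for a group model.  The training data of a
    leave-one-subject-out model does not involve the test subject's
    labels, so re-running the procedure under a permutation of those
    labels reuses the fitted scores and re-evaluates the AUC."""
    scores = result.extras["scores"]
    labels = result.extras["labels"]

    def auc_fn(perm_labels: np.ndarray) -> float:
        return float(roc_auc_score(perm_labels, scores))

    p, threshold, null = permutation_significance(auc_fn, labels, result.auc, n_perm, seed)
    result.p_value, result.threshold, result.null_aucs = p, threshold, null
    return result


def significance_across_subjects(
    results: Sequence[ModelResult], alpha: float = 0.05
) -> list[ModelResult]:
    """Benjamini-Hochberg FDR across the per-subject permutation
    p-values of one model family."""
    pvals = [r.p_value for r in results]
    reject, _ = fdr_bh(pvals, alpha=alpha)
    for r, rej in zip(results, reject):
        r.fdr_significant = bool(rej)
    return list(results)


def results_table(results: Sequence[ModelResult]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "model": r.model_kind,
            "mode": r.training_mode,
            "auc": r.auc,
            "accuracy": r.accuracy,
            "p_value": r.p_value,
            "threshold": r.threshold,
            "fdr_significant": r.fdr_significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
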