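"""Cross-validated evaluation of the perfusion decoder.

Generalisation is estimated by leave-one-*subject*-out cross-validation:
each fold holds out every scan of one subject and refits the classifier
(including hyperparameter optimisation) on the rest, so no subject ever
contributes to both sides of a fold.  Significance respects the
repeated-measures design: the null distribution is built by flipping the
condition labels of whole subjects (each subject's two classes swap
together, independently with probability 1/2) and re-running the entire
LOOCV, with a plus-one p-value estimator so the smallest attainable p
with 1,000 permutations is 1/1001 (~0.001).  Multiple tests from one
scan-reduction run are corrected with Holm's step-down procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import gpc
from .preprocess import (
    FeatureMatrix,
    aggregate_records,
    build_feature_matrix,
    preprocess_records,
)
from .synthetic import ScanRecord

log = logging.getLogger("aslgpc.evaluation")

__all__ = [
    "ClassifierConfig",
    "FoldPrediction",
    "EvalReport",
    "CurveEntry",
    "select_comparison",
    "comparison_feature_matrix",
    "classify_loocv",
    "confusion_stats",
    "roc_auc",
    "permutation_test",
    "holm_stepdown",
    "scan_reduction_curve",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """How each fold's GP classifier is trained.

    ``optimize`` turns type-II maximum likelihood on/off; ``start`` is the
    (fixed, deterministic) hyperparameter start; ``reoptimize_in_permutations``
    controls whether permutation replicates repeat the hyperparameter
    search (the default) or run EP at ``start`` for speed.
    """

    optimize: bool = True
    start: gpc.Hyperparams = field(default_factory=gpc.Hyperparams)
    reoptimize_in_permutations: bool = True


@dataclass
class FoldPrediction:
    """Held-out predictions of one LOOCV fold (one subject)."""

    subject_id: str
    probabilities: np.ndarray  # P(class +1) per held-out sample
    true_labels: np.ndarray


@dataclass
class EvalReport:
    """Confusion rates (and optionally AUC / permutation p) of one analysis."""

    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None

    def __post_init__(self) -> None:
        ba = 0.5 * (self.sensitivity + self.specificity)
        if not np.isclose(ba, self.balanced_accuracy):
            raise ValueError("balanced_accuracy must equal (sensitivity+specificity)/2")


# ---------------------------------------------------------------------------
# comparison construction
# ---------------------------------------------------------------------------

COMPARISONS = ("pre_vs_post", "left_vs_right", "followup_vs_post")


def select_comparison(
    records: Sequence[ScanRecord],
    comparison: str,
    side: str | None = None,
) -> tuple[list[ScanRecord], dict[str, int]]:
    """Filter records and build the condition -> {+1, -1} label map.

    ``pre_vs_post``: presurgery (-1) against postsurgery (+1), both sides.
    ``left_vs_right``: left (+1) against right (-1) postsurgical scans
    (labels carried via a side relabelling; chance-level by construction
    on synthetic data).  ``followup_vs_post``: pain-free follow-up (-1)
    against postsurgery (+1) of the requested ``side``.
    """
    if comparison == "pre_vs_post":
        keep = [r for r in records if r.condition in ("presurgery", "postsurgery")]
        return keep, {"postsurgery": 1, "presurgery": -1}
    if comparison == "followup_vs_post":
        if side not in ("left", "right"):
            raise ValueError("followup_vs_post requires side='left' or 'right'")
        keep = [
            r
            for r in records
            if r.condition == "followup"
            or (r.condition == "postsurgery" and r.side == side)
        ]
        return keep, {"postsurgery": 1, "followup": -1}
    if comparison == "left_vs_right":
        keep = [r for r in records if r.condition == "postsurgery"]
        # recode the side as the condition so the generic label map applies
        keep = [replace_condition(r, r.side) for r in keep]
        return keep, {"left": 1, "right": -1}
    raise ValueError(f"unknown comparison {comparison!r}; choose from {COMPARISONS}")


def replace_condition(rec: ScanRecord, condition: str) -> ScanRecord:
    return ScanRecord(
        subject_id=rec.subject_id,
        session_code=rec.session_code,
        condition=condition,
        side=rec.side,
        acquisition_index=rec.acquisition_index,
        volume=rec.volume,
        vas_pain=rec.vas_pain,
        vas_alertness=rec.vas_alertness,
    )


def comparison_feature_matrix(
    records: Sequence[ScanRecord],
    mask: np.ndarray,
    comparison: str = "pre_vs_post",
    side: str | None = None,
    aggregate: str = "condition",
) -> FeatureMatrix:
    """Build the feature matrix for one of the three analyses.

    ``aggregate`` is 'condition' (one averaged sample per subject and
    class — the default granularity of the all-scans analysis), 'session'
    (one averaged sample per subject-session) or 'scan' (every scan a
    sample).  Records are assumed already preprocessed.
    """
    keep, label_map = select_comparison(records, comparison, side=side)
    if aggregate == "condition":
        keep = aggregate_records(keep, by="condition")
    elif aggregate == "session":
        keep = aggregate_records(keep, by="session")
    elif aggregate != "scan":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return build_feature_matrix(keep, mask, label_map)


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def classify_loocv(
    fm: FeatureMatrix,
    config: ClassifierConfig = ClassifierConfig(),
    labels: np.ndarray | None = None,
) -> list[FoldPrediction]:
    """Leave-one-subject-out cross-validation.

    One fold per distinct subject; the held-out subject contributes no
    training samples to its own fold.  ``labels`` overrides ``fm.labels``
    (used by the permutation test).  Folds are returned sorted by
    subject id.
    """
    y = fm.labels if labels is None else np.asarray(labels)
    subjects = np.unique(fm.subject_ids.astype(str))
    if len(subjects) < 3:
        raise ValueError(f"need >= 3 subjects for LOOCV, got {len(subjects)}")
    folds = []
    for subj in subjects:
        test = fm.subject_ids.astype(str) == subj
        train = ~test
        y_train = y[train]
        present = np.unique(y_train)
        if not np.array_equal(np.sort(present), [-1, 1]):
            raise ValueError(
                f"training partition for held-out subject {subj!r} lacks a class "
                f"(labels present: {present})"
            )
        model = gpc.fit(
            fm.X[train],
            y_train,
            optimize_hyperparams=config.optimize,
            start=config.start,
        )
        probs = gpc.predict_probability(model, fm.X[test])
        log.debug(
            "fold %s: %d train / %d test samples, log evidence %.3f",
            subj, int(train.sum()), int(test.sum()), model.log_marginal,
        )
        folds.append(
            FoldPrediction(
                subject_id=str(subj),
                probabilities=probs,
                true_labels=y[test].copy(),
            )
        )
    return folds


def _fold_kernels(fm: FeatureMatrix, start: gpc.Hyperparams):
    """Per-fold kernel blocks for fixed hyperparameters.

    With hyperparameters frozen, each LOOCV fold's train kernel, cross
    kernel and test self-covariances do not depend on the labels, so the
    permutation loop only needs to rerun EP.  The blocks reproduce
    exactly what ``gpc.fit`` + ``gpc.predict_probability`` compute.
    """
    s, b = np.exp(start.log_signal), np.exp(start.log_bias)
    subjects = np.unique(fm.subject_ids.astype(str))
    folds = []
    for subj in subjects:
        test = fm.subject_ids.astype(str) == subj
        train = ~test
        Xtr = fm.X[train]
        mean = Xtr.mean(axis=0)
        Xc = Xtr - mean
        Xs = fm.X[test] - mean
        d = Xc.shape[1]
        K = s * (Xc @ Xc.T) / d + b
        Kstar = s * (Xc @ Xs.T) / d + b
        kss = s * np.einsum("ij,ij->i", Xs, Xs) / d + b
        folds.append((str(subj), train, test, K, Kstar, kss))
    return folds


def _predictions_from_kernels(folds, labels: np.ndarray) -> list[FoldPrediction]:
    """EP + prediction on precomputed kernel blocks (fixed hyperparameters)."""
    from scipy import linalg
    from scipy.special import ndtr

    out = []
    for subj, train, test, K, Kstar, kss in folds:
        y_train = labels[train].astype(float)
        present = np.unique(y_train)
        if not np.array_equal(np.sort(present), [-1.0, 1.0]):
            raise ValueError(
                f"training partition for held-out subject {subj!r} lacks a class "
                f"(labels present: {present})"
            )
        st = gpc.ep_inference(K, y_train)
        Kj = st.K
        srt = np.sqrt(st.site_precisions)
        n = Kj.shape[0]
        B = np.eye(n) + (srt[:, None] * Kj) * srt[None, :]
        L = linalg.cholesky(B, lower=True)
        w = linalg.cho_solve((L, True), srt * (Kj @ st.site_means))
        z = st.site_means - srt * w
        mu_star = Kstar.T @ z
        V = linalg.solve_triangular(L, srt[:, None] * Kstar, lower=True)
        var_star = np.maximum(kss - np.einsum("ij,ij->j", V, V), 1e-12)
        p = ndtr(mu_star / np.sqrt(1.0 + var_star))
        eps = np.finfo(np.float64).tiny
        out.append(
            FoldPrediction(
                subject_id=subj,
                probabilities=np.clip(p, eps, 1.0 - eps),
                true_labels=labels[test].copy(),
            )
        )
    return out


def _pooled(preds: Sequence[FoldPrediction]) -> tuple[np.ndarray, np.ndarray]:
    p = np.concatenate([f.probabilities for f in preds])
    y = np.concatenate([f.true_labels for f in preds])
    return p, y


def confusion_stats(
    preds: Sequence[FoldPrediction],
    threshold: float = 0.5,
) -> EvalReport:
    """Sensitivity, specificity and balanced accuracy across all folds.

    Sensitivity is the correct fraction among class +1 (postsurgery),
    specificity among class -1.  A probability exactly at the threshold
    counts as misclassified for whichever class the sample belongs to.
    """
    if not preds:
        raise ValueError("no fold predictions given")
    p, y = _pooled(preds)
    pos, neg = y == 1, y == -1
    if not (pos.any() and neg.any()):
        missing = "+1" if not pos.any() else "-1"
        raise ValueError(f"class {missing} absent from the test pool; rate undefined")
    sens = float(np.mean(p[pos] > threshold))
    spec = float(np.mean(p[neg] < threshold))
    return EvalReport(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=0.5 * (sens + spec),
    )


def balanced_accuracy(preds: Sequence[FoldPrediction], threshold: float = 0.5) -> float:
    return confusion_stats(preds, threshold).balanced_accuracy


def roc_auc(preds: Sequence[FoldPrediction]) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR over a threshold sweep) and rank-based AUC.

    The AUC is the Mann-Whitney statistic: the fraction of (+, -) pairs
    ranked concordantly, with ties counting one half.
    """
    p, y = _pooled(preds)
    pos, neg = y == 1, y == -1
    if not (pos.any() and neg.any()):
        raise ValueError("ROC requires both classes in the test pool")
    thresholds = np.concatenate(([np.inf], np.unique(p)[::-1]))
    tpr = np.array([np.mean(p[pos] >= t) for t in thresholds])
    fpr = np.array([np.mean(p[neg] >= t) for t in thresholds])
    # rank formulation with midranks for ties
    from scipy.stats import rankdata

    ranks = rankdata(p)
    n_pos, n_neg = pos.sum(), neg.sum()
    auc = float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def permutation_test(
    fm: FeatureMatrix,
    config: ClassifierConfig = ClassifierConfig(),
    n_perm: int = 1000,
    seed: int = 0,
    observed: float | None = None,
) -> tuple[float, np.ndarray, float]:
    """Subject-level permutation test of the LOOCV balanced accuracy.

    Each permutation independently flips all labels of each subject with
    probability 1/2 (a whole subject's two classes swap together), reruns
    the full LOOCV, and records the balanced accuracy.  Returns
    ``(p_value, null_distribution, observed)`` with the plus-one
    estimator ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed is None:
        observed = balanced_accuracy(classify_loocv(fm, config))
    null_config = config if config.reoptimize_in_permutations else replace(
        config, optimize=False
    )
    rng = np.random.default_rng(seed)
    subjects = np.unique(fm.subject_ids.astype(str))
    subj_idx = {s: np.flatnonzero(fm.subject_ids.astype(str) == s) for s in subjects}
    # frozen hyperparameters: fold kernels are label-independent, so build
    # them once and rerun only EP inside the permutation loop
    kernels = None if null_config.optimize else _fold_kernels(fm, null_config.start)
    log.info("permutation test: %d permutations, seed=%d", n_perm, seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        if b and b % 200 == 0:
            log.info("permutation %d/%d", b, n_perm)
        flips = rng.integers(0, 2, size=len(subjects))
        labels = fm.labels.copy()
        for s, f in zip(subjects, flips):
            if f:
                labels[subj_idx[s]] *= -1
        if kernels is not None:
            preds = _predictions_from_kernels(kernels, labels)
        else:
            preds = classify_loocv(fm, null_config, labels=labels)
        null[b] = balanced_accuracy(preds)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return float(p), null, float(observed)


def holm_stepdown(p_values: Sequence[float]) -> np.ndarray:
    """Holm's step-down adjustment, returned in the input order.

    With the sorted p-values p_(1) <= ... <= p_(m):
    adjusted_(k) = max_{j <= k} min(1, (m - j + 1) p_(j)).
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# scan-number reduction
# ---------------------------------------------------------------------------

@dataclass
class CurveEntry:
    """Results of one (n_scans, side) cell of the reduction experiment."""

    n_scans: int
    side: str | None
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float
    p_value: float
    p_value_holm: float | None = None


def scan_reduction_curve(
    records: Sequence[ScanRecord],
    mask: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    max_scans: int = 6,
    comparison: str = "followup_vs_post",
    sides: Sequence[str | None] = ("left", "right"),
    n_perm: int = 1000,
    seed: int = 0,
    fwhm_mm: float = 8.0,
    target_median: float = 1000.0,
    preprocessed: bool = False,
) -> list[CurveEntry]:
    """Progressively drop scans from the end of each session and re-analyse.

    For n = 1..max_scans only acquisition indices 1..n are kept (removal
    in reverse acquisition order); the kept scans are averaged into one
    image per subject and session, used for both training and testing,
    and the full LOOCV plus permutation test is run.  Holm's step-down is
    applied across *all* tests produced by the call (every n and every
    requested side form one family).
    """
    per_session: dict[tuple[str, str], int] = {}
    for r in records:
        key = (r.subject_id, r.session_code)
        per_session[key] = max(per_session.get(key, 0), r.acquisition_index)
    short = {k: v for k, v in per_session.items() if v < max_scans}
    if short:
        k, v = next(iter(short.items()))
        raise ValueError(
            f"session {k} has only {v} scans but max_scans={max_scans} requested"
        )
    if not preprocessed:
        records = preprocess_records(
            records, mask, fwhm_mm=fwhm_mm, target_median=target_median
        )
    entries: list[CurveEntry] = []
    for n in range(1, max_scans + 1):
        kept = [r for r in records if r.acquisition_index <= n]
        for side in sides if comparison == "followup_vs_post" else [None]:
            fm = comparison_feature_matrix(
                kept, mask, comparison=comparison, side=side, aggregate="session"
            )
            folds = classify_loocv(fm, config)
            report = confusion_stats(folds)
            _, _, auc = roc_auc(folds)
            p, _, _ = permutation_test(
                fm,
                config,
                n_perm=n_perm,
                seed=seed + n,
                observed=report.balanced_accuracy,
            )
            entries.append(
                CurveEntry(
                    n_scans=n,
                    side=side,
                    sensitivity=report.sensitivity,
                    specificity=report.specificity,
                    balanced_accuracy=report.balanced_accuracy,
                    auc=auc,
                    p_value=p,
                )
            )
    adjusted = holm_stepdown([e.p_value for e in entries])
    for e, pa in zip(entries, adjusted):
        e.p_value_holm = float(pa)
    return entries
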