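"""Diagnostic-test evaluation of a trajectory classification.

The classification becomes a binary test through the rule "subjects in
the group with the highest trajectory level are predicted diseased".
Because group labels are kept sorted by ascending trajectory level, the
positive class is always the last group index.

Accuracy metrics (sensitivity, specificity, PPV, NPV, percentage of
well-classified subjects) are reported against the gold-standard labels,
and a stratified k-fold cross-validation (default k = 4) estimates their
out-of-sample values: each fold's model is trained on the remaining
folds, held-out subjects are scored with the trained posteriors (pi and
all group parameters frozen; no refitting on test data), and the median
over folds is reported.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cem_engine import FitConfig, FitResult, c_step, cem_fit, e_step
from .kinetic_models import ModelSpec
from .likelihood import Assignment, GroupStructure
from .trajectory_data import Cohort

__all__ = [
    "AccuracySummary",
    "classify_disease",
    "predict_groups",
    "accuracy",
    "stratified_fold_indices",
    "stratified_kfold_cv",
    "CrossValidationResult",
]

_METRICS = ("sensitivity", "specificity", "ppv", "npv", "classification_rate")


def _pct(num: int, den: int) -> Optional[float]:
    """Percentage, or None when the denominator is empty (undefined, not 0)."""
    return None if den == 0 else 100.0 * num / den


@dataclass(frozen=True)
class AccuracySummary:
    """Confusion counts and the derived diagnostic accuracy features."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> Optional[float]:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return _pct(self.tn, self.tn + self.fn)

    @property
    def classification_rate(self) -> Optional[float]:
        return _pct(self.tp + self.tn, self.n)

    def to_dict(self) -> dict:
        d = {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}
        for m in _METRICS:
            d[m] = getattr(self, m)
        return d


def classify_disease(fit_or_assignment, n_groups: Optional[int] = None) -> np.ndarray:
    """Binary disease predictions from a fit: top-level group is positive.

    Accepts a :class:`FitResult` (group count taken from its spec) or an
    :class:`Assignment`/array plus ``n_groups``.
    """
    if isinstance(fit_or_assignment, FitResult):
        z = fit_or_assignment.assignment.z
        G = fit_or_assignment.structure.n_groups
    else:
        z = (
            fit_or_assignment.z
            if isinstance(fit_or_assignment, Assignment)
            else np.asarray(fit_or_assignment, dtype=int)
        )
        if n_groups is None:
            raise ValueError("n_groups required when passing a raw assignment")
        G = n_groups
    return (z == G - 1).astype(int)


def predict_groups(cohort: Cohort, structure: GroupStructure) -> Assignment:
    """Assign new subjects with a trained model (posteriors + argmax)."""
    return c_step(e_step(cohort.flat(), structure))


def accuracy(predictions, labels) -> AccuracySummary:
    """Confusion counts of binary predictions against gold-standard labels."""
    pred = np.asarray(predictions, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must have the same length")
    tp = int(np.sum((pred == 1) & (lab == 1)))
    fp = int(np.sum((pred == 1) & (lab == 0)))
    fn = int(np.sum((pred == 0) & (lab == 1)))
    tn = int(np.sum((pred == 0) & (lab == 0)))
    return AccuracySummary(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class CrossValidationResult:
    per_fold: list  # AccuracySummary per fold
    median: dict  # metric -> median over folds (None-safe)
    fold_of_subject: np.ndarray  # recorded test-fold index per subject
    k: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "per_fold": [f.to_dict() for f in self.per_fold],
            "median": self.median,
            "fold_of_subject": self.fold_of_subject.tolist(),
        }


def stratified_fold_indices(labels, k: int, seed: Optional[int] = None) -> list:
    """(train_idx, test_idx) pairs preserving disease prevalence.

    Per-stratum test counts differ by at most 1 across folds; every
    subject lands in exactly one test fold.
    """
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def _median_over_folds(per_fold, metric):
    vals = [getattr(f, metric) for f in per_fold]
    if any(v is None for v in vals):
        return None
    # even k: mean of the two middle values (numpy's convention)
    return float(np.median(vals))


def stratified_kfold_cv(
    cohort: Cohort,
    spec: ModelSpec,
    config: FitConfig,
    k: int = 4,
    seed: Optional[int] = None,
) -> CrossValidationResult:
    """Stratified k-fold cross-validated diagnostic accuracy.

    Folds preserve disease prevalence (per-stratum counts differ by at
    most 1 across folds).  Every subject appears in exactly one test
    fold; per-fold training seeds derive deterministically from the fold
    index so the result is reproducible and independent of execution
    order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = cohort.disease_labels()
    if seed is None:
        seed = config.seed
    fold_of_subject = np.full(cohort.n_subjects, -1, dtype=int)
    per_fold = []
    for fold, (train_idx, test_idx) in enumerate(
        stratified_fold_indices(labels, k, seed)
    ):
        if labels[test_idx].sum() == 0 or labels[train_idx].sum() == 0:
            raise ValueError(f"fold {fold} has no diseased subjects")
        fold_of_subject[test_idx] = fold
        train = cohort.subset(train_idx)
        fold_config = replace(config, seed=(config.seed or 0) * 1000 + fold)
        fit = cem_fit(train, spec, fold_config)
        test = cohort.subset(test_idx)
        z_test = predict_groups(test, fit.structure)
        pred = classify_disease(z_test, n_groups=spec.n_groups)
        per_fold.append(accuracy(pred, labels[test_idx]))
    median = {m: _median_over_folds(per_fold, m) for m in _METRICS}
    return CrossValidationResult(
        per_fold=per_fold,
        median=median,
        fold_of_subject=fold_of_subject,
        k=k,
        seed=seed,
    )
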