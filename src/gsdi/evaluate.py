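"""ROC analysis for the high-specificity regime and cross-validation.

Conventions: a higher score means more diseased, and an eye is called
abnormal when its score is at or above the threshold.  Partial AUC is
reported on the band's natural (unnormalized) scale, so a perfect
classifier over specificity 90-100% scores 0.100; McClish standardization
is available as an extra output.  The cross-validation unit is the
subject (both eyes held out together) because bilateral eyes are
correlated; eye-level folds are available for comparison.  The normative
reference is treated as fixed during CV, mirroring a design where a
separate reference subset defines the normative maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .index import (GSDIResults, apply_stage1, fit_gsdi, fit_stage1,
                    published_gsdi)

SPEC_BAND = (0.90, 1.00)


# --------------------------------------------------------------------------
# ROC primitives
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    """An empirical ROC curve: operating points ordered from the most
    specific (threshold above every score) to the least."""

    specificity: np.ndarray
    sensitivity: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.specificity, self.sensitivity])

    def partial_auc(self, spec_lo: float = SPEC_BAND[0],
                    spec_hi: float = SPEC_BAND[1],
                    mcclish: bool = False) -> float:
        return partial_auc(self, spec_lo, spec_hi, mcclish=mcclish)

    def sensitivity_at(self, target: float) -> tuple[float, float]:
        return sensitivity_at_specificity(self, target)

    def plot(self, ax=None, label: str | None = None):
        """Sensitivity vs 1-specificity; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(1.0 - self.specificity, self.sensitivity,
                label=label or f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC over all unique score thresholds.

    AUC is the trapezoidal area, equal to the tie-corrected rank
    (Mann-Whitney) statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_cases = int((labels == 1).sum())
    n_controls = int((labels == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(specificity=1.0 - fpr, sensitivity=tpr, thresholds=thr,
                     auc=auc, n_cases=n_cases, n_controls=n_controls)


def partial_auc(roc: ROCResult, spec_lo: float, spec_hi: float,
                mcclish: bool = False) -> float:
    """Trapezoidal area of sensitivity over a specificity band.

    Sensitivity is linearly interpolated at the band edges; the maximum
    attainable value is the band width.  ``mcclish=True`` rescales to
    [0.5, 1] (McClish standardization).
    """
    if not (0.0 <= spec_lo < spec_hi <= 1.0):
        raise ValueError("band must satisfy 0 <= lo < hi <= 1")
    fpr = 1.0 - roc.specificity  # increasing
    tpr = roc.sensitivity
    f_lo, f_hi = 1.0 - spec_hi, 1.0 - spec_lo
    grid = np.union1d(fpr, [f_lo, f_hi])
    grid = grid[(grid >= f_lo) & (grid <= f_hi)]
    sens = np.interp(grid, fpr, tpr)
    area = float(np.trapezoid(sens, grid))
    if mcclish:
        width = spec_hi - spec_lo
        min_area = 0.5 * (f_lo + f_hi) * width  # chance diagonal
        area = 0.5 * (1.0 + (area - min_area) / (width - min_area))
    return area


def sensitivity_at_specificity(roc: ROCResult,
                               target: float) -> tuple[float, float]:
    """Smallest threshold whose empirical specificity meets the target.

    Returns (threshold, sensitivity); an unreachable target falls back to
    the most specific operating point (specificity 1, maximal threshold).
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target specificity must lie in (0, 1)")
    ok = roc.specificity >= target
    # points are ordered by decreasing threshold; the last qualifying point
    # has the smallest threshold
    idx = int(np.flatnonzero(ok)[-1])
    return float(roc.thresholds[idx]), float(roc.sensitivity[idx])


# --------------------------------------------------------------------------
# paired AUC comparison
# --------------------------------------------------------------------------

def compare_auc(scores_a, scores_b, labels, subjects=None,
                method: str = "bootstrap", n_resamples: int = 2000,
                seed: int | None = 0) -> tuple[float, float]:
    """Paired difference of AUCs (a minus b) with a p-value.

    ``method='bootstrap'`` resamples subjects stratified by class
    (bilateral eyes move together) and reports a two-sided percentile
    p-value for the null of no difference.  ``method='permutation'``
    randomly swaps the two score assignments within subject (exhaustively
    when there are at most 14 subjects).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("score and label vectors must have matching length")
    if subjects is None:
        subjects = np.arange(labels.size)
    subjects = np.asarray(subjects)

    delta = roc_curve(scores_a, labels).auc - roc_curve(scores_b, labels).auc
    rng = np.random.default_rng(seed)
    uniq, subj_idx = np.unique(subjects, return_inverse=True)
    subj_label = np.array([labels[subj_idx == i].max() for i in range(uniq.size)])

    if method == "bootstrap":
        deltas = np.empty(n_resamples)
        groups = [np.flatnonzero(subj_label == g) for g in (0, 1)]
        members = [np.flatnonzero(subj_idx == i) for i in range(uniq.size)]
        for r in range(n_resamples):
            take = np.concatenate([rng.choice(g, size=g.size, replace=True)
                                   for g in groups])
            rows = np.concatenate([members[i] for i in take])
            try:
                deltas[r] = (roc_curve(scores_a[rows], labels[rows]).auc
                             - roc_curve(scores_b[rows], labels[rows]).auc)
            except ValueError:  # a resample lost one class entirely
                deltas[r] = np.nan
        deltas = deltas[np.isfinite(deltas)]
        shifted = deltas - deltas.mean()  # centre at the null
        p = 2.0 * min((np.sum(shifted <= -abs(delta)) + 1) / (shifted.size + 1),
                      (np.sum(shifted >= abs(delta)) + 1) / (shifted.size + 1))
        return float(delta), float(min(p, 1.0))

    if method == "permutation":
        members = [np.flatnonzero(subj_idx == i) for i in range(uniq.size)]

        def delta_for(swap_mask: np.ndarray) -> float:
            a, b = scores_a.copy(), scores_b.copy()
            for i in np.flatnonzero(swap_mask):
                rows = members[i]
                a[rows], b[rows] = scores_b[rows], scores_a[rows]
            return roc_curve(a, labels).auc - roc_curve(b, labels).auc

        if uniq.size <= 14:  # exhaustive
            masks = ((np.arange(2 ** uniq.size)[:, None]
                      >> np.arange(uniq.size)) & 1).astype(bool)
        else:
            masks = rng.random((n_resamples, uniq.size)) < 0.5
        null = np.array([delta_for(m) for m in masks])
        p = (np.sum(np.abs(null) >= abs(delta) - 1e-12) + 1) / (null.size + 1)
        return float(delta), float(min(p, 1.0))

    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# leave-one-subject-out cross-validation of the two-stage pipeline
# --------------------------------------------------------------------------

@dataclass
class CVReport:
    scores: pd.Series                   # out-of-fold index per eye
    fold_models: dict                   # held-out unit -> GSDIResults
    fold_weights: dict                  # held-out unit -> stage-1 weights
    skipped: list = field(default_factory=list)


def _fit_fold(train: pd.DataFrame):
    weights = fit_stage1(train)
    composites = apply_stage1(train, weights)
    model = fit_gsdi(composites)
    return weights, model


def loo_cv_scores(table: pd.DataFrame, unit: str = "subject",
                  model: str = "fitted",
                  score_table: pd.DataFrame | None = None) -> CVReport:
    """Out-of-fold GSDI scores with the whole two-stage fit inside each fold.

    ``table`` is a feature table (``build_feature_table`` output restricted
    to the N and PG groups).  For every held-out unit -- a subject by
    default, so both eyes leave together -- stage-1 weights and the
    stage-2 model are refit on the remaining eyes and the held-out eyes
    are scored.  With ``model='published'`` stage 2 is the fixed published
    scorer and only stage-1 weights are refit per fold.

    ``score_table`` optionally supplies a second copy of the same eyes
    used *only* for held-out scoring; it supports leakage audits (poison a
    subject there and verify no other subject's score moves).
    """
    if unit not in ("subject", "eye"):
        raise ValueError("unit must be 'subject' or 'eye'")
    table = table.reset_index(drop=True)
    score_table = (table if score_table is None
                   else score_table.reset_index(drop=True))
    if len(score_table) != len(table):
        raise ValueError("score_table must mirror the feature table rows")

    keys = (table["subject_id"] if unit == "subject"
            else table["subject_id"].str.cat(table["eye"], sep="/"))
    for lab in (0, 1):
        if keys[table["label"] == lab].nunique() < 2:
            raise ValueError("need at least 2 units per class")

    scores = pd.Series(np.nan, index=table.index, name="gsdi")
    fold_models: dict = {}
    fold_weights: dict = {}
    skipped: list = []
    for unit_key in keys.unique():
        held = keys == unit_key
        train = table[~held]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                weights = fit_stage1(train)
                if model == "published":
                    gsdi = published_gsdi()
                else:
                    gsdi = fit_gsdi(apply_stage1(train, weights))
        except Exception as exc:  # refit failure: record and skip the fold
            warnings.warn(f"fold {unit_key!r} skipped: {exc}", stacklevel=2)
            skipped.append(unit_key)
            continue
        held_rows = apply_stage1(score_table[held], weights)
        scores[held.to_numpy().nonzero()[0]] = gsdi.predict(held_rows)
        fold_models[unit_key] = gsdi
        fold_weights[unit_key] = weights
    return CVReport(scores=scores, fold_models=fold_models,
                    fold_weights=fold_weights, skipped=skipped)


# --------------------------------------------------------------------------
# severity-stratified reporting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StagePerformance:
    stage: str
    n_cases: int
    auc: float
    sens_at_99: float
    sens_at_95: float


def stage_stratified_performance(scores, labels, stages,
                                 targets: tuple[float, ...] = (0.99, 0.95),
                                 stage_order=None) -> list[StagePerformance]:
    """Per-stage AUC (stage's cases vs all controls) and sensitivities at
    cutoffs fixed from the full control set.

    ``stages`` gives the severity label of every case (entries for
    controls are ignored).  A stage with no cases yields a row with n=0
    and NaN metrics.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    stages = np.asarray(stages, dtype=object)
    case_stages = stages[labels == 1]
    if any(s is None or (isinstance(s, float) and np.isnan(s))
           for s in case_stages):
        raise ValueError("every case must carry a stage")

    full = roc_curve(scores, labels)
    cutoffs = {t: full.sensitivity_at(t)[0] for t in targets}
    controls = scores[labels == 0]
    if stage_order is None:
        stage_order = list(pd.unique(case_stages))

    out = []
    for st in stage_order:
        case_scores = scores[(labels == 1) & (stages == st)]
        if case_scores.size == 0:
            out.append(StagePerformance(stage=str(st), n_cases=0,
                                        auc=float("nan"),
                                        sens_at_99=float("nan"),
                                        sens_at_95=float("nan")))
            continue
        sub_scores = np.concatenate([controls, case_scores])
        sub_labels = np.concatenate([np.zeros(controls.size, dtype=int),
                                     np.ones(case_scores.size, dtype=int)])
        auc = roc_curve(sub_scores, sub_labels).auc
        sens = {t: float((case_scores >= cutoffs[t]).mean()) for t in targets}
        out.append(StagePerformance(
            stage=str(st), n_cases=int(case_scores.size), auc=float(auc),
            sens_at_99=sens.get(0.99, float("nan")),
            sens_at_95=sens.get(0.95, float("nan"))))
    return out


def stage_table(perf: list[StagePerformance]) -> pd.DataFrame:
    return pd.DataFrame([{
        "stage": p.stage, "n_cases": p.n_cases, "auc": p.auc,
        "sens_at_99_spec": p.sens_at_99, "sens_at_95_spec": p.sens_at_95,
    } for p in perf])
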