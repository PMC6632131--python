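"""Diagnostic-test evaluation: ROC curves, AUC with DeLong confidence
intervals, sensitivity/specificity/accuracy with binomial CIs, and
subgroup summaries by tumor stage or control cohort.

AUC is computed as the Mann-Whitney U statistic scaled to [0, 1] (ties
count one half), which equals trapezoidal integration of the ROC curve.
Proportion CIs default to the Wilson score interval with Clopper-Pearson
as an option; AUC CIs use DeLong's asymptotic variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .types import SampleMeta, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricWithCI:
    value: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.value <= self.ci_high + 1e-12):
            raise ValidationError("confidence interval does not contain the estimate")


def _split_scores(scores, y):
    scores = np.asarray(scores, dtype=float)
    y01 = (np.asarray(y) != 0).astype(int)
    if scores.shape != y01.shape:
        raise ValidationError("scores and labels differ in length")
    if y01.sum() == 0 or y01.sum() == len(y01):
        raise ValidationError("both classes must be present")
    return scores[y01 == 1], scores[y01 == 0]


def roc_points(scores, y) -> list[tuple[float, float]]:
    """ROC curve as (FPR, TPR) points.

    The threshold sweeps the unique score values in descending order; a
    sample is called positive when its score is at or above the
    threshold. All samples tied at one score enter in a single step, so
    ties move the curve diagonally. Endpoints (0,0) and (1,1) included.
    """
    cases, controls = _split_scores(scores, y)
    m, n = len(cases), len(controls)
    points = [(0.0, 0.0)]
    tp = fp = 0
    for v in np.unique(np.concatenate([cases, controls]))[::-1]:
        tp += int(np.sum(cases == v))
        fp += int(np.sum(controls == v))
        points.append((fp / n, tp / m))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    variance: float


def auc(scores, y, alpha: float = 0.05) -> AucResult:
    """Area under the ROC curve with a DeLong 95% CI.

    AUC is the probability a random case outscores a random control,
    with ties counted 1/2 (Mann-Whitney). The DeLong variance comes from
    the empirical placement values of cases among controls and vice
    versa; for degenerate data (perfect separation) the variance is 0
    and the CI collapses onto the point estimate.
    """
    cases, controls = _split_scores(scores, y)
    m, n = len(cases), len(controls)
    allscores = np.concatenate([cases, controls])
    r_all = stats.rankdata(allscores)
    r_cases = stats.rankdata(cases)
    r_controls = stats.rankdata(controls)
    theta = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_cases) / n            # placements of cases
    v01 = 1.0 - (r_all[m:] - r_controls) / m   # placements of controls
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return AucResult(
        auc=float(theta),
        ci_low=float(max(0.0, theta - half)),
        ci_high=float(min(1.0, theta + half)),
        variance=float(var),
    )


@dataclass(frozen=True)
class BinaryMetrics:
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    accuracy: MetricWithCI


def _proportion(k: int, n: int, alpha: float, method: str) -> MetricWithCI:
    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}[method]
    lo, hi = proportion_confint(k, n, alpha=alpha, method=sm_method)
    return MetricWithCI(value=k / n, ci_low=float(lo), ci_high=float(hi), n=n)


def binary_metrics(
    calls, y, alpha: float = 0.05, ci_method: str = "wilson"
) -> BinaryMetrics:
    """Sensitivity, specificity and accuracy with binomial CIs.

    ``calls`` are predicted labels (1/True = positive) and ``y`` the true
    labels. ``ci_method`` is ``"wilson"`` (default) or
    ``"clopper_pearson"``.
    """
    if ci_method not in ("wilson", "clopper_pearson"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    calls01 = (np.asarray(calls) != 0).astype(int)
    y01 = (np.asarray(y) != 0).astype(int)
    if calls01.shape != y01.shape:
        raise ValidationError("calls and labels differ in length")
    if y01.sum() == 0 or y01.sum() == len(y01):
        raise ValidationError("both classes must be present")
    tp = int(np.sum((calls01 == 1) & (y01 == 1)))
    tn = int(np.sum((calls01 == 0) & (y01 == 0)))
    n_case = int(y01.sum())
    n_ctrl = len(y01) - n_case
    return BinaryMetrics(
        sensitivity=_proportion(tp, n_case, alpha, ci_method),
        specificity=_proportion(tn, n_ctrl, alpha, ci_method),
        accuracy=_proportion(tp + tn, len(y01), alpha, ci_method),
    )


def subgroup_report(
    scores,
    y,
    meta: Sequence[SampleMeta],
    strata: str,
    threshold: float = 0.0,
    alpha: float = 0.05,
    ci_method: str = "wilson",
) -> dict[str, MetricWithCI]:
    """Per-stratum sensitivity (by stage) or specificity (by control
    cohort) at the model's fixed decision threshold.

    ``strata="stage"`` computes sensitivity within each tumor-stage
    stratum of the cases; ``strata="control_source"`` computes
    specificity within each control cohort. Strata with no samples are
    omitted (with a logged notice for labels that never appear).
    """
    scores = np.asarray(scores, dtype=float)
    y01 = (np.asarray(y) != 0).astype(int)
    calls = (scores > threshold).astype(int)
    if strata == "stage":
        relevant = [i for i, s in enumerate(meta) if y01[i] == 1]
        labels = {i: meta[i].stage for i in relevant}
        correct = calls  # sensitivity: called positive
    elif strata == "control_source":
        relevant = [i for i, s in enumerate(meta) if y01[i] == 0]
        labels = {i: meta[i].control_source for i in relevant}
        correct = 1 - calls  # specificity: called negative
    else:
        raise ValidationError(f"unknown strata {strata!r}")
    out: dict[str, MetricWithCI] = {}
    groups: dict[str, list[int]] = {}
    for i in relevant:
        lab = labels[i]
        if lab is None:
            logger.info("sample %s lacks a %s label; skipped", meta[i].sample_id, strata)
            continue
        groups.setdefault(lab, []).append(i)
    for lab in sorted(groups):
        idx = groups[lab]
        out[lab] = _proportion(int(correct[idx].sum()), len(idx), alpha, ci_method)
    return out


@dataclass(frozen=True)
class EvaluationReport:
    """Overall and per-stratum diagnostic performance of a score vector."""

    n_case: int
    n_control: int
    metrics: BinaryMetrics
    auc: AucResult
    by_stage: dict[str, MetricWithCI]
    by_control_source: dict[str, MetricWithCI]


def evaluate_scores(
    scores,
    y,
    meta: Sequence[SampleMeta] | None = None,
    threshold: float = 0.0,
    alpha: float = 0.05,
    ci_method: str = "wilson",
) -> EvaluationReport:
    """Full evaluation of continuous scores against case/control truth."""
    scores = np.asarray(scores, dtype=float)
    y01 = (np.asarray(y) != 0).astype(int)
    calls = (scores > threshold).astype(int)
    return EvaluationReport(
        n_case=int(y01.sum()),
        n_control=int(len(y01) - y01.sum()),
        metrics=binary_metrics(calls, y01, alpha=alpha, ci_method=ci_method),
        auc=auc(scores, y01, alpha=alpha),
        by_stage=(subgroup_report(scores, y01, meta, "stage", threshold, alpha, ci_method)
                  if meta is not None else {}),
        by_control_source=(subgroup_report(scores, y01, meta, "control_source",
                                           threshold, alpha, ci_method)
                           if meta is not None else {}),
    )
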