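"""Greedy beam search over miRNA subsets scored by leave-one-out
cross-validated discriminant accuracy.

The search reproduces the wrapper feature-selection procedure used to
build serum miRNA diagnostic indices: every single miRNA is scored by
LOOCV accuracy and the best ``beam_width`` (default 20) are kept; each
kept combination is then extended by every remaining miRNA, the
extensions are pooled, deduplicated as feature *sets*, re-ranked, and
the top ``beam_width`` kept again; this repeats up to ``max_features``
(default 8) miRNAs. Ties in LOOCV accuracy are broken by higher
training AUC, then by the lexicographically smallest sorted feature-ID
tuple, making the whole search deterministic. The final model is the
smallest subset size whose best accuracy is within ``epsilon`` of the
best accuracy at any size — "high accuracy with few miRNAs".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .discriminant import (
    LDAFitConfig,
    fit_fisher_lda,
    fit_scores_batch,
    loocv_scores_batch,
)
from .evaluation import auc as auc_with_ci
from .evaluation import binary_metrics
from .types import DiscriminantModel, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    beam_width: int = 20
    max_features: int = 8
    tie_break: str = "auc_then_lexicographic"
    rng_seed: int | None = None  # reserved for subsampling extensions
    lda: LDAFitConfig = field(default_factory=LDAFitConfig)

    def __post_init__(self) -> None:
        if self.beam_width < 1:
            raise ValidationError("beam_width must be >= 1")
        if self.max_features < 1:
            raise ValidationError("max_features must be >= 1")
        if self.tie_break != "auc_then_lexicographic":
            raise ValidationError(f"unknown tie_break {self.tie_break!r}")


@dataclass(frozen=True, eq=False)
class BeamCandidate:
    """One feature combination with its cross-validated performance."""

    features: tuple[str, ...]        # in order of addition
    loocv_accuracy: float
    training_auc: float
    model: DiscriminantModel
    loocv_scores: np.ndarray         # per-sample left-out scores
    loocv_predictions: np.ndarray    # per-sample 0/1 calls

    @property
    def feature_set(self) -> frozenset[str]:
        return frozenset(self.features)


@dataclass
class SearchResult:
    per_size_top: dict[int, list[BeamCandidate]]
    per_size_best: dict[int, BeamCandidate]
    selected: BeamCandidate
    labels: np.ndarray               # the 0/1 labels the search used

    def __post_init__(self) -> None:
        for s, top in self.per_size_top.items():
            if top and self.per_size_best[s] is not top[0]:
                raise ValidationError(f"per_size_best[{s}] is not rank 1 of per_size_top")


def _rank_auc_rows(scores: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC for each row of a (C, N) score matrix."""
    m = int(y01.sum())
    n = len(y01) - m
    ranks = stats.rankdata(scores, axis=1)
    case_rank_sum = ranks[:, y01 == 1].sum(axis=1)
    return (case_rank_sum - m * (m + 1) / 2) / (m * n)


def beam_search(
    X: np.ndarray,
    y: np.ndarray,
    candidate_mirnas: Sequence[str],
    cfg: SearchConfig | None = None,
    epsilon: float = 0.005,
) -> SearchResult:
    """Run the beam search and pick the final parsimonious model.

    ``X`` is the samples x candidates log2 feature matrix with columns
    aligned to ``candidate_mirnas``. Deterministic given inputs and
    config; stops early (with a logged notice) if the candidate pool is
    exhausted before ``max_features``.
    """
    cfg = cfg or SearchConfig()
    X = np.asarray(X, dtype=float)
    names = list(candidate_mirnas)
    if X.ndim != 2 or X.shape[1] != len(names):
        raise ValidationError("X columns must align with candidate_mirnas")
    if len(set(names)) != len(names):
        raise ValidationError("duplicate candidate miRNA IDs")
    if len(names) < 1:
        raise ValidationError("need at least one candidate miRNA")
    y01 = (np.asarray(y) != 0).astype(int)
    col = {m: j for j, m in enumerate(names)}

    per_size_top: dict[int, list[BeamCandidate]] = {}
    per_size_best: dict[int, BeamCandidate] = {}
    beam: list[tuple[str, ...]] = [()]
    max_size = min(cfg.max_features, len(names))
    if max_size < cfg.max_features:
        logger.info(
            "only %d candidate miRNAs; stopping search at size %d instead of %d",
            len(names), max_size, cfg.max_features,
        )
    for size in range(1, max_size + 1):
        # extensions of every beam member by every remaining miRNA,
        # deduplicated as unordered feature sets (best parent kept first)
        seen: set[frozenset[str]] = set()
        feature_tuples: list[tuple[str, ...]] = []
        for parent in beam:
            parent_set = set(parent)
            for m in names:
                if m in parent_set:
                    continue
                key = frozenset(parent_set | {m})
                if key in seen:
                    continue
                seen.add(key)
                feature_tuples.append(parent + (m,))
        subsets = np.array(
            [[col[m] for m in feats] for feats in feature_tuples], dtype=int
        )
        loocv_scores = loocv_scores_batch(X, y01, subsets, cfg.lda)
        preds = (loocv_scores > 0).astype(int)
        accs = (preds == y01[None, :]).mean(axis=1)
        train_scores = fit_scores_batch(X, y01, subsets, cfg.lda)
        train_aucs = _rank_auc_rows(train_scores, y01)
        order = sorted(
            range(len(feature_tuples)),
            key=lambda i: (-accs[i], -train_aucs[i], tuple(sorted(feature_tuples[i]))),
        )
        kept = order[: cfg.beam_width]
        top = [
            BeamCandidate(
                features=feature_tuples[i],
                loocv_accuracy=float(accs[i]),
                training_auc=float(train_aucs[i]),
                model=fit_fisher_lda(
                    X[:, subsets[i]], y01, cfg.lda,
                    feature_names=feature_tuples[i],
                ),
                loocv_scores=loocv_scores[i],
                loocv_predictions=preds[i],
            )
            for i in kept
        ]
        per_size_top[size] = top
        per_size_best[size] = top[0]
        beam = [c.features for c in top]

    selected = _select(per_size_best, epsilon)
    return SearchResult(
        per_size_top=per_size_top,
        per_size_best=per_size_best,
        selected=selected,
        labels=y01,
    )


def _select(per_size_best: dict[int, BeamCandidate], epsilon: float) -> BeamCandidate:
    best = max(c.loocv_accuracy for c in per_size_best.values())
    for size in sorted(per_size_best):
        if per_size_best[size].loocv_accuracy >= best - epsilon:
            return per_size_best[size]
    raise AssertionError("unreachable: the max itself satisfies the bound")


def select_final_model(result: SearchResult, epsilon: float = 0.005) -> BeamCandidate:
    """Smallest subset size whose best LOOCV accuracy is within
    ``epsilon`` of the best accuracy over all sizes."""
    if not result.per_size_best:
        raise ValidationError("empty search result")
    return _select(result.per_size_best, epsilon)


REPORT_COLUMNS = [
    "n_mirnas", "mirnas",
    "sensitivity", "sensitivity_ci_low", "sensitivity_ci_high",
    "specificity", "specificity_ci_low", "specificity_ci_high",
    "accuracy", "accuracy_ci_low", "accuracy_ci_high",
    "auc", "auc_ci_low", "auc_ci_high",
]


def report_table(result: SearchResult, ci_method: str = "wilson"):
    """Per-size best-model summary table.

    One row per subset size with the best model's miRNAs and its
    LOOCV-based sensitivity/specificity/accuracy (binomial CIs) and the
    AUC of the LOOCV scores (DeLong CI). Returns a pandas DataFrame with
    the fixed :data:`REPORT_COLUMNS` order.
    """
    import pandas as pd

    y01 = result.labels
    rows = []
    for size in sorted(result.per_size_best):
        c = result.per_size_best[size]
        bm = binary_metrics(c.loocv_predictions, y01, ci_method=ci_method)
        a = auc_with_ci(c.loocv_scores, y01)
        rows.append({
            "n_mirnas": size,
            "mirnas": ",".join(c.features),
            "sensitivity": bm.sensitivity.value,
            "sensitivity_ci_low": bm.sensitivity.ci_low,
            "sensitivity_ci_high": bm.sensitivity.ci_high,
            "specificity": bm.specificity.value,
            "specificity_ci_low": bm.specificity.ci_low,
            "specificity_ci_high": bm.specificity.ci_high,
            "accuracy": bm.accuracy.value,
            "accuracy_ci_low": bm.accuracy.ci_low,
            "accuracy_ci_high": bm.accuracy.ci_high,
            "auc": a.auc,
            "auc_ci_low": a.ci_low,
            "auc_ci_high": a.ci_high,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
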