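"""The published 6-miRNA EC index and screening predictive-value
arithmetic.

The EC index is a fixed linear discriminant over six serum miRNAs whose
score above zero flags esophageal squamous cell carcinoma (ESCC):

    EC = 0.961037*miR-8073 - 0.962054*miR-6794-5p + 1.31647*miR-3196
         - 1.0132*miR-6820-5p + 0.657628*miR-744-5p
         - 0.406723*miR-6799-5p - 9.799262

Inputs are internal-control-normalized expression signals on the log2
convention used by :mod:`ecindex.preprocess`; the original publication
does not state its signal scale, so scores of externally normalized
profiles should be interpreted with that caveat. Scoring goes through
the same code path as any other :class:`DiscriminantModel`.

:func:`screening_metrics` converts a test's sensitivity and specificity
into post-test probabilities at a given disease prevalence — the
positive predictive value and the residual risk after a negative result
(1 - NPV) — the quantities that determine a screening test's utility in
a low-prevalence population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .types import DiscriminantModel, ValidationError

#: The published EC index: six serum miRNAs, frozen coefficients.
PUBLISHED_EC_INDEX = DiscriminantModel(
    mirna_ids=(
        "miR-8073",
        "miR-6794-5p",
        "miR-3196",
        "miR-6820-5p",
        "miR-744-5p",
        "miR-6799-5p",
    ),
    coefficients=(0.961037, -0.962054, 1.31647, -1.0132, 0.657628, -0.406723),
    intercept=-9.799262,
    decision_threshold=0.0,
)


def ec_score(profile: Mapping[str, float]) -> tuple[float, str]:
    """Score one profile with the published EC index.

    ``profile`` maps miRNA IDs to normalized log2 signals and must cover
    all six index miRNAs (extra entries are ignored; upstream
    preprocessing is responsible for imputing negative calls). Returns
    the score and the call: ``"positive"`` iff score > 0, so a score of
    exactly zero is a negative call.
    """
    missing = [m for m in PUBLISHED_EC_INDEX.mirna_ids if m not in profile]
    if missing:
        raise KeyError(f"profile is missing EC index miRNAs: {missing}")
    s = PUBLISHED_EC_INDEX.score(profile)
    return s, ("positive" if s > PUBLISHED_EC_INDEX.decision_threshold else "negative")


@dataclass(frozen=True)
class ScreeningInputs:
    """Prevalence and test characteristics, all proportions in (0, 1)."""

    prevalence: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValidationError(f"prevalence must be in (0, 1), got {self.prevalence}")
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            # a perfect test (exactly 1) is a meaningful boundary case
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class ScreeningMetrics:
    ppv: float
    one_minus_npv: float


def screening_metrics(s: ScreeningInputs) -> ScreeningMetrics:
    """Post-test probabilities by Bayes' rule.

    ppv = sens*p / (sens*p + (1-spec)*(1-p)) is the disease probability
    after a positive result; one_minus_npv = (1-sens)*p /
    ((1-sens)*p + spec*(1-p)) is the residual disease probability after
    a negative result. Exact closed forms; full precision retained (use
    :func:`format_percent` for 2-significant-figure reporting).
    """
    p, sens, spec = s.prevalence, s.sensitivity, s.specificity
    ppv = sens * p / (sens * p + (1 - spec) * (1 - p))
    one_minus_npv = (1 - sens) * p / ((1 - sens) * p + spec * (1 - p))
    return ScreeningMetrics(ppv=ppv, one_minus_npv=one_minus_npv)


def format_percent(x: float, sig: int = 2) -> str:
    """Format a proportion as a percentage at ``sig`` significant figures
    (e.g. 0.0146 -> '1.5%')."""
    return f"{x * 100:.{sig}g}%"
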