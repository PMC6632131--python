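"""Microarray preprocessing: positive calls, background subtraction,
internal-control normalization, and the robust-miRNA filter.

The procedure mirrors the standard 3D-Gene style serum miRNA workflow:

1. A probe is a *positive call* on an array only when its signal exceeds
   that array's background; the background is then subtracted. Probes at
   or below background become explicit missing values (negative calls).
2. Each array is rescaled so that the mean linear signal of a fixed set
   of internal-control miRNAs (default miR-149-3p, miR-2861, miR-4463)
   matches a common reference level, removing per-array scanning and
   labeling intensity differences.
3. *Robust* miRNAs are those whose normalized linear signal exceeds a
   threshold (default 64) in more than a given fraction (default 50%) of
   the samples of every group; only these enter model search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import NormalizedMatrix, RawExpressionStudy, ValidationError

DEFAULT_INTERNAL_CONTROLS = ("miR-149-3p", "miR-2861", "miR-4463")


@dataclass(frozen=True)
class NormalizationConfig:
    """Settings for internal-control normalization.

    ``reference_level`` chooses the common level R the per-array control
    means are scaled to: the grand mean of the per-array control means
    (``"grand_mean"``, within-study normalization) or an explicit
    ``fixed_reference`` (required for scoring new arrays against a frozen
    training reference). ``pseudo_floor`` (linear scale) bounds values
    away from zero before the log2 transform and is also the imputation
    level for negative calls at model-scoring time.
    """

    internal_controls: tuple[str, ...] = DEFAULT_INTERNAL_CONTROLS
    reference_level: str = "grand_mean"
    fixed_reference: float | None = None
    log_base: int = 2
    pseudo_floor: float = 0.1

    def __post_init__(self) -> None:
        if not self.internal_controls:
            raise ValidationError("internal_controls must be nonempty")
        if self.reference_level not in ("grand_mean", "fixed_value"):
            raise ValidationError(
                f"unknown reference_level {self.reference_level!r}"
            )
        if (self.reference_level == "fixed_value") != (self.fixed_reference is not None):
            raise ValidationError(
                "fixed_reference is required iff reference_level='fixed_value'"
            )
        if self.fixed_reference is not None and self.fixed_reference <= 0:
            raise ValidationError("fixed_reference must be positive")
        if self.log_base != 2:
            raise ValidationError("only log base 2 is supported")
        if self.pseudo_floor <= 0:
            raise ValidationError("pseudo_floor must be positive")


@dataclass(frozen=True)
class RobustFilterConfig:
    """Retention rule for robustly detected miRNAs.

    Under ``group_rule="all_groups"`` a miRNA must exceed
    ``signal_threshold`` (strictly, linear normalized scale) in strictly
    more than ``sample_fraction`` of the samples of *every* group;
    ``"any_group"`` requires it in at least one group.
    """

    signal_threshold: float = 64.0
    sample_fraction: float = 0.5
    group_rule: str = "all_groups"

    def __post_init__(self) -> None:
        if self.signal_threshold <= 0:
            raise ValidationError("signal_threshold must be > 0")
        if not (0 < self.sample_fraction <= 1):
            raise ValidationError("sample_fraction must be in (0, 1]")
        if self.group_rule not in ("all_groups", "any_group"):
            raise ValidationError(f"unknown group_rule {self.group_rule!r}")


def positive_call_subtract(study: RawExpressionStudy) -> NormalizedMatrix:
    """Select positive calls and subtract the array background.

    Cell (i, j) becomes ``signal - background_i`` when the signal is
    strictly above the array background, and missing (NaN) otherwise.
    The result is linear-scale and not yet normalized across arrays; the
    log2 layer uses the default pseudo-floor of
    :class:`NormalizationConfig` purely for a well-defined log.
    """
    bg = study.background[:, None]
    positive = study.signal > bg
    linear = np.where(positive, study.signal - bg, np.nan)
    return _with_log(study.mirna_ids, study.sample_ids, linear,
                     NormalizationConfig().pseudo_floor)


def _with_log(mirna_ids, sample_ids, linear, pseudo_floor) -> NormalizedMatrix:
    with np.errstate(invalid="ignore"):
        values = np.log2(np.maximum(linear, pseudo_floor))
    return NormalizedMatrix(
        mirna_ids=list(mirna_ids),
        sample_ids=list(sample_ids),
        values=values,
        linear_values=linear,
    )


def control_means(m: NormalizedMatrix, cfg: NormalizationConfig) -> np.ndarray:
    """Per-array arithmetic mean of the internal-control linear signals.

    Controls that are negative calls on an array are ignored for that
    array's mean; an array with no detected control at all is an error
    because its scale factor would be undefined.
    """
    missing = [c for c in cfg.internal_controls if c not in m.mirna_ids]
    if missing:
        raise ValidationError(
            f"internal control miRNAs absent from matrix: {missing}"
        )
    cols = m.column_index(cfg.internal_controls)
    ctrl = m.linear_values[:, cols]
    n_present = np.sum(~np.isnan(ctrl), axis=1)
    dead = np.flatnonzero(n_present == 0)
    if dead.size:
        names = [m.sample_ids[i] for i in dead[:5]]
        raise ValidationError(
            f"arrays with no detected internal control: {names}"
        )
    with np.errstate(invalid="ignore"):
        return np.nanmean(ctrl, axis=1)


def normalize_internal_controls(
    m: NormalizedMatrix, cfg: NormalizationConfig | None = None
) -> NormalizedMatrix:
    """Scale every array so its internal-control mean hits the reference.

    Array i is multiplied by ``f_i = R / c_i`` where ``c_i`` is the mean
    linear signal of the internal controls on that array and R is either
    the grand mean of the ``c_i`` (default) or ``cfg.fixed_reference``.
    After scaling, log2 values are recomputed as
    ``log2(max(linear, pseudo_floor))``.
    """
    cfg = cfg or NormalizationConfig()
    c = control_means(m, cfg)
    if cfg.reference_level == "grand_mean":
        reference = float(np.mean(c))
    else:
        reference = float(cfg.fixed_reference)
    factors = reference / c
    linear = m.linear_values * factors[:, None]
    return _with_log(m.mirna_ids, m.sample_ids, linear, cfg.pseudo_floor)


def freeze_reference(
    m: NormalizedMatrix, cfg: NormalizationConfig | None = None
) -> NormalizationConfig:
    """Freeze a study's normalization reference for later scoring.

    Returns a ``fixed_value`` config whose reference is this study's
    grand mean of per-array control means, so a single new array can be
    normalized onto the training scale.
    """
    cfg = cfg or NormalizationConfig()
    if cfg.reference_level == "fixed_value":
        return cfg
    c = control_means(m, cfg)
    return NormalizationConfig(
        internal_controls=cfg.internal_controls,
        reference_level="fixed_value",
        fixed_reference=float(np.mean(c)),
        log_base=cfg.log_base,
        pseudo_floor=cfg.pseudo_floor,
    )


NORM_SCHEMA = "ecindex-normalization/1"


def write_normalization_config(cfg: NormalizationConfig, path) -> None:
    import json
    from pathlib import Path

    payload = {
        "schema": NORM_SCHEMA,
        "internal_controls": list(cfg.internal_controls),
        "reference_level": cfg.reference_level,
        "fixed_reference": cfg.fixed_reference,
        "log_base": cfg.log_base,
        "pseudo_floor": cfg.pseudo_floor,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_normalization_config(path) -> NormalizationConfig:
    import json
    from pathlib import Path

    from .types import SchemaError

    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != NORM_SCHEMA:
        raise SchemaError(
            f"{path}: expected schema {NORM_SCHEMA!r}, got {payload.get('schema')!r}"
        )
    return NormalizationConfig(
        internal_controls=tuple(payload["internal_controls"]),
        reference_level=payload["reference_level"],
        fixed_reference=payload["fixed_reference"],
        log_base=payload["log_base"],
        pseudo_floor=payload["pseudo_floor"],
    )


def robust_filter(
    m: NormalizedMatrix,
    group_labels: np.ndarray,
    cfg: RobustFilterConfig | None = None,
) -> list[str]:
    """Return the miRNAs robustly detected across groups, in input order.

    ``group_labels`` assigns each sample to a group (any hashable
    labels; for case/control use the study's 0/1 labels). Missing cells
    never count as exceeding the threshold.
    """
    cfg = cfg or RobustFilterConfig()
    labels = np.asarray(group_labels)
    if labels.shape[0] != len(m.sample_ids):
        raise ValidationError("group_labels length differs from sample count")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) < 2:
        raise ValidationError("robust filter needs at least two groups")
    exceeds = np.where(np.isnan(m.linear_values), False,
                       m.linear_values > cfg.signal_threshold)
    per_group = []
    for g in uniq:
        mask = labels == g
        n = int(mask.sum())
        if n == 0:
            raise ValidationError(f"group {g!r} has zero samples")
        frac = exceeds[mask].sum(axis=0) / n
        per_group.append(frac > cfg.sample_fraction)
    per_group = np.array(per_group)
    keep = per_group.all(axis=0) if cfg.group_rule == "all_groups" else per_group.any(axis=0)
    return [mid for mid, k in zip(m.mirna_ids, keep) if k]
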