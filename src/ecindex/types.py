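"""Domain types for case-control serum miRNA expression studies.

The objects here mirror the stages of a microarray diagnostic pipeline:
raw scanner output with per-array background (:class:`RawExpressionStudy`),
the background-subtracted / internal-control-normalized matrix
(:class:`NormalizedMatrix`), and a fitted linear discriminant
(:class:`DiscriminantModel`) whose score above a threshold flags a case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

GROUPS = ("case", "control")
CONTROL_SOURCES = ("noncancer1", "noncancer2", "noncancer3")
STAGES = ("0", "I", "II", "III", "IV")


class ValidationError(ValueError):
    """An object violates a structural invariant."""


class SchemaError(ValueError):
    """A serialized artifact has an unexpected schema or version."""


class ParseError(ValueError):
    """An on-disk table could not be parsed."""


@dataclass(frozen=True)
class SampleMeta:
    """Clinical annotation for one serum sample.

    ``control_source`` identifies which non-cancer control cohort the
    sample came from and is only meaningful for controls; ``stage`` is
    the clinical stage of the tumor and is only meaningful for cases.
    """

    sample_id: str
    group: str
    control_source: str | None = None
    stage: str | None = None
    age: float | None = None
    sex: str | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.control_source is not None:
            if self.group != "control":
                raise ValidationError(
                    f"sample {self.sample_id!r}: control_source set on a non-control sample"
                )
            if self.control_source not in CONTROL_SOURCES:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unknown control_source {self.control_source!r}"
                )
        if self.stage is not None:
            if self.group != "case":
                raise ValidationError(
                    f"sample {self.sample_id!r}: stage set on a non-case sample"
                )
            if self.stage not in STAGES:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unknown stage {self.stage!r}"
                )
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown sex {self.sex!r}"
            )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class RawExpressionStudy:
    """Raw fluorescence signals plus per-array background for a cohort.

    ``signal`` is samples x miRNAs in linear fluorescence units;
    ``background`` holds one scalar background level per array (sample).
    """

    mirna_ids: list[str]
    samples: list[SampleMeta]
    signal: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n, m = len(self.samples), len(self.mirna_ids)
        if self.signal.shape != (n, m):
            raise ValidationError(
                f"signal shape {self.signal.shape} != (n_samples={n}, n_mirnas={m})"
            )
        if self.background.shape != (n,):
            raise ValidationError(
                f"background shape {self.background.shape} != ({n},)"
            )
        _check_unique(self.mirna_ids, "miRNA ID")
        _check_unique([s.sample_id for s in self.samples], "sample ID")
        if not np.all(np.isfinite(self.signal)):
            bad = np.argwhere(~np.isfinite(self.signal))[0]
            raise ValidationError(
                f"non-finite signal at sample {self.samples[bad[0]].sample_id!r}, "
                f"miRNA {self.mirna_ids[bad[1]]!r}"
            )
        if np.any(self.signal < 0):
            raise ValidationError("negative raw signal values")
        if not np.all(np.isfinite(self.background)) or np.any(self.background < 0):
            raise ValidationError("background must be finite and >= 0 for every array")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def group_labels(self) -> np.ndarray:
        """0/1 array, 1 for case."""
        return np.array([1 if s.group == "case" else 0 for s in self.samples])


@dataclass
class NormalizedMatrix:
    """Expression matrix after background subtraction (and optionally
    internal-control normalization).

    ``linear_values`` is on the linear fluorescence scale, ``values`` is
    log2 of the same cells; both use NaN as the explicit marker for a
    negative call (signal not above the array background).
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    linear_values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.linear_values = np.asarray(self.linear_values, dtype=float)
        n, m = len(self.sample_ids), len(self.mirna_ids)
        if self.values.shape != (n, m) or self.linear_values.shape != (n, m):
            raise ValidationError("values/linear_values shape mismatch with IDs")
        _check_unique(self.mirna_ids, "miRNA ID")
        _check_unique(self.sample_ids, "sample ID")
        if not np.array_equal(np.isnan(self.values), np.isnan(self.linear_values)):
            raise ValidationError(
                "missingness pattern differs between log2 and linear values"
            )
        present = ~np.isnan(self.linear_values)
        if np.any(self.linear_values[present] <= 0):
            raise ValidationError("linear values must be > 0 wherever present")

    def column_index(self, mirna_ids: Sequence[str]) -> np.ndarray:
        lookup = {m: j for j, m in enumerate(self.mirna_ids)}
        missing = [m for m in mirna_ids if m not in lookup]
        if missing:
            raise KeyError(f"miRNAs absent from matrix: {missing}")
        return np.array([lookup[m] for m in mirna_ids], dtype=int)

    def feature_matrix(
        self, mirna_ids: Sequence[str], pseudo_floor: float = 0.1
    ) -> np.ndarray:
        """Log2 feature matrix for the given miRNAs with negative calls
        imputed at ``pseudo_floor`` (linear scale) before the log."""
        cols = self.column_index(mirna_ids)
        x = self.values[:, cols].copy()
        x[np.isnan(x)] = np.log2(pseudo_floor)
        return x


@dataclass(frozen=True)
class DiscriminantModel:
    """A linear discriminant over named miRNA features.

    score(x) = coefficients . x + intercept; a score strictly above
    ``decision_threshold`` predicts the case class. Ties predict control.
    """

    mirna_ids: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    decision_threshold: float = 0.0

    def __post_init__(self) -> None:
        if len(self.mirna_ids) == 0:
            raise ValidationError("a discriminant model needs at least one miRNA")
        if len(self.coefficients) != len(self.mirna_ids):
            raise ValidationError(
                f"{len(self.coefficients)} coefficients for {len(self.mirna_ids)} miRNAs"
            )
        _check_unique(self.mirna_ids, "miRNA ID")

    @property
    def w(self) -> np.ndarray:
        return np.asarray(self.coefficients, dtype=float)

    def score(self, x: Mapping[str, float] | Sequence[float] | np.ndarray) -> float:
        """Linear score for one profile.

        ``x`` is either a mapping from miRNA ID to normalized log2 signal
        (extra keys ignored) or a vector aligned with ``mirna_ids``.
        """
        if isinstance(x, Mapping):
            missing = [m for m in self.mirna_ids if m not in x]
            if missing:
                raise KeyError(f"profile is missing model miRNAs: {missing}")
            vec = np.array([float(x[m]) for m in self.mirna_ids])
        else:
            vec = np.asarray(x, dtype=float)
            if vec.shape != (len(self.mirna_ids),):
                raise ValidationError(
                    f"profile vector shape {vec.shape} != ({len(self.mirna_ids)},)"
                )
        return float(self.w @ vec + self.intercept)

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.w + self.intercept

    def predict(self, x) -> str:
        return "case" if self.score(x) > self.decision_threshold else "control"


@dataclass
class StudyBundle:
    """A preprocessed study ready for model search: normalized matrix,
    sample annotations, and the robust-filter survivor list."""

    normalized: NormalizedMatrix
    samples: list[SampleMeta]
    selected_mirnas: list[str]

    def __post_init__(self) -> None:
        if [s.sample_id for s in self.samples] != self.normalized.sample_ids:
            raise ValidationError("sample metadata order differs from matrix order")
        known = set(self.normalized.mirna_ids)
        stray = [m for m in self.selected_mirnas if m not in known]
        if stray:
            raise ValidationError(f"selected miRNAs not in matrix: {stray}")

    @property
    def group_labels(self) -> np.ndarray:
        return np.array([1 if s.group == "case" else 0 for s in self.samples])
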