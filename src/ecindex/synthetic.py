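"""Synthetic case-control serum miRNA microarray cohorts.

The generator emulates the statistical structure the pipeline assumes of
real scanner output, so every stage is testable without any download:

* log-normal fluorescence signals (Gaussian on the log2 scale) with
  per-miRNA baselines spanning the detection range around the robust
  threshold of 64;
* a per-array multiplicative scaling artifact (log-normal), exactly the
  nuisance internal-control normalization is meant to remove;
* three near-constant internal-control miRNAs carrying the standard
  control names;
* a planted set of differentially expressed miRNAs whose log2 means are
  shifted in cases (alternating up/down), optionally scaled per tumor
  stage;
* additive per-array background with sub-detection (negative call)
  signals injected at a configurable dropout rate.

Ground truth (planted miRNAs, array factors, stages) is returned
alongside the study for recovery experiments. A single seeded generator
stream drives all draws, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_expression_table
from .preprocess import DEFAULT_INTERNAL_CONTROLS
from .types import RawExpressionStudy, SampleMeta, ValidationError

# stage mix of a typical ESCC case series (half early-stage)
DEFAULT_STAGE_DISTRIBUTION = {
    "0": 23 / 283, "I": 139 / 283, "II": 52 / 283, "III": 59 / 283, "IV": 10 / 283,
}
DEFAULT_CONTROL_SOURCE_DISTRIBUTION = {
    "noncancer1": 162 / 283, "noncancer2": 61 / 283, "noncancer3": 60 / 283,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults give a clearly learnable
    6-miRNA signal in a 100 + 100 cohort on a 500-probe panel."""

    n_case: int = 100
    n_control: int = 100
    n_mirna: int = 500               # includes the 3 internal controls
    n_differential: int = 6
    effect_size: float = 4.0         # log2 mean shift in cases
    baseline_log2_mean_range: tuple[float, float] = (6.0, 14.0)
    biological_sd: float = 1.0
    array_scale_sd: float = 0.25     # sd of log array factor
    background_mean: float = 30.0    # linear fluorescence units
    background_sd: float = 5.0
    internal_control_log2_levels: tuple[float, float, float] = (10.0, 10.5, 11.0)
    internal_control_sd: float = 0.05
    detection_dropout: float = 0.02
    stage_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_DISTRIBUTION))
    effect_by_stage: dict[str, float] | None = None
    control_source_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_SOURCE_DISTRIBUTION))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential > self.n_mirna - len(DEFAULT_INTERNAL_CONTROLS):
            raise ValidationError("n_differential exceeds available non-control miRNAs")
        if self.n_mirna < len(DEFAULT_INTERNAL_CONTROLS) + 1:
            raise ValidationError("n_mirna too small for controls plus signal")
        for name in ("biological_sd", "array_scale_sd", "background_sd",
                     "internal_control_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0 <= self.detection_dropout < 1):
            raise ValidationError("detection_dropout must be in [0, 1)")
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("need at least one case and one control")


@dataclass(frozen=True, eq=False)
class SimulationTruth:
    differential_mirna_ids: tuple[str, ...]
    effects: dict[str, float]        # signed planted log2 shifts
    array_factors: np.ndarray        # linear per-array multiplier
    stages: tuple[str | None, ...]   # per sample, None for controls


def _sample_categorical(rng, dist: dict[str, float], size: int) -> list[str]:
    keys = list(dist)
    p = np.array([dist[k] for k in keys], dtype=float)
    p = p / p.sum()
    return [keys[i] for i in rng.choice(len(keys), size=size, p=p)]


def simulate_cohort(
    cfg: SimulationConfig | None = None,
    sample_seed: int | None = None,
) -> tuple[RawExpressionStudy, SimulationTruth]:
    """Draw one cohort. Reproducible given ``cfg.seed``.

    Panel-level properties (per-miRNA baselines, which miRNAs are
    differential, their effects) are a property of the chip and the
    disease, so they depend only on ``cfg.seed``; sample-level draws
    come from ``sample_seed`` when given. Passing a different
    ``sample_seed`` therefore yields an independent cohort measured on
    the same panel with the same planted truth — e.g. a validation set.
    """
    cfg = cfg or SimulationConfig()
    panel_ss, default_sample_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    panel_rng = np.random.default_rng(panel_ss)
    rng = np.random.default_rng(
        default_sample_ss if sample_seed is None else sample_seed)
    n = cfg.n_case + cfg.n_control
    controls = list(DEFAULT_INTERNAL_CONTROLS)
    n_free = cfg.n_mirna - len(controls)
    mirna_ids = controls + [f"miR-sim-{j:04d}" for j in range(1, n_free + 1)]

    # planted differential miRNAs, alternating up/down in cases
    diff_idx = np.sort(
        panel_rng.choice(n_free, size=cfg.n_differential, replace=False)
        + len(controls))
    effects = np.zeros(cfg.n_mirna)
    for r, j in enumerate(diff_idx):
        effects[j] = cfg.effect_size * (1 if r % 2 == 0 else -1)

    baselines = panel_rng.uniform(*cfg.baseline_log2_mean_range, size=cfg.n_mirna)
    baselines[: len(controls)] = cfg.internal_control_log2_levels

    stages = _sample_categorical(rng, cfg.stage_distribution, cfg.n_case)
    sources = _sample_categorical(rng, cfg.control_source_distribution, cfg.n_control)
    stage_mult = np.array(
        [(cfg.effect_by_stage or {}).get(s, 1.0) for s in stages] + [0.0] * cfg.n_control
    )
    is_case = np.array([1.0] * cfg.n_case + [0.0] * cfg.n_control)

    log2sig = baselines[None, :] + rng.normal(0, cfg.biological_sd, size=(n, cfg.n_mirna))
    log2sig[:, : len(controls)] = (
        np.asarray(cfg.internal_control_log2_levels)[None, :]
        + rng.normal(0, cfg.internal_control_sd, size=(n, len(controls)))
    )
    log2sig += (is_case * stage_mult)[:, None] * effects[None, :]

    array_factors = np.exp(rng.normal(0, cfg.array_scale_sd, size=n))
    linear = np.exp2(log2sig) * array_factors[:, None]
    background = np.clip(
        rng.normal(cfg.background_mean, cfg.background_sd, size=n),
        a_min=1e-3, a_max=None,
    )
    # sub-detection signals: drop a fraction of non-control cells below background
    drop = rng.random(size=(n, cfg.n_mirna)) < cfg.detection_dropout
    drop[:, : len(controls)] = False
    linear = np.where(drop, rng.random(size=(n, cfg.n_mirna)) * background[:, None], linear)

    samples = []
    ages_case = np.clip(rng.normal(66, 10, size=cfg.n_case), 30, 95)
    ages_ctrl = np.clip(rng.normal(58, 14, size=cfg.n_control), 20, 100)
    sex_case = rng.random(cfg.n_case) < 0.83
    sex_ctrl = rng.random(cfg.n_control) < 0.44
    for i in range(cfg.n_case):
        samples.append(SampleMeta(
            sample_id=f"case_{i + 1:04d}", group="case", stage=stages[i],
            age=float(round(ages_case[i])), sex="male" if sex_case[i] else "female",
        ))
    for i in range(cfg.n_control):
        samples.append(SampleMeta(
            sample_id=f"ctrl_{i + 1:04d}", group="control", control_source=sources[i],
            age=float(round(ages_ctrl[i])), sex="male" if sex_ctrl[i] else "female",
        ))

    study = RawExpressionStudy(
        mirna_ids=mirna_ids, samples=samples, signal=linear, background=background,
    )
    truth = SimulationTruth(
        differential_mirna_ids=tuple(mirna_ids[j] for j in diff_idx),
        effects={mirna_ids[j]: float(effects[j]) for j in diff_idx},
        array_factors=array_factors,
        stages=tuple(stages) + (None,) * cfg.n_control,
    )
    return study, truth


def write_fixture(
    study: RawExpressionStudy, truth: SimulationTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write the TSV fixture (expression + metadata) and the truth JSON.

    Output round-trips through :func:`ecindex.io.read_expression_table`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
    }
    write_expression_table(study, paths["expression"], paths["metadata"])
    paths["truth"].write_text(json.dumps({
        "differential_mirna_ids": list(truth.differential_mirna_ids),
        "effects": truth.effects,
        "array_factors": [float(f) for f in truth.array_factors],
        "stages": [s for s in truth.stages],
    }, indent=1) + "\n")
    return paths


def write_geo_series_matrix(study: RawExpressionStudy, path: str | Path) -> Path:
    """Write a GEO series-matrix-style text rendering of a raw study,
    used to exercise the best-effort GEO reader without any download."""
    path = Path(path)
    lines = ["!Series_title\t\"synthetic serum miRNA cohort\""]
    sid = study.sample_ids
    lines.append("!Sample_geo_accession\t" + "\t".join(f'"{s}"' for s in sid))
    lines.append("!Sample_title\t" + "\t".join(f'"{s}"' for s in sid))

    def chars(values):
        return "!Sample_characteristics_ch1\t" + "\t".join(f'"{v}"' for v in values)

    lines.append(chars(f"group: {s.group}" for s in study.samples))
    lines.append(chars(
        f"control source: {s.control_source}" if s.control_source else ""
        for s in study.samples))
    lines.append(chars(
        f"stage: {s.stage}" if s.stage else "" for s in study.samples))
    lines.append(chars(
        f"background: {float(b)!r}" for b in study.background))
    lines.append("!series_matrix_table_begin")
    lines.append("\t".join(["\"ID_REF\""] + [f'"{s}"' for s in sid]))
    for j, mid in enumerate(study.mirna_ids):
        lines.append("\t".join([f'"{mid}"'] + [repr(float(v)) for v in study.signal[:, j]]))
    lines.append("!series_matrix_table_end")
    path.write_text("\n".join(lines) + "\n")
    return path
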