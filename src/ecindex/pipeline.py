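"""End-to-end orchestration with a reproducible run manifest.

A run is described by one configuration mapping (or YAML file):

.. code-block:: yaml

    seed: 7
    simulate: {n_case: 100, n_control: 100, n_mirna: 500}
    # or:  input: {expression: expr.tsv, metadata: meta.tsv}
    normalization: {pseudo_floor: 0.1}
    robust_filter: {signal_threshold: 64, sample_fraction: 0.5}
    search: {beam_width: 20, max_features: 8, epsilon: 0.005}

Stages run in order simulate|ingest -> positive calls & background
subtraction -> internal-control normalization -> robust filter -> beam
search -> final-model selection -> evaluation. Every artifact directory
carries a ``manifest.json`` (config snapshot, input digests, package
version, seed, timestamp) written before any result, and a failing
stage leaves a ``FAILED`` marker naming the stage while keeping partial
outputs for inspection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .discriminant import LDAFitConfig
from .evaluation import evaluate_scores
from .io import read_expression_table, write_model
from .preprocess import (
    NormalizationConfig,
    RobustFilterConfig,
    freeze_reference,
    normalize_internal_controls,
    positive_call_subtract,
    robust_filter,
    write_normalization_config,
)
from .search import SearchConfig, beam_search, report_table
from .synthetic import SimulationConfig, simulate_cohort, write_fixture
from .types import ValidationError

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(source, Mapping):
        return dict(source)
    import yaml

    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{source}: pipeline config must be a mapping")
    return cfg


def _metric_json(m):
    return {"value": m.value, "ci_low": m.ci_low, "ci_high": m.ci_high, "n": m.n}


def run_pipeline(
    config: str | Path | Mapping[str, Any], out_dir: str | Path
) -> Path:
    """Execute the full pipeline, writing artifacts under ``out_dir``.

    Returns the artifact directory. Re-running with an identical config
    (and identical input files) reproduces identical result digests.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    manifest: dict[str, Any] = {
        "package": "ecindex",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": cfg,
        "input_digests": {},
    }
    if "input" in cfg:
        for key in ("expression", "metadata"):
            p = Path(cfg["input"][key])
            manifest["input_digests"][key] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str) + "\n")

    stage = "ingest"
    try:
        if "simulate" in cfg or "input" not in cfg:
            stage = "simulate"
            sim_kwargs = dict(cfg.get("simulate", {}))
            sim_kwargs.setdefault("seed", seed)
            sim = SimulationConfig(**_coerce_tuples(sim_kwargs, SimulationConfig))
            study, truth = simulate_cohort(sim)
            write_fixture(study, truth, out / "cohort")
        else:
            study = read_expression_table(
                cfg["input"]["expression"], "wide_tsv", cfg["input"]["metadata"]
            )

        stage = "preprocess"
        norm_cfg = NormalizationConfig(
            **_coerce_tuples(dict(cfg.get("normalization", {})), NormalizationConfig))
        subtracted = positive_call_subtract(study)
        normalized = normalize_internal_controls(subtracted, norm_cfg)
        write_normalization_config(
            freeze_reference(subtracted, norm_cfg), out / "normalization.json")

        stage = "robust_filter"
        rf_cfg = RobustFilterConfig(**dict(cfg.get("robust_filter", {})))
        labels = study.group_labels
        selected_mirnas = robust_filter(normalized, labels, rf_cfg)
        (out / "robust_mirnas.txt").write_text("\n".join(selected_mirnas) + "\n")
        logger.info("robust filter kept %d of %d miRNAs",
                    len(selected_mirnas), len(study.mirna_ids))
        if not selected_mirnas:
            raise ValidationError("no miRNA passed the robust filter")

        stage = "beam_search"
        s = dict(cfg.get("search", {}))
        epsilon = float(s.pop("epsilon", 0.005))
        search_cfg = SearchConfig(
            **{**s, "lda": LDAFitConfig(**dict(cfg.get("lda", {})))})
        X = normalized.feature_matrix(selected_mirnas, norm_cfg.pseudo_floor)
        result = beam_search(X, labels, selected_mirnas, search_cfg, epsilon=epsilon)
        report_table(result).to_csv(out / "per_size_models.tsv", sep="\t", index=False)

        stage = "select_final_model"
        write_model(result.selected.model, out / "model.json")

        stage = "evaluate"
        report = evaluate_scores(
            result.selected.loocv_scores, labels, meta=study.samples)
        (out / "evaluation.json").write_text(json.dumps({
            "n_case": report.n_case,
            "n_control": report.n_control,
            "selected_mirnas": list(result.selected.features),
            "loocv_accuracy": result.selected.loocv_accuracy,
            "sensitivity": _metric_json(report.metrics.sensitivity),
            "specificity": _metric_json(report.metrics.specificity),
            "accuracy": _metric_json(report.metrics.accuracy),
            "auc": {"value": report.auc.auc, "ci_low": report.auc.ci_low,
                    "ci_high": report.auc.ci_high},
            "sensitivity_by_stage": {k: _metric_json(v)
                                     for k, v in report.by_stage.items()},
            "specificity_by_control_source": {k: _metric_json(v)
                                              for k, v in report.by_control_source.items()},
        }, indent=1) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _coerce_tuples(kwargs: dict, cls) -> dict:
    """YAML has no tuples; coerce list values into the tuple-typed fields
    of the target dataclass so frozen configs stay hashable."""
    for f in dataclasses.fields(cls):
        v = kwargs.get(f.name)
        if isinstance(v, list):
            kwargs[f.name] = tuple(v)
    return kwargs
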