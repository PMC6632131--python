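"""Readers and writers for expression tables, sample metadata, and models.

On-disk conventions
-------------------
* Expression matrix: wide TSV, first column ``mirna_id``, one column per
  sample, linear fluorescence values. Empty cells are missing values.
* Sample metadata: sidecar TSV with columns ``sample_id, group,
  control_source, stage, age, sex, background`` (blank = absent); any
  further columns are preserved as opaque annotations.
* Discriminant models: versioned JSON, coefficients at full double
  precision (``read_model(write_model(m)) == m`` bit-exactly).
* GEO series-matrix text: best-effort read-only import of
  ``!Sample_characteristics_ch1`` annotations plus the ID_REF table.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    DiscriminantModel,
    ParseError,
    RawExpressionStudy,
    SampleMeta,
    SchemaError,
    ValidationError,
)

MODEL_SCHEMA = "ecindex-model/1"
_META_COLUMNS = ["sample_id", "group", "control_source", "stage", "age", "sex", "background"]


# ---------------------------------------------------------------------------
# sample metadata

def write_sample_metadata(
    samples: Sequence[SampleMeta], background: np.ndarray, path: str | Path
) -> None:
    rows = []
    extra_keys: list[str] = []
    for s in samples:
        for k in s.extra:
            if k not in extra_keys:
                extra_keys.append(k)
    for s, b in zip(samples, background):
        row = {
            "sample_id": s.sample_id,
            "group": s.group,
            "control_source": s.control_source or "",
            "stage": s.stage or "",
            "age": "" if s.age is None else repr(float(s.age)),
            "sex": s.sex or "",
            "background": repr(float(b)),
        }
        for k in extra_keys:
            row[k] = s.extra.get(k, "")
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLUMNS + extra_keys).to_csv(
        path, sep="\t", index=False
    )


def read_sample_metadata(path: str | Path) -> tuple[list[SampleMeta], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "group", "background"):
        if col not in df.columns:
            raise ParseError(f"{path}: metadata is missing required column {col!r}")
    extra_cols = [c for c in df.columns if c not in _META_COLUMNS]
    samples, background = [], []
    for _, row in df.iterrows():
        try:
            bg = float(row["background"])
        except ValueError as exc:
            raise ParseError(
                f"{path}: non-numeric background for sample {row['sample_id']!r}"
            ) from exc
        samples.append(
            SampleMeta(
                sample_id=row["sample_id"],
                group=row["group"],
                control_source=row.get("control_source") or None,
                stage=row.get("stage") or None,
                age=float(row["age"]) if row.get("age") else None,
                sex=row.get("sex") or None,
                extra={c: row[c] for c in extra_cols if row[c]},
            )
        )
        background.append(bg)
    return samples, np.array(background)


# ---------------------------------------------------------------------------
# expression tables

def write_expression_table(
    study: RawExpressionStudy, expr_path: str | Path, meta_path: str | Path
) -> None:
    """Write the wide TSV matrix and its metadata sidecar."""
    df = pd.DataFrame(
        study.signal.T, index=pd.Index(study.mirna_ids, name="mirna_id"),
        columns=study.sample_ids,
    )
    df.to_csv(expr_path, sep="\t", float_format=None)
    write_sample_metadata(study.samples, study.background, meta_path)


def read_expression_table(
    path: str | Path,
    format: str = "wide_tsv",
    meta_path: str | Path | None = None,
) -> RawExpressionStudy:
    """Read a raw expression study.

    Parameters
    ----------
    path
        The expression matrix (wide TSV) or GEO series-matrix text file.
    format
        ``"wide_tsv"`` (requires ``meta_path``) or ``"geo_series_matrix"``.
    meta_path
        Sidecar metadata TSV; required for ``wide_tsv``, optional override
        for the GEO format.
    """
    if format == "wide_tsv":
        if meta_path is None:
            raise ParseError("wide_tsv format requires a metadata sidecar (meta_path)")
        return _read_wide_tsv(Path(path), Path(meta_path))
    if format == "geo_series_matrix":
        return _read_geo_series_matrix(Path(path), meta_path)
    raise ValueError(f"unknown expression table format {format!r}")


def _read_wide_tsv(path: Path, meta_path: Path) -> RawExpressionStudy:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises several parse error types
        raise ParseError(f"{path}: cannot parse wide TSV: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicated miRNA row ID {dup!r}")
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    for col in non_numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            raise ParseError(
                f"{path}: non-numeric signal at row {bad.idxmax()!r}, column {col!r}"
            )
        df[col] = coerced
    samples, background = read_sample_metadata(meta_path)
    meta_ids = [s.sample_id for s in samples]
    if set(meta_ids) != set(df.columns):
        raise ValidationError(
            f"{path}: sample columns differ from metadata sample_ids "
            f"(matrix only: {sorted(set(df.columns) - set(meta_ids))[:5]}, "
            f"metadata only: {sorted(set(meta_ids) - set(df.columns))[:5]})"
        )
    df = df[meta_ids]  # metadata order is authoritative
    signal = df.to_numpy(dtype=float).T
    if np.isnan(signal).any():
        # raw scanner export should be dense; treat empties as zeros is wrong,
        # so reject with a pointer to the offending cell
        i, j = np.argwhere(np.isnan(signal))[0]
        raise ParseError(
            f"{path}: empty/missing raw signal for sample {meta_ids[i]!r}, "
            f"miRNA {df.index[j]!r}"
        )
    return RawExpressionStudy(
        mirna_ids=list(df.index.astype(str)),
        samples=samples,
        signal=signal,
        background=background,
    )


def _read_geo_series_matrix(path: Path, meta_path=None) -> RawExpressionStudy:
    """Parse a GEO series-matrix style text file.

    Sample annotations are taken from ``!Sample_geo_accession`` /
    ``!Sample_title`` and ``key: value`` pairs in
    ``!Sample_characteristics_ch1`` lines (recognized keys: group,
    control_source/control source, stage, age, sex, background). A
    metadata sidecar, when given, overrides the embedded annotations.
    """
    header: dict[str, list[str]] = {}
    characteristics: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    for raw in path.read_text().splitlines():
        line = raw.rstrip("\n")
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            if line.strip():
                table_lines.append(line)
        elif line.startswith("!Sample_"):
            key, *vals = line.split("\t")
            vals = [v.strip().strip('"') for v in vals]
            if key == "!Sample_characteristics_ch1":
                characteristics.append(vals)
            else:
                header[key[len("!Sample_"):]] = vals
    if not table_lines:
        raise ParseError(f"{path}: no series_matrix_table found")

    cols = [c.strip().strip('"') for c in table_lines[0].split("\t")]
    if not cols or cols[0].upper() != "ID_REF":
        raise ParseError(f"{path}: table header must start with ID_REF")
    sample_ids = cols[1:]
    mirna_ids, rows = [], []
    for line in table_lines[1:]:
        parts = [p.strip().strip('"') for p in line.split("\t")]
        if len(parts) != len(cols):
            raise ParseError(
                f"{path}: ragged table row {parts[0]!r} "
                f"({len(parts)} fields, expected {len(cols)})"
            )
        mirna_ids.append(parts[0])
        try:
            rows.append([float(v) if v not in ("", "null") else math.nan for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric signal in row {parts[0]!r}") from exc
    signal = np.array(rows).T  # samples x miRNAs

    if meta_path is not None:
        samples, background = read_sample_metadata(meta_path)
        order = {s.sample_id: i for i, s in enumerate(samples)}
        if set(order) != set(sample_ids):
            raise ValidationError(f"{path}: sidecar sample_ids differ from table columns")
        perm = [sample_ids.index(s.sample_id) for s in samples]
        return RawExpressionStudy(mirna_ids, samples, signal[perm], background)

    per_sample: list[dict[str, str]] = [dict() for _ in sample_ids]
    for vals in characteristics:
        for i, v in enumerate(vals[: len(sample_ids)]):
            if ":" in v:
                k, val = v.split(":", 1)
                per_sample[i][k.strip().lower().replace(" ", "_")] = val.strip()
    samples, background = [], []
    for i, sid in enumerate(sample_ids):
        ann = per_sample[i]
        known = {"group", "control_source", "stage", "age", "sex", "background"}
        if "group" not in ann:
            raise ParseError(
                f"{path}: sample {sid!r} has no 'group: ...' characteristics line"
            )
        if "background" not in ann:
            raise ParseError(
                f"{path}: sample {sid!r} has no 'background: ...' characteristics line"
            )
        samples.append(
            SampleMeta(
                sample_id=sid,
                group=ann["group"],
                control_source=ann.get("control_source"),
                stage=ann.get("stage"),
                age=float(ann["age"]) if "age" in ann else None,
                sex=ann.get("sex"),
                extra={k: v for k, v in ann.items() if k not in known},
            )
        )
        background.append(float(ann["background"]))
    if np.isnan(signal).any():
        raise ParseError(f"{path}: missing values in series-matrix signal table")
    return RawExpressionStudy(mirna_ids, samples, signal, np.array(background))


# ---------------------------------------------------------------------------
# discriminant models

def write_model(model: DiscriminantModel, path: str | Path) -> None:
    payload = {
        "schema": MODEL_SCHEMA,
        "mirna_ids": list(model.mirna_ids),
        "coefficients": [float(c) for c in model.coefficients],
        "intercept": float(model.intercept),
        "decision_threshold": float(model.decision_threshold),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_model(path: str | Path) -> DiscriminantModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema") != MODEL_SCHEMA:
        raise SchemaError(
            f"{path}: expected schema {MODEL_SCHEMA!r}, got {payload.get('schema')!r}"
        )
    missing = {"mirna_ids", "coefficients", "intercept"} - payload.keys()
    if missing:
        raise SchemaError(f"{path}: model file missing fields {sorted(missing)}")
    return DiscriminantModel(
        mirna_ids=tuple(payload["mirna_ids"]),
        coefficients=tuple(float(c) for c in payload["coefficients"]),
        intercept=float(payload["intercept"]),
        decision_threshold=float(payload.get("decision_threshold", 0.0)),
    )
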