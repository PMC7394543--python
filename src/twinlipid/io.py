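"""Delimited-table reading/writing with schema validation, run manifests.

All pipeline artifacts are plain delimited text (CSV/TSV, sniffed by
delimiter) or JSON; validation aggregates every violation into a single
error rather than stopping at the first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "TableSchema",
    "read_table",
    "read_matrix",
    "write_matrix",
    "RunConfig",
    "write_manifest",
    "PAIRS_SCHEMA",
    "PEAKS_SCHEMA",
]


class SchemaError(ValueError):
    """Raised with the full list of schema violations of a table."""

    def __init__(self, path, violations: list[str]):
        self.violations = violations
        super().__init__(
            f"{path}: {len(violations)} schema violation(s):\n  "
            + "\n  ".join(violations)
        )


@dataclass
class TableSchema:
    """Declared expectations for a delimited table."""

    required: tuple[str, ...] = ()
    numeric: tuple[str, ...] = ()
    unique_key: tuple[str, ...] = ()


PAIRS_SCHEMA = TableSchema(
    required=("pair_id", "member", "zygosity"),
    numeric=("member",),
    unique_key=("pair_id", "member"),
)
PEAKS_SCHEMA = TableSchema(
    required=("lipid", "sample", "batch", "area", "is_area", "rej",
              "peak_quality", "m_score"),
    numeric=("area", "is_area", "rej", "peak_quality", "m_score"),
    unique_key=(),
)


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_table(
    path, schema: TableSchema | None = None, index_col=None
) -> pd.DataFrame:
    """Read a CSV or TSV (delimiter sniffed) and validate it.

    Collects all violations — missing columns, non-numeric cells in
    numeric columns, duplicate keys — into one :class:`SchemaError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=index_col)
    if schema is None:
        return df
    violations: list[str] = []
    for col in schema.required:
        if col not in df.columns:
            violations.append(f"missing required column {col!r}")
    for col in schema.numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in list(bad)[:10]:
            violations.append(f"non-numeric value {df.loc[i, col]!r} in column "
                              f"{col!r} (row {i})")
        df[col] = coerced
    if schema.unique_key and all(c in df.columns for c in schema.unique_key):
        dups = df.duplicated(subset=list(schema.unique_key))
        for i in list(df.index[dups])[:10]:
            key = tuple(df.loc[i, list(schema.unique_key)])
            violations.append(f"duplicate key {key} (row {i})")
    if violations:
        raise SchemaError(path, violations)
    return df


def read_matrix(path) -> pd.DataFrame:
    """Read a sample x feature matrix (first column = sample id); all
    feature columns must be numeric."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    violations = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in list(bad)[:10]:
            violations.append(
                f"non-numeric value {df.loc[i, col]!r} in column {col!r} (row {i})"
            )
        df[col] = coerced
    if violations:
        raise SchemaError(path, violations)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (echoed to the manifest)."""

    input_paths: dict = field(default_factory=dict)
    covariates: list = field(default_factory=lambda: [
        "age", "sex", "education", "bmi", "lipid_med", "smoking", "batch", "apoe4",
    ])
    int_offset: float = 3.0 / 8.0
    alpha: float = 0.05
    cv_max: float = 0.4
    peak_quality_min: float = 0.75
    ci_method: str = "profile"
    h2_reference: str = "chi2_1"  # or "boundary_mixture"
    moderation: bool = False
    seed: int = 0
    outdir: str = "."


def write_manifest(outdir, config: RunConfig, outputs: dict[str, str],
                   counts: dict | None = None) -> str:
    """Write a run manifest (config, seed, software version, artifact list,
    per-stage in/out counts) sufficient to reproduce the run."""
    from . import __version__

    payload = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": asdict(config),
        "outputs": outputs,
        "counts": counts or {},
    }
    path = Path(outdir) / "run_manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return str(path)
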