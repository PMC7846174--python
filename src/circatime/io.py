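"""Readers, writers and pipeline configuration.

Matrices travel as plain TSV (UTF-8, '.' decimal): genes as rows with a
leading ``gene_id`` column, samples as columns, plus a sample-metadata TSV
keyed by ``sample_id``.  Every pipeline run writes a JSON manifest of its
settings and seed next to its outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import CircatimeError, ExpressionMatrix, REQUIRED_METADATA

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "PipelineConfig",
    "write_manifest",
]

logger = logging.getLogger(__name__)


def write_expression_tsv(matrix: ExpressionMatrix, matrix_path, metadata_path) -> None:
    matrix.values.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
    matrix.samples.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_expression_tsv(matrix_path, metadata_path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV plus its sample metadata into a typed matrix.

    Sample ids in the matrix header must match the metadata rows exactly;
    harvest times outside [0, 24) are wrapped with a warning.  Errors carry
    the offending row/column.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    for p in (matrix_path, metadata_path):
        if not p.exists():
            raise CircatimeError(f"file not found: {p}")
    values = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise CircatimeError(f"non-numeric expression cell in {matrix_path}: {exc}")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    missing = [c for c in REQUIRED_METADATA if c not in meta.columns]
    if missing:
        raise CircatimeError(f"{metadata_path}: missing metadata columns {missing}")
    only_matrix = values.columns.difference(meta.index)
    only_meta = meta.index.difference(values.columns)
    if len(only_matrix) or len(only_meta):
        raise CircatimeError(
            f"sample id mismatch: in matrix only {list(only_matrix)[:5]}, "
            f"in metadata only {list(only_meta)[:5]}"
        )
    meta = meta.loc[values.columns]
    ht = meta["harvest_time_hours"].astype(float)
    wrapped = (ht < 0) | (ht >= 24)
    if wrapped.any():
        warnings.warn(
            f"harvest times outside [0, 24) wrapped for samples "
            f"{list(meta.index[wrapped])[:5]}",
            stacklevel=2,
        )
        meta["harvest_time_hours"] = ht % 24.0
    return ExpressionMatrix(values, meta)


@dataclass
class PipelineConfig:
    """Validated settings for a pipeline run, loadable from YAML/JSON.

    Numeric settings are checked against the module preconditions at load
    time and all violations reported in a single error.
    """

    matrix_path: str | None = None
    metadata_path: str | None = None
    output_dir: str = "circatime_out"
    bundle_period_hours: float = 24.0
    bundle_increment_hours: float = 1.0 / 6.0
    selection_mode: str = "LDDD_05"
    r_cutoff: float = 0.5
    cv_cutoff: float = 0.20
    outlier_threshold_hours: float = 3.4
    window_grid_step_minutes: float = 1.0
    simulation: dict = field(default_factory=dict)
    line_effects: list = field(default_factory=list)
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        errors = []
        if self.bundle_period_hours <= 0 or self.bundle_increment_hours <= 0:
            errors.append("bundle period and increment must be positive")
        else:
            n = self.bundle_period_hours / self.bundle_increment_hours
            if abs(n - round(n)) > 1e-9:
                errors.append("bundle period must be a multiple of the increment")
        if not -1.0 <= self.r_cutoff <= 1.0:
            errors.append(f"r_cutoff must lie in [-1, 1], got {self.r_cutoff}")
        if self.cv_cutoff < 0:
            errors.append("cv_cutoff must be non-negative")
        if self.outlier_threshold_hours <= 0:
            errors.append("outlier_threshold_hours must be positive")
        if self.window_grid_step_minutes <= 0:
            errors.append("window_grid_step_minutes must be positive")
        if self.selection_mode not in ("LDDD_05", "LD_DD_05"):
            errors.append(f"unknown selection_mode {self.selection_mode!r}")
        if errors:
            raise CircatimeError("invalid configuration: " + "; ".join(errors))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise CircatimeError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def write_manifest(output_dir, config: PipelineConfig | dict, stage: str) -> Path:
    """Drop a JSON manifest (settings, seed, version) next to stage outputs."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "stage": stage,
        "version": __version__,
        "settings": config.to_dict() if isinstance(config, PipelineConfig) else config,
    }
    path = output_dir / f"{stage}_manifest.json"
    path.write_text(json.dumps(payload, indent=1, default=str))
    return path
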