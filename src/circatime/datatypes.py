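"""Core containers shared across the pipeline.

Expression data travel as a genes-by-samples table bound to per-sample
metadata (line, tissue, harvest time, light regime, replicate).  Times are
hours; harvest times live on the circular [0, 24) axis (ZT under light-dark,
CT under constant darkness, one common axis), while ``time_hours`` keeps the
wall-clock hours since the start of the experiment for multi-day series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every ExpressionMatrix must carry
REQUIRED_METADATA = ("line_id", "tissue", "harvest_time_hours", "regime", "replicate")


class CircatimeError(ValueError):
    """Base class for input-contract violations raised by this package."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    samples
        DataFrame indexed by sample id with at least the columns in
        :data:`REQUIRED_METADATA`; an optional ``time_hours`` column keeps
        wall-clock time for series longer than one day (it defaults to the
        harvest time).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        v, s = self.values, self.samples
        if v.index.has_duplicates:
            raise CircatimeError("duplicate gene ids in expression matrix")
        if v.columns.has_duplicates or s.index.has_duplicates:
            raise CircatimeError("duplicate sample ids")
        if list(v.columns) != list(s.index):
            raise CircatimeError(
                "sample ids of matrix columns and metadata rows do not match"
            )
        missing = [c for c in REQUIRED_METADATA if c not in s.columns]
        if missing:
            raise CircatimeError(f"metadata missing required columns: {missing}")
        arr = v.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(arr)):
            bad = v.columns[np.argwhere(~np.isfinite(arr))[0][1]]
            raise CircatimeError(f"non-finite expression value (first in sample {bad!r})")
        ht = s["harvest_time_hours"].to_numpy(dtype=float)
        if np.any((ht < 0) | (ht >= 24)):
            raise CircatimeError("harvest_time_hours must lie in [0, 24)")
        if "time_hours" not in s.columns:
            self.samples = s = s.assign(time_hours=s["harvest_time_hours"])

    # -- conveniences -----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Wall-clock sampling times in hours (one per sample)."""
        return self.samples["time_hours"].to_numpy(dtype=float)

    @property
    def harvest_times(self) -> np.ndarray:
        return self.samples["harvest_time_hours"].to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(self.values[sample_ids], self.samples.loc[sample_ids])

    def drop_sample(self, sample_id: str) -> "ExpressionMatrix":
        keep = [s for s in self.sample_ids if s != sample_id]
        return self.subset_samples(keep)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.samples)


def circular_difference(t_a: float, t_b: float, period: float = 24.0):
    """Signed circular difference ``t_a - t_b`` mapped to ``(-period/2, period/2]``.

    Positive means ``t_a`` is ahead of ``t_b``; the antipode maps to
    ``+period/2``.  Works elementwise on arrays.
    """
    d = np.mod(np.asarray(t_a, dtype=float) - np.asarray(t_b, dtype=float), period)
    d = np.where(d > period / 2, d - period, d)
    return float(d) if d.ndim == 0 else d
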