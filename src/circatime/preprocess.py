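"""Per-gene transformations applied ahead of rhythm detection.

Unit-interval scaling puts every gene on a comparable [0, 1] range before
correlation-based phase inference; the coefficient of variation (CV),
computed on the *unscaled* values, serves as the amplitude filter for
time-indicating-gene selection (scaling would destroy the mean the CV
needs).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CircatimeError, ExpressionMatrix

__all__ = [
    "scale_unit_interval",
    "coefficient_of_variation",
    "gene_summaries",
    "average_replicates",
]

logger = logging.getLogger(__name__)


def scale_unit_interval(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene linearly so its minimum is 0 and its maximum is 1.

    Constant genes have no defined scaling; they are dropped from the output
    with a logged warning rather than propagating NaNs.
    """
    v = matrix.values
    lo = v.min(axis=1)
    hi = v.max(axis=1)
    constant = hi - lo == 0
    if constant.any():
        dropped = list(v.index[constant])
        logger.warning(
            "scale_unit_interval: dropped %d constant gene(s): %s",
            len(dropped), ", ".join(map(str, dropped[:10])),
        )
        v = v.loc[~constant]
        lo, hi = lo[~constant], hi[~constant]
    if v.empty:
        raise CircatimeError("all genes constant; nothing to scale")
    scaled = v.sub(lo, axis=0).div(hi - lo, axis=0)
    return ExpressionMatrix(scaled, matrix.samples)


def coefficient_of_variation(trace) -> float:
    """Sample CV (SD with n-1 denominator over mean) of one expression trace.

    Defined only for traces with a positive mean.
    """
    x = np.asarray(trace, dtype=float)
    m = x.mean()
    if m <= 0:
        raise CircatimeError("CV undefined: trace mean is not positive")
    return float(x.std(ddof=1) / m)


def gene_summaries(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean, SD, CV and a flag for genes whose CV is undefined."""
    v = matrix.values
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    cv = pd.Series(np.where(mean > 0, sd / mean, np.nan), index=v.index)
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "cv": cv, "cv_defined": mean > 0}
    )


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicates to their arithmetic mean per (tissue, timepoint).

    Tolerates unequal replicate counts across timepoints; the collapsed
    metadata keeps one row per group with ``replicate`` set to the count
    averaged.
    """
    s = matrix.samples
    keys = list(zip(s["tissue"], s["time_hours"]))
    groups: dict[tuple, list[str]] = {}
    for sid, key in zip(s.index, keys):
        groups.setdefault(key, []).append(sid)
    new_cols, new_meta = {}, []
    for (tissue, t), sids in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        new_id = f"{tissue}_t{t:g}"
        new_cols[new_id] = matrix.values[sids].mean(axis=1)
        row = s.loc[sids[0]].copy()
        row["replicate"] = len(sids)
        row.name = new_id
        new_meta.append(row)
    values = pd.DataFrame(new_cols)
    samples = pd.DataFrame(new_meta)
    samples.index.name = "sample_id"
    return ExpressionMatrix(values, samples)
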