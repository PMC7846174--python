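"""The modified molecular timetable (MTT) method.

The molecular timetable method infers the internal circadian time of a
*single* static expression profile.  Training correlates each gene's time
course against a bundle of artificial cosine waves of one period whose peak
times tile the day in fixed increments (144 waves at the reference settings
of a 24-hour period and 10-minute increments).  Genes whose best correlation
exceeds a cutoff (default 0.5) and whose coefficient of variation exceeds an
amplitude cutoff (default 0.20) become time-indicating genes (TIGs); the
peak time of each TIG's best-correlated wave is its molecular peak time
(MPT).  Prediction correlates a test sample's TIG values against cosine
templates anchored at the MPTs for every candidate time on the bundle grid;
the best-correlated candidate is the sample's physiological time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CircatimeError, ExpressionMatrix, circular_difference
from .preprocess import gene_summaries

__all__ = [
    "CosineBundle",
    "TimetableModel",
    "PhasePrediction",
    "TimetableError",
    "build_cosine_bundle",
    "rhythmicity_score",
    "select_tigs",
    "predict_time",
    "predict_times",
    "circular_difference",
]

_EPS = 1e-12


class TimetableError(CircatimeError):
    """Raised when the timetable cannot be built or applied."""


@dataclass(frozen=True)
class CosineBundle:
    """Ordered family of unit cosine waves tiling one period.

    Wave ``k`` peaks at ``k * increment_hours``; its value at time ``t`` is
    ``cos(2*pi*(t - peak)/period)``.
    """

    period_hours: float
    increment_hours: float
    peak_times: np.ndarray

    @property
    def n_waves(self) -> int:
        return self.peak_times.size

    def wave_matrix(self, times: np.ndarray) -> np.ndarray:
        """(n_waves, n_times) matrix of wave values at the given times."""
        t = np.asarray(times, dtype=float)
        return np.cos(
            2 * np.pi * (t[None, :] - self.peak_times[:, None]) / self.period_hours
        )


def build_cosine_bundle(period_hours: float = 24.0,
                        increment_hours: float = 1.0 / 6.0) -> CosineBundle:
    """Build the reference wave bundle (24 h / 10 min gives 144 waves)."""
    if period_hours <= 0 or increment_hours <= 0:
        raise TimetableError("period and increment must be positive")
    n = period_hours / increment_hours
    if abs(n - round(n)) > 1e-9:
        raise TimetableError(
            f"period ({period_hours} h) must be an integer multiple of the "
            f"increment ({increment_hours} h)"
        )
    n = int(round(n))
    peaks = np.arange(n) * increment_hours
    return CosineBundle(float(period_hours), float(increment_hours), peaks)


def _row_standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; return (standardized, valid mask)."""
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1, keepdims=True)
    valid = norm[:, 0] > _EPS
    xc = np.divide(xc, np.where(norm > _EPS, norm, 1.0))
    return xc, valid


def _correlate_rows(traces: np.ndarray, waves: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson r of every trace row against every wave row.

    Returns (r_max, argmax wave index, valid mask).  Ties at the maximum
    resolve to the smallest wave index because argmax takes the first hit
    and peak times are strictly increasing.
    """
    tn, t_ok = _row_standardize(traces)
    wn, _ = _row_standardize(waves)
    r = tn @ wn.T
    idx = np.argmax(r, axis=1)
    return r[np.arange(r.shape[0]), idx], idx, t_ok


def rhythmicity_score(trace, times, bundle: CosineBundle) -> tuple[float, float]:
    """Best correlation of one trace against the wave bundle.

    Returns ``(r_max, best_peak_time)``; ties break to the smallest peak
    time.  Constant traces carry no phase information and are rejected.
    """
    x = np.atleast_2d(np.asarray(trace, dtype=float))
    t = np.asarray(times, dtype=float)
    if t.size < 3:
        raise TimetableError("need at least 3 timepoints to score rhythmicity")
    r_max, idx, ok = _correlate_rows(x, bundle.wave_matrix(t))
    if not ok[0]:
        raise TimetableError("constant trace: rhythmicity undefined")
    return float(r_max[0]), float(bundle.peak_times[idx[0]])


@dataclass
class TimetableModel:
    """Trained timetable: the TIG table plus its selection settings.

    ``tigs`` is indexed by gene id with columns ``mpt_hours`` (molecular
    peak time), ``r_max`` and ``cv``.
    """

    tigs: pd.DataFrame
    bundle: CosineBundle
    selection_mode: str = "LDDD_05"
    r_cutoff: float = 0.5
    cv_cutoff: float = 0.20

    def __post_init__(self) -> None:
        if len(self.tigs) < 2 or self.tigs["mpt_hours"].nunique() < 2:
            raise TimetableError(
                "timetable unusable: need >= 2 TIGs with >= 2 distinct MPTs "
                f"(got {len(self.tigs)} TIGs)"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.tigs.index

    # -- persistence ------------------------------------------------------
    def save(self, table_path, settings_path=None) -> None:
        """Write the TIG table as TSV and the settings as a JSON sidecar."""
        table_path = Path(table_path)
        self.tigs.rename_axis("gene_id").to_csv(table_path, sep="\t")
        settings = {
            "selection_mode": self.selection_mode,
            "r_cutoff": self.r_cutoff,
            "cv_cutoff": self.cv_cutoff,
            "bundle_period_hours": self.bundle.period_hours,
            "bundle_increment_hours": self.bundle.increment_hours,
        }
        sp = Path(settings_path) if settings_path else table_path.with_suffix(".json")
        sp.write_text(json.dumps(settings, indent=1))

    @classmethod
    def load(cls, table_path, settings_path=None) -> "TimetableModel":
        table_path = Path(table_path)
        tigs = pd.read_csv(table_path, sep="\t", index_col="gene_id")
        sp = Path(settings_path) if settings_path else table_path.with_suffix(".json")
        s = json.loads(sp.read_text())
        return cls(
            tigs,
            build_cosine_bundle(s["bundle_period_hours"], s["bundle_increment_hours"]),
            s["selection_mode"],
            s["r_cutoff"],
            s["cv_cutoff"],
        )


@dataclass
class PhasePrediction:
    """Inferred physiological time of one sample."""

    sample_id: str
    predicted_time_hours: float
    r_at_max: float
    harvest_time_hours: float | None = None
    signed_diff_hours: float | None = None
    outlier: bool | None = None


def _passes_filters(matrix: ExpressionMatrix, bundle: CosineBundle,
                    r_cutoff: float, cv_cutoff: float):
    """Boolean TIG mask plus per-gene (r_max, best peak) on this sample set."""
    values = matrix.values.to_numpy(dtype=float)
    r_max, idx, ok = _correlate_rows(values, bundle.wave_matrix(matrix.times))
    summ = gene_summaries(matrix)
    cv_ok = summ["cv_defined"].to_numpy() & (summ["cv"].to_numpy() > cv_cutoff)
    passes = ok & (r_max > r_cutoff) & cv_ok
    return passes, r_max, bundle.peak_times[idx], summ["cv"].to_numpy()


def select_tigs(
    matrix: ExpressionMatrix,
    mode: str = "LDDD_05",
    r_cutoff: float = 0.5,
    cv_cutoff: float = 0.20,
    bundle: CosineBundle | None = None,
) -> TimetableModel:
    """Select time-indicating genes and record their molecular peak times.

    ``LDDD_05`` treats the full series as one unit; ``LD_DD_05`` applies the
    rhythmicity and amplitude filters separately within the LD and the DD
    portion and keeps only genes passing in both, with the MPT taken from
    the unified fit.
    """
    bundle = bundle or build_cosine_bundle()
    if matrix.n_samples < 3:
        raise TimetableError("need at least 3 samples to select TIGs")
    passes, r_max, peaks, cv = _passes_filters(matrix, bundle, r_cutoff, cv_cutoff)
    if mode == "LDDD_05":
        keep = passes
    elif mode == "LD_DD_05":
        regimes = matrix.samples["regime"].to_numpy()
        keep = passes.copy()
        for regime in ("LD", "DD"):
            sub_ids = matrix.sample_ids[regimes == regime]
            if len(sub_ids) < 3:
                raise TimetableError(f"LD_DD_05 mode needs >= 3 samples per regime "
                                     f"(got {len(sub_ids)} in {regime})")
            sub_pass, _, _, _ = _passes_filters(
                matrix.subset_samples(sub_ids), bundle, r_cutoff, cv_cutoff
            )
            keep &= sub_pass
    else:
        raise TimetableError(f"unknown selection mode {mode!r}")
    tigs = pd.DataFrame(
        {"mpt_hours": peaks[keep], "r_max": r_max[keep], "cv": cv[keep]},
        index=matrix.gene_ids[keep],
    )
    return TimetableModel(tigs, bundle, mode, r_cutoff, cv_cutoff)


def _candidate_templates(model: TimetableModel) -> np.ndarray:
    """(n_candidates, n_tigs) cosine templates anchored at the MPTs."""
    mpt = model.tigs["mpt_hours"].to_numpy()
    phi = model.bundle.peak_times
    return np.cos(
        2 * np.pi * (mpt[None, :] - phi[:, None]) / model.bundle.period_hours
    )


def predict_times(model: TimetableModel, values: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`predict_time` over the columns of a TIG-value table.

    ``values`` rows must cover the model's TIGs (extra genes are ignored).
    Returns a DataFrame indexed by sample id with ``predicted_time_hours``
    and ``r_at_max``.
    """
    missing = model.gene_ids.difference(values.index)
    if len(missing):
        raise TimetableError(f"sample lacks values for TIGs: {list(missing)[:5]} ...")
    x = values.loc[model.gene_ids].to_numpy(dtype=float).T  # samples x tigs
    xn, ok = _row_standardize(x)
    if not ok.all():
        bad = list(values.columns[~ok])
        raise TimetableError(f"zero-variance TIG vector for sample(s) {bad[:5]}")
    tn, _ = _row_standardize(_candidate_templates(model))
    r = xn @ tn.T  # samples x candidates
    idx = np.argmax(r, axis=1)  # ties -> smallest candidate time
    return pd.DataFrame(
        {
            "predicted_time_hours": model.bundle.peak_times[idx],
            "r_at_max": r[np.arange(r.shape[0]), idx],
        },
        index=values.columns,
    )


def predict_time(
    model: TimetableModel,
    sample: pd.Series,
    sample_id: str = "sample",
    harvest_time_hours: float | None = None,
) -> PhasePrediction:
    """Infer the physiological time of one static sample.

    ``sample`` maps gene id to expression value and must cover the model's
    TIGs.  If the harvest time is given, the signed circular difference is
    filled in (positive = predicted ahead of harvest).
    """
    res = predict_times(model, sample.to_frame(name=sample_id))
    pred = float(res.iloc[0, 0])
    diff = None
    if harvest_time_hours is not None:
        diff = circular_difference(pred, harvest_time_hours)
    return PhasePrediction(sample_id, pred, float(res.iloc[0, 1]),
                           harvest_time_hours, diff)
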