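"""Benchmarking of a physiological-time predictor.

Three pieces: leave-one-out (LOO) calibration of prediction error against a
reference time course, outlier flagging of static samples whose inferred
time deviates from the harvest time by more than a calibrated threshold
(default 3.4 h, three SDs of the LOO error distribution), and the
detection-window simulation that asks *at which harvest times* a line with
an aberrant molecular clock is distinguishable from the reference at all.

The harness is predictor-agnostic: any factory that maps a training
:class:`~circatime.datatypes.ExpressionMatrix` to a ``sample -> hours``
callable can be evaluated; the default factory is the molecular timetable
method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .datatypes import CircatimeError, ExpressionMatrix, circular_difference
from .preprocess import scale_unit_interval
from .simulate import SimulationConfig, generate_reference_timecourse
from .timetable import TimetableModel, predict_times, select_tigs

__all__ = [
    "EvaluationReport",
    "WindowResult",
    "timetable_predictor_factory",
    "loo_evaluate",
    "flag_outliers",
    "detection_window",
]

DEFAULT_OUTLIER_THRESHOLD_HOURS = 3.4


def timetable_predictor_factory(
    mode: str = "LDDD_05",
    r_cutoff: float = 0.5,
    cv_cutoff: float = 0.20,
    bundle=None,
) -> Callable[[ExpressionMatrix], Callable[[pd.Series], float]]:
    """Default predictor factory: full timetable training on each fold."""

    def factory(train: ExpressionMatrix) -> Callable[[pd.Series], float]:
        model = select_tigs(train, mode=mode, r_cutoff=r_cutoff,
                            cv_cutoff=cv_cutoff, bundle=bundle)

        def predict(sample: pd.Series) -> float:
            res = predict_times(model, sample.to_frame(name="held_out"))
            return float(res["predicted_time_hours"].iloc[0])

        return predict

    return factory


@dataclass
class EvaluationReport:
    """LOO error summary: per-sample differences and their calibration.

    ``precision_hours`` is three SDs of the signed differences — the
    conservative radius within which a prediction for a normal sample is
    expected to land.
    """

    per_sample: pd.DataFrame
    mean_abs_diff_hours: float
    sd_signed_diff_hours: float
    precision_hours: float
    per_tissue: pd.DataFrame
    failures: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "mean_abs_diff_hours": self.mean_abs_diff_hours,
            "sd_signed_diff_hours": self.sd_signed_diff_hours,
            "precision_hours": self.precision_hours,
            "n_samples": int(len(self.per_sample)),
            "n_failures": len(self.failures),
        }


def _summarize(per_sample: pd.DataFrame, failures: list) -> EvaluationReport:
    d = per_sample["signed_diff_hours"]
    sd = float(d.std(ddof=1)) if len(d) > 1 else float("nan")
    per_tissue = per_sample.groupby("tissue")["signed_diff_hours"].agg(
        mean_abs_diff_hours=lambda x: float(np.abs(x).mean()),
        sd_signed_diff_hours=lambda x: float(x.std(ddof=1)),
        n="size",
    )
    return EvaluationReport(
        per_sample=per_sample,
        mean_abs_diff_hours=float(np.abs(d).mean()),
        sd_signed_diff_hours=sd,
        precision_hours=3.0 * sd,
        per_tissue=per_tissue,
        failures=failures,
    )


def loo_evaluate(
    reference: ExpressionMatrix,
    predictor_factory: Callable | None = None,
    scale: bool = True,
) -> EvaluationReport:
    """Leave-one-out benchmark of a time predictor on a reference series.

    Tissues are evaluated independently: each held-out sample is predicted
    by a predictor retrained from scratch on the remaining samples of the
    same tissue.  Expression is 0-1 scaled per gene across the full set
    before the procedure.  A predictor failure on a fold is recorded and the
    fold skipped rather than aborting the benchmark.
    """
    factory = predictor_factory or timetable_predictor_factory()
    rows, failures = [], []
    for tissue, ids in reference.samples.groupby("tissue").groups.items():
        sub = reference.subset_samples(ids)
        if sub.n_samples < 3:
            raise CircatimeError(f"tissue {tissue!r} has < 3 samples")
        if scale:
            sub = scale_unit_interval(sub)
        for sid in sub.sample_ids:
            train = sub.drop_sample(sid)
            harvest = float(sub.samples.loc[sid, "harvest_time_hours"])
            try:
                predict = factory(train)
                pred = float(predict(sub.values[sid]))
            except CircatimeError as exc:
                failures.append((sid, str(exc)))
                continue
            rows.append(
                {
                    "sample_id": sid,
                    "tissue": tissue,
                    "harvest_time_hours": harvest,
                    "predicted_time_hours": pred,
                    "signed_diff_hours": circular_difference(pred, harvest),
                }
            )
    if not rows:
        raise CircatimeError("every LOO fold failed; no report to build")
    return _summarize(pd.DataFrame(rows).set_index("sample_id"), failures)


def flag_outliers(
    predictions: pd.DataFrame,
    threshold_hours: float = DEFAULT_OUTLIER_THRESHOLD_HOURS,
) -> pd.DataFrame:
    """Flag samples whose |predicted - harvest| strictly exceeds the threshold.

    ``predictions`` needs a ``signed_diff_hours`` column; a copy with a
    boolean ``outlier`` column is returned.  The inequality is strict: a
    difference exactly at the threshold is not an outlier.
    """
    if threshold_hours <= 0:
        raise CircatimeError("threshold_hours must be positive")
    out = predictions.copy()
    out["outlier"] = np.abs(out["signed_diff_hours"].to_numpy()) > threshold_hours
    return out


@dataclass
class WindowResult:
    """Outcome of the detection-window simulation for one aberrant line."""

    period_hours: float
    phase_offset_hours: float
    amplitude_to_noise: float
    threshold_hours: float
    grid_hours: np.ndarray
    predicted_hours: np.ndarray
    signed_diff_hours: np.ndarray
    flagged: np.ndarray

    @property
    def window_hours(self) -> float:
        """Total flagged duration over one day."""
        step = self.grid_hours[1] - self.grid_hours[0]
        return float(self.flagged.sum() * step)

    def to_json_dict(self) -> dict:
        return {
            "period_hours": self.period_hours,
            "phase_offset_hours": self.phase_offset_hours,
            "threshold_hours": self.threshold_hours,
            "window_hours": round(self.window_hours, 1),
            "window_hours_rounded": int(round(self.window_hours)),
        }


def _default_window_config(seed: int = 0) -> SimulationConfig:
    # noiseless, all genes cycling with phases tiling the day: the idealized
    # timetable the simulation probes
    return SimulationConfig(
        n_genes=12,
        cycler_fraction=1.0,
        amplitude=100.0,
        mesor=200.0,
        amplitude_to_noise=math.inf,
        sampling_interval_hours=2.0,
        duration_hours=24.0,
        replicates=1,
        seed=seed,
    )


def detection_window(
    period_hours: float,
    phase_offset_hours: float = 0.0,
    config: SimulationConfig | None = None,
    threshold_hours: float = DEFAULT_OUTLIER_THRESHOLD_HOURS,
    grid_step_minutes: float = 1.0,
    model: TimetableModel | None = None,
) -> WindowResult:
    """How long per day is a clock-deviant line detectably out of phase?

    A timetable is trained on a one-day reference generated from ``config``
    (noiseless by default).  For every harvest time ``t`` on a fine grid
    over [0, 24) the line's TIG vector is generated at internal time
    ``tau = (24/period) * (t + offset)``, its physiological time predicted,
    and ``t`` flagged when the circular difference from the harvest time
    strictly exceeds the threshold.  The window is the total flagged
    duration.
    """
    if period_hours <= 0:
        raise CircatimeError("period_hours must be positive")
    config = config or _default_window_config()
    reference, truth = generate_reference_timecourse(config)
    if model is None:
        model = select_tigs(reference, mode="LDDD_05")
    grid = np.arange(0.0, 24.0, grid_step_minutes / 60.0)
    tau = (config.period_hours / period_hours) * (grid + phase_offset_hours)
    tig_truth = truth.loc[model.gene_ids]
    phase = tig_truth["phase_hours"].to_numpy()[:, None]
    amp = tig_truth["amplitude"].to_numpy()[:, None]
    mesor = tig_truth["mesor"].to_numpy()[:, None]
    values = mesor + amp * np.cos(
        2 * np.pi * (tau[None, :] - phase) / config.period_hours
    )
    if config.noise_sd:
        rng = np.random.default_rng(config.seed + 1)
        values = values + rng.normal(0.0, config.noise_sd, values.shape)
    frame = pd.DataFrame(values, index=model.gene_ids,
                         columns=[f"t{i}" for i in range(grid.size)])
    res = predict_times(model, frame)
    pred = res["predicted_time_hours"].to_numpy()
    diff = circular_difference(pred, grid)
    flagged = np.abs(diff) > threshold_hours
    return WindowResult(
        period_hours=float(period_hours),
        phase_offset_hours=float(phase_offset_hours),
        amplitude_to_noise=config.amplitude_to_noise,
        threshold_hours=float(threshold_hours),
        grid_hours=grid,
        predicted_hours=pred,
        signed_diff_hours=diff,
        flagged=flagged,
    )
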