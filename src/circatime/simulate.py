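"""Synthetic circadian expression data.

Three designs are emulated so every downstream stage can be exercised
without real sequencing data:

* a **reference time course** — sampling every ``sampling_interval_hours``
  over ``duration_hours`` in ``replicates`` replicates, one light-dark day
  followed by one constant-darkness day by default;
* a **static cohort** — one sample per genetic line, lines harvested on a
  fine arithmetic time grid (~minutes apart) so the cohort as a whole tiles
  the day even though each line is seen once;
* a **deviating trace** — a single sinusoid with configurable period and
  phase offset on a 10-minute grid over one day, the classical set-up for
  asking when an aberrant clock is distinguishable from a normal one.

Cycling genes follow ``mesor + amplitude * cos(2*pi*(t - phase)/period)``
with additive i.i.d. Gaussian noise of standard deviation
``amplitude / amplitude_to_noise``; non-cycling genes are mesor plus noise.
A line with intrinsic period ``P`` and phase advance ``dt`` experiences
internal clock time ``tau = (24/P) * (t + dt)`` (clocks aligned at t = 0),
and its genes express the reference waveform evaluated at ``tau``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import CircatimeError, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "LineEffect",
    "generate_reference_timecourse",
    "generate_static_cohort",
    "make_deviating_trace",
]

_GRID_TOL = 1e-9


@dataclass
class SimulationConfig:
    """Settings of the synthetic expression generator.

    ``amplitude_to_noise`` (ANR) is the ratio of the cycling amplitude to the
    Gaussian noise SD; ``math.inf`` switches noise off entirely.  The default
    design mirrors a 2-hour / 48-hour / triplicate reference series with one
    LD day followed by one DD day.
    """

    n_genes: int = 100
    cycler_fraction: float = 0.2
    period_hours: float = 24.0
    amplitude: float = 100.0
    mesor: float = 200.0
    amplitude_to_noise: float = 4.0
    sampling_interval_hours: float = 2.0
    duration_hours: float = 48.0
    replicates: int = 3
    start_time_hours: float = 0.0
    regime_schedule: tuple = ((0, "LD"), (1, "DD"))
    seed: int = 0
    allow_negative_baseline: bool = False

    def __post_init__(self) -> None:
        errors = []
        if self.n_genes < 1:
            errors.append("n_genes must be >= 1")
        if not 0.0 <= self.cycler_fraction <= 1.0:
            errors.append("cycler_fraction must lie in [0, 1]")
        if self.period_hours <= 0:
            errors.append("period_hours must be positive")
        if self.mesor <= 0:
            errors.append("mesor must be positive")
        if self.amplitude < 0:
            errors.append("amplitude must be non-negative")
        if not self.amplitude_to_noise > 0:
            errors.append("amplitude_to_noise must be positive (inf = noiseless)")
        if self.sampling_interval_hours <= 0 or self.duration_hours <= 0:
            errors.append("sampling interval and duration must be positive")
        else:
            n = self.duration_hours / self.sampling_interval_hours
            if abs(n - round(n)) > _GRID_TOL:
                errors.append(
                    "duration_hours must be an integer multiple of "
                    "sampling_interval_hours"
                )
        if self.replicates < 1:
            errors.append("replicates must be >= 1")
        if not 0.0 <= self.start_time_hours < 24.0:
            errors.append("start_time_hours must lie in [0, 24)")
        if self.mesor < self.amplitude and not self.allow_negative_baseline:
            errors.append(
                "mesor < amplitude would allow negative expression; set "
                "allow_negative_baseline=True to permit it"
            )
        if errors:
            raise CircatimeError("; ".join(errors))

    @property
    def noise_sd(self) -> float:
        if math.isinf(self.amplitude_to_noise):
            return 0.0
        return self.amplitude / self.amplitude_to_noise

    @property
    def n_timepoints(self) -> int:
        return int(round(self.duration_hours / self.sampling_interval_hours))

    def regime_at(self, wall_time: float) -> str:
        day = int(wall_time // 24)
        schedule = dict(self.regime_schedule)
        return schedule.get(day, self.regime_schedule[-1][1])


@dataclass
class LineEffect:
    """Genotype effect of one line on its molecular clock.

    ``phase_offset_hours`` is a clock *advance* (positive = line ahead of
    the reference), interpreted modulo the line's own period.  ``disrupted``
    multiplies the cycling amplitude by ``damping`` (default 0: flat clock).
    """

    line_id: str
    phase_offset_hours: float = 0.0
    period_hours: float = 24.0
    disrupted: bool = False
    damping: float = 0.0

    def __post_init__(self) -> None:
        if self.period_hours <= 0:
            raise CircatimeError(f"line {self.line_id}: period must be positive")
        self.phase_offset_hours = self.phase_offset_hours % self.period_hours


def _gene_truth(config: SimulationConfig, true_phases) -> pd.DataFrame:
    """Per-gene ground truth: cycling flag, phase, amplitude, mesor."""
    n_cyc = int(round(config.cycler_fraction * config.n_genes))
    if n_cyc < 2:
        raise CircatimeError("need at least 2 cycling genes (cycler_fraction * n_genes >= 2)")
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    phases = np.full(config.n_genes, np.nan)
    if isinstance(true_phases, str):
        if true_phases != "uniform":
            raise CircatimeError(f"unknown phase scheme {true_phases!r}")
        # even tiling of the day keeps the timetable informative at every hour
        phases[:n_cyc] = np.arange(n_cyc) * 24.0 / n_cyc
    else:
        arr = np.asarray(true_phases, dtype=float)
        if arr.shape != (n_cyc,):
            raise CircatimeError(f"true_phases must have length {n_cyc}")
        phases[:n_cyc] = arr % 24.0
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_cycling": [i < n_cyc for i in range(config.n_genes)],
            "phase_hours": phases,
            "amplitude": np.where(np.arange(config.n_genes) < n_cyc, config.amplitude, 0.0),
            "mesor": config.mesor,
        }
    ).set_index("gene_id")


def _signal_matrix(truth: pd.DataFrame, internal_times: np.ndarray,
                   period: float, damping: np.ndarray | float = 1.0) -> np.ndarray:
    """Noiseless expression of every gene at the given internal clock times."""
    phase = truth["phase_hours"].to_numpy()[:, None]
    amp = truth["amplitude"].to_numpy()[:, None] * damping
    mesor = truth["mesor"].to_numpy()[:, None]
    wave = np.cos(2 * np.pi * (internal_times[None, :] - phase) / period)
    return mesor + np.where(np.isnan(phase), 0.0, amp * np.nan_to_num(wave))


def generate_reference_timecourse(
    config: SimulationConfig,
    true_phases="uniform",
    tissue: str = "tissue",
    line_id: str = "reference",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the reference time series the timetable is trained on.

    Returns the expression matrix and a per-gene ground-truth table
    (cycling flag, phase, amplitude, mesor).  Reproducible given
    ``config.seed``.
    """
    truth = _gene_truth(config, true_phases)
    times = config.start_time_hours + config.sampling_interval_hours * np.arange(
        config.n_timepoints
    )
    wall = np.repeat(times, config.replicates)
    replicate = np.tile(np.arange(1, config.replicates + 1), config.n_timepoints)
    rng = np.random.default_rng(config.seed)
    signal = _signal_matrix(truth, wall, config.period_hours)
    noise = rng.normal(0.0, config.noise_sd, signal.shape) if config.noise_sd else 0.0
    sample_ids = [f"s{i:03d}" for i in range(wall.size)]
    samples = pd.DataFrame(
        {
            "line_id": line_id,
            "tissue": tissue,
            "time_hours": wall,
            "harvest_time_hours": wall % 24.0,
            "regime": [config.regime_at(t) for t in wall],
            "replicate": replicate,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame(signal + noise, index=truth.index, columns=sample_ids)
    return ExpressionMatrix(values, samples), truth


def generate_static_cohort(
    config: SimulationConfig,
    effects: Sequence[LineEffect],
    interval_minutes: float = 9.0,
    true_phases="uniform",
    tissue: str = "tissue",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a one-sample-per-line cohort harvested on a fine time grid.

    Line ``i`` is harvested at ``start + i * interval_minutes`` (mod 24 h);
    its genes express the reference waveform at internal time
    ``(24/P_i) * (t + offset_i)``, with amplitude damped for disrupted
    clocks.  Returns the matrix and a per-line ground-truth table.
    """
    if not effects:
        raise CircatimeError("effects list must contain at least one line")
    if interval_minutes <= 0:
        raise CircatimeError("interval_minutes must be positive")
    truth = _gene_truth(config, true_phases)
    n = len(effects)
    harvest = (config.start_time_hours + interval_minutes / 60.0 * np.arange(n)) % 24.0
    rng = np.random.default_rng(config.seed)
    cols = np.empty((config.n_genes, n))
    for j, (eff, t) in enumerate(zip(effects, harvest)):
        tau = (config.period_hours / eff.period_hours) * (t + eff.phase_offset_hours)
        damping = eff.damping if eff.disrupted else 1.0
        cols[:, j] = _signal_matrix(
            truth, np.array([tau]), config.period_hours, damping
        )[:, 0]
    if config.noise_sd:
        cols = cols + rng.normal(0.0, config.noise_sd, cols.shape)
    sample_ids = [f"{eff.line_id}" for eff in effects]
    if len(set(sample_ids)) != n:
        raise CircatimeError("duplicate line ids in effects list")
    samples = pd.DataFrame(
        {
            "line_id": sample_ids,
            "tissue": tissue,
            "time_hours": harvest,
            "harvest_time_hours": harvest,
            "regime": [config.regime_at(t) for t in harvest],
            "replicate": 1,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame(cols, index=truth.index, columns=sample_ids)
    line_truth = pd.DataFrame(
        {
            "line_id": sample_ids,
            "harvest_time_hours": harvest,
            "phase_offset_hours": [e.phase_offset_hours for e in effects],
            "period_hours": [e.period_hours for e in effects],
            "disrupted": [e.disrupted for e in effects],
        }
    ).set_index("line_id")
    return ExpressionMatrix(values, samples), line_truth


def make_deviating_trace(
    period_hours: float,
    phase_offset_hours: float,
    config: SimulationConfig,
    grid_minutes: float = 10.0,
) -> pd.Series:
    """One sinusoidal gene sampled on a fine half-open grid over one day.

    Returns ``amplitude * sin(2*pi*(t + offset)/period) + noise`` on the
    ``grid_minutes`` grid over [0, 24) — 144 points at the default 10-minute
    spacing.
    """
    if period_hours <= 0:
        raise CircatimeError("period_hours must be positive")
    step = grid_minutes / 60.0
    t = np.arange(0.0, 24.0 - _GRID_TOL, step)
    values = config.amplitude * np.sin(2 * np.pi * (t + phase_offset_hours) / period_hours)
    if config.noise_sd:
        rng = np.random.default_rng(config.seed)
        values = values + rng.normal(0.0, config.noise_sd, t.size)
    return pd.Series(values, index=pd.Index(t, name="time_hours"), name="trace")
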