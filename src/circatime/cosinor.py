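"""Single-component cosinor rhythmometry and rhythm comparison.

A trace is regressed on ``y = M + b1*cos(w t) + b2*sin(w t)`` with
``w = 2*pi/period`` and the period held fixed (24 h for circadian work).
The mesor is ``M``, the amplitude ``sqrt(b1^2 + b2^2)`` and the acrophase
— reported as a peak time in hours, not radians — is
``atan2(b2, b1)/w mod period``.  Standard errors for amplitude and
acrophase come from the linear-model covariance via the delta method.

On top of the fit sit three analyses used for inter-tissue and
inter-genotype comparisons: a zero-amplitude F-test as the in-repo
rhythmicity screen, a Wald test on the circular acrophase difference
between two fits (a shift is *called* only when it exceeds a biological
minimum, 2 h by default, AND survives FDR control), and a two-sided t test
comparing the amplitudes of the top-N cycling genes of two conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CircatimeError, ExpressionMatrix, circular_difference
from .preprocess import scale_unit_interval

__all__ = [
    "CosinorFit",
    "PhaseComparison",
    "CosinorError",
    "fit_cosinor",
    "detect_cycling",
    "compare_phases",
    "call_phase_shifts",
    "compare_amplitudes_top",
    "bh_fdr",
]


class CosinorError(CircatimeError):
    """Raised when a cosinor fit or comparison is undefined."""


@dataclass
class CosinorFit:
    """Least-squares cosinor estimates for one trace at a fixed period."""

    mesor: float
    amplitude: float
    acrophase_hours: float
    period_hours: float
    se_mesor: float
    se_amplitude: float
    se_acrophase_hours: float
    resid_var: float
    n: int
    rss: float
    tss: float

    @property
    def amplitude_z(self) -> float:
        """Amplitude over its SE (inf when the fit is exact)."""
        if self.se_amplitude == 0:
            return math.inf if self.amplitude > 0 else 0.0
        return self.amplitude / self.se_amplitude


def fit_cosinor(times, values, period_hours: float = 24.0) -> CosinorFit:
    """Fit a fixed-period cosinor to one trace by ordinary least squares.

    Needs at least 4 timepoints with a full-rank design (timestamps not all
    congruent modulo half the period).  Exact on noiseless cosine input.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise CosinorError("times and values must be equal-length 1-D arrays")
    n = t.size
    if n < 4:
        raise CosinorError("need at least 4 timepoints for a cosinor fit")
    w = 2 * np.pi / period_hours
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise CosinorError(
            "rank-deficient design: timestamps do not resolve phase "
            "(fewer than 3 informative timepoints modulo the period)"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    dof = n - 3
    sigma2 = rss / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    m, b1, b2 = beta
    amp = float(np.hypot(b1, b2))
    acro = float((math.atan2(b2, b1) / w) % period_hours)
    if amp > 0:
        # delta method: A = sqrt(b1^2+b2^2), phi = atan2(b2, b1)/w
        gA = np.array([0.0, b1 / amp, b2 / amp])
        gP = np.array([0.0, -b2 / amp**2, b1 / amp**2]) / w
        se_amp = float(np.sqrt(gA @ cov @ gA))
        se_acro = float(np.sqrt(gP @ cov @ gP))
    else:
        se_amp = float(np.sqrt(cov[1, 1] + cov[2, 2]) / np.sqrt(2))
        se_acro = float("inf")
    return CosinorFit(
        mesor=float(m),
        amplitude=amp,
        acrophase_hours=acro,
        period_hours=float(period_hours),
        se_mesor=float(np.sqrt(cov[0, 0])),
        se_amplitude=se_amp,
        se_acrophase_hours=se_acro,
        resid_var=float(sigma2),
        n=int(n),
        rss=rss,
        tss=tss,
    )


def zero_amplitude_pvalue(fit: CosinorFit) -> float:
    """F-test of the cosinor terms against a mesor-only model."""
    dof = fit.n - 3
    if dof <= 0:
        raise CosinorError("no residual degrees of freedom for the F-test")
    num = (fit.tss - fit.rss) / 2.0
    if fit.rss <= 1e-300 * max(fit.tss, 1.0):
        return 0.0 if num > 0 else 1.0
    f = num / (fit.rss / dof)
    return float(stats.f.sf(f, 2, dof))


def detect_cycling(
    matrix: ExpressionMatrix,
    period_hours: float = 24.0,
    alpha: float = 0.05,
    scale: bool = True,
) -> pd.DataFrame:
    """Cosinor rhythmicity screen: per-gene fit + zero-amplitude F-test.

    Genes are 0-1 scaled first (constant genes drop out), p-values are
    BH-adjusted, and a gene is called cycling when ``q < alpha``.  Returns
    a per-gene table (mesor, amplitude, acrophase, SEs, p, q, cycling).
    """
    if scale:
        matrix = scale_unit_interval(matrix)
    t = matrix.times
    rows = []
    for gene in matrix.gene_ids:
        fit = fit_cosinor(t, matrix.values.loc[gene].to_numpy(), period_hours)
        rows.append(
            {
                "gene_id": gene,
                "mesor": fit.mesor,
                "amplitude": fit.amplitude,
                "acrophase_hours": fit.acrophase_hours,
                "se_amplitude": fit.se_amplitude,
                "se_acrophase_hours": fit.se_acrophase_hours,
                "p_value": zero_amplitude_pvalue(fit),
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    table["cycling"] = table["q_value"] < alpha
    return table


@dataclass
class PhaseComparison:
    """Circular acrophase difference between two cosinor fits.

    ``significant`` is only set once ``q_value`` is known (after FDR
    adjustment across a batch via :func:`call_phase_shifts`); a shift is
    called when BOTH |delta| exceeds the minimum shift AND q clears FDR.
    """

    delta_phase_hours: float
    p_value: float
    q_value: float | None = None
    significant: bool | None = None


def compare_phases(fit_a: CosinorFit, fit_b: CosinorFit) -> PhaseComparison:
    """Wald test on the circular difference of two acrophases (A minus B).

    Both fits must have an amplitude clearly above zero (z > 2), otherwise
    their acrophase carries no information and the comparison is undefined.
    """
    if fit_a.period_hours != fit_b.period_hours:
        raise CosinorError("cannot compare acrophases at different periods")
    for name, fit in (("A", fit_a), ("B", fit_b)):
        if not fit.amplitude_z > 2:
            raise CosinorError(
                f"fit {name}: amplitude not distinguishable from zero "
                f"(z = {fit.amplitude_z:.2f}); phase comparison undefined"
            )
    delta = circular_difference(
        fit_a.acrophase_hours, fit_b.acrophase_hours, fit_a.period_hours
    )
    se = math.hypot(fit_a.se_acrophase_hours, fit_b.se_acrophase_hours)
    if se == 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(delta) / se))
    return PhaseComparison(delta_phase_hours=float(delta), p_value=p)


def call_phase_shifts(
    comparisons: list[PhaseComparison],
    min_shift_hours: float = 2.0,
    fdr_alpha: float = 0.05,
) -> list[PhaseComparison]:
    """Fill in FDR-adjusted q-values and make the phase-shift calls.

    A comparison is significant iff ``|delta| > min_shift_hours`` AND
    ``q < fdr_alpha``; q-values are BH-adjusted across the whole batch.
    """
    q = bh_fdr([c.p_value for c in comparisons])
    for c, qv in zip(comparisons, q):
        c.q_value = float(qv)
        c.significant = bool(
            abs(c.delta_phase_hours) > min_shift_hours and qv < fdr_alpha
        )
    return comparisons


def compare_amplitudes_top(fits_a, fits_b, n: int = 50):
    """Two-sided t test on the top-``n`` amplitudes of two fit collections.

    Each side's genes are ranked by fitted amplitude and the ``n`` largest
    amplitudes compared.  Returns the scipy t-test result (statistic,
    pvalue).
    """
    amps_a = np.sort([f.amplitude for f in fits_a])[::-1]
    amps_b = np.sort([f.amplitude for f in fits_b])[::-1]
    if n > amps_a.size or n > amps_b.size:
        raise CosinorError(
            f"n={n} exceeds available fits ({amps_a.size} vs {amps_b.size})"
        )
    return stats.ttest_ind(amps_a[:n], amps_b[:n])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise CosinorError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
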