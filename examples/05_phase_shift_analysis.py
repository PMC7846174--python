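"""Inter-tissue cosinor analysis: rhythm detection, phase shifts, amplitudes.

Per-gene cosinor fits (fixed 24-h period) give mesor, amplitude and
acrophase; a zero-amplitude F-test screens for cycling genes; acrophases of
genes cycling in two tissues are compared with a Wald test, and a shift is
called only when it exceeds 2 h AND survives FDR < 0.05.  Finally the
top-50 amplitudes of two conditions are compared with a two-sided t test.
"""

import numpy as np

from circatime import (
    SimulationConfig,
    call_phase_shifts,
    compare_amplitudes_top,
    compare_phases,
    detect_cycling,
    fit_cosinor,
    generate_reference_timecourse,
)

# two "tissues": the same 60 cyclers, the second delayed by 0/1/6 h in thirds
config = SimulationConfig(n_genes=60, cycler_fraction=1.0, amplitude_to_noise=6.0, seed=3)
gut, truth = generate_reference_timecourse(config)
delays = np.repeat([0.0, 1.0, 6.0], 20)
fat_phases = (truth["phase_hours"].to_numpy()[:60] + delays) % 24.0
fat, _ = generate_reference_timecourse(
    SimulationConfig(**{**config.__dict__, "seed": 4}), true_phases=fat_phases
)

cyc = detect_cycling(gut)
print(f"cycling screen: {int(cyc['cycling'].sum())}/{len(cyc)} genes at q < 0.05")

comparisons, genes = [], []
for gene in gut.gene_ids:
    fa = fit_cosinor(gut.times, gut.values.loc[gene], 24.0)
    fb = fit_cosinor(fat.times, fat.values.loc[gene], 24.0)
    comparisons.append(compare_phases(fb, fa))
    genes.append(gene)
called = call_phase_shifts(comparisons, min_shift_hours=2.0, fdr_alpha=0.05)
n_sig = sum(c.significant for c in called)
by_delay = {d: sum(c.significant for c, dd in zip(called, delays) if dd == d) / 20
            for d in (0.0, 1.0, 6.0)}
print(f"phase-shift calls: {n_sig}/60 genes "
      f"(fraction called by true delay: {by_delay})")
print("A 1-h delay is statistically detectable but stays below the 2-h "
      "biological minimum, so it is not called — only the 6-h group is.")

# genotype with a damped clock: amplitudes halved
damped, _ = generate_reference_timecourse(
    SimulationConfig(**{**config.__dict__, "amplitude": 50.0, "seed": 5})
)
fits_wt = [fit_cosinor(gut.times, gut.values.loc[g], 24.0) for g in gut.gene_ids]
fits_dp = [fit_cosinor(damped.times, damped.values.loc[g], 24.0) for g in damped.gene_ids]
res = compare_amplitudes_top(fits_wt, fits_dp, n=50)
print(f"\ntop-50 amplitude comparison (wild type vs damped): "
      f"t = {res.statistic:.1f}, p = {res.pvalue:.2e}")
print("The damped genotype's rhythm amplitudes are significantly reduced.")
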