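"""Generate the two study designs the pipeline is built around.

A reference time course (every 2 h over 48 h, triplicates, one light-dark
day then one dark-dark day) and a static cohort (141 lines, one sample
each, harvested ~9 min apart so the cohort tiles the day).
"""

import numpy as np

from circatime import LineEffect, SimulationConfig, generate_reference_timecourse, generate_static_cohort

config = SimulationConfig(n_genes=100, cycler_fraction=0.2, amplitude_to_noise=4.0, seed=1)
reference, gene_truth = generate_reference_timecourse(config)
print(f"reference: {reference.n_genes} genes x {reference.n_samples} samples "
      f"({len(np.unique(reference.times))} timepoints x {config.replicates} replicates)")
print(f"  regimes: {sorted(set(reference.samples['regime']))} "
      "(day 1 entrained, day 2 free-running)")
print(f"  {int(gene_truth['is_cycling'].sum())} genes cycle with phases tiling the day")

effects = [LineEffect(f"line{i:03d}") for i in range(141)]
effects[3] = LineEffect("line003", phase_offset_hours=6.0)      # clock 6 h ahead
effects[7] = LineEffect("line007", period_hours=30.0)            # slow clock
effects[11] = LineEffect("line011", disrupted=True)              # no clock at all
cohort, line_truth = generate_static_cohort(config, effects, interval_minutes=9.0)
spacing = np.diff(cohort.harvest_times)[0] * 60
print(f"\ncohort: {cohort.n_samples} lines, one sample each, {spacing:.0f} min apart")
print("  first harvests (h):", np.round(cohort.harvest_times[:5], 2))
print("  line_truth records each line's period / phase offset / disruption —")
print("  the ground truth every evaluation below is scored against.")
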