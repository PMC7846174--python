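# Methods

## The molecular timetable model

The method assumes that a sufficient number of genes are expressed as
stable sinusoids of a common circadian period and that a sample's
transcriptome is a snapshot of those sinusoids at its internal clock time.

**Wave bundle.** The reference grid is a family of unit cosine waves of one
period whose peak times tile the period at a fixed increment:
wave *k* has value `cos(2π(t − k·δ)/T)` with defaults `T = 24 h` and
`δ = 10 min`, i.e. 144 waves. The bundle doubles as the candidate-time grid
at prediction, so δ is also the resolution of the inferred time.

**TIG selection.** Each gene's time course is Pearson-correlated with every
wave (the original timetable formulation is correlation-based and "most
correlated" is read as product-moment correlation); the maximum `r_max` and
its peak time are recorded, ties resolving to the smallest peak time. A
gene becomes a time-indicating gene (TIG) when `r_max > 0.5` and its
coefficient of variation (sample SD over mean, n−1 denominator) exceeds
0.20. The CV is computed on unscaled expression — after per-gene 0–1
scaling every gene's CV would be an artifact of its noise shape, so scaling
is applied only where correlation (which is affine-invariant per gene)
consumes the values. The molecular peak time (MPT) of a TIG is the peak
time of its best wave. Two selection modes exist: `LDDD_05` scores the full
series as one unit; `LD_DD_05` applies both filters separately within the
light-dark and the constant-darkness day and keeps genes passing in both,
with the MPT taken from the unified fit (the per-day fits estimate the same
phase; the unified one uses all the data).

**Prediction.** For a candidate time φ on the bundle grid, the template for
TIG *g* is `cos(2π(mpt_g − φ)/24)`. The physiological time of a sample is
the φ whose template best correlates, across TIGs, with the sample's TIG
expression vector; ties resolve to the smallest φ. Positive signed
differences mean the prediction runs ahead of the harvest time; circular
differences are mapped to (−12, 12], the antipode reporting +12.
Prediction requires ≥ 2 TIGs with ≥ 2 distinct MPTs (a single phase column
cannot resolve time) and a non-constant sample vector.

## Evaluation harness

Leave-one-out: per tissue, each sample is predicted by a predictor trained
from scratch (including TIG re-selection) on the remaining samples of that
tissue. The whole set is 0–1 scaled per gene before the procedure; because
per-gene correlation is affine-invariant this does not leak information
into the predictions. The summary reports the mean |circular error|, the SD
of the *signed* errors, and the precision 3·SD — signed errors because the
calibration asks how dispersed predictions are around zero error, and a
systematic sign bias should widen, not cancel, the radius. The harness is
predictor-agnostic: any `factory(train_matrix) -> (sample -> hours)`
callable can be benchmarked; a failing fold is recorded and skipped. A
sample is an outlier when |signed difference| **strictly** exceeds the
threshold (default 3.4 h, i.e. the 3-SD radius of the original
calibration); strictness makes the boundary case reproducible.

## Detection window

For a line with period `P` and phase advance `Δ`, internal time is
`τ(t) = (24/P)(t + Δ)` with clocks aligned at `t = 0` (release from
entrainment); its TIG expression at harvest time `t` is the reference
waveform at `τ`. The simulation trains a timetable on a noiseless one-day
reference whose cycler phases tile the day, predicts the physiological time
of the deviant line at every harvest time on a 1-minute grid over [0, 24),
and flags times whose circular error strictly exceeds the threshold. The
window is the flagged measure; widths are reported to 0.1 h and rounded to
the nearest hour when quoted as integers. In the noiseless limit the
flagged set equals the closed-form drift set
`{t : |τ(t) − t|_circ > 3.4}` up to the 10-min quantization of the
prediction grid (≤ 5 min per boundary); the tests assert agreement within
0.15 h. Notable geometry: a 30-h period yields a 7-h window, unchanged by a
phase offset (the offset slides the drift, the width depends only on the
drift rate); a 6-h offset at a 24-h period is visible all day.

## Cosinor rhythmometry

Fixed-period cosinor: `y = M + β₁cos(ωt) + β₂sin(ωt)`, `ω = 2π/T`, fit by
least squares (the 3-parameter design is solved directly; the covariance is
`σ̂²(XᵀX)⁻¹`). Amplitude `A = √(β₁²+β₂²)` and acrophase
`φ = atan2(β₂, β₁)/ω mod T` (reported as a peak time in hours) get
delta-method standard errors. The fit is exact on a noiseless cosine of the
fitted period. Preconditions: ≥ 4 timepoints and a rank-3 design (two
distinct timestamps modulo the period cannot resolve phase).

**Rhythmicity screen** (`detect_cycling`): per gene, an F-test of the two
cosine terms against the mesor-only model on 0–1-scaled expression,
BH-adjusted; cycling iff `q < α`. This is a parametric stand-in for
nonparametric periodicity tests; at a fixed known period the F-test is the
natural screen and is exactly calibrated under Gaussian noise.

**Phase comparison**: the signed circular acrophase difference between two
fits with SE `√(SE_A² + SE_B²)` and a normal (Wald) test. Both fits must
have amplitude clearly above zero (z > 2) — the acrophase of a flat trace
is meaningless. A shift is *called* only when |Δφ| exceeds a biological
minimum (2 h, matching a 2-h sampling grid's resolution) **and** the
BH-adjusted q across the comparison batch is < 0.05; a statistically crisp
1-h shift is deliberately not called. Joint refitting of both groups in one
model is a known alternative; at the signal levels where calls are made the
two are equivalent, and the Wald form keeps the per-gene fits reusable.

**Amplitude comparison**: each condition's genes ranked by fitted
amplitude, the top N (default 50) compared by a two-sided t test.

FDR throughout is Benjamini–Hochberg (the classical step-up with
monotonicity enforcement, via statsmodels).

## Synthetic data: what it emulates and what it does not

Cycling genes are `mesor + amplitude·cos(2π(t − phase)/period)` plus
i.i.d. Gaussian noise with SD `amplitude/ANR`; flat genes are mesor plus
noise. Defaults: amplitude 100 U, mesor 200 U (keeps traces positive and
gives noiseless cyclers CV `a/(m√2) ≈ 0.35`, comfortably above the 0.20
filter while flat genes at ANR 4 sit near 0.13, below it), ANR 4 — a level
at which phase recovery is accurate but not trivial, chosen once as a
realistic strong-clock-gene regime since measured ANRs are instrument- and
pipeline-specific. `"uniform"` true phases mean an even deterministic
tiling of [0, 24): the generator's role is to realize the model's
assumption of an informative timetable at every hour, and tiling makes the
noiseless phase-recovery guarantees exact rather than probabilistic.

The generator does **not** model counting noise or overdispersion, library
size, batch effects, gene–gene correlation, non-sinusoidal waveforms, or
amplitude damping across days. Passing tests therefore demonstrate the
correctness of the *method's logic* and its calibration machinery under its
own model — not the error rates to expect on real sequencing data, where
normalization quality and waveform shape dominate.

## Numerical choices and degenerate inputs

- Grids are half-open: "every 10 min for 24 h" is 144 points, matching the
  144-wave bundle; sampling grids must divide the duration exactly.
- All argmax ties break to the smallest candidate (deterministic).
- Constant genes: dropped with a warning at scaling; excluded (not fatal)
  during TIG selection; fatal for a single-trace rhythmicity score.
- CV is undefined for non-positive means; such genes are flagged and fail
  the amplitude filter rather than erroring the pipeline.
- All randomness flows from a single integer seed per generator call;
  identical config + seed reproduces matrices bitwise.
- Test problem sizes (tens of genes, 12–72 samples, 20–60 seeds for
  Monte-Carlo assertions) are the smallest at which each property is
  decidable with comfortable margins; every guarantee above is scale-free.

## Known limitations

- Only the timetable predictor ships; the LOO harness accepts alternative
  predictors but none are bundled.
- The cosinor period is fixed, not estimated; period scanning and
  multi-component fits are out of scope.
- The detection-window geometry with both a short period *and* a phase
  offset depends on the sign convention of the offset; this package defines
  offsets as advances applied before the period scaling, and windows for
  combined deviations should be read under that convention only.
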