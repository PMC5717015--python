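# Methods

`landmarklab` analyses two-alternative forced-choice (2AFC) landmark-task
experiments: the observer judges which side of a pre-transected horizontal
line is shorter, and the lateral position at which judgements flip quantifies
their spatial attention bias. The package covers the full chain used in
sham-controlled brain-stimulation studies of pseudoneglect: a synthetic
cohort generator, per-block psychometric fits, sham-normalized and
baseline-corrected shift pipelines, performance-group splits with bootstrap
confidence intervals, and replication Bayes factors.

## Psychometric model

For a transector offset `x` (left-segment length minus right-segment length,
pixels), the probability of judging the left side shorter is modelled as a
cumulative logistic

    f(mu, x, s) = 1 / (1 + exp((x - mu) / s))

`mu` is the point of subjective equality (PSE): the offset with a 50% "left
shorter" rate, negative values denoting the leftward bias (pseudoneglect)
typical of healthy observers. `s` is the curve width; small widths mean
steep, precise judgements (high discrimination sensitivity), large widths
poor sensitivity. `f` is decreasing in `x`: lengthening the left segment
makes "left shorter" judgements rarer. The model carries no lapse parameter;
the generator can nonetheless inject lapses (up to 10%) to stress-test
fitting.

Fits maximize the binomial likelihood of the per-offset counts
(least-squares on proportions is used only as a cross-check). The optimizer
is L-BFGS-B with the analytic gradient, started from a 3 x 3 grid
(`mu` in {-10, 0, 10}, `s` in {2, 6, 12}), `s` bounded in [0.1, 100] px,
objective tolerance 1e-8. Degenerate blocks (all responses identical, or no
start converging) are returned with `converged=False` and excluded
downstream rather than silently dropped. Blocks whose data are effectively a
step function (true width well below the 6-px stimulus spacing) drive the
width estimate to its lower bound; the stimulus grid cannot resolve such
curves and the tests treat them as out of the recoverable domain.

MLE agrees with an independent dense grid search (0.01-px final step) to
within one grid step, and over 500 simulated 272-trial blocks at
(mu = -2.57, s = 6.31) the mean fitted PSE is within 0.3 px of truth and the
mean width within 5% (the residual ~1.5% downward width bias is the usual
small-sample bias of the ML slope estimate at 16 trials per offset).

## Synthetic cohort generator

The generator emulates the design the pipeline assumes: 29 subjects x 3
sessions (1 mA, 2 mA, sham) x 6 blocks x 272 trials; 17 offsets from -48 to
+48 px in steps of 6 (8 left-longer, 8 right-longer, 1 veridical), 16
repeats per offset per block. Blocks 1-2 are pre-stimulation baseline,
blocks 3-4 online, blocks 5-6 offline.

Population model and defaults (units px unless noted):

| parameter | default | rationale |
|---|---|---|
| `pse_population_mean` | -2.0 | group-level pseudoneglect of a few px leftward |
| `pse_population_sd` | 4.0 | back-solved from a one-sample t of about -3.4 at mean -2.57 with n = 29 |
| `width_population_median` | 6.3 | typical median baseline curve width |
| `width_population_log_sd` | 0.35 (log units) | right-skewed widths spanning roughly 4.4-9 px |
| `cross_session_icc` | 0.6 | cross-session PSE/width correlations of ~0.55-0.67 |
| `pse_block_sd` | 0.5 | block-to-block state fluctuation beyond binomial fit noise |
| `width_block_log_sd` | 0.1 (log units) | same, on the log-width scale |
| `lapse_rate` | 0.0 | the fitted model has no lapse term |

Subject-level PSE in condition `c` is `mean + u_i + v_ic` with
`u_i ~ N(0, icc * sd^2)` shared across sessions and
`v_ic ~ N(0, (1 - icc) * sd^2)` session-specific, so the between-condition
correlation of subject-level PSE equals `icc`, attenuated by block jitter to
`icc * sd^2 / (sd^2 + block_sd^2 / 2)` for the two-block baseline mean
(about 0.595 under defaults). Log width follows the same decomposition
around `log(median)`, making widths lognormal — positive and right-skewed,
which is also why a >3 SD upper-tail exclusion rule is meaningful.
`injected_shift` adds a fixed displacement to chosen (condition, block)
PSEs, planting a known stimulation effect for positive controls.

What the generator does **not** emulate: reaction times, within-block
non-stationarity (fatigue, drift), response lapses correlated in time,
sequential dependencies between trials, and any electrophysiological
correlate. Passing tests therefore demonstrate that the analysis chain
recovers effects under the stated statistical structure, not that real
observers satisfy that structure.

## Analysis pipeline

1. **Aggregation and fitting** — per subject x condition x block, counts per
   offset are fitted as above.
2. **Exclusion** — subjects whose pooled baseline width (mean of blocks 1-2,
   then across conditions) exceeds the group mean by more than 3 sample SDs
   (ddof = 1) are excluded; the rule is strict (`>`) and one-sided.
3. **Sham normalization** — the sham PSE series is subtracted block-by-block
   from each active condition, per subject; the sham condition maps to zero.
4. **Baseline correction** — each series' mean of blocks 1-2 is subtracted
   from every block, leaving blocks 3-6 as shifts relative to the subject's
   own pre-stimulation bias. The two transforms are affine and commute.
5. **Performance split** — `pooled-median`: baseline width pooled across
   conditions, split at the cohort median, the at-median subject joining the
   high-sensitivity (HDS) group; `per-condition`: one label per condition,
   split at that condition's mean width; `consistent-subset`: subjects
   labeled identically in all conditions under `per-condition`. Narrow
   width always means HDS.
6. **Summaries** — window means per subject x active condition: online
   (blocks 3-4) and overall (blocks 3-6); directional counts use strict
   inequalities (a zero shift is not rightward).
7. **Uncertainty** — 95% percentile bootstrap intervals for mean shifts
   (default 20,000 with-replacement resamples, seeded); one-sample/paired
   t-tests and Spearman correlations via scipy.

## Replication Bayes factor

Given a replication's observed effect `d` with standard error `SE`, and the
original study's effect `d_orig`, evidence is summarized as

    B = [ integral L(theta) pi(theta) dtheta ] / L(0)

where `L(theta)` is the normal density of `d` at mean `theta`, SD `SE`, and
the H1 prior `pi` is half-normal on `theta >= 0` with scale `d_orig`
(one-tailed; a zero-mean normal with SD `d_orig` two-tailed). `B < 1/3` is a
failed replication, `B > 3` a successful one, and values between (bounds
inclusive) leave the data insensitive. Integration uses adaptive quadrature
(relative tolerance 1e-6) over `[0, 10 * prior + 8 * SE]`; the truncated
tail mass is below 1e-8, and a 10^6-point trapezoid oracle agrees to
relative error < 1e-4.

Supporting machinery: a 1-df interaction effect is the difference of
differences `(HDS_1mA - HDS_2mA) - (LDS_1mA - LDS_2mA)`; its SE follows from
the interaction F as `|effect| / sqrt(F)` (t = sqrt(F) for one df); and for
tests with fewer than 30 degrees of freedom the SE is inflated by
`(1 + 20 / df^2)` to compensate for the normal likelihood's thinner tails
relative to the t. The df is that of the test the SE came from (27 for an
F(1, 27) interaction, 28 for a t(28) one-sample test).

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.Generator`; cohort generation,
  trial simulation and the bootstrap use distinct child seeds spawned from
  the run seed, so every stage is reproducible in isolation.
- Simulation-based checks use: 500 blocks for parameter-recovery bias, 50
  blocks against the grid-search oracle, 1,000 datasets of n = 100 for
  bootstrap coverage, 1,000 cohorts of 29 for the null rejection rate, and
  n = 200 cohorts for the injected-shift positive/negative controls.
- The null-calibration check runs the transform stages on generator-true
  parameters: the property at stake is the null fidelity of the
  normalize/correct/summarize/t-test chain, which fitting noise would only
  dilute. The known-truth controls exercise the full chain including
  fitting.
- Bootstrap coverage is evaluated at n = 100 per dataset, where the
  percentile method is asymptotically calibrated (~94.6% true coverage).

## Known limitations

- The percentile bootstrap undercovers at small n: at n = 29 its true
  coverage is ~93.4% rather than 95%. BCa or studentized intervals would
  narrow the gap; the percentile interval is kept as the standard reading of
  a bootstrap CI for a mean.
- The ML width estimate carries a small (~1-2%) downward bias at 16 trials
  per offset.
- Exact numerical parity with any particular published per-subject fit is
  not guaranteed: fitting method (MLE vs least squares) and convergence
  criteria are implementation choices on which such reports are typically
  silent.
- Repeated-measures/mixed ANOVAs, Friedman tests and blinding chi-square
  tests are out of scope; users wanting them should feed the exported
  tables to statsmodels or R.
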