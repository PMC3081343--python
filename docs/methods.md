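# Methods

This note documents the model implemented by `csmsim`: its structure,
assumptions, parameters, calibration policy, numerical choices, and
limitations.

## Decision problem

Five strategies for managing a possibly unstable cervical spine in a
comatose severe-TBI patient are compared on mean QALYs per simulated case:
early collar removal (ECR), late collar removal (LCR), each with or without
cervical spine MRI (ECR/MRI, LCR/MRI), and an idealized benchmark with
perfect quadriplegia prevention and no management-induced injury.  Cohorts
are simulated separately for three categories of cervical spine status on
imaging: unstable, high-risk, and stable.

## Chance-tree structure

Each simulated case passes through, in order:

1. **Primary and secondary brain injury** — independent gamma draws on a
   dimensionless severity scale.  Means are fixed inputs per category
   (unstable 0.50/0.075, high-risk 0.70/0.02, stable 0.50/0.02); shapes are
   calibrated (below).
2. **Management complications** — each complication source the strategy is
   exposed to fires independently with a per-category probability, adding a
   gamma(shape 4, mean 0.025) injury when it fires.  The six sources are
   collar delirium/IICP/VAP and MRI transport/IICP/VAP.  Collar sources
   apply only to the late-removal arms (the probabilities are *marginal*
   probabilities of late over early removal, so ECR's exposure is zero by
   construction).  MRI sources use the early-scan column for ECR/MRI and
   the late-scan column for LCR/MRI.  The benchmark is exposed to nothing.
3. **Outcome classification** — total injury (primary + secondary +
   complication injuries) below 0.56 is functional survival (FS); in
   [0.56, 0.65] severe brain disability (SBD); above 0.65 death.
4. **Cervical spine instability and quadriplegia** — instability is
   Bernoulli(p_csi), baseline 0.025 (0.05 in sensitivity analyses).  An
   unstable case progresses to quadriplegia unless the strategy protects
   it: protection 0 for ECR, 0.8 for LCR, 1.0 for the MRI strategies and
   the benchmark.  The quadriplegic outcome class is recorded only when the
   brain outcome is FS; SBD and dead cases keep their brain-outcome class
   regardless of quadriplegia (their counts are unaffected by the spine
   branch, and a quadriplegic SBD case's valuation is governed by the
   lesser-utility rule anyway).

## QALY valuation

QALYs are life expectancy times utility: FS 39.5 × 0.9 = 35.55,
quadriplegic FS survivor 20 × 0.2 = 4.0, SBD 20 × 0.1 = 2.0, dead 0.  A
case with both quadriplegia and a brain outcome receives the lesser of the
two valuations (so quadriplegia + SBD scores 2.0).

Strategy comparisons report a loss decomposition against the benchmark:
running the same draws with quadriplegia progression disabled, and again
with complications also disabled, splits the QALY shortfall exactly into a
quadriplegia channel and a management-injury channel (net + both losses =
benchmark, to machine precision, because the three runs are paired).

## Calibration of the gamma shapes

Under the benchmark, total injury is just primary + secondary, so the
benchmark outcome fractions per category pin down where the sum
distribution's mass falls relative to the two thresholds.  The calibration
targets are the benchmark counts per 1,000: unstable 394/216/390,
high-risk 165/167/668, stable 610/175/214 (FS/SBD/dead).

The outcome fractions of a shape pair are computed deterministically:
each gamma is discretized on a 2¹⁴-bin grid over [0, 2], the two
probability mass functions are convolved with an FFT, tail mass beyond the
grid is folded into the death bin, and the three fractions are read off the
thresholds (they sum to one exactly).  This removes Monte Carlo noise from
the objective and makes calibration bitwise reproducible.

An exhaustive search of shape space shows that the family "sum of two
independent gammas with these fixed means" cannot reach all three target
triples: with both shapes free, the best achievable maximum error in
(FS, dead) is about 0.10 for the unstable category and 0.02 for the other
two; in particular the right skew of the gamma prevents simultaneously
placing enough mass below 0.56 and above 0.65 for the unstable targets.  A
policy choice is therefore unavoidable.  The default, `weighted`, minimizes

  (w_fs · (FS − FS*))² + (w_dead · (dead − dead*))²

over both log-shapes (multi-start Nelder–Mead, fixed starting points), with
weights equal to each fraction's marginal effect on mean QALYs:
w_fs = QALY(FS) − QALY(SBD) = 33.55 and w_dead = QALY(dead) − QALY(SBD) =
2.0.  The rationale: every downstream comparison is expressed in QALYs, and
a unit of misplaced FS mass distorts mean QALYs ~17× more than a unit of
misplaced death mass, so the fit spends the family's limited reach where it
matters.  The cost is that the SBD/death split can sit far from its target
where the family is most constrained (the unstable category).  Residuals
are always attached to the result; `CalibrationResult.check(tol)` enforces
a strict tolerance when exact reproduction matters, and raises for the
default targets.  Alternative policies are selectable in the config:
`cv_matched` (secondary shape tied to primary) and `fixed_secondary`
(secondary shape pinned at 4).

The complication-injury gamma (mean 0.025) is not constrained by any
benchmark quantity; its shape defaults to 4 and is a config input.

## Random-number organisation

Each cohort's draws come from named substreams — one per chance node
(primary, secondary, instability, progression, and occurrence + injury per
complication source) — derived from the seed with `numpy` `SeedSequence`
spawn keys.  All draws are generated once per (category, n, seed);
strategies differ only in which draws they use.  Consequences:

- Strategies compared at one seed are paired case-for-case (common random
  numbers), so ranking and region-map comparisons are low variance.
- Adding a node never perturbs existing streams.
- The MRI strategies and the benchmark are *exactly* invariant to p_csi,
  and paired loss decompositions are exactly additive.

## Numerical and size choices

- Baseline cohort size 100,000; at this size quadriplegic counts per 1,000
  are stable to ±1 across seeds.
- Convolution grid: 2¹⁴ bins on [0, 2]; discretization error in the
  fractions is far below the 10⁻³ scale that matters here (verified against
  independent Monte Carlo sampling in the test suite).
- Optimizer: Nelder–Mead on log-shapes from four fixed starts, tolerances
  1e-8 (x) / 1e-14 (f); deterministic by construction.
- Sensitivity grids default to 21 points per axis; region maps use a 0.02
  QALY tie tolerance to flag indifference boundaries.

## Limitations

- The calibration targets are not exactly reachable (above); reported
  benchmark outcome counts and QALYs therefore deviate from the targets by
  the documented residuals, most visibly in the unstable category's
  SBD/death split.  Quantities driven by the FS fraction (quadriplegia
  counts, QALY differences between collar strategies) are robust to this.
- Complication occurrences are modeled as independent Bernoulli events;
  real complications correlate (e.g. VAP and IICP both lengthen
  ventilation).
- Life expectancies and utilities are fixed scalars; no discounting, no
  age structure, no parameter uncertainty (the sensitivity module varies
  probabilities, not valuations).
- The brain-injury scale is relative; thresholds 0.56/0.65 are inputs, not
  estimated quantities, and the model's absolute outcome fractions are only
  as good as those inputs.
- MRI is assumed perfectly sensitive for instability; collar protection
  (0.8 for LCR) is a fixed input.
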