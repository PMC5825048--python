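# Methods

`swayblocks` scores postural control from center-of-pressure (CoP)
recordings by modelling a statokinesigram as a *heterogeneous* signal: short
stretches of quiet stance (quiet blocks, QB) interleaved with short unstable
or exploratory stretches (unquiet blocks, UB).  The working hypothesis is
that fallers and non-fallers share both regimes and differ mainly in how
much time they spend unquiet, so a per-block soft classification carries
more discriminative information than indices averaged over the whole
recording.

## Pipeline

1. **Resampling (SWARII).**  Consumer force platforms emit samples at an
   uneven native rate.  Each recording is moved onto a uniform grid
   `t_k = t_0 + k/rate` (default 25 Hz) by averaging the raw samples inside
   the window `[t_k − w/2, t_k + w/2]` (default `w` = one output period,
   0.04 s).  A window that catches no raw sample falls back to linear
   interpolation between the bracketing raw samples, with nearest-sample
   values beyond the ends.  The scheme is idempotent on its own output and
   exact for coincident uniform input.
2. **Trimming.**  `floor(trim_s · rate)` samples are dropped from each end
   (default 2.5 s, so a 25-s recording keeps its central 20 s), removing
   step-on/step-off transients.  The floor rule means trims that are not
   multiples of the sample period discard slightly less than the nominal
   duration; trim composition is exact only for grid-aligned trims.
3. **Blocks.**  The trimmed signal is cut into blocks of
   `L = floor(block_length_s · rate)` samples starting at multiples of the
   stride `s = max(1, round(L · (1 − overlap)))` (round half away from
   zero); a trailing partial block is discarded.  The default overlap is
   50%; `block_length = "full"` keeps the whole signal as one block and is
   the classical global-indices baseline.
4. **Descriptors.**  Each block is summarised by
   `Z = (s95, v_mean, σ_X)`:
   * `s95 = π · χ²₀.₉₅,₂ · √det(S)` — area of the 95% prediction ellipse,
     with `S` the 2×2 sample covariance of (x, y) and
     `χ²₀.₉₅,₂ ≈ 5.9915`; a numerically degenerate `S` yields 0.
   * `v_mean` — mean of `√(Δx² + Δy²) · rate` over consecutive samples.
   * `σ_X` — sample standard deviation (n−1) of the medio-lateral series.
   Descriptors are z-normalized per index with mean/sd fitted on the pooled
   **training** blocks of one condition and applied unchanged to test
   blocks, so no test information leaks into the scaling.
5. **Mixture model.**  A k = 2 Gaussian mixture is fitted to the normalized
   training descriptors of each condition separately (eyes open and eyes
   closed are never pooled) by EM: posterior responsibilities in the E-step
   (computed in log space with max-subtraction), weighted means and biased
   covariances plus a ridge `λI`, `λ = 1e−6`, in the M-step.  EM restarts
   from 20 random initializations (component means at two distinct random
   data points, covariances at the global data covariance, equal weights)
   and keeps the run with the highest final log-likelihood.  Convergence:
   relative log-likelihood change below 1e−8, cap 500 iterations.  An
   emptied component is re-seeded at a random data point and logged.
6. **UB designation.**  The component maximizing the weighted density
   `π_i N(m; μ_i, Σ_i)` of the mean `m` of the faller-derived training
   descriptors is designated unquiet; exact ties break toward the larger
   mean-velocity coordinate.  The rule works because sway descriptors form
   a tight quiet cluster and a broad displaced unquiet cluster: `m` sits in
   the quiet component's far tail, where the broad unquiet component's
   density dominates even at a lower mixing weight.  With two artificial
   equal-covariance components and a faller mean near the midpoint, the
   heavier component can legitimately win instead — the rule is a
   heuristic tied to the shape of real sway features, not a theorem.
7. **Scores.**  Block score = posterior of the UB component; trajectory
   score = mean block score; global subject score = mean of the available
   per-condition scores (normally (EO + EC)/2).  UB occupancy = fraction of
   a trajectory's blocks with score strictly above 0.5, reported for the
   eyes-closed condition.
8. **Evaluation.**  Monte-Carlo cross-validation: per repetition a
   stratified subject-level 70/30 split (per class, `round(0.7 · n)` train
   subjects, half rounded up; both conditions of a subject stay together),
   full retraining (normalizer, mixture, labeling), scoring of test
   subjects, and ROC/AUC with faller as the positive class.  The ROC uses a
   threshold sweep over unique scores with tied scores entering as one
   diagonal segment, so the trapezoidal area equals the Mann-Whitney
   statistic with half-credit for ties.  Repetition seeds are
   `base_seed + r`; ROC curves are averaged vertically on a fixed 101-point
   FPR grid.  Block-length settings are compared by the two-sided rank-sum
   (Mann-Whitney/Wilcoxon) test on the per-repetition AUC samples — exact
   null distribution for combined n ≤ 20 without ties, normal approximation
   with tie correction otherwise.

Orientation is fixed by the labeling rule (higher score = more
faller-like); a repetition whose test AUC lands below 0.5 is reported
as-is, never flipped.

## Numerical choices

* Units: positions in cm, time in s.  cm is the conventional CoP scale and
  the z-normalization makes downstream results unit-free.
* All sample standard deviations use the n−1 denominator except the
  mixture's M-step covariance, which is the standard responsibility-
  weighted (biased) estimator.
* Degenerate inputs: constant blocks give the descriptor (0, 0, 0); an
  index with zero variance across the training blocks is a hard error (the
  normalizer would divide by zero); a mixture fit needs at least 10
  descriptors.
* The EM hot path evaluates component densities through one 3×3 Cholesky
  solve per component per iteration and updates covariances via weighted
  second moments; it is algebraically identical to the reference
  `e_step`/`m_step` functions, which the tests cross-check against direct
  density computations and an independent mixture implementation.
* Model serialization is plain JSON (weights, means, covariances, UB index,
  condition, training log-likelihood, seed).

## Synthetic cohorts

No clinical recordings ship with the package; the `synthetic_data` module
generates cohorts with planted regime structure so the whole pipeline is
testable against ground truth.  Defaults emulate the study conditions the
package targets: 126 subjects (18 fallers ≈ 14% prevalence), two 25-s
recordings per subject (eyes open/closed), irregular native sampling around
34 Hz with ±40% timestamp jitter, and unquiet occupancies 0.37 (fallers)
versus 0.10 (non-fallers).

Per trajectory: a two-state Markov chain over consecutive 2-s windows picks
the regime (transition matrix `T = ρI + (1 − ρ)1πᵀ`, persistence ρ = 0.7,
so the stationary UB probability equals the configured occupancy exactly
and mean unquiet episodes last a few seconds).  Each sway axis is an
exactly discretized Ornstein-Uhlenbeck process (mean-reversion 1.5 s⁻¹;
innovation scales 0.25/0.40 cm·s^−1/2 ML/AP) around a centre that itself
follows a much slower OU process (diffusion 0.06 cm·s^−1/2, relaxation
50 s — effectively a bounded random walk within one recording) modelling
postural drift.  The unquiet regime multiplies the sway innovations by 4.
Eyes-closed recordings inflate all amplitudes by 1.3.  Each subject carries
a log-normal baseline amplitude multiplier (sd 0.25 on the log scale,
class-independent), reflecting the large between-individual spread of sway
magnitude in elderly cohorts.

Two design points matter and were chosen deliberately:

* **Class difference is occupancy only.**  Faller and non-faller subjects
  draw from identical quiet dynamics, identical unquiet dynamics and the
  identical baseline-amplitude distribution; only the regime chain's
  stationary probability differs.  Any faller/non-faller separation the
  pipeline finds is therefore attributable to the planted occupancy gap.
* **Between-subject heterogeneity is what separates local from global
  analysis.**  If every subject had the same baseline, any time-averaged
  global index would be nearly as informative as block counting (both are
  monotone in realized occupancy, and AUC is invariant under monotone
  transforms).  The baseline multiplier corrupts global averages directly,
  while block counting is protected by the saturating posterior: a quiet
  block stays near score 0 until a subject's baseline crosses the cluster
  boundary.  The slow centre drift likewise inflates whole-signal spread
  indices (`s95`, `σ_X`) with realization noise while leaving 1-s blocks
  almost untouched.  These two ingredients reproduce the qualitative
  pattern that block-based scoring beats whole-signal scoring.

What the generator does **not** emulate: platform quantization and sensor
noise, frequency structure of physiological tremor, postural strategy
changes (the regimes are memoryless beyond the chain), inter-condition
correlations beyond a shared amplitude, and any demographic covariates.
Passing tests on these cohorts show the pipeline recovers planted structure
under realistic sampling artifacts and heterogeneity — not that the
clinical effect sizes would be reproduced on real recordings.

Estimated occupancies carry a known upward bias of a few points: an
overlapping block touching an unquiet window at any overlap scores as
unquiet (its indices are dominated by the episode), so the measured
fraction approaches the probability of *touching* an episode rather than
the stationary occupancy.  With 1-s blocks, 50% overlap and 2-s regime
windows this adds roughly +0.03 to +0.05 for fallers.  The recovery
tolerance of ±0.10 used in the acceptance tests absorbs this bias.

## Problem sizes used by the test suite and acceptance script

EM parameter recovery uses 50 simulated mixtures of 2000 points at 5-10σ
separation.  Planted-structure checks run 30-repetition MCCV on one
126-subject cohort for block lengths 1/2/3 s, and 20 independent
experiments (fresh cohort each) of 12-repetition paired MCCV for the
1-s-versus-whole-signal comparison.  The null control averages 3-repetition
MCCV over 10 cohorts with the class difference removed.  The acceptance
script mirrors the 30-repetition MCCV at all four block lengths plus a
5-cohort null control.

## Known limitations

* The SWARII variant implemented is fixed by this package's contract
  (closed window, plain averaging, linear-interpolation fallback); other
  relevance-weighted variants exist.
* The UB labeling heuristic can mislabel when the two mixture components
  have similar covariances (see above); on whole-signal descriptors, where
  the two-cluster structure is weak, occasional mislabeling in a repetition
  is expected and is visible as a low-AUC repetition.
* The score is a ranking signal for ROC analysis, not a calibrated fall
  probability.
* `p`-values from repeated-measures MCCV AUC samples are descriptive; the
  repetitions share subjects and are not independent.
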