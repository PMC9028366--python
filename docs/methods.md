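# Methods

`limbrqa` analyzes the joint dynamics of an infant's four limbs from
wrist/ankle accelerometry. This note documents the models, conventions and
numerical choices the package implements, and what its synthetic data do
and do not emulate.

## Signal model and preprocessing

Input is 3-axis acceleration per limb at 60 Hz (the rate of common
wearable motion trackers), with missing samples allowed. Preprocessing is
a fixed four-stage pipeline per limb:

1. **Gap filling.** Missing samples are interpolated per axis with a
   not-a-knot cubic spline through the valid samples at their integer
   sample indices. Interpolation runs *before* the magnitude collapse
   because the axes are what the sensor drops, and the magnitude of
   interpolated axes is not the interpolation of magnitudes. Leading and
   trailing gaps take the nearest valid value — cubic extrapolation can
   diverge and there is no data to constrain it.
2. **Magnitude.** The three axes collapse to the Euclidean norm
   sqrt(ax² + ay² + az²), one unsigned activity series per limb,
   invariant to sensor orientation.
3. **Median smoothing.** A third-order (3-point) median filter removes
   one-point outliers. Endpoints use a truncated window (the median, i.e.
   mean, of the two available samples) rather than zero padding: an
   acceleration magnitude hovers near gravity (~9.8 m/s²), so a padded
   zero would inject a large spurious outlier exactly where the filter
   has least support.
4. **z-scoring.** Each limb series is standardized with the sample
   (N − 1) standard deviation so that no high-variance limb dominates the
   joint recurrence analysis. A constant channel is a hard error — it
   carries no dynamics and would otherwise divide by zero.

The stage order is load-bearing and tested: swapping smoothing and
z-scoring changes the output.

## Embedding and parameter policy

The four z-scored limb series are delay-embedded jointly: state vector
x(t) = (x_d(t + jτ)) for limbs d = 1..4 and lags j = 0..m−1, giving
N′ = N − (m−1)τ states in 4m dimensions. Here m is the *per-channel*
embedding dimension (so "dimension 14" means a 56-coordinate state
space).

* **Delay τ** — first local minimum of the average mutual information
  (AMI) between each channel and its lagged copy, averaged over channels.
  MI uses a plug-in estimator on a 10 × 10 equal-width histogram (bin
  count configurable). "Local minimum" is the first lag where the curve
  stops decreasing; if the curve decreases over the whole range the
  argmin is returned with a warning.
* **Dimension m** — false nearest neighbors with the Kennel criteria:
  a neighbor is false when the added coordinate stretches the pair by
  more than rtol = 10 times its distance, or past atol = 2 times the
  attractor size (the overall SD of the z-scored data, ≈ 1). The chosen
  m is the smallest with false fraction below 10 %. Neighbor searches use
  a k-d tree with a Theiler exclusion of temporally adjacent states.
* **Radius ε** — bisection between 0 and the maximum pairwise distance
  until the recurrence rate (RR) reaches a 5 % target within 0.1
  percentage points (at most 60 iterations; RR is monotone in ε so
  bisection is valid). For state sets up to 6,000 points the condensed
  distance vector is pre-sorted and each bisection step is a binary
  search; above that, distances are re-scanned in a streaming pass.
  A state set whose duplicate-pair baseline already exceeds the target is
  reported as a calibration failure.

**Anchoring.** τ, m and ε are fixed on each subject's *earliest available
visit* (per task by default; a pooled switch exists) and reused at all
later visits, so longitudinal changes in the measures reflect changes in
the dynamics, not re-tuning of the analysis. A consequence visible in all
outputs: RR is pinned at ~5 % at anchor visits and becomes right-skewed
and variable afterwards — the anchored radius is the instrument, RR drift
is the signal. The pipeline default uses the preset τ = 1, m = 14 (a
standard operating point for biological signals at this rate); estimation
per subject is available via `estimate_embedding`.

## Recurrence measures

The recurrence plot marks state pairs with Euclidean distance ≤ ε.
Conventions (configurable, defaults stated):

* **Theiler window 1**: cells with |i − j| ≥ theiler are counted, so the
  default excludes exactly the main diagonal (every state trivially
  recurs with itself); 0 includes it.
* **lmin 2**: a diagonal line is a maximal run of ≥ 2 recurrent cells
  parallel to the main diagonal (both triangles counted).
* **RR** = 100 × recurrent / counted cells (percent).
* **Ent** = Shannon entropy of the diagonal line-length distribution, in
  nats (log2 available).
* **ML** = mean diagonal line length, in samples. An empty histogram
  yields Ent = ML = 0 by convention.

Long sessions never materialize the N′ × N′ plot: a compiled per-diagonal
streaming pass (O(N′²) time, O(N′) memory) accumulates the cell counts
and run-length histogram. The explicit-matrix implementation is retained
and the test suite asserts bit-exact agreement between the two paths,
including the histogram summation order entering the entropy.

## Surrogate control

Each preprocessed limb series is independently permuted uniformly at
random, which preserves the per-channel value distribution but destroys
temporal structure. Surrogates reuse the same anchored embedding
parameters, so the comparison isolates temporal organization. Observed vs
shuffled measures are compared with two-sided paired t-tests per visit
(one shuffle per session by default). Degenerate cases are explicit:
identical pairs give t = 0, p = 1; zero-variance nonzero differences give
an infinite t and p = 0.

## Longitudinal model

Each measure is regressed on task (2) × time point (4) by GEE: Gaussian
family, identity link, exchangeable working correlation over each
subject's sessions (independence and AR(1) switches exist), sandwich
covariance. Subjects with missing visits contribute their remaining
sessions. Term tests are Wald chi-squares.

**Small-sample convention.** With only tens of subjects the plain
sandwich Wald χ²(3) over-rejects badly (≈14 % at nominal 5 % in our null
simulations at 26 clusters). The package therefore defaults to the
Mancl–DeRouen bias-reduced sandwich covariance and refers Wald/df to an
F(df, K − p) distribution (K clusters, p mean parameters). The test
suite's 500-replicate null study holds the 5 % level under this
convention. The uncorrected large-sample behavior is available via
`cov_type="robust"`, `df_correction=False`.

Post hoc comparisons are Wald z-tests on differences of the eight
task × visit cell means, Bonferroni-multiplied by the full 28-pair family
(the conservative reading); contrasts touching an empty cell are flagged
non-estimable rather than dropped. `task_within_visit_contrasts` is a
convenience view of the four rattle-vs-free-play contrasts.

## Synthetic data: what it emulates, and what it does not

No public recordings of this kind exist, so the generator produces
sessions with the statistical structure the analysis assumes:

* **Rhythmic regime** (rattle-shaking): all limbs oscillate at a shared
  frequency (default 2.5 Hz) with coupling weight 0.7 between the shared
  and limb-private phase, arm amplitudes twice leg amplitudes
  (rattle-shaking is arm-led), and phase jitter that decays with the
  `regularity` parameter. Jitter is a phase diffusion of
  2·(1 − regularity) rad/√s — parameterized per unit time, so a session's
  decoherence is independent of the sampling rate.
* **Unstructured regime** (free play): intermittent movement bursts
  (Poisson onsets, default 0.8 bursts/s across limbs; exponential
  lengths, mean 1.2 s; carrier frequency uniform in 0.5–6 Hz) on a noise
  floor — no stable dominant frequency.
* Both regimes ride on a gravity offset with movement directions biased
  vertically (|z-component| ≥ 0.5), since only movement parallel to
  gravity survives the magnitude collapse to first order; additive sensor
  noise has SD 0.35 m/s².
* **Missingness**: contiguous gaps with geometric lengths (mean 5
  samples — dropouts are bursty), targeted at an overall 10.1 % rate, the
  rate reported for recordings of this kind; first/last samples are never
  dropped. Sessions whose worst limb exceeds 15 % missing are excluded by
  the pipeline.
* **Cohort**: per-visit Ns (19, 21, 26, 17) drawn from a 26-subject pool
  (longitudinal attrition), both tasks per visit, a per-subject latent
  regularity offset (SD 0.05) inducing within-subject correlation, and a
  built-in task × visit interaction: the rhythmic task's regularity
  rises by +0.40 / +0.45 at the last two visits only, while free play is
  visit-invariant. The defaults were set so the two regimes' anchor-visit
  entropy levels match (no spurious early task differences) and the
  late-visit interaction is detectable at the cohort's size — these are
  the study conditions every downstream simulation inherits.

What the generator does *not* emulate: biomechanically realistic infant
kinematics, orientation/quaternion dynamics, caregiver sensors, task
learning within a session, or non-stationary posture changes. Passing
tests therefore demonstrate that the pipeline recovers structure it is
designed to detect from signals with the assumed statistics — not that
real infant data carry that structure.

## Problem sizes and numerical choices

Replicated simulation studies (surrogate null calibration, GEE power and
type-I studies) run a scaled analysis profile — 50 s sessions sampled at
12 Hz, embedding m = 4 (25 s for the 500-replicate type-I study), chosen
as the package's desk-scale operating point so that hundreds of full
cohort replicates run on one CPU. Single-session checks (radius
calibration) use the full 60 Hz rate and m = 14. The oscillation
frequency stays well below both Nyquist limits.

Other numerics: distances are squared-compared (no square roots in the
hot loop); bisection tolerance 0.1 pp on RR; AMI bins 10; FNN thresholds
rtol 10 / atol 2 / cutoff 10 %; all randomness flows from named integer
seeds through `numpy.random.default_rng`, with no global RNG state;
reruns of the pipeline under a fixed config are byte-identical.

## Known limitations

* The AMI histogram estimator is degenerate on noiseless signals that
  take few distinct values (e.g., an exactly integer-period sinusoid):
  the lag-joint distribution is then a bijection and MI barely depends on
  lag. Real sensor data are never in this regime; the estimators are
  validated on noisy and incommensurate-period signals.
* The Kennel FNN fraction does not vanish for noise-dominated series
  (noise is infinite-dimensional); the estimator then saturates at
  `max_dim` with a warning, which is the designed behavior.
* GEE cell means are non-estimable for empty task × visit cells; they
  are flagged, and the affected interaction df is absorbed by the
  pseudo-inverse fit rather than redistributed.
* Entropy magnitudes depend on lmin, the Theiler window and the log
  base; comparisons across studies require matching these conventions,
  which is why they are explicit configuration with documented defaults.
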