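# limbrqa

Multidimensional Recurrence Quantification Analysis (MdRQA) of four-limb
accelerometry, built for longitudinal studies of infant movement
complexity: how the joint dynamics of both arms and both legs differ
between a rhythmic task (rattle-shaking) and unconstrained free play, and
how that difference develops across visits.

The package covers the whole analysis path:

* **Simulation** — four-limb 3-axis accelerometer sessions at 60 Hz with
  a rhythmic regime (shared-frequency oscillation across limbs) and an
  unstructured regime (intermittent random bursts), bursty missing
  samples (~10.1 %), and longitudinal cohorts with a built-in late-visit
  task × time interaction.
* **Preprocessing** — cubic-spline gap filling → acceleration magnitude
  → 3-point median filter → per-limb z-scoring.
* **Embedding** — delay via average mutual information, per-channel
  dimension via false nearest neighbors, and a recurrence radius
  calibrated by bisection to a fixed recurrence rate (RR = 5 %), all
  anchored on each subject's first visit and frozen thereafter.
* **MdRQA** — recurrence rate (RR), diagonal-line entropy (Ent) and mean
  line (ML) from the joint 4-limb embedding, computed by a streaming
  per-diagonal pass that never materializes the recurrence plot.
* **Surrogate control** — per-channel random shuffles with paired
  t-tests, proving the measures reflect temporal structure.
* **Longitudinal statistics** — GEE (Gaussian, exchangeable working
  correlation, bias-reduced sandwich errors) for task, time point and
  their interaction, with Bonferroni pairwise contrasts of the eight
  task × visit cells.

## The measures

With embedded states x(i) and radius ε, the recurrence plot is
R[i,j] = 1 iff ‖x(i) − x(j)‖ ≤ ε. From the histogram P(ℓ) of maximal
diagonal line lengths ℓ ≥ lmin (Theiler-excluded):

* RR = 100 · Σ R[i,j] / #cells — probability that a joint limb state
  recurs;
* Ent = −Σ p(ℓ) ln p(ℓ) — diversity of repeating movement patterns;
* ML = Σ ℓ P(ℓ) / Σ P(ℓ) — persistence of repeating patterns.

See `docs/methods.md` for conventions, the embedding-parameter policy and
the synthetic-data model.

## Worked example

```python
from limbrqa import (RegimeParams, generate_session, preprocess_session,
                     embed_multidim, calibrate_radius, measures_from_states,
                     shuffle_channels)

session = generate_session(RegimeParams("rhythmic", 50.0), seed=11, rate_hz=60.0)
series = preprocess_session(session)            # 3000 x 4, z-scored magnitudes
states = embed_multidim(series, tau=1, m=14)    # 2987 x 56 joint states
epsilon = calibrate_radius(states, target_rr=5.0)
observed = measures_from_states(states.values, epsilon)
shuffled_series = shuffle_channels(series, seed=99)
shuffled = measures_from_states(embed_multidim(shuffled_series, 1, 14).values, epsilon)
print(f"observed: RR={observed.rr:.2f}% Ent={observed.ent:.3f} ML={observed.ml:.2f}")
print(f"shuffled: RR={shuffled.rr:.2f}% Ent={shuffled.ent:.3f} ML={shuffled.ml:.2f}")
```

prints

```
observed: RR=5.00% Ent=3.452 ML=13.59
shuffled: RR=0.00% Ent=0.000 ML=0.00
```

The observed rhythmic session sits at the calibrated 5 % recurrence rate
with long, diverse diagonal lines (Ent ≈ 3.5 nats, mean line ≈ 14
samples); shuffling the same values in time leaves almost no recurrent
structure at the same radius — the measures are driven by temporal
organization, not by the value distribution.

The full pipeline (simulate → preprocess → calibrate → MdRQA → surrogate
→ GEE) runs from a config file or the CLI:

```bash
limbrqa run-all --seed 1 --out results/
limbrqa simulate --seed 1 cohort.csv   # write a synthetic cohort as tidy CSV
```

Outputs: `measures.csv` (one row per session), `params.csv` (per-subject
anchored τ/m/ε), `control.csv` (per-visit surrogate t-tests) and
`stats.json`/`stats.txt` (Wald tables and Bonferroni contrasts).

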