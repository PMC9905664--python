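# Methods

## Model

Breath δ¹³C of a captured bird is modelled as single-pool exponential
washout between two physiological endpoints:

    δ¹³C(bird i, t) ~ Normal( δ∞ᵢ − (δ∞ᵢ − δ₀ᵢ)·e^(−t/τ), σ )

* δ₀ᵢ (‰ VPDB) — the fed-state breath value at the first measurement
  (t = 0), reflecting the most recent meal;
* δ∞ᵢ (‰) — the fasted asymptote, reflecting oxidation of stored lipid;
* τ (min) — the average retention time, **shared by every bird in a fit**
  (1/τ is the instantaneous turnover rate). Sharing τ is the hierarchical
  pooling assumption: crop passage physiology is common to the birds even
  though their diets differ;
* σ (‰) — a single Gaussian residual sd shared across birds and
  instruments.

Time is measured from the first breath measurement; no correction to
time-since-capture is attempted (in the 2018 design, "minute 0" is 2.5 min
after the bird is sealed in the cuvette, after equilibration).

Priors are uniform: δ₀, δ∞ ~ U(−30, −10)‰ (the plausible range of breath
values given the dietary sources and discrimination), τ ~ U(0, 20) min,
σ ~ U(0, 5)‰. The σ prior and the Gaussian single-σ likelihood are this
package's reading of a conventional normal-error model; a per-year σ was
considered but a single σ is the default because the posterior for the
endpoints is insensitive to it at the observed noise levels.

## Sampler

Metropolis-within-Gibbs with Gaussian random-walk proposals:

1. all δ₀ᵢ updated simultaneously (birds are conditionally independent
   given τ, σ, so component-wise accept/reject is a valid blocked update);
2. all δ∞ᵢ likewise;
3. scalar update of τ against the full likelihood;
4. scalar update of σ.

Proposal scales adapt every 100 iterations toward ~30% acceptance **during
burn-in only**; retained draws therefore come from a fixed, valid kernel.
Chains start from cheap data-derived values (δ₀ᵢ at the bird's first
observation, δ∞ᵢ at its last, τ at 3 min, σ at the pooled residual sd of
per-bird least-squares prefits), each chain jittered for overdispersion.
Chain streams are spawned from one seed and run sequentially, so results
are bitwise reproducible.

Defaults are 3 chains × 10,000 iterations, burn-in 1,000, thin 3 → 3,000
retained draws per chain. Convergence is the rank-normalized split-R̂
(computed via arviz) with the conventional < 1.1 threshold on every
parameter; zero-variance chains yield an explicitly undefined (NaN)
diagnostic, which counts as a failure, never a silent pass.

## Posterior summaries

* **HPDI** — the shortest contiguous interval containing ⌈mass·n⌉ of the
  sorted draws (default mass 0.85). Ties between equally narrow windows
  break toward the lowest starting index. On multimodal pooled
  distributions the interval is still reported as one contiguous window;
  `is_multimodal` flags distributions whose KDE shows ≥ 2 peaks above 10%
  of the maximum.
* **Mode** — argmax of a Gaussian KDE over a 512-point grid spanning the
  draw range padded by one bandwidth; bandwidth is Silverman's rule of
  thumb, 0.9·min(sd, IQR/1.34)·n^(−1/5). A zero-variance vector returns
  the common value exactly. In the rare case where the global KDE mode
  falls outside the HPDI window, the attached mode is the KDE argmax
  restricted to the window, keeping the interval's "includes the mode"
  contract.
* **Peaks** — all local KDE maxima above 10% of the global maximum,
  rounded to 1‰ in reports. The 10% threshold is this package's
  convention for what counts as a peak.
* **Pooling** — per-bird draw vectors are concatenated within
  (species × year) groups; equal retained draw counts give each bird equal
  weight. Pooled summaries are invariant to bird order because the KDE
  grid derives from the data range alone.

## Mixing model

A two-endpoint linear mixing model converts breath δ¹³C into the
proportional contribution p of C₄ feeder sugar. Expected breath endpoints
are the diet values minus the state's diet-to-breath discrimination:

* fed (recent meals, Δ = 0.7‰): (−26.6 − 0.7, −11.4 − 0.7) = (−27.3, −12.1)‰
* fasted (stored reserves, Δ = 1.9‰): (−28.5, −13.3)‰

and p = (δ − flower_end)/(feeder_end − flower_end), clamped to [0, 1] with
the clamped fraction reported. The subtraction direction is fixed by the
endpoint arithmetic above; because breath and diet differ by a constant
offset, subtracting Δ from the diet values and adding Δ to the breath
values are the same inversion. The fed state pairs with δ₀ and the fasted
state with δ∞; the API enforces this pairing. The feeder endpoint default
is the 2010 sugar value −11.4‰ (used for combined-year analyses); the 2018
value −12.2‰ is available as `FEEDER_D13C_2018` for year-specific runs.
Endpoint sds (±0.1‰ feeder, ±1.1‰ flower) are carried in the config for
reference but not propagated — the inversion uses fixed endpoints, not a
source-variance mixing framework.

## Synthetic data

The generator emulates the two field designs: 26 birds (13 broad-tailed,
13 rufous) at {0, 3, 6, 9, 12} min with analytical sd 0.3‰ (2010, IRMS),
and 24 birds (3 + 21) at {0, 0.5, 1.5, 3.5, 7.5, 11.5, 15.5, 19.5} min,
optionally extended to 31.5 min, with sd 0.1‰ (2018, cavity ring-down).
Per-bird endpoints are drawn from Gaussian mixtures whose components sit
near the pooled-posterior peaks of each season's dominant species
(2010: δ₀ at −23/−15‰, δ∞ at −25/−19/−15‰; 2018: δ₀ at −19/−12.5‰, δ∞ at
−25/−17/−14‰), the only published hint at population structure; all
mixtures are user-configurable. The shared retention time defaults to
2.67 min. Draws are rejection-sampled into (−30, −10)‰ so truths stay
inside the analysis prior support — without this, prior truncation would
bias coverage tests at the margins.

What the generator does **not** emulate: trapping bias and recapture,
crop-volume dynamics, within-bird correlation between δ₀ and δ∞ (available
via `delta_corr` but defaulting to 0, as nothing is published on it), and
any biological scatter beyond instrument precision (an extra `bio_sd` is
added in quadrature if requested, default 0 — residual scatter around the
real fitted curves is unpublished). Passing recovery/calibration tests on
these simulations therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness to
model misspecification in field data.

## Equilibration QC

The 2018 cuvette equilibration check is a two-segment continuous
piecewise-linear (hinge) least-squares fit of the CO₂ concentration trace.
The breakpoint is grid-searched over interior observation times (two
points excluded at each end); SSE ties break toward the earliest
candidate, so a perfectly linear trace returns its first interior time.
Equilibration is declared when |post-break slope| ≤ 1% of |pre-break
slope| (relative tolerance and absolute floor configurable). Continuity,
the grid search, and the 1% criterion are this package's conventions; no
model form or threshold is published for this check.

## Problem sizes and determinism

The recovery check fits the full 26-bird 2010 design at the complete chain
settings (3 × 10,000); the calibration check uses 50 replicates of an
8-bird design at 3 × 2,000 iterations, sizes at which the vectorized
sampler completes each fit in under a second while leaving the coverage
estimate's Monte-Carlo error (~2 percentage points over 400 cases) well
inside the ±10-point acceptance band. Every stochastic path — generator,
sampler, pipeline — is seeded; identical configs give byte-identical
artifacts, and every pipeline output embeds the seed and a config hash.

## Known limitations

* Single-pool washout only; no double-exponential (two-pool) turnover.
* One contiguous HPDI even when a union of disjoint intervals would be
  shorter (flagged via the multimodality diagnostic).
* No endpoint-uncertainty propagation in the mixing model, no model
  comparison, no covariate effects on the washout parameters.
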