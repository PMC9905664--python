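# isowash

Estimating how much wild hummingbirds rely on supplemental feeders from the
carbon isotopes in their breath.

A hummingbird that has just fed on C₄ cane-sugar feeder nectar exhales CO₂
with a distinctly heavier δ¹³C than one fuelled by C₃ flower nectar. As a
captured bird fasts, its breath value washes out exponentially from the
fed-state signal δ¹³C₀ toward the fasted asymptote δ¹³C∞ set by its stored
(lipid) reserves:

    δ¹³C(t) = δ¹³C∞ − (δ¹³C∞ − δ¹³C₀) · e^(−t/τ)

with τ the average retention time in minutes. `isowash` provides, as a
tested reusable pipeline:

* a hierarchical Bayesian fit of per-bird (δ¹³C₀, δ¹³C∞) with a single τ
  shared by all birds and uniform priors (τ ∈ (0, 20) min, δ ∈ (−30, −10)‰),
  sampled by a vectorized Metropolis-within-Gibbs MCMC (3 chains × 10,000
  iterations, burn-in 1,000, thin 3 by default) with rank-normalized
  split-R̂ convergence checks;
* posterior summaries: 85% highest posterior density intervals (shortest
  contiguous interval), KDE modes and peaks, and pooling of per-bird
  posteriors into population-level (species × year) distributions;
* a discrimination-corrected two-endpoint mixing model converting breath
  δ¹³C into the proportional contribution p of C₄ feeder sugar, at two
  timescales: fed (recent meals, discrimination 0.7‰) and fasted (stored
  reserves, 1.9‰). With feeder sugar at −11.4‰ and C₃ flowers at −26.6‰ the
  expected breath endpoints are (−27.3, −12.1)‰ fed and (−28.5, −13.3)‰
  fasted, and p = (δ − δ_flower-end)/(δ_feeder-end − δ_flower-end), clamped
  to [0, 1];
* a synthetic-data generator reproducing both field designs (26 birds at
  {0,3,6,9,12} min with 0.3‰ analytical noise; 24 birds on the dense 2018
  schedule with 0.1‰ noise) for recovery and calibration testing;
* segmented-regression QC confirming cuvette CO₂ equilibration.

It is aimed at stable-isotope ecologists and ecophysiologists who have
timed breath δ¹³C series (or want to plan such a study by simulation).

## Worked example

```python
import isowash as iw

spec = iw.preset_2010(seed=42)                      # 26 birds, 2010 design
data, truth = iw.simulate_population(spec)
samples = iw.fit_hierarchical(data, iw.PriorSpec(), iw.MCMCConfig(seed=42))

report = iw.convergence_check(samples)
h = iw.hpdi(samples.tau.reshape(-1), 0.85)
pooled = iw.pool(samples, "d13c_0", group_by=("species",))
pp = iw.proportion_posterior(pooled[("rufous",)], iw.MixingConfig(), "fed")
```

printing the pieces gives:

```
converged: True (max R-hat 1.002)
tau mode 2.74 min, 85% HPDI (2.62, 2.87)
rufous fed feeder-use: mode 0.81, 85% HPDI (0.21, 0.95)
```

The simulated truth has τ = 2.67 min, so the shared retention time is
recovered to well within its HPDI; the feeder-use interval says the pooled
fed-state breath values of the simulated rufous birds correspond to anywhere
from ~21% to ~95% feeder sugar, with the most common value around 81% — the
kind of population-level statement the method is built for.

The same flow is available from the shell:

```sh
isowash simulate --preset 2010 --seed 42 --out breath.csv
isowash fit --data breath.csv --out posterior.csv
isowash report --posterior posterior.csv --out table1.csv
isowash mix --posterior posterior.csv --out proportions.csv
isowash run --config run.yaml --out artifacts/   # all stages, one config
```

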