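# movescape

State-dependent movement modelling, path simulation and Merriam
connectivity for large carnivores in developed mountain landscapes.

Towns, roads and recreational trails reshape where wolves and grizzly
bears can rest, forage and travel. `movescape` is for movement ecologists
and conservation planners who want to quantify those effects as a chain of
fitted models rather than a static resistance map:

1. **Movement behaviour** — a two-state hidden Markov model: step lengths
   `l_t ~ Gamma(mu_s, sigma_s)` and turn angles
   `theta_t ~ vonMises(m_s, kappa_s)` for latent states
   `s ∈ {slow, fast}`, with covariate-dependent switching
   `logit γ_{slow→fast}(x_t) = β₀ + β' x_t` driven by time of day
   (cos of hour), distance to town (capped-linear decay) and trail-road
   density (km/km² within 500 m). Alternative town-decay forms are ranked
   by AIC, and each fix gets a smoothed fast-state probability `p_Fast`.
2. **Resource selection** — a step selection function: each observed step
   versus 20 available steps drawn from the pooled empirical step/turn
   distributions, fitted by stratified conditional logistic regression
   (`P(used) = e^{η_used} / Σ_{21} e^{η}`) with a cluster-robust sandwich
   covariance over animals, interactions of anthropogenic and movement
   terms with `p_Fast` and time of day, and QIC backward selection.
   Effect sizes are reported as relative selection strength
   `RSS = exp(β'(x₁ − x₀))`.
3. **Simulation and connectivity** — individual-based paths (720 steps =
   60 days × 12 fixes) that propose 20 candidate steps from the HMM,
   reject candidates crossing unavailable habitat (checked at four points
   along each segment), and select among survivors with SSF weights —
   under *reference* (anthropogenic coefficients zeroed, towns available),
   *current*, and *future* (expanded towns + informal trails) scenarios.
   Ensembles become utilization distributions, ten equal-area
   habitat-quality bins (rank ≥ 7 = high quality, validated by Spearman
   rank correlation against observed GPS use), percent-intact habitat, and
   Merriam connectivity `n_traverse / n_reference` from unique paths
   traversing habitat patches or crossing digital cross-valley transects.

A synthetic valley generator (Gaussian-random-field habitat, two towns
pinching a ridge-bounded corridor, trail/road/railway network) provides
ground-truth tracks so every stage is testable by parameter recovery.

## Worked example

Simulate labelled tracks from known parameters on a synthetic valley and
refit the movement model:

```python
import io
from movescape import (LandscapeConfig, generate_landscape,
                       generate_labelled_tracks, MovementHMM, build_steps)
from movescape.pipeline import default_true_hmm, default_true_ssf
from movescape.io import read_tracks

stack, scene = generate_landscape(LandscapeConfig(n_rows=140, n_cols=240),
                                  seed=11)
df = generate_labelled_tracks(stack, scene, default_true_hmm(),
                              default_true_ssf(), n_animals=10,
                              n_steps=360, seed=42)
buf = io.StringIO()
df.drop(columns="true_state").to_csv(buf, index=False)
buf.seek(0)
series = [build_steps(t, stack) for t in read_tracks(buf)]
fit = MovementHMM(series).fit(seed=0)
print(fit.summary())
```

```
Two-state hidden Markov movement model
======================================================
n steps: 3600   log-lik: -27004.838   AIC: 54041.676
converged: True

Emission parameters (state: slow, fast)
  step mean (m):          48.06     480.25
  step sd (m):            47.82     391.35
  angle mean (rad):       3.057     -0.052
  concentration:          0.476      1.851

Transition coefficients (logit scale)
                                  estimate        se
beta[slow_to_fast].intercept       -1.7524    0.1874
beta[slow_to_fast].c_hour           0.2442    0.1107
beta[slow_to_fast].town_dist       -1.0255    0.2671
beta[slow_to_fast].trail_density    0.9177    0.1402
beta[fast_to_slow].intercept       -1.1536    0.2055
beta[fast_to_slow].c_hour          -0.1205    0.1239
beta[fast_to_slow].town_dist        1.3202    0.3027
beta[fast_to_slow].trail_density   -1.1782    0.1451
```

The refit recovers the generating emissions (true step means 50/500 m,
sds 50/400 m, concentrations 0.5/2; the slow-state mean angle 3.06 ≈ π is
the reversal bias of foraging movement) and the development effects on
behaviour: the negative `town_dist` and positive `trail_density`
coefficients on the slow→fast row mean animals are more likely to speed up
close to towns and in dense trail networks, and the mirrored fast→slow row
means they keep travelling there rather than settling to rest. Time-of-day
coefficients are the one place the full simulation chain leaves its mark:
selection interacts with state and hour, so the refitted diurnal terms
absorb part of that preference rather than matching the bare generator
values.

The full chain — decay selection, SSF with robust errors, three-scenario
simulation, habitat bins and connectivity — runs from one call
(`movescape.pipeline.run_pipeline`) or from the CLI:

```sh
movescape simulate --seed 11 --n-paths 300 --steps 720 --out run_dir
```

which prints, among other things, the pooled Spearman validation of
predicted habitat use, percent-intact habitat per scenario, and
patch/transect connectivity ratios with Monte-Carlo CIs.

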