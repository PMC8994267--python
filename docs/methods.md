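# Methods

`movescape` implements a three-stage, individual-based workflow for
quantifying how anthropogenic development (towns, recreational trails,
roads, a railway) affects large-carnivore movement behaviour, habitat use
and Merriam connectivity: (1) a behavioural-state movement model, (2) a
state-dependent step selection function, (3) SSF-weighted path simulation
under landscape scenarios, summarised as utilization distributions,
habitat-quality bins and connectivity ratios. A synthetic valley landscape
with known ground truth stands in for real telemetry and GIS layers, so
every stage of the chain can be validated by parameter recovery.

## 1. Movement-state model

Two latent states — *slow* (foraging/resting) and *fast*
(travelling/hunting) — emit step lengths `l_t` from state-specific gamma
distributions (parameterised by mean `mu_s` and sd `sigma_s`, in metres)
and turn angles `theta_t` from von Mises distributions (mean angle `m_s`,
concentration `kappa_s`). State switching follows logit-linear transition
probabilities

    logit P(slow -> fast at t) = b_0 + b' x_t

with one coefficient row per direction. The transition covariates are the
cosine of the hour of day (`cos(2*pi*h/24)`, so midnight = +1, noon = −1),
capped-linear distance to town (`min(d, R)/R`, default R = 5 km, so 0 at
the town edge and 1 beyond R), and trail+road density within a 500 m
radius (km/km²). Alternative town-decay transforms (capped-linear or
exponential, asymptote 500 m – 5 km) are compared by AIC
(`decay_model_selection`).

**Fitting.** Direct maximum likelihood on a working scale (`log mu`,
`log sigma`, unconstrained `m` wrapped to (−π, π], `log kappa`,
unconstrained transition coefficients). The forward recursion is scaled
per step; gap-separated track segments are independent likelihood blocks;
the initial state distribution is the stationary distribution of the
transition matrix at the first step's covariates (two states, short
memory — one parameter pair saved). The score is analytic via the Fisher
identity: one forward–backward pass yields posterior state and transition
probabilities, which weight the closed-form derivatives of the gamma, von
Mises, logistic-transition and stationary-initial terms. This makes a
20-track × 720-step fit run in seconds where finite differences would take
minutes, and it is verified against central finite differences in the test
suite. Optimisation is L-BFGS-B inside generous working-scale bounds
(0.4 m–60 km for means/sds, |logit coefficients| ≤ 15); a non-finite trial
point returns a large finite penalty so the line search backtracks rather
than aborting. Multi-start: the moment-based default initialisation (median
split of step lengths) plus randomly jittered candidates are screened by
log-likelihood and the best two optimised fully — the screen gives the same
basin coverage as optimising every restart at a fraction of the cost.
States are relabelled post-fit so `mu_fast > mu_slow`. The covariance is
the inverse observed information, obtained by numerically differentiating
the analytic score; transition-coefficient standard errors are read off
directly (those parameters are untransformed).

**Decoding.** `p_Fast`, the smoothed posterior probability of the fast
state per step, comes from the same forward–backward machinery and feeds
the SSF.

Zero-length steps (stationary GPS jitter) are floored at 1 m. Steps are
retained only when the interfix gap is 2 h ± 15 min; other gaps split
the series. A missing first turn angle contributes its length density
only.

## 2. Step selection function

Each observed step is paired with 20 available steps whose lengths and
turn angles are drawn with replacement from the pooled empirical marginals
of all observed steps, projected from the step's start location and
previous bearing; endpoints falling off the grid are redrawn up to 10
times, then the stratum is dropped (counted). Available steps inherit the
used step's `p_Fast` and `c_hour` — state and time belong to the decision
moment, not the candidate endpoint.

The design matrix holds endpoint covariates (raster values; on/off
indicators = endpoint within 30 m of the feature class), movement terms
(step length in km, cos of turn angle), a quadratic in trail density, and
interactions of the anthropogenic and movement terms with `p_Fast` and
`c_hour`. Coefficients are estimated by stratified conditional logistic
regression — the exact softmax-over-21-candidates likelihood — with
Newton-Raphson to a gradient norm below 1e-8. Columns with no
within-stratum variation carry no information and are excluded with
coefficients fixed at zero; complete separation is detected when the
conditional likelihood approaches its supremum of zero and flagged.
Variance is the cluster sandwich `A⁻¹ M A⁻¹` over animals (GEE with
independence working correlation), guarding against temporal
autocorrelation of fixes. Backward stepwise selection minimises
QIC = −2·QL + 2·trace(A_I · V_robust) (Pan 2001), never removing a main
effect while its quadratic or interaction remains. Relative selection
strength between two covariate vectors is `exp(beta'(x1 − x0))` with a
delta-method CI on the log scale.

Habitat prediction maps use endpoint terms only (movement terms describe
the step, not the place), normalise `exp(eta)` over available cells, and
define high-quality habitat as the top third of available cells (ties
broken by row-major cell index for determinism). In simulation the on/off
indicator is evaluated at cell centres (within 30 m of the class), a
cell-level approximation of the exact point-distance rule used in fitting;
at 120 m resolution this affects only cells the feature passes through.

## 3. Path simulation

Paths start at uniform random locations within top-third habitat cells,
at a uniform fix time, with a uniform initial bearing and an initial state
drawn from the local stationary distribution. Each step: transition
probabilities at the current location and time generate 20 candidate
states; candidate lengths and angles are drawn from the corresponding
emission laws; each candidate segment is checked at fractions 0.25, 0.5,
0.75 and 1.0 of its length (the origin is known available) and rejected if
any checkpoint is unavailable or off-grid; one surviving candidate is
selected with probability proportional to `exp(eta)`, where the
candidate's binary state stands in for `p_Fast` (Gumbel-max sampling).
If all 20 candidates are rejected the set is redrawn up to 5 times, after
which the animal holds position for that step (state resampled); more than
10 consecutive holds terminates the path as "stuck". Paths also terminate
when the running fraction of proposed candidate endpoints outside the
study area exceeds 40% (cumulative rule by default; a per-step variant is
a config switch). The clock advances 2 h per step; 720 steps = 60 days at
12 fixes/day.

The engine advances all paths of an ensemble in lockstep with a single
seeded PCG64 stream and a fixed draw layout: per-cell selection scores are
precomputed for each (state, fix-hour) pair, so a 1 000-path × 720-step
ensemble simulates in seconds and is bit-reproducible given the master
seed. `simulate_path` is the single-path case of the same engine.

**Scenarios.** *Reference*: all anthropogenic SSF terms (including
quadratics, on/off indicators and their interactions) and anthropogenic
HMM transition coefficients set to zero, and town/developed cells restored
to available habitat. *Current*: fitted coefficients, current layers.
*Future*: expanded town footprint (buffered polygons made unavailable) and
informal trails added to the network with trail density recomputed; other
layers unchanged. Zeroing is idempotent; with anthropogenic coefficients
zeroed and the reference mask, a "current" ensemble is bit-identical to
the reference ensemble under a shared seed (a tested invariant).

## 4. Habitat use and connectivity

Simulated locations are counted on the 120 m grid and normalised into a
utilization distribution; locations within 5 km of the study-area edge are
clipped first, and slow/fast/combined UDs are tallied separately.
Available cells **inside the clip window** are ranked into ten equal-count
bins by UD value (ties by row-major index; bin sizes equal within one
cell); restricting the bins to the clipped interior matters because the UD
is undefined (zero) in the margin and would otherwise poison the low
ranks. Validation is the Spearman rank correlation between bin rank and
the proportion of observed GPS locations per bin, pooled and per animal.
High-quality habitat is bin rank ≥ 7; percent intact habitat is the focal
high-quality proportion under a scenario divided by the reference
proportion, × 100.

Merriam connectivity counts **unique paths**: a path traverses the patch
metric if it has at least one location in each of two habitat patches (any
order), and crosses a transect if any of its step segments geometrically
intersects the cross-valley line (endpoint touch counts). Connectivity is
`n_traverse / n_reference` with a Monte-Carlo binomial CI; fewer than ten
reference paths is flagged as unreliable, a zero reference as undefined.

## 5. The synthetic valley

The generator emulates the study system's essential structure: an
east-west mountain valley whose floor (half-width 2 km, steep partly
barren ridges beyond — barren cells with slope > 35° are unavailable)
holds a smooth Gaussian-random-field habitat-quality layer with a
valley-bottom bonus, two towns whose footprints block most of the corridor
width (leaving narrow pinch-point gaps against the ridges), a highway,
railway and main trail along the valley, and recreational spur trails
concentrated in the developed reach between the towns. Habitat patches sit
at the valley ends, cross-valley transects run through each town, and the
focal area is the valley bottom between the towns (±5 km of the axis).
Trail-road density uses exact circle–segment geometry (500 m radius), so
the analytic single-chord value is reproduced to machine precision;
segments are accumulated in a canonical order so layers are exactly
invariant to input ordering.

Ground-truth parameters define the study conditions: gamma means 50/500 m
(sds 50/400 m), von Mises concentrations 0.5/2 with mean angles π/0
(reversal-biased foraging vs. persistent travel), unit-magnitude
transition coefficients (switching to fast more likely near towns, in high
trail density, and by day), and selection coefficients with strong
avoidance of town proximity (−8 on a 500 m exponential decay, consistent
in scale with wolf-grade avoidance) that wanes in the fast state (+4) and
at night (+1.5), a humped trail-density response, and trails avoided when
slow but selected when fast. Labelled tracks for recovery tests are
simulated by the same path engine with these parameters, states retained.

**What the generator does not emulate:** real covariate construction
(NDVI, snow, land cover), multi-year/seasonal data volumes, individual
heterogeneity in selection, fix-rate bias, and GPS positional error.
Passing recovery tests therefore demonstrates correctness of the
estimators and simulator under the model, not robustness to those
real-data complications.

## Problem sizes and test design

Verification uses sizes chosen to make each property measurable with
controlled error: the forward algorithm is checked exactly against
enumeration at T ≤ 8; emission recovery at 100 tracks × 720 steps (5%
relative tolerance); transition-coefficient coverage over 100 replicates
of 20 tracks × 720 steps — 100 rather than a couple of dozen because the
binomial noise of a correctly calibrated 95.4%-coverage estimator must not
mimic a coverage deficit at the 90% acceptance line; SSF recovery at 2 000
strata with the robust SE compared to the Monte-Carlo SD over 200
replicates (15% band); simulator null-consistency at 1 000 paths × 720
steps on a 200 × 200 grid; UD self-consistency with 10⁵ draws; and
connectivity monotonicity over 10 replicate ensembles × 3 nested town
footprints (0 / 600 / 1 200 m buffers), paired one-sided t-test at 5%.
Statistical tests with a fixed seed are one-shot draws from their null
distribution, so frequency-style checks pool replicates rather than assert
on a single ensemble.

The pipeline driver (`run_pipeline`) executes the full chain on the
synthetic valley at desk scale (default 15 animals × 360 steps for
fitting; hundreds of paths × 720 steps per scenario for simulation) and
writes per-stage manifests with named seed substreams derived from one
master seed. Headline quantities at this scale are stochastic:
scenario-to-scenario differences of a few percent (e.g. future-vs-current
percent-intact habitat) lie within Monte-Carlo noise, whereas the
qualitative signatures — habitat loss concentrated in the developed reach,
connectivity declining from current to future, stronger degradation for
slow-state use — are stable across seeds.

## Known limitations

- The two-stage design (HMM then SSF on decoded `p_Fast`) ignores
  uncertainty in the decoded state probabilities; an integrated SSF is out
  of scope by design.
- Only two states, gamma step lengths and a single fix interval are
  supported; hierarchical/random-coefficient extensions are not.
- The wolf-summer worked example against the study's deposited telemetry
  requires that external archive and cannot run offline; the refit
  machinery itself is exercised on synthetic tracks.
- Simulation evaluates on/off-feature terms at cell resolution (see §2).
- `percent intact` compares top-third/bin-based proportions whose bins are
  recomputed per scenario; with small ensembles bin boundaries themselves
  are noisy.
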