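# Methods

## The model

Soil organic carbon (SOC) on an agricultural field is represented as a set
of conceptual pools whose masses (Mg C/ha, 0–30 cm) evolve on an annual
time step.  Four nested topologies are implemented:

| id      | pools                      | idea |
|---------|----------------------------|------|
| `one`   | C                          | all SOC as one homogeneous decaying pool |
| `two`   | C, IOM                     | adds an inert pool not subject to biological transformation |
| `three` | C, BIO, IOM                | adds an explicit microbial biomass pool |
| `five`  | DPM, RPM, BIO, HUM, IOM    | the RothC pool set, without RothC's monthly rate modifiers |

Each decaying pool loses mass by first-order kinetics.  Over one year a
pool with rate `K` (1/yr) retains `exp(-K)` of its mass; the decayed
fraction `1 - exp(-K)` is split across destination pools by transfer
fractions, the remainder leaving the system as CO2.  This
survival-fraction discretisation is exact for independent first-order
decay and keeps the transition linear; simultaneous multi-pool exchange
within a year is ignored (first-order operator splitting).  The inert pool
(IOM) has no dynamics: its mass is a single estimated constant.  In the
three-pool model decayed C is partly assimilated by BIO and decayed BIO is
re-assimilated, returned to C, or respired; in the five-pool model plant
input is split between DPM and RPM (default 0.59:0.41, the RothC arable
convention) and the retained share of each active pool's decay is split
BIO:HUM = 0.46:0.54.  Those two splits are fixed constants by default and
the per-source retained-vs-respired share is an estimated parameter; a
single retention parameter per source pool was chosen over a shared one so
the five-pool model can attribute stabilisation differently to plant
material and to the slow pools.

The statistical structure is a Bayesian hierarchical state-space model:
an observation layer p(Y | X, θ), a process layer p(X | θ) and a parameter
layer p(θ).  The latent state X per field holds the pool masses and the
annual plant dry matter; the data Y are sparse measurements of total
organic carbon, TOC = sum of pool masses, 3–6 observations across ~20
years.  Fields of one site share θ but carry independent latent
trajectories; the joint likelihood is the product over fields.

**Input sub-model.**  Annual plant dry matter is
`X_W = yield_coef · rain · exp(ε)`, `ε ~ N(0, input_sd_log²)` in crop or
pasture years and zero in fallow/cleared years; annual draws are
independent.  The carbon input to the soil is
`carbon_content · residue_fraction(treatment) · X_W`, with treatment-
specific residue fractions (grain 0.60 > sorghum 0.55 > hay 0.45 >
pasture 0.35; fallow and cleared 0).  Harvesting hay removes more biomass
than taking grain, hence the ordering.  The positive multiplicative noise
is the simplest stochastic crop model consistent with simulating input
states; dry-matter records do not enter the likelihood, only TOC does.

**Noise.**  Process and observation noise are additive Gaussian
(standard deviations `process_sd`, `obs_sd`, Mg C/ha).  Additive noise is
what permits exact Kalman marginalisation of the pool sub-model; the cost
is that forward simulation can produce small negative excursions, which
are clipped to zero and reported (`Trajectory.clipped_years`) — clipping
happens only in simulation, never inside the filter.

**Initial state.**  The active-pool prior is Gaussian, centred by default
on each field's first observation (minus the inert mass) allocated across
active pools by fixed fractions, with standard deviation `x0_sd`
(default 5 Mg C/ha).  Alternatively the initial total is itself a
parameter (`x0_mode="parameter"`), which is also what reduces the one-pool
model to an exactly conjugate normal-mean model for validation.

**Microbial cap.**  Expert knowledge bounds microbial biomass at about 5%
of TOC.  The cap is enforced by rejection inside the MCMC: each proposal's
sampled latent trajectory is checked and proposals whose BIO share exceeds
the cap in any year are rejected.  The boundary is inclusive (exactly 5%
passes), reading "exceeds" strictly.

## Inference

The marginal likelihood p(Y | θ) is intractable because of the nonlinear
input sub-model, but conditional on a realised input path the pool
dynamics are linear-Gaussian.  The Rao-Blackwellised particle filter
(RBPF) therefore carries particles only for the input path and
marginalises the pool states exactly with a Kalman filter per particle;
since the transition matrix, process covariance and initial covariance are
particle-independent, all particles share one covariance recursion and
only the means differ.  Resampling is stratified, at every observation
event (weights are constant between observations, so this coincides with
per-step resampling of the named bootstrap filter); the filter runs on the
decaying pools only, folding the constant inert mass into the observation
offset, which keeps covariances non-singular whenever the noise scales are
positive.  The estimator is unbiased for the likelihood; with zero input
noise it collapses exactly to a single Kalman run.

Parameter draws come from correlated pseudo-marginal (CPM)
Metropolis-Hastings: the RBPF estimate replaces the likelihood in the
acceptance ratio, and the auxiliary standard normals driving the estimate
are proposed jointly with θ as `aux' = ρ·aux + sqrt(1-ρ²)·fresh`
(default ρ = 0.99, typical CPM practice), so estimator noise largely
cancels in the ratio and few particles suffice; ρ = 0 recovers the plain
pseudo-marginal sampler exactly.  Proposals are independent Gaussian
random walks in the unconstrained parameterisation (log for positive
parameters, logit for fractions), with scales configurable per parameter
(defaults aim at 10–30% acceptance).  Latent trajectories are drawn by
backward simulation along a weight-selected particle's Kalman quantities
(forward-filter backward-sampler); the same draw is reused for the BIO cap
check and stored with retained iterations.

Production defaults mirror a full run — 4 chains × 200,000 iterations,
80,000 burn-in, thinning every 30th draw, hence 4,000 retained draws per
chain; predictive densities average over the retained draws of all chains
pooled (the per-chain count is also recorded).  All examples, tests and
the acceptance script use scaled-down chains (thousands of iterations,
20–30 particles); the scales are stated with each run and were chosen as
the smallest sizes at which the conjugate and recovery oracles are
comfortably met.

## Priors

Every carbon and input parameter carries exactly one prior, classified
informative / weakly informative / uninformative.  Defaults (all
overridable): log-normal priors on decay rates centred at RothC-magnitude
annual rates (K_D ~ 8, K_R ~ 0.3, K_B ~ 0.6, K_H ~ 0.02, aggregated-pool
K_C ~ 0.06 /yr), beta(2,8) on assimilation fractions, beta(3,5) on
five-pool retention shares, log-normal on the inert mass (median 5 Mg
C/ha), weakly informative log-normals on the noise scales, and an
informative log-normal on `yield_coef` (median 0.01 Mg DM/ha/mm, so 355 mm
of growing-season rain yields about 3.55 Mg/ha dry matter).  The
dry-matter carbon share is fixed at 0.45.  These are this package's
declared defaults, not values taken from any particular field study.

## Model selection

Leave-future-out cross-validation over observation events (a year in
which any field was measured; simultaneous measurements form one fold
jointly).  For each fold t ∈ {L, …, T-1} the model is refitted to the
first t events and the one-event-ahead log predictive density accumulated
into the ELPD; each per-draw conditional density is the RBPF's likelihood
increment at the held-out event, predicting through multi-year gaps with
no intermediate conditioning.  ELPD is preferred over point-error scores
because it evaluates the whole predictive distribution; an RMSE report is
available as a secondary output.  Models within twice the combined
Monte-Carlo standard error are flagged indistinguishable.  Study-design
defaults for the minimum event count L are 12 (Mediterranean template)
and 13 (semi-arid template); synthetic runs use smaller L matching their
event counts.  Fold refits default to scaled-down chains (2,000
iterations, 500 burn-in, thin 5).

## Diagnostics and summaries

SOC change since the first trial year is the posterior functional
g = X_TOC(t) − X_TOC(1), summarised by its Monte-Carlo mean, sample
variance (n−1 denominators throughout) and percentiles; negative values
mean expected carbon loss.  Trajectory uncertainty is reported as
empirical per-year percentile bands (2.5/25/50/75/97.5 by default).
Convergence uses the classic (non-split) Gelman-Rubin potential scale
reduction factor — the form matching the originally cited criterion —
with R̂ < 1.2 read as no evidence of non-convergence; a split-R̂ variant
is available.

## Synthetic data

The generator emulates the structure of long-term Australian trials: a
Mediterranean template (3 fields, 1979–1997, winter rainfall averaging
355 mm, sampling in 1979/1985/1996, wheat/hay/pasture/fallow rotations)
and a semi-arid subtropical template (3 soil types, 1981–2000, clearing in
1982, fallow 1983 and 1993, wheat with occasional sorghum).  Rainfall is
log-normal with the configured mean; true parameters give realistic
magnitudes (initial TOC 42–55 Mg C/ha, inert mass 5–15% of TOC) so
constraint and recovery tests are non-degenerate.  Observation years in
the semi-arid template are a plausible sparse pattern, marked synthetic.
Depth-resolved coring is collapsed to a single 0–30 cm stock — the
quantity the models operate on.

What the generator does not emulate: real rainfall autocorrelation and
trends, yield responses beyond rainfall proportionality, soil-type
covariates, spatial sampling designs, measurement-method changes across
campaigns.  Passing recovery tests therefore demonstrates correctness of
the inference machinery under the model's own assumptions, not adequacy of
those assumptions for any particular field dataset.

## Numerical choices

- Filter and backward-sampler inner loops are jit-compiled; a likelihood
  evaluation is O(T) small dense operations.
- Backward sampling uses eigendecomposition-based PSD square roots and
  pseudo-inverses, so zero-noise (degenerate) configurations sample the
  deterministic trajectory exactly.
- Weight normalisation is done in log space; an all-underflow weight set
  returns −∞ and is flagged, and the MH step rejects such proposals.
- Chains are seeded via independent spawned streams from one integer
  seed; identical configurations reproduce traces bit for bit.
- Initialisation draws from the prior until a point with finite estimated
  likelihood and an admissible trajectory is found (500 attempts cap).

## Known limitations

- Microbial growth is not dynamic: the BIO pool is linear with a hard
  share cap, rather than e.g. logistic growth to a carrying capacity.
- Annual time step without temperature/moisture/cover rate modifiers.
- The scaled-down default fits used in examples trade Monte-Carlo error
  for speed; production-scale settings are one configuration flag away
  but take correspondingly longer.
- LFO-CV refits the model per fold; for long series a sampled
  approximation (e.g. importance-sampling variants) would be needed.
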