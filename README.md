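# soilcarbon

Bayesian multi-pool state-space modelling of soil organic carbon (SOC)
from sparse agricultural time series.

Land managers tracking carbon sequestration typically have a handful of
soil measurements spread over two decades.  Fitting a mechanistic turnover
model to such data raises two linked questions: how much pool structure
(RothC-style DPM/RPM/BIO/HUM/IOM compartments) does the data support, and
how uncertain are the resulting carbon-change estimates?  `soilcarbon`
answers both with a fully Bayesian workflow aimed at
scientists and analysts working on soil-carbon accounting:

- **Four stochastic pool models** — one-pool, two-pool (adds an inert
  pool, IOM), three-pool (adds microbial biomass, BIO, capped at 5% of
  TOC) and a RothC-like five-pool model — as annual linear-Gaussian
  state-space models driven by a stochastic, rainfall- and
  management-driven plant-input sub-model.
- **Exact-in-the-linear-part inference**: a Rao-Blackwellised particle
  filter (particles for the nonlinear input path, Kalman marginalisation
  of the pools) supplies unbiased likelihood estimates to a correlated
  pseudo-marginal Metropolis-Hastings sampler.
- **Model selection by leave-future-out cross-validation** (ELPD), which
  scores each candidate's ability to predict the next observation event
  from the past only.
- **Uncertainty quantification**: posterior SOC-change functionals
  X_TOC(t) − X_TOC(1), percentile bands, Gelman-Rubin R̂.
- **A synthetic-site generator** emulating Mediterranean and semi-arid
  Australian long-term trials, so the whole pipeline is testable without
  any data download.

The hierarchical model factorises as

    p(Y, X, θ) = p(Y | X, θ) · p(X | θ) · p(θ)

with sparse TOC observations Y, latent pool/input states X and parameters
θ (decay rates K_C, K_D, K_R, K_B, K_H, transfer fractions, inert mass,
noise scales, input-model coefficients).  See `docs/methods.md` for the
full model description and design rationale.

## Worked example

```python
import soilcarbon as sc

# a synthetic Mediterranean-climate site: 3 fields, 1979-1997,
# TOC sampled in 1979, 1985 and 1996, generated from the three-pool model
sites, truth, _ = sc.make_site(sc.tarlee_template(seed=3))

model = sc.SoilCarbonModel(sites, model_id="three")
result = model.fit(iterations=8000, burn_in=2000, thin=6,
                   n_chains=2, n_particles=30, seed=5)
print(result.summary()[["mean", "p2.5", "p97.5", "rhat"]])
print(result.soc_change("field1").tail(1))
```

which prints (numbers from this exact configuration):

```
                  mean      p2.5      p97.5      rhat
parameter
process_sd    0.406036  0.194231   0.675872  1.002572
obs_sd        1.029093  0.387934   2.135292  1.009497
yield_coef    0.008405  0.004786   0.013161  1.004219
input_sd_log  0.277696  0.119451   0.547473  1.004935
K_C           0.048080  0.031143   0.075370  1.156093
iom_mass      7.321497  1.563309  17.488795  1.160222
K_B           0.835731  0.286518   1.767926  1.010967
C_to_BIO      0.146021  0.036383   0.367250  1.072986
BIO_to_BIO    0.185172  0.048291   0.422656  1.045633
BIO_to_C      0.188870  0.039636   0.402754  1.011613

     field  year   t       mean       var       p2.5     p97.5
18  field1  1997  19 -10.101562  2.668754 -13.086983 -6.408007
```

Read: the decay rate of the aggregated carbon pool is estimated around
0.048/yr (the generating value was 0.05/yr, well inside the 95% interval),
the inert mass around 7.3 Mg C/ha (truth 6.0, also covered), and field 1
is expected to have lost about 10.1 Mg C/ha since 1979, with a 95%
credible interval of roughly (−13.1, −6.4).  All R̂ < 1.2, so there is no
evidence of non-convergence.  Negative SOC change means carbon loss.

Model comparison and the command line:

```bash
soilcarbon simulate --template tarlee --model three --seed 3 --out site/
soilcarbon fit    --model three --data site/ --out fit/   # paper-scale defaults
soilcarbon select --models one,two,three --data site/ --min-obs 2 \
    --iterations 2000 --burn-in 500 --thin 5 --chains 2 --particles 20 \
    --seed 1 --out sel/
soilcarbon diagnose --trace fit/trace.csv --out rhat.csv
```

`select` writes per-fold log predictive densities (`elpd_report.csv`) and
a ranking with Monte-Carlo errors (`ranking.json`); models whose ELPDs
differ by less than twice the combined error are flagged
indistinguishable.  Every `fit` writes a `manifest.json` sufficient to
replay the run bit for bit.

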