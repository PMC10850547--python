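"""Prior distributions over model parameters.

Each parameter of the carbon and input sub-models carries exactly one
prior, classified as informative, weakly informative or uninformative.
Supported families: log-normal, normal, uniform, beta, plus a degenerate
``fixed`` family for parameters held at a point value (fixed parameters are
not sampled and contribute nothing to the log-prior).

The MCMC samples in an unconstrained space; each family declares the
natural transform (log for positive parameters, logit for fractions) and
the matching log-Jacobian so the chain targets the correct density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit

_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)

FAMILIES = ("lognormal", "normal", "uniform", "beta", "fixed")
CLASSIFICATIONS = ("informative", "weakly informative", "uninformative")


@dataclass(frozen=True)
class Prior:
    """One marginal prior.

    hyperparameters by family:
      lognormal: (mu, sigma) of log(x)
      normal:    (mean, sd)
      uniform:   (low, high)
      beta:      (a, b)
      fixed:     (value,)
    """

    family: str
    params: tuple
    classification: str = "weakly informative"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")

    def _dist(self):
        if self.family == "lognormal":
            mu, sigma = self.params
            return stats.lognorm(s=sigma, scale=math.exp(mu))
        if self.family == "normal":
            m, s = self.params
            return stats.norm(loc=m, scale=s)
        if self.family == "uniform":
            a, b = self.params
            return stats.uniform(loc=a, scale=b - a)
        if self.family == "beta":
            a, b = self.params
            return stats.beta(a, b)
        raise ValueError("fixed priors have no distribution")

    def logpdf(self, x: float) -> float:
        # closed forms (the MCMC evaluates these in its inner loop)
        if self.family == "lognormal":
            if x <= 0:
                return -np.inf
            mu, sigma = self.params
            lx = math.log(x)
            return -lx - math.log(sigma) - _HALF_LOG_2PI - (lx - mu) ** 2 / (2 * sigma**2)
        if self.family == "normal":
            m, s = self.params
            return -math.log(s) - _HALF_LOG_2PI - (x - m) ** 2 / (2 * s**2)
        if self.family == "uniform":
            a, b = self.params
            return -math.log(b - a) if a <= x <= b else -np.inf
        if self.family == "beta":
            if not 0.0 < x < 1.0:
                return -np.inf
            a, b = self.params
            log_beta = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
            return (a - 1) * math.log(x) + (b - 1) * math.log1p(-x) - log_beta
        return 0.0 if x == self.params[0] else -np.inf

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return float(self.params[0])
        return float(self._dist().rvs(random_state=rng))

    def median(self) -> float:
        if self.family == "fixed":
            return float(self.params[0])
        return float(self._dist().median())

    # --- unconstrained-space transform -------------------------------
    def transform(self, x: float) -> float:
        """Constrained value -> unconstrained coordinate."""
        if self.family == "lognormal":
            return math.log(x)
        if self.family == "beta":
            return float(logit(x))
        if self.family == "uniform":
            a, b = self.params
            return float(logit((x - a) / (b - a)))
        return float(x)

    def untransform(self, z: float) -> float:
        if self.family == "lognormal":
            return math.exp(z)
        if self.family == "beta":
            return float(expit(z))
        if self.family == "uniform":
            a, b = self.params
            return a + (b - a) * float(expit(z))
        return float(z)

    def log_jacobian(self, z: float) -> float:
        """log |dx/dz| at unconstrained coordinate z."""
        if self.family == "lognormal":
            return float(z)
        if self.family == "beta":
            p = expit(z)
            return float(np.log(p) + np.log1p(-p))
        if self.family == "uniform":
            a, b = self.params
            p = expit(z)
            return float(math.log(b - a) + np.log(p) + np.log1p(-p))
        return 0.0


class PriorSet(dict):
    """Mapping parameter name -> Prior."""

    def require(self, names) -> None:
        missing = [n for n in names if n not in self]
        if missing:
            raise ValueError(f"parameters lacking a prior: {missing}")

    def sampled_names(self, names=None) -> list[str]:
        names = list(self) if names is None else list(names)
        return [n for n in names if self[n].family != "fixed"]


def log_prior(params: dict, priors: PriorSet) -> float:
    """Sum of marginal log prior densities over the entries of ``params``."""
    priors.require(params)
    total = 0.0
    for name, value in params.items():
        lp = priors[name].logpdf(value)
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return total


def default_priors(model_id: str) -> PriorSet:
    """Declared default priors for each model variant.

    Decay-rate priors are centred on RothC-magnitude annual rates; transfer
    fractions get beta priors favouring modest assimilation; noise scales
    get weakly informative log-normals.  All overridable in configuration.
    """
    ps = PriorSet()
    # input sub-model (shared by all variants)
    ps["yield_coef"] = Prior("lognormal", (math.log(0.01), 0.3), "informative")
    ps["input_sd_log"] = Prior("lognormal", (math.log(0.25), 0.4), "weakly informative")
    ps["carbon_content"] = Prior("fixed", (0.45,), "informative")
    # noise
    ps["process_sd"] = Prior("lognormal", (math.log(0.8), 0.5), "weakly informative")
    ps["obs_sd"] = Prior("lognormal", (math.log(1.2), 0.5), "weakly informative")

    if model_id in ("one", "two", "three"):
        ps["K_C"] = Prior("lognormal", (math.log(0.06), 0.6), "weakly informative")
    if model_id in ("two", "three", "five"):
        ps["iom_mass"] = Prior("lognormal", (math.log(5.0), 0.5), "weakly informative")
    if model_id == "three":
        ps["K_B"] = Prior("lognormal", (math.log(0.6), 0.5), "weakly informative")
        ps["C_to_BIO"] = Prior("beta", (2.0, 8.0), "weakly informative")
        ps["BIO_to_BIO"] = Prior("beta", (2.0, 8.0), "weakly informative")
        ps["BIO_to_C"] = Prior("beta", (2.0, 8.0), "weakly informative")
    if model_id == "five":
        ps["K_D"] = Prior("lognormal", (math.log(8.0), 0.5), "informative")
        ps["K_R"] = Prior("lognormal", (math.log(0.3), 0.5), "informative")
        ps["K_B"] = Prior("lognormal", (math.log(0.66), 0.5), "informative")
        ps["K_H"] = Prior("lognormal", (math.log(0.02), 0.5), "informative")
        for src in ("DPM", "RPM", "BIO", "HUM"):
            # share of decayed mass retained in the soil (non-CO2)
            ps[f"ret_{src}"] = Prior("beta", (3.0, 5.0), "weakly informative")
        ps["dpm_split"] = Prior("fixed", (0.59,), "informative")
        ps["bio_hum_split"] = Prior("fixed", (0.46,), "informative")
    return ps
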