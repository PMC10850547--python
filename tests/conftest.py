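"""Shared fixtures and independent oracles.

The oracles here are deliberately written independently of the package's
filtering code: the joint-Gaussian log-density assembles the full
covariance of the observation vector by brute force, and the conjugate
normal-mean site reduces the soil-carbon machinery to a model with a
closed-form posterior.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from soilcarbon.inputs import ClimateSeries, ManagementSchedule
from soilcarbon.model import SoilCarbonModel
from soilcarbon.priors import Prior
from soilcarbon.site import SiteSeries


def random_linear_system(rng, d=2, T=5, n_obs=3):
    """A random stable linear-Gaussian system with sparse scalar observations."""
    A = rng.uniform(-0.6, 0.9, size=(d, d)) / d
    Q = np.diag(rng.uniform(0.1, 1.0, size=d))
    H = rng.uniform(0.5, 1.5, size=(1, d))
    R = rng.uniform(0.2, 1.5)
    b_seq = rng.normal(0, 1, size=(T - 1, d))
    m0 = rng.normal(0, 1, size=d)
    P0 = np.diag(rng.uniform(0.1, 1.0, size=d))
    obs_pos = np.sort(rng.choice(T, size=n_obs, replace=False))
    return dict(A=A, Q=Q, H=H, R=R, b_seq=b_seq, m0=m0, P0=P0, obs_pos=obs_pos)


def joint_gaussian_loglik(sys, obs_vals, obs_offset=0.0):
    """Brute-force log-density of the observation vector.

    Stacks the state sequence into one multivariate normal via the
    recursions  E[x_{t+1}] = A E[x_t] + b_t  and
    Cov(x_{t+1}, x_s) = A Cov(x_t, x_s), then conditions nothing: the
    observation vector is a linear map of the stacked states plus
    independent noise.
    """
    A, Q = sys["A"], sys["Q"]
    b_seq, m0, P0 = sys["b_seq"], sys["m0"], sys["P0"]
    h = np.asarray(sys["H"], float).reshape(-1)
    R = sys["R"]
    d = A.shape[0]
    T = b_seq.shape[0] + 1
    means = [m0]
    for t in range(T - 1):
        means.append(A @ means[-1] + b_seq[t])
    cov = np.zeros((T * d, T * d))
    cov[:d, :d] = P0
    for t in range(1, T):
        # Cov(x_t, x_t) and cross terms with all earlier states
        cov[t * d:(t + 1) * d, t * d:(t + 1) * d] = (
            A @ cov[(t - 1) * d:t * d, (t - 1) * d:t * d] @ A.T + Q
        )
        for s in range(t):
            c = A @ cov[(t - 1) * d:t * d, s * d:(s + 1) * d]
            cov[t * d:(t + 1) * d, s * d:(s + 1) * d] = c
            cov[s * d:(s + 1) * d, t * d:(t + 1) * d] = c.T
    obs_pos = np.asarray(sys["obs_pos"], int)
    k = obs_pos.size
    Hbig = np.zeros((k, T * d))
    for i, t in enumerate(obs_pos):
        Hbig[i, t * d:(t + 1) * d] = h
    mu_y = Hbig @ np.concatenate(means) + obs_offset
    cov_y = Hbig @ cov @ Hbig.T + R * np.eye(k)
    return float(stats.multivariate_normal(mu_y, cov_y).logpdf(np.asarray(obs_vals)))


def fallow_site(obs_years, obs_vals, years=None, field_id="f1") -> SiteSeries:
    """A site with no plant growth at all (every year fallow)."""
    if years is None:
        years = list(range(2001, 2001 + 12))
    years = np.asarray(years, int)
    schedule = ManagementSchedule(years=years, treatments=["fallow"] * len(years))
    climate = ClimateSeries(years=years, rain_mm=np.full(len(years), 300.0))
    return SiteSeries(
        field_id=field_id,
        schedule=schedule,
        climate=climate,
        obs_years=np.asarray(obs_years, int),
        obs_toc=np.asarray(obs_vals, float),
    )


def conjugate_model(obs_years, obs_vals, sigma=1.0, m0=40.0, s0=4.0, years=None):
    """One-pool configuration that reduces exactly to the conjugate
    normal-mean model: no decay, no input, no process noise, the initial
    total mass is the single sampled parameter with a normal prior, so
    y_t ~ N(x0_total, sigma^2) i.i.d."""
    site = fallow_site(obs_years, obs_vals, years=years)
    model = SoilCarbonModel(
        site,
        model_id="one",
        x0_mode="parameter",
        x0_sd=0.0,
        priors={"x0_total": Prior("normal", (m0, s0))},
        fixed={
            "K_C": 0.0,
            "process_sd": 0.0,
            "obs_sd": sigma,
            "yield_coef": 0.01,
            "input_sd_log": 0.0,
        },
        sampled=["x0_total"],
    )
    return model


def conjugate_posterior(obs_vals, sigma, m0, s0):
    """Closed-form N(mean, var) posterior of the normal-mean model."""
    y = np.asarray(obs_vals, float)
    prec = 1.0 / s0**2 + y.size / sigma**2
    var = 1.0 / prec
    mean = var * (m0 / s0**2 + y.sum() / sigma**2)
    return mean, var


class NormalMeanToy:
    """y_i ~ N(mu, sigma^2), mu ~ N(m0, s0^2); likelihood optionally
    perturbed by unbiased log-normal estimator noise driven by the
    auxiliary variables (exact when noise_sd == 0)."""

    constrained = False

    def __init__(self, y, sigma=1.0, m0=0.0, s0=2.0, noise_sd=0.0):
        from soilcarbon.filters import AuxiliaryBlock
        from soilcarbon.mcmc import PseudoMarginalProblem
        from soilcarbon.priors import PriorSet

        self._aux_cls = AuxiliaryBlock
        self.y = np.asarray(y, float)
        self.sigma = sigma
        self.noise_sd = noise_sd
        self.param_names = ["mu"]
        self.priors = PriorSet(mu=Prior("normal", (m0, s0)))
        # borrow the protocol's transform plumbing
        for name in ("init_params", "draw_states", "check_states",
                     "to_z", "to_theta", "log_prior_z"):
            setattr(self, name, PseudoMarginalProblem.__dict__[name].__get__(self))

    def make_aux(self, rng):
        return self._aux_cls.draw(rng, 1, 1, 1) if self.noise_sd > 0 else None

    def loglik(self, theta, aux):
        mu = theta["mu"]
        ll = float(
            np.sum(-0.5 * (np.log(2 * np.pi * self.sigma**2)
                           + (self.y - mu) ** 2 / self.sigma**2))
        )
        if self.noise_sd > 0:
            # exp(ll_hat) remains unbiased for exp(ll)
            z = aux.normals[0, 0, 0]
            ll = ll + self.noise_sd * z - 0.5 * self.noise_sd**2
        return ll, None


@pytest.fixture(scope="session")
def rng0():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def tarlee_site():
    from soilcarbon import make_site, tarlee_template

    sites, theta, trajs = make_site(tarlee_template(seed=11, model_id="three"))
    return sites, theta, trajs
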