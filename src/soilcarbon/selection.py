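"""Model comparison by leave-future-out cross-validation (LFO-CV).

For a time series of observation events Y_1..Y_T (an event is a year in
which any field of the site was measured; simultaneous measurements form
one event jointly), the expected log pointwise predictive density is

    ELPD = sum_{t=L}^{T-1} log p(Y_{t+1} | Y_{1:t}),

where L is the minimum number of events required before predicting.  Each
per-fold density is estimated by Monte Carlo over S posterior draws
obtained by refitting the model to Y_{1:t}:

    p(Y_{t+1} | Y_{1:t}) ~= (1/S) sum_s p(Y_{t+1} | Y_{1:t}, theta_s),

with each conditional density estimated by a Rao-Blackwellised particle
filter extended one observation event ahead (predicting through any
multi-year gap with no intermediate conditioning).  Larger ELPD means
better out-of-sample predictive ability; models whose ELPDs differ by less
than twice the combined Monte-Carlo error are flagged indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .mcmc import CpmConfig
from .model import SoilCarbonModel
from .site import SiteSeries

#: minimum-observation defaults used for the two study designs
DEFAULT_L = {"tarlee": 12, "brigalow": 13}

#: scaled-down per-fold MCMC defaults for model-selection refits
FOLD_CONFIG = dict(iterations=2000, burn_in=500, thin=5)


def observation_events(sites: list[SiteSeries]) -> list[int]:
    """Sorted years in which at least one field was observed."""
    years = set()
    for s in sites:
        years.update(int(y) for y in s.obs_years)
    return sorted(years)


def truncate_model(model: SoilCarbonModel, n_events: int) -> SoilCarbonModel:
    """Copy of ``model`` whose data contain only the first ``n_events``
    observation events (forcing kept in full)."""
    events = observation_events(model.sites)
    keep = set(events[:n_events])
    new_sites = []
    for s in model.sites:
        mask = np.isin(s.obs_years, sorted(keep))
        new_sites.append(
            SiteSeries(
                field_id=s.field_id,
                schedule=s.schedule,
                climate=s.climate,
                obs_years=s.obs_years[mask],
                obs_toc=s.obs_toc[mask],
            )
        )
    return SoilCarbonModel(
        new_sites,
        model_id=model.model_id,
        priors=model.priors,
        fixed=model.fixed,
        sampled=list(model.param_names),
        residue_fraction=model.residue_fraction,
        x0_mode=model.x0_mode,
        x0_sd=model.x0_sd,
        x0_alloc=model._x0_alloc_arg,
        bio_cap=model.bio_cap,
    )


@dataclass
class PredictiveDensity:
    value: float        # p(Y_{t+1} | Y_{1:t}), Monte-Carlo estimate
    log_value: float
    mc_se_log: float    # delta-method standard error of log_value
    n_draws: int


def predictive_density(
    model: SoilCarbonModel,
    theta_draws,
    t_event: int,
    n_particles: int = 50,
    seed=None,
) -> PredictiveDensity:
    """Monte-Carlo one-event-ahead predictive density.

    ``theta_draws`` are posterior draws given the first ``t_event`` events
    (list of dicts or an array aligned with ``model.param_names``);
    the returned density is for the observations of event ``t_event + 1``.
    """
    draws = _as_dicts(theta_draws, model.param_names)
    if len(draws) == 0:
        raise ValueError("need at least one posterior draw")
    events = observation_events(model.sites)
    if t_event < 1 or t_event >= len(events):
        raise ValueError("t_event must leave at least one future event")
    target_year = events[t_event]  # event t_event + 1, 0-based list
    ext = truncate_model(model, t_event + 1)
    rng = np.random.default_rng(seed)
    log_ps = np.empty(len(draws))
    for i, theta in enumerate(draws):
        aux = ext.make_aux_sized(n_particles, rng)
        ll, extras = ext.loglik(theta, aux)
        if not np.isfinite(ll):
            log_ps[i] = -np.inf
            continue
        inc = 0.0
        found = False
        for s, r in zip(ext.sites, extras["filters"]):
            pos = {int(y): j for j, y in enumerate(s.years)}.get(target_year)
            if pos is not None and pos in r.increments:
                inc += r.increments[pos]
                found = True
        log_ps[i] = inc if found else -np.inf
    S = len(draws)
    log_mean = float(logsumexp(log_ps) - np.log(S))
    # relative MC error of the mean of p_s, propagated to the log
    p_rel = np.exp(log_ps - log_ps.max()) if np.isfinite(log_ps.max()) else np.zeros(S)
    m = p_rel.mean()
    se_log = float(p_rel.std(ddof=1) / (m * np.sqrt(S))) if S > 1 and m > 0 else np.inf
    return PredictiveDensity(
        value=float(np.exp(log_mean)), log_value=log_mean, mc_se_log=se_log, n_draws=S
    )


def _as_dicts(theta_draws, names):
    if isinstance(theta_draws, np.ndarray):
        return [dict(zip(names, row)) for row in theta_draws]
    return list(theta_draws)


@dataclass
class ElpdResult:
    """Expected log pointwise predictive density for one model."""

    model_id: str
    L: int
    fold_years: list[int]
    per_fold: dict = field(default_factory=dict)       # event year -> log density
    per_fold_se: dict = field(default_factory=dict)
    elpd_total: float = 0.0
    mc_se: float = 0.0
    per_chain_S: int = 0
    pooled_S: int = 0

    def finalize(self) -> "ElpdResult":
        self.elpd_total = float(sum(self.per_fold.values()))
        self.mc_se = float(np.sqrt(sum(se * se for se in self.per_fold_se.values())))
        return self

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model": self.model_id,
                "fold_year": list(self.per_fold),
                "log_pred_density": list(self.per_fold.values()),
                "mc_se": [self.per_fold_se[y] for y in self.per_fold],
            }
        )


def lfo_cv(
    model: SoilCarbonModel,
    L: int,
    config: CpmConfig | None = None,
    n_particles_predict: int | None = None,
    seed: int | None = None,
) -> ElpdResult:
    """Leave-future-out cross-validation of one model on its site.

    For each fold t in {L, ..., T-1} (T = number of observation events)
    the model is refitted by CPM-MCMC to the first t events and the log
    predictive density of event t+1 accumulated.  Only past events inform
    each fold's posterior, so no future information leaks into predictions.
    """
    events = observation_events(model.sites)
    T = len(events)
    if L >= T:
        raise ValueError(f"L = {L} must be smaller than the {T} observation events")
    if L < 1:
        raise ValueError("L must be >= 1")
    if config is None:
        config = CpmConfig(**FOLD_CONFIG, n_chains=2, n_particles=30)
    base_seed = config.seed if seed is None else seed
    res = ElpdResult(model_id=model.model_id, L=L, fold_years=events[L:])
    for t in range(L, T):
        fold_seed = int(
            np.random.SeedSequence([int(base_seed), t]).generate_state(1)[0] % (2**31)
        )
        fold_cfg = CpmConfig(
            iterations=config.iterations,
            burn_in=config.burn_in,
            thin=config.thin,
            n_chains=config.n_chains,
            n_particles=config.n_particles,
            rho=config.rho,
            seed=fold_seed,
            proposal_scales=config.proposal_scales,
        )
        fold_model = truncate_model(model, t)
        fit = fold_model.fit_config(fold_cfg)
        draws = fit.trace.pooled()
        pd_res = predictive_density(
            model,
            draws,
            t_event=t,
            n_particles=n_particles_predict or config.n_particles,
            seed=fold_seed + 1,
        )
        year = events[t]
        res.per_fold[year] = pd_res.log_value
        res.per_fold_se[year] = pd_res.mc_se_log
        res.per_chain_S = fold_cfg.n_retained
        res.pooled_S = pd_res.n_draws
    return res.finalize()


def rank_models(results: list[ElpdResult]) -> list[dict]:
    """Rank models by ELPD (largest first).

    Pairs whose ELPD difference is within twice the combined Monte-Carlo
    error are flagged as statistically indistinguishable.
    """
    if not results:
        raise ValueError("no results to rank")
    if len(results) > 1:
        folds = {tuple(r.fold_years) for r in results}
        if len(folds) != 1:
            raise ValueError("results were computed on different fold sets")
    ordered = sorted(results, key=lambda r: r.elpd_total, reverse=True)
    out = []
    for i, r in enumerate(ordered):
        ties = []
        for other in ordered:
            if other is r:
                continue
            combined = np.sqrt(r.mc_se**2 + other.mc_se**2)
            if abs(r.elpd_total - other.elpd_total) < 2 * combined:
                ties.append(other.model_id)
        out.append(
            {
                "rank": i + 1,
                "model": r.model_id,
                "elpd": r.elpd_total,
                "mc_se": r.mc_se,
                "indistinguishable_from": ties,
            }
        )
    return out
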