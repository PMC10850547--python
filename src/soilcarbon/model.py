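"""Model and results objects for Bayesian soil-carbon inference.

:class:`SoilCarbonModel` binds one of the four pool topologies to the data
of a site (one or more fields sharing a parameter vector, each with its own
latent trajectory) and exposes ``fit()``, which runs correlated
pseudo-marginal MCMC with Rao-Blackwellised particle-filter likelihood
estimates and returns a :class:`SoilCarbonResults` carrying parameter
draws, sampled latent trajectories, convergence diagnostics and SOC-change
summaries.

Example
-------
>>> from soilcarbon import synthetic, SoilCarbonModel
>>> sites, truth, _ = synthetic.make_site(synthetic.tarlee_template(seed=1))
>>> model = SoilCarbonModel(sites, model_id="two")
>>> res = model.fit(iterations=2000, burn_in=500, thin=5, n_chains=2,
...                 n_particles=30, seed=1)
>>> res.summary()  # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diagnostics
from .filters import AuxiliaryBlock, rbpf_backward_sample, rbpf_filter
from .inputs import InputParameters
from .mcmc import CpmConfig, McmcTrace, PseudoMarginalProblem, check_bio_constraint, run_cpm
from .pools import CarbonParameters, LinearSystem, build_linear_system, build_pool_structure
from .priors import PriorSet, default_priors
from .site import SiteSeries, sites_from_frames

#: default allocation of the non-inert initial mass across active pools
DEFAULT_X0_ALLOC = {
    "one": {"C": 1.0},
    "two": {"C": 1.0},
    "three": {"C": 0.97, "BIO": 0.03},
    "five": {"DPM": 0.01, "RPM": 0.14, "BIO": 0.02, "HUM": 0.83},
}


def param_names_for(model_id: str) -> list[str]:
    """Names of the parameters a model variant draws from its priors."""
    names = ["process_sd", "obs_sd", "yield_coef", "input_sd_log", "carbon_content"]
    if model_id in ("one", "two", "three"):
        names.append("K_C")
    if model_id in ("two", "three", "five"):
        names.append("iom_mass")
    if model_id == "three":
        names += ["K_B", "C_to_BIO", "BIO_to_BIO", "BIO_to_C"]
    if model_id == "five":
        names += ["K_D", "K_R", "K_B", "K_H"]
        names += [f"ret_{src}" for src in ("DPM", "RPM", "BIO", "HUM")]
        names += ["dpm_split", "bio_hum_split"]
    return names


def build_carbon_parameters(model_id: str, theta: dict) -> CarbonParameters:
    """Map a flat parameter dictionary onto :class:`CarbonParameters`."""
    if model_id in ("one", "two"):
        decay = {"C": theta["K_C"]}
        fractions = {"input_C": 1.0}
    elif model_id == "three":
        decay = {"C": theta["K_C"], "BIO": theta["K_B"]}
        fractions = {
            "input_C": 1.0,
            "C_to_BIO": theta["C_to_BIO"],
            "BIO_to_BIO": theta["BIO_to_BIO"],
            "BIO_to_C": theta["BIO_to_C"],
        }
    elif model_id == "five":
        decay = {
            "DPM": theta["K_D"],
            "RPM": theta["K_R"],
            "BIO": theta["K_B"],
            "HUM": theta["K_H"],
        }
        bio_share = theta.get("bio_hum_split", 0.46)
        fractions = {
            "input_DPM": theta.get("dpm_split", 0.59),
            "input_RPM": 1.0 - theta.get("dpm_split", 0.59),
        }
        for src in ("DPM", "RPM", "BIO", "HUM"):
            ret = theta[f"ret_{src}"]
            fractions[f"{src}_to_BIO"] = ret * bio_share
            fractions[f"{src}_to_HUM"] = ret * (1.0 - bio_share)
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    return CarbonParameters(
        decay_rates=decay,
        transfer_fractions=fractions,
        iom_mass=theta.get("iom_mass", 0.0),
        process_sd=theta.get("process_sd", 0.0),
        obs_sd=theta.get("obs_sd", 0.0),
    )


def build_input_parameters(theta: dict, residue_fraction: dict | None = None) -> InputParameters:
    kwargs = {}
    if residue_fraction is not None:
        kwargs["residue_fraction"] = dict(residue_fraction)
    return InputParameters(
        yield_coef=theta["yield_coef"],
        carbon_content=theta.get("carbon_content", 0.45),
        input_sd_log=theta["input_sd_log"],
        **kwargs,
    )


@dataclass
class _FieldCache:
    """Per-field quantities that do not depend on the parameter vector."""

    obs_pos: np.ndarray
    obs_vals: np.ndarray
    rain: np.ndarray
    residue: np.ndarray    # residue fraction per year (treatment driven)
    growth: np.ndarray     # bool, crop grows this year
    x0_obs: float          # first observation (initial-state anchor)


class SoilCarbonModel(PseudoMarginalProblem):
    """One pool topology fitted to the sparse TOC series of a site.

    Parameters
    ----------
    sites
        a :class:`SiteSeries` or list of them (fields share the parameter
        vector; each carries an independent latent trajectory).
    model_id
        "one", "two", "three" or "five".
    priors
        overrides merged over :func:`soilcarbon.priors.default_priors`.
    fixed
        mapping name -> value for parameters held constant.
    sampled
        explicit list of sampled parameter names (default: every relevant
        parameter whose prior is not fixed).
    x0_mode
        "first_obs" anchors the initial-state prior mean at each field's
        first observation; "parameter" uses the sampled/fixed parameter
        ``x0_total`` (one shared initial total across fields).
    x0_sd
        prior standard deviation (inflation) of the initial active-pool
        masses, Mg C/ha.
    bio_cap
        microbial-biomass cap as a share of TOC (default 5%).
    """

    def __init__(
        self,
        sites,
        model_id: str = "three",
        priors: PriorSet | dict | None = None,
        fixed: dict | None = None,
        sampled: list[str] | None = None,
        residue_fraction: dict | None = None,
        x0_mode: str = "first_obs",
        x0_sd: float = 5.0,
        x0_alloc: dict | None = None,
        bio_cap: float = 0.05,
    ):
        self.sites: list[SiteSeries] = [sites] if isinstance(sites, SiteSeries) else list(sites)
        if not self.sites:
            raise ValueError("need at least one field")
        self.model_id = model_id
        self.structure = build_pool_structure(model_id)
        self.active_pools = [p for p in self.structure.pools if p not in self.structure.constant]
        self.bio_cap = bio_cap
        self.x0_mode = x0_mode
        self.x0_sd = float(x0_sd)
        self.residue_fraction = residue_fraction
        self._x0_alloc_arg = dict(x0_alloc) if x0_alloc else None
        alloc = dict(x0_alloc or DEFAULT_X0_ALLOC[model_id])
        self.x0_alloc = np.array([alloc.get(p, 0.0) for p in self.active_pools])
        if not np.isclose(self.x0_alloc.sum(), 1.0):
            raise ValueError("x0 allocation fractions must sum to 1 over active pools")

        self.priors = default_priors(model_id)
        if priors:
            self.priors.update(priors)
        names = param_names_for(model_id)
        if x0_mode == "parameter":
            names.append("x0_total")
            if "x0_total" not in self.priors:
                first = float(self.sites[0].obs_toc[0]) if self.sites[0].obs_toc.size else 40.0
                from .priors import Prior

                self.priors["x0_total"] = Prior("normal", (first, 10.0), "weakly informative")
        self.fixed = dict(fixed or {})
        self.all_names = names
        self.priors.require(n for n in names if n not in self.fixed)
        if sampled is None:
            sampled = [
                n for n in names
                if n not in self.fixed and self.priors[n].family != "fixed"
            ]
        self.param_names = list(sampled)
        self.constrained = self.structure.has_bio

        res_frac = InputParameters(residue_fraction=dict(residue_fraction)).residue_fraction \
            if residue_fraction else InputParameters().residue_fraction
        self._fields = []
        for s in self.sites:
            if s.obs_toc.size == 0 and x0_mode == "first_obs":
                raise ValueError(f"field {s.field_id!r} has no observations to anchor x0")
            self._fields.append(
                _FieldCache(
                    obs_pos=s.obs_index(),
                    obs_vals=s.obs_toc,
                    rain=s.climate.rain_mm,
                    residue=np.array([res_frac[t] for t in s.schedule.treatments]),
                    growth=np.array([res_frac[t] > 0 for t in s.schedule.treatments]),
                    x0_obs=float(s.obs_toc[0]) if s.obs_toc.size else float("nan"),
                )
            )
        self.n_fields = len(self.sites)
        self.n_years = self.sites[0].n_years
        self.n_particles = 50  # overridden by fit()

    # -- constructors --------------------------------------------------
    @classmethod
    def from_dataframes(cls, observations, schedule, climate, **kwargs) -> "SoilCarbonModel":
        return cls(sites_from_frames(observations, schedule, climate), **kwargs)

    @classmethod
    def from_csv(cls, observations_path, schedule_path, climate_path, **kwargs) -> "SoilCarbonModel":
        return cls.from_dataframes(
            pd.read_csv(observations_path),
            pd.read_csv(schedule_path),
            pd.read_csv(climate_path),
            **kwargs,
        )

    # -- parameter plumbing -------------------------------------------
    def full_theta(self, theta: dict) -> dict:
        out = {}
        for n in self.all_names:
            if n in theta:
                out[n] = theta[n]
            elif n in self.fixed:
                out[n] = self.fixed[n]
            else:
                out[n] = self.priors[n].median() if self.priors[n].family != "fixed" \
                    else self.priors[n].params[0]
        return out

    def _active_system(self, params: CarbonParameters) -> LinearSystem:
        sys_full = build_linear_system(self.structure, params)
        idx = [self.structure.index(p) for p in self.active_pools]
        return LinearSystem(
            A=sys_full.A[np.ix_(idx, idx)],
            b_alloc=sys_full.b_alloc[idx],
            Q=sys_full.Q[np.ix_(idx, idx)],
            H=np.ones((1, len(idx))),
            R=sys_full.R,
            co2_fractions=sys_full.co2_fractions[idx],
        )

    def _x0(self, theta: dict, fc: _FieldCache):
        total = theta["x0_total"] if self.x0_mode == "parameter" else fc.x0_obs
        iom = theta.get("iom_mass", 0.0)
        active_total = total - iom
        if active_total <= 0:
            return None, None
        m0 = active_total * self.x0_alloc
        P0 = np.eye(len(self.active_pools)) * self.x0_sd ** 2
        return m0, P0

    # -- pseudo-marginal problem interface ----------------------------
    def make_aux(self, rng: np.random.Generator) -> AuxiliaryBlock:
        return AuxiliaryBlock.draw(rng, self.n_particles, self.n_fields, self.n_years)

    def make_aux_sized(self, n_particles: int, rng: np.random.Generator) -> AuxiliaryBlock:
        return AuxiliaryBlock.draw(rng, n_particles, self.n_fields, self.n_years)

    def loglik(self, theta: dict, aux: AuxiliaryBlock):
        """Joint RBPF log-likelihood estimate over fields (independent
        trajectories, shared parameters)."""
        full = self.full_theta(theta)
        try:
            params = build_carbon_parameters(self.model_id, full)
            sys = self._active_system(params)
        except ValueError:
            # outside the joint support (e.g. one source pool's transfer
            # fractions exceeding 1): zero posterior density
            return -np.inf, None
        base_scale = full["carbon_content"] * full["yield_coef"]
        results = []
        ll = 0.0
        for f, fc in enumerate(self._fields):
            m0, P0 = self._x0(full, fc)
            if m0 is None:
                return -np.inf, None
            base_input = base_scale * fc.residue * fc.rain
            r = rbpf_filter(
                A=sys.A,
                Q=sys.Q,
                R=sys.R,
                b_alloc=sys.b_alloc,
                base_input=base_input,
                input_sd_log=full["input_sd_log"],
                m0=m0,
                P0=P0,
                obs_pos=fc.obs_pos,
                obs_vals=fc.obs_vals,
                obs_offset=full.get("iom_mass", 0.0) if "IOM" in self.structure.pools else 0.0,
                normals=aux.normals[:, f, :],
                resample_normals=aux.resample_normals[:, f, :],
            )
            if not np.isfinite(r.log_likelihood):
                return -np.inf, None
            ll += r.log_likelihood
            results.append(r)
        return ll, {"filters": results, "system": sys, "theta": full}

    def draw_states(self, theta: dict, extras, rng: np.random.Generator):
        """One latent active-pool trajectory per field from p(X | theta, Y)."""
        if extras is None:
            return None
        sys = extras["system"]
        states = []
        for r in extras["filters"]:
            x, u = rbpf_backward_sample(r, sys.A, sys.Q, sys.b_alloc, rng)
            states.append({"masses": x, "inputs": u})
        return states

    def check_states(self, states) -> bool:
        if states is None:
            return False
        if not self.structure.has_bio:
            return True
        return all(
            check_bio_constraint(
                st["masses"], self.structure,
                iom_mass=st.get("iom_mass", 0.0), cap=self.bio_cap, warn=False,
            )
            for st in states
        )

    # -- fitting -------------------------------------------------------
    def fit(
        self,
        iterations: int = 200_000,
        burn_in: int = 80_000,
        thin: int = 30,
        n_chains: int = 4,
        n_particles: int = 50,
        rho: float = 0.99,
        seed: int = 0,
        proposal_scales: float | dict = 0.15,
    ) -> "SoilCarbonResults":
        config = CpmConfig(
            iterations=iterations,
            burn_in=burn_in,
            thin=thin,
            n_chains=n_chains,
            n_particles=n_particles,
            rho=rho,
            seed=seed,
            proposal_scales=proposal_scales,
        )
        return self.fit_config(config)

    def fit_config(self, config: CpmConfig) -> "SoilCarbonResults":
        self.n_particles = config.n_particles
        trace = run_cpm(_ConstraintAwareView(self), config)
        return SoilCarbonResults(model=self, trace=trace)

    # -- simulation ----------------------------------------------------
    def simulate(self, theta: dict, seed=None, noise: bool = True):
        """Forward-simulate trajectories and noisy observations per field.

        Returns a list of dicts with keys ``masses`` (T, n_active),
        ``toc`` (T,), ``inputs`` (T,) and ``obs`` (values at the field's
        observation years).
        """
        from .inputs import carbon_input, simulate_dry_matter

        rng = np.random.default_rng(seed)
        full = self.full_theta(theta)
        params = build_carbon_parameters(self.model_id, full)
        sys = self._active_system(params)
        ip = build_input_parameters(full, self.residue_fraction)
        iom = full.get("iom_mass", 0.0) if "IOM" in self.structure.pools else 0.0
        out = []
        noise_sd = params.process_sd if noise else 0.0
        for s, fc in zip(self.sites, self._fields):
            xw = simulate_dry_matter(s.climate, s.schedule, ip, rng) if noise else \
                ip.yield_coef * s.climate.rain_mm * fc.growth
            u = carbon_input(xw, s.schedule, ip)
            m0, _ = self._x0(full, fc)
            if m0 is None:
                raise ValueError("initial TOC does not exceed the inert mass")
            x = m0.copy()
            T = s.n_years
            traj = np.empty((T, len(self.active_pools)))
            traj[0] = x
            for t in range(1, T):
                x = sys.A @ x + sys.b_alloc * u[t - 1]
                if noise_sd > 0:
                    x = np.clip(x + rng.normal(0, noise_sd, x.size), 0.0, None)
                traj[t] = x
            toc = traj.sum(axis=1) + iom
            obs = toc[fc.obs_pos] + (rng.normal(0, params.obs_sd, fc.obs_pos.size) if noise else 0.0)
            out.append({"masses": traj, "toc": toc, "inputs": u, "obs": obs})
        return out


def sample_posterior_states(
    model: SoilCarbonModel,
    trace: McmcTrace,
    n_particles: int = 50,
    seed: int = 0,
    max_retry: int = 200,
):
    """Draw one latent trajectory per retained parameter draw.

    Re-runs the RBPF at each retained theta (fresh auxiliaries) and draws
    a pool trajectory by backward simulation; draws violating the
    microbial-biomass cap are redrawn.  Returns a list (one entry per
    pooled retained draw) of per-field state dicts.
    """
    if not trace.chains or trace.chains[0].shape[0] == 0:
        raise ValueError("trace holds no retained draws")
    rng = np.random.default_rng(seed)
    names = trace.param_names
    out = []
    for row in trace.pooled():
        theta = dict(zip(names, row))
        full = model.full_theta(theta)
        iom = full.get("iom_mass", 0.0) if "IOM" in model.structure.pools else 0.0
        states = None
        for _ in range(max_retry):
            aux = model.make_aux_sized(n_particles, rng)
            ll, extras = model.loglik(theta, aux)
            if not np.isfinite(ll):
                continue
            states = model.draw_states(theta, extras, rng)
            for st in states:
                st["iom_mass"] = iom
            if model.check_states(states):
                break
        else:
            raise RuntimeError("no admissible trajectory found for a retained draw")
        out.append(states)
    return out


class _ConstraintAwareView(PseudoMarginalProblem):
    """Adapter passing the per-theta inert mass into the BIO check."""

    def __init__(self, model: SoilCarbonModel):
        self._m = model
        self.param_names = model.param_names
        self.priors = model.priors
        self.constrained = model.constrained

    def init_params(self, rng):
        return self._m.init_params(rng)

    def make_aux(self, rng):
        return self._m.make_aux(rng)

    def loglik(self, theta, aux):
        return self._m.loglik(theta, aux)

    def draw_states(self, theta, extras, rng):
        states = self._m.draw_states(theta, extras, rng)
        if states is not None:
            full = self._m.full_theta(theta)
            iom = full.get("iom_mass", 0.0) if "IOM" in self._m.structure.pools else 0.0
            for st in states:
                st["iom_mass"] = iom
        return states

    def check_states(self, states):
        if states is None:
            return False
        if not self._m.structure.has_bio:
            return True
        return all(
            check_bio_constraint(
                st["masses"], self._m.structure,
                iom_mass=st.get("iom_mass", 0.0), cap=self._m.bio_cap, warn=False,
            )
            for st in states
        )


class SoilCarbonResults:
    """Posterior draws and summaries for one fitted soil-carbon model."""

    def __init__(self, model: SoilCarbonModel, trace: McmcTrace):
        self.model = model
        self.trace = trace

    # -- parameters ----------------------------------------------------
    @property
    def param_names(self) -> list[str]:
        return self.trace.param_names

    def posterior(self) -> pd.DataFrame:
        """Pooled retained draws, one column per parameter."""
        return pd.DataFrame(self.trace.pooled(), columns=self.param_names)

    def rhat(self, split: bool = False) -> pd.DataFrame:
        return diagnostics.gelman_rubin_frame(self.trace.by_param(), split=split)

    def credible_interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        draws = self.posterior()[name].to_numpy()
        a = 100 * (1 - prob) / 2
        lo, hi = np.percentile(draws, [a, 100 - a])
        return float(lo), float(hi)

    def summary(self) -> pd.DataFrame:
        post = self.posterior()
        rows = []
        rhat = None
        if self.trace.n_chains >= 2:
            rhat = self.rhat().set_index("parameter")["rhat"]
        for n in self.param_names:
            d = post[n].to_numpy()
            lo, med, hi = np.percentile(d, [2.5, 50, 97.5])
            rows.append(
                {
                    "parameter": n,
                    "mean": d.mean(),
                    "sd": d.std(ddof=1),
                    "p2.5": lo,
                    "p50": med,
                    "p97.5": hi,
                    "rhat": float(rhat[n]) if rhat is not None else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    # -- latent states -------------------------------------------------
    def toc_draws(self, field: int | str = 0) -> np.ndarray:
        """(n_draws, T) posterior draws of the TOC trajectory of one field."""
        f = self._field_index(field)
        rows = []
        for chain_states in self.trace.states:
            for st in chain_states:
                rec = st[f]
                rows.append(rec["masses"].sum(axis=1) + rec.get("iom_mass", 0.0))
        return np.array(rows)

    def state_draws(self, field: int | str = 0) -> np.ndarray:
        """(n_draws, T, n_active) active-pool mass draws of one field."""
        f = self._field_index(field)
        return np.array(
            [st[f]["masses"] for chain in self.trace.states for st in chain]
        )

    def _field_index(self, field) -> int:
        if isinstance(field, int):
            return field
        for i, s in enumerate(self.model.sites):
            if s.field_id == field:
                return i
        raise KeyError(f"unknown field {field!r}")

    def soc_change(self, field: int | str = 0, t: int | None = None):
        """SOC change since the first trial year (negative = carbon loss)."""
        f = self._field_index(field)
        draws = self.toc_draws(f)
        years = self.model.sites[f].years
        if t is not None:
            return diagnostics.soc_change(draws, t)
        return diagnostics.soc_change_summary(draws, years, self.model.sites[f].field_id)

    def credible_band(self, field: int | str = 0, probabilities=diagnostics.DEFAULT_BAND_PROBS):
        f = self._field_index(field)
        return diagnostics.credible_band_frame(
            self.toc_draws(f), self.model.sites[f].years, probabilities
        )

    def rmse(self) -> pd.DataFrame:
        """Secondary point-accuracy report: RMSE of the posterior-median
        TOC trajectory against the observations, per field."""
        rows = []
        for i, s in enumerate(self.model.sites):
            med = np.median(self.toc_draws(i), axis=0)
            resid = med[s.obs_index()] - s.obs_toc
            rows.append(
                {
                    "field": s.field_id,
                    "rmse": float(np.sqrt(np.mean(resid**2))),
                    "n_obs": int(s.obs_toc.size),
                }
            )
        return pd.DataFrame(rows)

    # -- persistence ----------------------------------------------------
    def save(self, outdir) -> None:
        """Write trace, SOC summaries, diagnostics and a replay manifest."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.trace.to_frame().to_csv(out / "trace.csv", index=False)
        for i, s in enumerate(self.model.sites):
            self.soc_change(i).to_csv(out / f"soc_change_{s.field_id}.csv", index=False)
            self.credible_band(i).to_csv(out / f"credible_band_{s.field_id}.csv", index=False)
        if self.trace.n_chains >= 2:
            self.rhat().to_csv(out / "diagnostics.csv", index=False)
        cfg = self.trace.config
        manifest = {
            "model_id": self.model.model_id,
            "fields": [s.field_id for s in self.model.sites],
            "sampled_parameters": self.param_names,
            "fixed": self.model.fixed,
            "mcmc": {
                "iterations": cfg.iterations,
                "burn_in": cfg.burn_in,
                "thin": cfg.thin,
                "n_chains": cfg.n_chains,
                "n_particles": cfg.n_particles,
                "rho": cfg.rho,
                "seed": cfg.seed,
            },
            "accept_rates": self.trace.accept_rates,
            "constraint_rejections": self.trace.constraint_rejections,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
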