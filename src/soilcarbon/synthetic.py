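"""Synthetic site generator.

Builds complete synthetic agricultural trials with the structure of the
long-term Australian experiments the models are designed for: roughly two
decades of annual forcing for a handful of fields or soil types, sparse
total-organic-carbon observations (3-6 per field), Mediterranean or
semi-arid growing-season rainfall, and management schedules drawn from a
closed vocabulary of treatments (wheat for grain/hay, pasture, sorghum,
fallow, land clearing).

The generator simulates rainfall, plant dry matter, pool dynamics (with
process noise) and noisy observations from a chosen pool model at known
parameter values, and returns the ground truth alongside the data so
parameter- and model-recovery can be tested end to end without any real
deposit.  Observation-year patterns for the Brigalow-style template are
synthetic (plausible sparse patterns, not the real campaign years).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .inputs import ClimateSeries, InputParameters, ManagementSchedule, carbon_input, simulate_dry_matter
from .model import DEFAULT_X0_ALLOC, build_carbon_parameters, build_input_parameters
from .pools import CarbonState, Trajectory, build_pool_structure, simulate_process
from .site import SiteSeries

#: default generating parameters per model variant (annual rates, Mg C/ha)
TRUE_PARAMS = {
    "one": {"K_C": 0.04},
    "two": {"K_C": 0.05, "iom_mass": 6.0},
    "three": {
        "K_C": 0.05,
        "K_B": 0.5,
        "C_to_BIO": 0.12,
        "BIO_to_BIO": 0.15,
        "BIO_to_C": 0.35,
        "iom_mass": 6.0,
    },
    "five": {
        "K_D": 8.0,
        "K_R": 0.25,
        "K_B": 0.6,
        "K_H": 0.02,
        "ret_DPM": 0.4,
        "ret_RPM": 0.4,
        "ret_BIO": 0.4,
        "ret_HUM": 0.4,
        "iom_mass": 6.0,
        "dpm_split": 0.59,
        "bio_hum_split": 0.46,
    },
}

COMMON_TRUE = {
    "process_sd": 0.6,
    "obs_sd": 1.2,
    "yield_coef": 0.01,
    "input_sd_log": 0.25,
    "carbon_content": 0.45,
}


@dataclass
class SiteConfig:
    """Recipe for one synthetic site."""

    name: str
    years: tuple[int, int]                      # inclusive range
    treatments: dict[str, list[str]]            # field id -> one label per year
    obs_years: dict[str, list[int]]             # field id -> sampling years
    x0_total: dict[str, float]                  # field id -> initial TOC, Mg C/ha
    rainfall_mean: float = 355.0                # growing-season mm
    rainfall_sd_log: float = 0.25
    model_id: str = "three"
    true_params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_fields(self) -> int:
        return len(self.treatments)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def validate(self) -> None:
        yrs = set(self.year_list)
        n = len(self.year_list)
        for fid, tr in self.treatments.items():
            if len(tr) != n:
                raise ValueError(f"field {fid!r}: {len(tr)} treatments for {n} years")
        for fid, oy in self.obs_years.items():
            bad = set(oy) - yrs
            if bad:
                raise ValueError(f"field {fid!r}: observation years outside trial: {sorted(bad)}")
            if len(oy) < 2:
                raise ValueError(f"field {fid!r}: need at least 2 observations")

    def resolved_params(self) -> dict:
        theta = dict(COMMON_TRUE)
        theta.update(TRUE_PARAMS[self.model_id])
        theta.update(self.true_params)
        return theta

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SiteConfig":
        d = json.loads(text)
        d["years"] = tuple(d["years"])
        return cls(**d)


def _years_with(template: dict[str, list], default: str, year_list: list[int]) -> list[str]:
    """Expand {treatment: [years or (start, end) ranges]} into per-year labels."""
    labels = [default] * len(year_list)
    pos = {y: i for i, y in enumerate(year_list)}
    for treat, spans in template.items():
        for span in spans:
            if isinstance(span, (tuple, list)):
                lo, hi = span
                for y in range(lo, hi + 1):
                    labels[pos[y]] = treat
            else:
                labels[pos[span]] = treat
    return labels


def tarlee_template(seed: int = 0, model_id: str = "three") -> SiteConfig:
    """Mediterranean-climate template: 3 fields, 1979-1997, winter rainfall
    averaging 355 mm, soil sampled in 1979, 1985 and 1996."""
    years = list(range(1979, 1998))
    f1 = _years_with(
        {"wheat_grain": [(1979, 1987), (1990, 1996)], "wheat_hay": [1988, 1989],
         "fallow": [1997]},
        "wheat_grain", years,
    )
    # alternating wheat and fallow rotation
    f2 = ["wheat_grain" if (y - 1979) % 2 == 0 else "fallow" for y in years]
    f2[years.index(1989)] = "wheat_hay"
    f2[years.index(1997)] = "fallow"
    f3 = _years_with(
        {"wheat_pasture": [(1979, 1987), (1990, 1996)], "wheat_hay": [1988, 1989],
         "fallow": [1997]},
        "wheat_pasture", years,
    )
    obs = [1979, 1985, 1996]
    return SiteConfig(
        name="tarlee",
        years=(1979, 1997),
        treatments={"field1": f1, "field2": f2, "field3": f3},
        obs_years={"field1": obs, "field2": obs, "field3": obs},
        x0_total={"field1": 42.0, "field2": 45.0, "field3": 48.0},
        rainfall_mean=355.0,
        rainfall_sd_log=0.25,
        model_id=model_id,
        seed=seed,
    )


def brigalow_template(seed: int = 0, model_id: str = "three") -> SiteConfig:
    """Semi-arid subtropical template: 3 soil types cleared in 1982, then
    continuous wheat with occasional sorghum over 18 years; fallow in 1983
    and 1993.  Observation years are a synthetic sparse pattern."""
    years = list(range(1981, 2001))
    sched = _years_with(
        {
            "cleared": [1982],
            "fallow": [1983, 1993],
            "sorghum": [1984, 1995, 1997, 1999],
            "wheat_grain": [(1985, 1992), 1994, 1996, 1998, 2000],
        },
        "pasture",  # pre-clearing native vegetation approximated as pasture
        years,
    )
    obs = [1981, 1986, 1990, 1994, 1997, 2000]
    return SiteConfig(
        name="brigalow",
        years=(1981, 2000),
        treatments={f"soil{i}": list(sched) for i in (1, 2, 3)},
        obs_years={f"soil{i}": list(obs) for i in (1, 2, 3)},
        x0_total={"soil1": 50.0, "soil2": 55.0, "soil3": 45.0},
        rainfall_mean=500.0,
        rainfall_sd_log=0.3,
        model_id=model_id,
        seed=seed,
    )


def make_site(config: SiteConfig):
    """Generate one synthetic site.

    Returns ``(sites, theta_true, trajectories)``: one :class:`SiteSeries`
    per field with sparse noisy TOC observations, the generating parameter
    dictionary, and the true latent :class:`~soilcarbon.pools.Trajectory`
    per field.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    theta = config.resolved_params()
    structure = build_pool_structure(config.model_id)
    params = build_carbon_parameters(config.model_id, theta)
    input_params: InputParameters = build_input_parameters(theta)
    year_list = config.year_list
    n = len(year_list)
    sigma = config.rainfall_sd_log
    # log-normal rainfall with mean equal to the configured regime mean
    rain = config.rainfall_mean * np.exp(sigma * rng.standard_normal(n) - 0.5 * sigma**2)
    climate = ClimateSeries(years=np.array(year_list), rain_mm=rain)

    alloc = DEFAULT_X0_ALLOC[config.model_id]
    iom = theta.get("iom_mass", 0.0) if "IOM" in structure.pools else 0.0
    sites, trajectories = [], []
    for fid, labels in config.treatments.items():
        schedule = ManagementSchedule(years=np.array(year_list), treatments=list(labels))
        xw = simulate_dry_matter(climate, schedule, input_params, rng)
        u = carbon_input(xw, schedule, input_params)
        active_total = config.x0_total[fid] - iom
        if active_total <= 0:
            raise ValueError(f"field {fid!r}: initial TOC does not exceed the inert mass")
        masses0 = np.array(
            [alloc.get(p, 0.0) * active_total if p not in structure.constant else iom
             for p in structure.pools]
        )
        x0 = CarbonState(year=1, masses=masses0)
        traj: Trajectory = simulate_process(
            structure, params, u[:-1], x0, noise=params.process_sd > 0, rng=rng
        )
        toc = traj.toc_series()
        obs_years = np.array(sorted(config.obs_years[fid]), dtype=int)
        pos = np.array([year_list.index(int(y)) for y in obs_years])
        obs = toc[pos] + rng.normal(0.0, params.obs_sd, obs_years.size)
        sites.append(
            SiteSeries(
                field_id=fid,
                schedule=schedule,
                climate=climate,
                obs_years=obs_years,
                obs_toc=obs,
            )
        )
        trajectories.append(traj)
    return sites, theta, trajectories


def write_site(config: SiteConfig, outdir) -> None:
    """Generate a site and write the pipeline CSVs plus a truth JSON."""
    from pathlib import Path

    from .site import write_site_csvs

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sites, theta, trajectories = make_site(config)
    write_site_csvs(
        sites, out / "observations.csv", out / "schedule.csv", out / "climate.csv"
    )
    truth = {
        "config": json.loads(config.to_json()),
        "parameters": theta,
        "toc_trajectories": {
            s.field_id: t.toc_series().tolist() for s, t in zip(sites, trajectories)
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
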