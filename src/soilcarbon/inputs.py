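"""Stochastic plant-input sub-model.

Annual plant dry matter ``X_W`` (Mg/ha) is the nonlinear, non-Gaussian part
of the state-space model: in crop or pasture years it is proportional to
growing-season rainfall with multiplicative log-normal noise, and zero in
fallow or newly-cleared years.  Dry matter is converted to the annual
carbon input feeding the pools through a treatment-specific residue
fraction and the carbon content of dry matter.

Conditional on a realised ``X_W`` sequence the remaining pool dynamics are
linear-Gaussian, which is the split the Rao-Blackwellised particle filter
exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

TREATMENTS = (
    "wheat_grain",
    "wheat_hay",
    "wheat_pasture",
    "pasture",
    "sorghum",
    "fallow",
    "cleared",
)

#: treatments in which no crop grows and the annual input is zero
NO_GROWTH = frozenset({"fallow", "cleared"})

#: default share of dry matter returned to the soil per treatment;
#: harvesting hay removes more biomass than taking grain.
DEFAULT_RESIDUE_FRACTIONS = {
    "wheat_grain": 0.60,
    "wheat_hay": 0.45,
    "wheat_pasture": 0.35,
    "pasture": 0.35,
    "sorghum": 0.55,
    "fallow": 0.0,
    "cleared": 0.0,
}


@dataclass
class ManagementSchedule:
    """One treatment label per trial year for one field."""

    years: np.ndarray
    treatments: list[str]

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        if len(self.years) != len(self.treatments):
            raise ValueError("years and treatments must align")
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatment labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.years)


@dataclass
class ClimateSeries:
    """Growing-season rainfall (mm) per trial year."""

    years: np.ndarray
    rain_mm: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.rain_mm = np.asarray(self.rain_mm, dtype=float)
        if self.years.shape != self.rain_mm.shape:
            raise ValueError("years and rain_mm must align")
        if np.any(self.rain_mm < 0):
            raise ValueError("rainfall must be nonnegative")

    def __len__(self) -> int:
        return len(self.years)


@dataclass
class InputParameters:
    """Parameters of the plant-input sub-model.

    yield_coef
        dry matter produced per mm of growing-season rainfall
        (Mg DM / ha / mm).
    residue_fraction
        share of dry matter left in/on the soil per treatment; zero in
        fallow and cleared years.
    carbon_content
        carbon share of dry matter (default 0.45).
    input_sd_log
        standard deviation of the log-scale yield noise.
    """

    yield_coef: float = 0.01
    residue_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_FRACTIONS)
    )
    carbon_content: float = 0.45
    input_sd_log: float = 0.25

    def validate(self) -> None:
        if self.yield_coef <= 0:
            raise ValueError("yield_coef must be positive")
        if not 0.0 <= self.carbon_content <= 1.0:
            raise ValueError("carbon_content must be in [0, 1]")
        if self.input_sd_log < 0:
            raise ValueError("input_sd_log must be nonnegative")
        if self.residue_fraction.get("fallow", 0.0) != 0.0:
            raise ValueError("fallow residue fraction must be zero")


def growth_mask(schedule: ManagementSchedule) -> np.ndarray:
    return np.array([t not in NO_GROWTH for t in schedule.treatments])


def simulate_dry_matter(
    climate: ClimateSeries,
    schedule: ManagementSchedule,
    params: InputParameters,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw one annual dry-matter sequence X_W (Mg/ha).

    Crop/pasture years: ``X_W = yield_coef * rain * exp(eps)`` with
    ``eps ~ N(0, input_sd_log^2)``; fallow and cleared years are zero.
    """
    if len(climate) != len(schedule):
        raise ValueError("climate and schedule must cover the same years")
    params.validate()
    rng = np.random.default_rng(rng)
    eps = rng.normal(0.0, params.input_sd_log, size=len(climate))
    xw = params.yield_coef * climate.rain_mm * np.exp(eps)
    return np.where(growth_mask(schedule), xw, 0.0)


def carbon_input(
    xw: Sequence[float],
    schedule: ManagementSchedule,
    params: InputParameters,
) -> np.ndarray:
    """Annual carbon input to the soil (Mg C/ha) from dry matter X_W."""
    xw = np.asarray(xw, dtype=float)
    if xw.shape[0] != len(schedule):
        raise ValueError("xw and schedule must align")
    try:
        resid = np.array([params.residue_fraction[t] for t in schedule.treatments])
    except KeyError as e:
        raise ValueError(f"treatment {e.args[0]!r} has no residue fraction") from None
    return params.carbon_content * resid * xw
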