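"""Site data container and plain-CSV I/O.

A :class:`SiteSeries` holds everything known about one field: the trial
years, the management schedule, growing-season rainfall, and the sparse
total-organic-carbon (TOC) observations.  A site typically has several
fields (or soil types) measured under different managements; they share one
parameter vector during inference but carry independent latent
trajectories.

CSV schemas (one site, all fields in one file each):

* observations: ``field,year,toc``
* schedule:     ``field,year,treatment``
* climate:      ``year,rain_mm``  (shared across fields)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inputs import ClimateSeries, ManagementSchedule


@dataclass
class SiteSeries:
    """Forcing and data for one field."""

    field_id: str
    schedule: ManagementSchedule
    climate: ClimateSeries
    obs_years: np.ndarray
    obs_toc: np.ndarray

    def __post_init__(self):
        self.obs_years = np.asarray(self.obs_years, dtype=int)
        self.obs_toc = np.asarray(self.obs_toc, dtype=float)
        if self.obs_years.shape != self.obs_toc.shape:
            raise ValueError("obs_years and obs_toc must align")
        if len(self.schedule) != len(self.climate):
            raise ValueError("schedule and climate must cover the same years")
        if not np.array_equal(self.schedule.years, self.climate.years):
            raise ValueError("schedule and climate years differ")
        missing = set(self.obs_years) - set(self.schedule.years.tolist())
        if missing:
            raise ValueError(f"observation years outside trial years: {sorted(missing)}")
        order = np.argsort(self.obs_years)
        self.obs_years = self.obs_years[order]
        self.obs_toc = self.obs_toc[order]

    @property
    def years(self) -> np.ndarray:
        return self.schedule.years

    @property
    def n_years(self) -> int:
        return len(self.schedule)

    def obs_index(self) -> np.ndarray:
        """0-based positions of the observation years within the trial years."""
        year_to_pos = {int(y): i for i, y in enumerate(self.years)}
        return np.array([year_to_pos[int(y)] for y in self.obs_years], dtype=int)

    def truncated(self, obs_keep: int) -> "SiteSeries":
        """Copy keeping only the first ``obs_keep`` observations (full forcing)."""
        return SiteSeries(
            field_id=self.field_id,
            schedule=self.schedule,
            climate=self.climate,
            obs_years=self.obs_years[:obs_keep],
            obs_toc=self.obs_toc[:obs_keep],
        )


def sites_from_frames(
    observations: pd.DataFrame,
    schedule: pd.DataFrame,
    climate: pd.DataFrame,
) -> list[SiteSeries]:
    """Assemble one SiteSeries per field from the three flat tables."""
    for col, frame, name in [
        ("field", observations, "observations"),
        ("field", schedule, "schedule"),
        ("rain_mm", climate, "climate"),
    ]:
        if col not in frame.columns:
            raise ValueError(f"{name} table lacks required column {col!r}")
    clim = ClimateSeries(
        years=climate["year"].to_numpy(),
        rain_mm=climate["rain_mm"].to_numpy(),
    )
    sites = []
    for fid, sched_f in schedule.groupby("field", sort=True):
        sched_f = sched_f.sort_values("year")
        sched = ManagementSchedule(
            years=sched_f["year"].to_numpy(),
            treatments=sched_f["treatment"].tolist(),
        )
        obs_f = observations[observations["field"] == fid].sort_values("year")
        sites.append(
            SiteSeries(
                field_id=str(fid),
                schedule=sched,
                climate=clim,
                obs_years=obs_f["year"].to_numpy(),
                obs_toc=obs_f["toc"].to_numpy(),
            )
        )
    return sites


def read_site_csvs(observations_path, schedule_path, climate_path) -> list[SiteSeries]:
    return sites_from_frames(
        pd.read_csv(observations_path),
        pd.read_csv(schedule_path),
        pd.read_csv(climate_path),
    )


def write_site_csvs(sites: list[SiteSeries], observations_path, schedule_path, climate_path) -> None:
    obs_rows, sched_rows = [], []
    for s in sites:
        for y, v in zip(s.obs_years, s.obs_toc):
            obs_rows.append({"field": s.field_id, "year": int(y), "toc": float(v)})
        for y, t in zip(s.schedule.years, s.schedule.treatments):
            sched_rows.append({"field": s.field_id, "year": int(y), "treatment": t})
    clim = sites[0].climate
    pd.DataFrame(obs_rows).to_csv(observations_path, index=False)
    pd.DataFrame(sched_rows).to_csv(schedule_path, index=False)
    pd.DataFrame({"year": clim.years, "rain_mm": clim.rain_mm}).to_csv(
        climate_path, index=False
    )
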