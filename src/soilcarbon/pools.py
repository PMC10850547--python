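"""Multi-pool soil carbon dynamics.

Four nested pool topologies describe the turnover of soil organic carbon
(SOC) on an annual time step:

* ``one``   — all SOC as a single homogeneous decaying pool C.
* ``two``   — C plus an inert pool (IOM) that undergoes no biological
  transformation and stays constant.
* ``three`` — a decomposable pool C, a microbial biomass pool (BIO) and IOM.
  Decayed C is partly assimilated by BIO, the rest respired as CO2; decayed
  BIO is re-assimilated, returned to C, or respired.
* ``five``  — the RothC pool set: DPM, RPM (fast/slow plant material), BIO,
  HUM (humified matter) and IOM.  Plant input is split between DPM and RPM;
  decay products of the four active pools are routed to BIO and HUM or lost
  as CO2.

Each decaying pool loses mass by first-order decay: over one year a pool
with rate ``K`` (1/yr) retains the fraction ``exp(-K)`` and the decayed
fraction ``1 - exp(-K)`` is split across destination pools (and CO2) by
transfer fractions.  This keeps the process linear-Gaussian conditional on
the annual carbon inputs, which is what permits exact Kalman marginalisation
of the pool states during inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

CO2 = "CO2"

MODEL_IDS = ("one", "two", "three", "five")


@dataclass(frozen=True)
class PoolStructure:
    """Topology of a soil-carbon model.

    ``routes`` maps a source pool to ``(destination, fraction_name)`` pairs;
    the CO2 destination is implicit (remainder of the decayed mass).
    ``input_split`` maps the pools receiving plant input to the name of the
    fraction parameter governing the split.
    """

    model_id: str
    pools: tuple[str, ...]
    decaying: frozenset[str]
    constant: frozenset[str]
    routes: Mapping[str, tuple[tuple[str, str], ...]]
    input_split: Mapping[str, str]

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def index(self, pool: str) -> int:
        return self.pools.index(pool)

    @property
    def has_bio(self) -> bool:
        return "BIO" in self.pools

    def to_dict(self) -> dict:
        """JSON-serialisable description of the topology."""
        return {
            "model_id": self.model_id,
            "pools": list(self.pools),
            "decaying": sorted(self.decaying),
            "constant": sorted(self.constant),
            "routes": {
                src: [[dest, name] for dest, name in dests]
                for src, dests in self.routes.items()
            },
            "input_split": dict(self.input_split),
        }

    def validate(self) -> None:
        for p in self.constant:
            if p in self.routes and self.routes[p]:
                raise ValueError(f"constant pool {p!r} must have no outgoing routes")
            for src, dests in self.routes.items():
                for dest, _ in dests:
                    if dest == p:
                        raise ValueError(f"constant pool {p!r} must have no incoming routes")
        for src in self.routes:
            if src not in self.decaying:
                raise ValueError(f"route source {src!r} is not a decaying pool")


def build_pool_structure(model_id: str) -> PoolStructure:
    """Return the fixed pool topology for one of the four model variants."""
    if model_id == "one":
        s = PoolStructure(
            model_id="one",
            pools=("C",),
            decaying=frozenset({"C"}),
            constant=frozenset(),
            routes={"C": ()},
            input_split={"C": "input_C"},
        )
    elif model_id == "two":
        s = PoolStructure(
            model_id="two",
            pools=("C", "IOM"),
            decaying=frozenset({"C"}),
            constant=frozenset({"IOM"}),
            routes={"C": ()},
            input_split={"C": "input_C"},
        )
    elif model_id == "three":
        # C decays to BIO or CO2; BIO decays to BIO (re-assimilation), C, or CO2.
        s = PoolStructure(
            model_id="three",
            pools=("C", "BIO", "IOM"),
            decaying=frozenset({"C", "BIO"}),
            constant=frozenset({"IOM"}),
            routes={
                "C": (("BIO", "C_to_BIO"),),
                "BIO": (("BIO", "BIO_to_BIO"), ("C", "BIO_to_C")),
            },
            input_split={"C": "input_C"},
        )
    elif model_id == "five":
        active = ("DPM", "RPM", "BIO", "HUM")
        routes = {
            src: ((("BIO", f"{src}_to_BIO"), ("HUM", f"{src}_to_HUM")))
            for src in active
        }
        s = PoolStructure(
            model_id="five",
            pools=("DPM", "RPM", "BIO", "HUM", "IOM"),
            decaying=frozenset(active),
            constant=frozenset({"IOM"}),
            routes=routes,
            input_split={"DPM": "input_DPM", "RPM": "input_RPM"},
        )
    else:
        raise ValueError(
            f"unknown model_id {model_id!r}: expected one of {MODEL_IDS}"
        )
    s.validate()
    return s


@dataclass
class CarbonParameters:
    """Parameter values for one pool structure.

    decay_rates
        per decaying pool, first-order rate (1/yr).
    transfer_fractions
        route-name -> fraction in [0, 1]; per source the fractions to pools
        sum to <= 1, the remainder is the CO2 share.  Also holds the
        plant-input split fractions named in ``PoolStructure.input_split``.
    iom_mass
        constant inert-pool mass (Mg C/ha); ignored by the one-pool model.
    process_sd, obs_sd
        additive-Gaussian process and observation standard deviations
        (Mg C/ha).
    """

    decay_rates: dict[str, float]
    transfer_fractions: dict[str, float] = field(default_factory=dict)
    iom_mass: float = 0.0
    process_sd: float = 0.0
    obs_sd: float = 0.0

    def validate(self, structure: PoolStructure) -> None:
        for p in structure.decaying:
            k = self.decay_rates.get(p, 0.0)
            if k < 0:
                raise ValueError(f"decay rate for {p!r} must be >= 0, got {k}")
        for p in structure.constant:
            if self.decay_rates.get(p, 0.0) != 0.0:
                raise ValueError(f"constant pool {p!r} must have zero decay rate")
        for src, dests in structure.routes.items():
            total = 0.0
            for _, name in dests:
                f = self.transfer_fractions.get(name, 0.0)
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"transfer fraction {name} = {f} outside [0, 1]")
                total += f
            if total > 1.0 + 1e-12:
                raise ValueError(
                    f"transfer fractions out of pool {src!r} sum to {total} > 1"
                )
        if self.iom_mass < 0:
            raise ValueError("iom_mass must be nonnegative")
        if self.process_sd < 0 or self.obs_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")


@dataclass
class CarbonState:
    """Pool masses (Mg C/ha) in one trial year (1-based year index)."""

    year: int
    masses: np.ndarray
    cumulative_co2: float = 0.0


def toc(state: CarbonState) -> float:
    """Total organic carbon: the summation of all pool masses."""
    return float(np.sum(state.masses))


@dataclass
class LinearSystem:
    """Discrete annual linear-Gaussian realisation of a pool structure.

    x_{t+1} = A x_t + b_alloc * u_t + w_t,  w_t ~ N(0, Q)
    y_t     = H x_t + v_t,                  v_t ~ N(0, R)

    ``co2_fractions[j]`` is the share of pool j's current mass emitted as
    CO2 during the year, so emission(t) = co2_fractions @ x_t.
    """

    A: np.ndarray
    b_alloc: np.ndarray
    Q: np.ndarray
    H: np.ndarray
    R: float
    co2_fractions: np.ndarray


def build_linear_system(structure: PoolStructure, params: CarbonParameters) -> LinearSystem:
    """Assemble the annual transition system for ``structure`` at ``params``.

    Decaying pool j survives with A[j,j] = exp(-K_j); the decayed share
    (1 - exp(-K_j)) is routed by the transfer fractions, with the CO2 share
    implicit.  Constant pools are unit self-loops with no noise.
    """
    params.validate(structure)
    d = structure.n_pools
    A = np.zeros((d, d))
    co2 = np.zeros(d)
    for j, p in enumerate(structure.pools):
        if p in structure.constant:
            A[j, j] = 1.0
            continue
        k = params.decay_rates.get(p, 0.0)
        surv = np.exp(-k)
        decayed = 1.0 - surv
        A[j, j] = surv
        routed = 0.0
        for dest, name in structure.routes.get(p, ()):
            f = params.transfer_fractions.get(name, 0.0)
            A[structure.index(dest), j] += decayed * f
            routed += f
        co2[j] = decayed * (1.0 - routed)
    b = np.zeros(d)
    for p, name in structure.input_split.items():
        b[structure.index(p)] = params.transfer_fractions.get(name, 1.0)
    Q = np.zeros((d, d))
    for p in structure.decaying:
        Q[structure.index(p), structure.index(p)] = params.process_sd ** 2
    H = np.ones((1, d))
    return LinearSystem(A=A, b_alloc=b, Q=Q, H=H, R=params.obs_sd ** 2, co2_fractions=co2)


@dataclass
class Trajectory:
    """Forward-simulation output: a sequence of states plus bookkeeping."""

    structure: PoolStructure
    states: list[CarbonState]
    clipped_years: list[int] = field(default_factory=list)

    def toc_series(self) -> np.ndarray:
        return np.array([toc(s) for s in self.states])

    def masses(self) -> np.ndarray:
        return np.array([s.masses for s in self.states])

    def to_frame(self):
        import pandas as pd

        rows = {
            "year": [s.year for s in self.states],
        }
        m = self.masses()
        for j, p in enumerate(self.structure.pools):
            rows[p] = m[:, j]
        rows["toc"] = self.toc_series()
        rows["co2_cum"] = [s.cumulative_co2 for s in self.states]
        return pd.DataFrame(rows)


def simulate_process(
    structure: PoolStructure,
    params: CarbonParameters,
    inputs: Sequence[float],
    x0: CarbonState,
    noise: bool = False,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Simulate the pool process forward for ``len(inputs)`` annual steps.

    Returns a trajectory of T+1 states (the initial state then one per
    transition); step t consumes ``inputs[t]``.  With ``noise`` on, additive
    Gaussian process noise is applied to decaying pools; a negative
    excursion is clipped to zero and the year recorded in
    ``Trajectory.clipped_years``.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 1 or inputs.size < 1:
        raise ValueError("inputs must be a nonempty 1-d sequence")
    if np.any(inputs < 0):
        raise ValueError("annual carbon inputs must be nonnegative")
    if np.any(np.asarray(x0.masses) < 0):
        raise ValueError("initial pool masses must be nonnegative")
    sys = build_linear_system(structure, params)
    if noise:
        rng = np.random.default_rng(rng)
        noise_mask = np.array([p in structure.decaying for p in structure.pools])
    x = np.asarray(x0.masses, dtype=float).copy()
    co2_cum = float(x0.cumulative_co2)
    states = [CarbonState(year=x0.year, masses=x.copy(), cumulative_co2=co2_cum)]
    clipped = []
    for t, u in enumerate(inputs):
        co2_cum += float(sys.co2_fractions @ x)
        x = sys.A @ x + sys.b_alloc * u
        if noise:
            x = x + noise_mask * rng.normal(0.0, params.process_sd, size=x.size)
            if np.any(x < 0):
                clipped.append(x0.year + t + 1)
                x = np.clip(x, 0.0, None)
        states.append(CarbonState(year=x0.year + t + 1, masses=x.copy(), cumulative_co2=co2_cum))
    return Trajectory(structure=structure, states=states, clipped_years=clipped)
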