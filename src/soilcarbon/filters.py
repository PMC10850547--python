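"""Likelihood machinery: Kalman filter, bootstrap particle filter, and the
Rao-Blackwellised particle filter (RBPF).

The state-space model factorises into a nonlinear sub-model (annual plant
dry matter, log-normal) and, conditional on the realised input path, a
linear-Gaussian pool sub-model.  The RBPF therefore carries particles only
for the input path and marginalises the pool states exactly with a Kalman
filter per particle.  Because the transition matrix, process noise and
initial covariance are shared across particles, all particles share one
covariance recursion; only the means differ, which keeps a likelihood
evaluation cheap.

Constant pools (IOM) have zero dynamics and zero noise, so the filter runs
on the decaying pools only and folds the inert mass into the observation
offset; this keeps covariances non-singular whenever the noise scales are
positive.

All randomness is injected through :class:`AuxiliaryBlock` arrays of
standard normals so that likelihood estimates are deterministic functions
of (parameters, data, auxiliary variables) — the property the correlated
pseudo-marginal sampler relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, ndtr

LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------
# auxiliary randomness
# ---------------------------------------------------------------------
@dataclass
class AuxiliaryBlock:
    """Standard-normal innovations and resampling variates for one run.

    ``normals``           (n_particles, n_fields, T)  input-noise draws
    ``resample_normals``  (n_particles, n_fields, T)  mapped to uniforms
    ``extra_normals``     optional (n_particles, n_fields, T, k) for joint
                          bootstrap filtering over pools as well.
    """

    normals: np.ndarray
    resample_normals: np.ndarray
    extra_normals: np.ndarray | None = None

    @classmethod
    def draw(
        cls,
        rng: np.random.Generator,
        n_particles: int,
        n_fields: int,
        n_years: int,
        extra_dim: int = 0,
    ) -> "AuxiliaryBlock":
        shape = (n_particles, n_fields, n_years)
        extra = rng.standard_normal(shape + (extra_dim,)) if extra_dim else None
        return cls(
            normals=rng.standard_normal(shape),
            resample_normals=rng.standard_normal(shape),
            extra_normals=extra,
        )

    def refresh(self, rho: float, rng: np.random.Generator) -> "AuxiliaryBlock":
        """Correlated proposal: rho * current + sqrt(1 - rho^2) * fresh."""
        c = np.sqrt(1.0 - rho * rho)

        def mix(a):
            if a is None:
                return None
            return rho * a + c * rng.standard_normal(a.shape)

        return AuxiliaryBlock(
            normals=mix(self.normals),
            resample_normals=mix(self.resample_normals),
            extra_normals=mix(self.extra_normals),
        )

    def resample_uniforms(self) -> np.ndarray:
        return ndtr(self.resample_normals)


def stratified_resample(weights: np.ndarray, uniforms: np.ndarray) -> np.ndarray:
    """Stratified resampling indices from normalised weights.

    ``uniforms[i]`` positions the draw inside stratum i of [0, 1).
    """
    n = weights.size
    positions = (np.arange(n) + uniforms) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(0, n - 1)


# ---------------------------------------------------------------------
# Kalman filter
# ---------------------------------------------------------------------
@dataclass
class KalmanResult:
    log_likelihood: float
    means: np.ndarray       # (T, d) filtered means
    covs: np.ndarray        # (T, d, d) filtered covariances
    increments: dict        # obs position -> log-likelihood increment


def kalman_filter(
    A: np.ndarray,
    Q: np.ndarray,
    H: np.ndarray,
    R: float,
    b_seq: np.ndarray,
    m0: np.ndarray,
    P0: np.ndarray,
    obs_pos: np.ndarray,
    obs_vals: np.ndarray,
    obs_offset: float = 0.0,
) -> KalmanResult:
    """Exact Gaussian marginal likelihood of sparse scalar observations.

    State x_0 ~ N(m0, P0); x_{t+1} = A x_t + b_seq[t] + w_t; observations
    y = H x + obs_offset + v at the 0-based positions ``obs_pos``.  Years
    without observations are pure prediction steps.
    """
    A = np.asarray(A, float)
    d = A.shape[0]
    h = np.asarray(H, float).reshape(d)
    b_seq = np.asarray(b_seq, float).reshape(-1, d)
    T = b_seq.shape[0] + 1
    obs_pos = np.asarray(obs_pos, int)
    if obs_pos.size and (obs_pos.min() < 0 or obs_pos.max() >= T):
        raise ValueError("observation positions outside the trajectory")
    obs_map = dict(zip(obs_pos.tolist(), np.asarray(obs_vals, float).tolist()))

    m = np.asarray(m0, float).copy()
    P = np.asarray(P0, float).copy()
    means = np.empty((T, d))
    covs = np.empty((T, d, d))
    ll = 0.0
    increments: dict[int, float] = {}
    for t in range(T):
        if t > 0:
            m = A @ m + b_seq[t - 1]
            P = A @ P @ A.T + Q
        if t in obs_map:
            s = float(h @ P @ h) + R
            if s <= 0:
                if s < 0:
                    raise ValueError("non-positive-definite innovation variance")
                s = 1e-300  # degenerate noise-free observation
            e = obs_map[t] - float(h @ m) - obs_offset
            inc = -0.5 * (LOG2PI + np.log(s) + e * e / s)
            ll += inc
            increments[t] = inc
            K = (P @ h) / s
            m = m + K * e
            P = P - np.outer(K, h @ P)
        means[t] = m
        covs[t] = P
    return KalmanResult(log_likelihood=ll, means=means, covs=covs, increments=increments)


# ---------------------------------------------------------------------
# generic bootstrap particle filter
# ---------------------------------------------------------------------
@dataclass
class ParticleFilterResult:
    log_likelihood: float
    weights: dict = field(default_factory=dict)   # obs position -> normalised weights
    ess: dict = field(default_factory=dict)       # obs position -> effective sample size
    increments: dict = field(default_factory=dict)
    particles: np.ndarray | None = None           # final particle set
    degenerate: bool = False                      # all-zero weights encountered


def bootstrap_pf(
    init,
    propagate,
    log_obs_density,
    T: int,
    obs_pos: np.ndarray,
    n_particles: int,
    aux_normals: np.ndarray,
    aux_resample: np.ndarray,
    ess_threshold: float = 1.0,
) -> ParticleFilterResult:
    """Unbiased likelihood estimation for a generic state-space model.

    ``init(normals) -> (N, d)`` builds initial particles from
    ``aux_normals[:, 0]``; ``propagate(x, t, normals) -> (N, d)`` advances
    them with ``aux_normals[:, t]``; ``log_obs_density(x, t) -> (N,)``
    scores observed steps.  Stratified resampling is driven by
    ``aux_resample`` (standard normals, mapped to uniforms), so identical
    auxiliaries give identical estimates.  ``ess_threshold`` optionally
    gates resampling on the effective sample size (as a fraction of the
    particle count; 1.0 resamples at every weighted step).
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    obs_set = set(int(t) for t in np.asarray(obs_pos).ravel())
    uniforms = ndtr(aux_resample)
    x = init(aux_normals[:, 0])
    res = ParticleFilterResult(log_likelihood=0.0)
    last_obs = max(obs_set) if obs_set else -1
    w = np.full(n_particles, 1.0 / n_particles)
    for t in range(T):
        if t > 0:
            x = propagate(x, t, aux_normals[:, t])
        if t in obs_set:
            logw = np.asarray(log_obs_density(x, t), float)
            mx = np.max(logw)
            if not np.isfinite(mx):
                res.log_likelihood = -np.inf
                res.degenerate = True
                return res
            unnorm = w * np.exp(logw - mx)
            inc = mx + np.log(unnorm.sum())
            res.log_likelihood += inc
            res.increments[t] = inc
            w = unnorm / unnorm.sum()
            res.weights[t] = w
            ess = 1.0 / float(np.sum(w * w))
            res.ess[t] = ess
            if t != last_obs and n_particles > 1 and ess <= ess_threshold * n_particles:
                idx = stratified_resample(w, uniforms[:, t])
                x = x[idx]
                w = np.full(n_particles, 1.0 / n_particles)
    res.particles = x
    return res


# ---------------------------------------------------------------------
# Rao-Blackwellised particle filter for the pool/input model
# ---------------------------------------------------------------------
@dataclass
class RbpfResult:
    """RBPF output for one field.

    ``means``/``covs`` are the per-year Kalman quantities over the active
    (decaying) pools; covariances are shared across particles.  ``inputs``
    holds each particle's realised annual carbon-input path.
    """

    log_likelihood: float
    weights: dict
    ess: dict
    increments: dict
    means: np.ndarray        # (N, T, d_active)
    covs: np.ndarray         # (T, d_active, d_active)
    pred_covs: np.ndarray    # (T, d_active, d_active) pre-update covariances
    inputs: np.ndarray       # (N, T) carbon input applied in the step into year t+1
    final_weights: np.ndarray
    degenerate: bool = False


def rbpf_filter(
    A: np.ndarray,
    Q: np.ndarray,
    R: float,
    b_alloc: np.ndarray,
    base_input: np.ndarray,
    input_sd_log: float,
    m0: np.ndarray,
    P0: np.ndarray,
    obs_pos: np.ndarray,
    obs_vals: np.ndarray,
    obs_offset: float,
    normals: np.ndarray,
    resample_normals: np.ndarray,
) -> RbpfResult:
    """Rao-Blackwellised particle filter for one field.

    Particles are realised input paths: particle i applies the carbon input
    ``base_input[t] * exp(input_sd_log * normals[i, t])`` in year t.
    Conditional on that path the pool sub-model is linear-Gaussian and is
    marginalised exactly by a Kalman filter whose covariance recursion is
    shared across particles.  With ``input_sd_log == 0`` every particle is
    identical and the estimate equals the single Kalman-filter likelihood
    exactly.
    """
    from ._kernels import rbpf_kernel

    obs_pos = np.ascontiguousarray(obs_pos, dtype=np.int64)
    obs_vals = np.ascontiguousarray(obs_vals, dtype=np.float64)
    uniforms = ndtr(resample_normals)
    ll, means, covs, pred_covs, inputs, final_w, incs, w_hist, ok = rbpf_kernel(
        np.ascontiguousarray(A, dtype=np.float64),
        np.ascontiguousarray(Q, dtype=np.float64),
        float(R),
        np.ascontiguousarray(b_alloc, dtype=np.float64),
        np.ascontiguousarray(base_input, dtype=np.float64),
        float(input_sd_log),
        np.ascontiguousarray(m0, dtype=np.float64),
        np.ascontiguousarray(P0, dtype=np.float64),
        obs_pos,
        obs_vals,
        float(obs_offset),
        np.ascontiguousarray(normals, dtype=np.float64),
        np.ascontiguousarray(uniforms, dtype=np.float64),
    )
    increments = {int(p): float(v) for p, v in zip(obs_pos, incs)}
    weights = {int(p): w_hist[k] for k, p in enumerate(obs_pos)}
    ess = {
        int(p): (1.0 / float(np.sum(w_hist[k] ** 2)) if w_hist[k].sum() > 0 else 0.0)
        for k, p in enumerate(obs_pos)
    }
    return RbpfResult(
        log_likelihood=float(ll),
        weights=weights,
        ess=ess,
        increments=increments,
        means=means,
        covs=covs,
        pred_covs=pred_covs,
        inputs=inputs,
        final_weights=final_w,
        degenerate=not bool(ok),
    )


def rbpf_backward_sample(
    result: RbpfResult,
    A: np.ndarray,
    Q: np.ndarray,
    b_alloc: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one pool-state trajectory from the conditional smoothing law.

    Picks an input-path particle proportional to the final weights, then
    runs the Gaussian forward-filter backward-sampler along that particle's
    Kalman quantities.  Degenerate (zero) covariances yield the filtered
    means exactly.  Returns (trajectory (T, d_active), input path (T,)).
    """
    from ._kernels import ffbs_kernel

    N, T, d = result.means.shape
    w = result.final_weights
    # weight-proportional particle choice via a single uniform
    i = int(np.searchsorted(np.cumsum(w), rng.uniform() * w.sum()).clip(0, N - 1))
    ms = np.ascontiguousarray(result.means[i])
    u = np.ascontiguousarray(result.inputs[i])
    z = rng.standard_normal((T, d))
    x = ffbs_kernel(
        ms,
        np.ascontiguousarray(result.covs),
        np.ascontiguousarray(result.pred_covs),
        np.ascontiguousarray(A, dtype=np.float64),
        np.ascontiguousarray(b_alloc, dtype=np.float64),
        u,
        z,
    )
    return x, u
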