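"""Compiled inner loops for the particle filter and backward sampler.

A likelihood evaluation is a T-year recursion over small (N, d) arrays; at
that size Python/numpy call overhead dominates, so the recursions are
written as explicit loops and jit-compiled.  The surrounding modules keep
all model logic; nothing here knows about pools or priors.
"""

from __future__ import annotations

import numba as nb
import numpy as np

LOG2PI = np.log(2.0 * np.pi)


@nb.njit(cache=True)
def _stratified_indices(w, u, out):
    """Stratified resampling: stratum i draws at (i + u[i]) / N."""
    n = w.shape[0]
    c = w[0]
    j = 0
    for i in range(n):
        p = (i + u[i]) / n
        while c < p and j < n - 1:
            j += 1
            c += w[j]
        out[i] = j


@nb.njit(cache=True)
def rbpf_kernel(A, Q, R, b, base_input, sd_log, m0, P0,
                obs_pos, obs_vals, offset, normals, resample_u):
    """One-field Rao-Blackwellised particle filter.

    Returns (ll, means, covs, pred_covs, inputs, final_w, increments,
    weights_hist, ok).  ``weights_hist[k]`` holds the normalised particle
    weights at the k-th observation event; ``ok`` is 0 when every particle
    weight underflowed (impossible data).
    """
    N, T = normals.shape
    d = A.shape[0]
    K = obs_pos.shape[0]
    means = np.zeros((N, T, d))
    covs = np.zeros((T, d, d))
    pred_covs = np.zeros((T, d, d))
    inputs = np.empty((N, T))
    increments = np.zeros(K)
    weights_hist = np.zeros((K, N))
    for i in range(N):
        for t in range(T):
            inputs[i, t] = base_input[t] * np.exp(sd_log * normals[i, t])
    m = np.empty((N, d))
    for i in range(N):
        for j in range(d):
            m[i, j] = m0[j]
    P = P0.copy()
    w = np.full(N, 1.0 / N)
    logw = np.empty(N)
    err = np.empty(N)
    idx = np.empty(N, np.int64)
    ll = 0.0
    obs_ptr = 0
    last_obs = obs_pos[K - 1] if K > 0 else -1
    for t in range(T):
        if t > 0:
            newm = np.empty((N, d))
            for i in range(N):
                u_prev = inputs[i, t - 1]
                for j in range(d):
                    acc = u_prev * b[j]
                    for k2 in range(d):
                        acc += A[j, k2] * m[i, k2]
                    newm[i, j] = acc
            m = newm
            P = A @ P @ A.T + Q
        for j in range(d):
            for k2 in range(d):
                pred_covs[t, j, k2] = P[j, k2]
        if obs_ptr < K and obs_pos[obs_ptr] == t:
            s = R
            for j in range(d):
                for k2 in range(d):
                    s += P[j, k2]
            if s <= 0.0:
                s = 1e-300
            y = obs_vals[obs_ptr]
            const = -0.5 * (LOG2PI + np.log(s))
            mx = -np.inf
            for i in range(N):
                e = y - offset
                for j in range(d):
                    e -= m[i, j]
                err[i] = e
                lw = const - 0.5 * e * e / s
                logw[i] = lw
                if lw > mx:
                    mx = lw
            if not np.isfinite(mx):
                return (-np.inf, means, covs, pred_covs, inputs, w, increments,
                        weights_hist, 0)
            sumw = 0.0
            for i in range(N):
                w[i] = np.exp(logw[i] - mx)
                sumw += w[i]
            inc = mx + np.log(sumw) - np.log(N)
            ll += inc
            increments[obs_ptr] = inc
            for i in range(N):
                w[i] /= sumw
                weights_hist[obs_ptr, i] = w[i]
            # Kalman update shared across particles (same covariance)
            gain = np.empty(d)
            colsum = np.empty(d)
            for j in range(d):
                g = 0.0
                cs = 0.0
                for k2 in range(d):
                    g += P[j, k2]
                    cs += P[k2, j]
                gain[j] = g / s
                colsum[j] = cs
            for i in range(N):
                for j in range(d):
                    m[i, j] += err[i] * gain[j]
            for j in range(d):
                for k2 in range(d):
                    P[j, k2] -= gain[j] * colsum[k2]
            if t != last_obs and N > 1:
                _stratified_indices(w, resample_u[:, t], idx)
                m = m[idx].copy()
                inputs = inputs[idx].copy()
                if t > 0:
                    means[:, :t] = means[idx, :t].copy()
                for i in range(N):
                    w[i] = 1.0 / N
            obs_ptr += 1
        for i in range(N):
            for j in range(d):
                means[i, t, j] = m[i, j]
        for j in range(d):
            for k2 in range(d):
                covs[t, j, k2] = P[j, k2]
    return (ll, means, covs, pred_covs, inputs, w, increments, weights_hist, 1)


@nb.njit(cache=True)
def _draw_gaussian(mean, cov, z, out):
    """out = mean + cov^{1/2} z via eigendecomposition (PSD-safe)."""
    d = mean.shape[0]
    sym = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(sym)
    for j in range(d):
        out[j] = mean[j]
    for k in range(d):
        v = vals[k]
        if v <= 0.0:
            continue
        scale = np.sqrt(v) * z[k]
        for j in range(d):
            out[j] += vecs[j, k] * scale
    return out


@nb.njit(cache=True)
def _pinv_sym(S, out):
    """Moore-Penrose pseudo-inverse of a small symmetric PSD matrix."""
    d = S.shape[0]
    sym = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(sym)
    vmax = 0.0
    for k in range(d):
        if vals[k] > vmax:
            vmax = vals[k]
    tol = vmax * 1e-12
    for j in range(d):
        for k2 in range(d):
            out[j, k2] = 0.0
    for k in range(d):
        if vals[k] > tol:
            iv = 1.0 / vals[k]
            for j in range(d):
                for k2 in range(d):
                    out[j, k2] += vecs[j, k] * iv * vecs[k2, k]
    return out


@nb.njit(cache=True)
def ffbs_kernel(ms, covs, pred_covs, A, b, u, z):
    """Backward simulation along one particle's Kalman quantities.

    ``ms`` (T, d) filtered means of the chosen particle, ``covs`` filtered
    and ``pred_covs`` one-step-ahead covariances, ``u`` the particle's
    input path, ``z`` (T, d) standard normals.  Returns the sampled
    trajectory (T, d); exact (zero-variance) when all covariances vanish.
    """
    T, d = ms.shape
    x = np.empty((T, d))
    tmp = np.empty(d)
    Sinv = np.empty((d, d))
    _draw_gaussian(ms[T - 1], covs[T - 1], z[T - 1], tmp)
    for j in range(d):
        x[T - 1, j] = tmp[j]
    for t in range(T - 2, -1, -1):
        P = covs[t]
        _pinv_sym(pred_covs[t + 1], Sinv)
        # G = P A' Sinv
        G = P @ A.T @ Sinv
        # conditional mean and covariance
        pred = np.empty(d)
        for j in range(d):
            acc = u[t] * b[j]
            for k2 in range(d):
                acc += A[j, k2] * ms[t, k2]
            pred[j] = acc
        mean = np.empty(d)
        for j in range(d):
            acc = ms[t, j]
            for k2 in range(d):
                acc += G[j, k2] * (x[t + 1, k2] - pred[k2])
            mean[j] = acc
        cov = P - G @ A @ P
        _draw_gaussian(mean, cov, z[t], tmp)
        for j in range(d):
            x[t, j] = tmp[j]
    return x
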