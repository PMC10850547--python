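"""Kalman filter, particle filters and backward sampling against
independent oracles (brute-force joint Gaussians, degenerate limits)."""

import numpy as np
import pytest

from soilcarbon.filters import (
    AuxiliaryBlock,
    bootstrap_pf,
    kalman_filter,
    rbpf_backward_sample,
    rbpf_filter,
    stratified_resample,
)

from conftest import joint_gaussian_loglik, random_linear_system


def run_kf(sys, obs_vals, offset=0.0):
    return kalman_filter(
        sys["A"], sys["Q"], sys["H"], sys["R"], sys["b_seq"],
        sys["m0"], sys["P0"], sys["obs_pos"], obs_vals, obs_offset=offset,
    )


class TestKalmanFilter:
    def test_standard_normal_single_observation(self):
        res = kalman_filter(
            A=np.array([[1.0]]), Q=np.array([[0.0]]), H=np.array([[1.0]]), R=1.0,
            b_seq=np.zeros((0, 1)), m0=np.array([0.0]), P0=np.array([[0.0]]),
            obs_pos=np.array([0]), obs_vals=np.array([0.0]),
        )
        assert res.log_likelihood == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_matches_joint_gaussian_on_random_systems(self):
        rng = np.random.default_rng(101)
        for _ in range(10):
            sys = random_linear_system(rng)
            y = rng.normal(0, 2, size=sys["obs_pos"].size)
            assert run_kf(sys, y).log_likelihood == pytest.approx(
                joint_gaussian_loglik(sys, y), abs=1e-8
            )

    def test_noise_free_filter_recovers_deterministic_trajectory(self):
        A = np.array([[0.9, 0.1], [0.0, 0.8]])
        b_seq = np.tile([0.5, 0.2], (5, 1))
        x = np.array([3.0, 1.0])
        traj = [x]
        for t in range(5):
            traj.append(A @ traj[-1] + b_seq[t])
        traj = np.array(traj)
        h = np.array([[1.0, 1.0]])
        obs_pos = np.array([0, 2, 5])
        y = traj[obs_pos] @ h.ravel()
        res = kalman_filter(
            A, np.zeros((2, 2)), h, 0.0, b_seq, x, np.zeros((2, 2)), obs_pos, y
        )
        assert np.allclose(res.means, traj, atol=1e-9)

    def test_out_of_range_observation_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            kalman_filter(
                np.eye(1), np.eye(1), np.ones((1, 1)), 1.0, np.zeros((2, 1)),
                np.zeros(1), np.eye(1), np.array([5]), np.array([0.0]),
            )


def gaussian_pf_callbacks(sys, obs_vals, rng_free=True):
    """Joint bootstrap filter over the linear-Gaussian system itself."""
    A, Q, R = sys["A"], sys["Q"], sys["R"]
    h = sys["H"].ravel()
    b_seq, m0, P0 = sys["b_seq"], sys["m0"], sys["P0"]
    sqQ = np.sqrt(np.diag(Q))
    sqP0 = np.sqrt(np.diag(P0))
    obs_map = dict(zip(sys["obs_pos"].tolist(), np.asarray(obs_vals).tolist()))

    def init(normals):
        return m0[None, :] + normals[:, : m0.size] * sqP0[None, :]

    def propagate(x, t, normals):
        return x @ A.T + b_seq[t - 1][None, :] + normals[:, : m0.size] * sqQ[None, :]

    def log_obs(x, t):
        e = obs_map[t] - x @ h
        return -0.5 * (np.log(2 * np.pi * R) + e * e / R)

    return init, propagate, log_obs


class TestBootstrapPF:
    def test_deterministic_dynamics_exact_for_any_particle_count(self):
        rng = np.random.default_rng(5)
        sys = random_linear_system(rng, d=2, T=5, n_obs=3)
        sys["Q"] = np.zeros((2, 2))
        sys["P0"] = np.zeros((2, 2))
        y = rng.normal(0, 1, size=3)
        exact = run_kf(sys, y).log_likelihood
        init, prop, lod = gaussian_pf_callbacks(sys, y)
        for n in (1, 7, 40):
            aux_n = rng.standard_normal((n, 5, 2))
            aux_r = rng.standard_normal((n, 5))
            res = bootstrap_pf(init, prop, lod, 5, sys["obs_pos"], n, aux_n, aux_r)
            assert res.log_likelihood == pytest.approx(exact, abs=1e-9)

    def test_single_particle_equals_direct_importance_path(self):
        rng = np.random.default_rng(6)
        sys = random_linear_system(rng, d=2, T=4, n_obs=2)
        y = rng.normal(0, 1, size=2)
        init, prop, lod = gaussian_pf_callbacks(sys, y)
        aux_n = rng.standard_normal((1, 4, 2))
        aux_r = rng.standard_normal((1, 4))
        res = bootstrap_pf(init, prop, lod, 4, sys["obs_pos"], 1, aux_n, aux_r)
        # replay the single path by hand with the same auxiliaries
        x = init(aux_n[:, 0])
        ll = 0.0
        for t in range(4):
            if t > 0:
                x = prop(x, t, aux_n[:, t])
            if t in set(sys["obs_pos"].tolist()):
                ll += float(lod(x, t)[0])
        assert res.log_likelihood == pytest.approx(ll, abs=1e-12)

    def test_unbiased_for_kalman_likelihood(self):
        rng = np.random.default_rng(7)
        sys = random_linear_system(rng, d=2, T=5, n_obs=3)
        y = rng.normal(0, 1, size=3)
        exact = run_kf(sys, y).log_likelihood
        init, prop, lod = gaussian_pf_callbacks(sys, y)
        reps = 200
        n = 100
        ratios = np.empty(reps)
        for r in range(reps):
            aux_n = rng.standard_normal((n, 5, 2))
            aux_r = rng.standard_normal((n, 5))
            res = bootstrap_pf(init, prop, lod, 5, sys["obs_pos"], n, aux_n, aux_r)
            ratios[r] = np.exp(res.log_likelihood - exact)
        se = ratios.std(ddof=1) / np.sqrt(reps)
        assert abs(ratios.mean() - 1.0) <= 3 * se

    def test_identical_auxiliaries_identical_estimate(self):
        rng = np.random.default_rng(8)
        sys = random_linear_system(rng)
        y = rng.normal(0, 1, size=3)
        init, prop, lod = gaussian_pf_callbacks(sys, y)
        aux_n = rng.standard_normal((20, 5, 2))
        aux_r = rng.standard_normal((20, 5))
        a = bootstrap_pf(init, prop, lod, 5, sys["obs_pos"], 20, aux_n, aux_r)
        b = bootstrap_pf(init, prop, lod, 5, sys["obs_pos"], 20, aux_n, aux_r)
        assert a.log_likelihood == b.log_likelihood


def rbpf_toy(T=8, sd_log=0.3, n_obs=4, seed=0):
    """A two-active-pool toy with stochastic inputs for RBPF testing."""
    rng = np.random.default_rng(seed)
    A = np.array([[0.92, 0.05], [0.03, 0.6]])
    Q = np.diag([0.25, 0.04])
    R = 0.8
    b = np.array([0.9, 0.1])
    base = rng.uniform(0.5, 1.5, size=T)
    m0 = np.array([28.0, 1.0])
    P0 = np.diag([4.0, 0.25])
    obs_pos = np.sort(rng.choice(T, size=n_obs, replace=False))
    y = rng.normal(30, 2, size=n_obs)
    return dict(A=A, Q=Q, R=R, b=b, base=base, sd_log=sd_log, m0=m0, P0=P0,
                obs_pos=obs_pos, y=y, offset=5.0)


def run_rbpf(toy, n, rng):
    normals = rng.standard_normal((n, len(toy["base"])))
    res_n = rng.standard_normal((n, len(toy["base"])))
    return rbpf_filter(
        toy["A"], toy["Q"], toy["R"], toy["b"], toy["base"], toy["sd_log"],
        toy["m0"], toy["P0"], toy["obs_pos"], toy["y"], toy["offset"],
        normals, res_n,
    )


def run_joint_bpf(toy, n, rng):
    """Oracle: plain bootstrap filter over the joint (input, pools) state."""
    T = len(toy["base"])
    A, Q, b = toy["A"], toy["Q"], toy["b"]
    sqQ = np.sqrt(np.diag(Q))
    sqP0 = np.sqrt(np.diag(toy["P0"]))
    obs_map = dict(zip(toy["obs_pos"].tolist(), toy["y"].tolist()))

    def init(normals):
        return toy["m0"][None, :] + normals[:, 1:3] * sqP0[None, :]

    def propagate(x, t, normals):
        u = toy["base"][t - 1] * np.exp(toy["sd_log"] * normals[:, 0])
        return x @ A.T + u[:, None] * b[None, :] + normals[:, 1:3] * sqQ[None, :]

    def log_obs(x, t):
        e = obs_map[t] - x.sum(axis=1) - toy["offset"]
        return -0.5 * (np.log(2 * np.pi * toy["R"]) + e * e / toy["R"])

    aux_n = rng.standard_normal((n, T, 3))
    aux_r = rng.standard_normal((n, T))
    return bootstrap_pf(init, propagate, log_obs, T, toy["obs_pos"], n, aux_n, aux_r)


class TestRbpf:
    def test_deterministic_inputs_reduce_to_kalman(self):
        # with zero input noise the nonlinear part is degenerate and the
        # estimate equals the single Kalman run exactly, any particle count
        toy = rbpf_toy(sd_log=0.0, seed=1)
        T = len(toy["base"])
        b_seq = toy["base"][: T - 1, None] * toy["b"][None, :]
        kf = kalman_filter(
            toy["A"], toy["Q"], np.ones((1, 2)), toy["R"], b_seq,
            toy["m0"], toy["P0"], toy["obs_pos"], toy["y"], obs_offset=toy["offset"],
        )
        rng = np.random.default_rng(2)
        for n in (1, 5, 64):
            res = run_rbpf(toy, n, rng)
            assert res.log_likelihood == pytest.approx(kf.log_likelihood, abs=1e-9)

    def test_matches_joint_bootstrap_filter(self):
        # both estimate the same marginal likelihood of the observed data
        toy = rbpf_toy(sd_log=0.35, seed=3)
        rng = np.random.default_rng(4)
        reps = 150
        r_est = np.array([run_rbpf(toy, 60, rng).log_likelihood for _ in range(reps)])
        j_est = np.array([run_joint_bpf(toy, 400, rng).log_likelihood for _ in range(reps)])
        ref = np.exp(j_est - j_est.mean())
        val = np.exp(r_est - j_est.mean())
        se = np.sqrt(ref.var(ddof=1) / reps + val.var(ddof=1) / reps)
        assert abs(val.mean() - ref.mean()) <= 3 * se

    def test_rao_blackwell_variance_reduction(self):
        toy = rbpf_toy(sd_log=0.35, seed=5)
        rng = np.random.default_rng(6)
        reps = 200
        n = 40
        r_est = np.array([run_rbpf(toy, n, rng).log_likelihood for _ in range(reps)])
        j_est = np.array([run_joint_bpf(toy, n, rng).log_likelihood for _ in range(reps)])
        assert r_est.var(ddof=1) <= j_est.var(ddof=1)

    def test_impossible_data_flagged(self):
        toy = rbpf_toy(seed=7)
        toy["y"] = toy["y"] + 1e9
        toy["R"] = 1e-12
        res = run_rbpf(toy, 10, np.random.default_rng(0))
        assert res.log_likelihood == -np.inf or res.log_likelihood < -1e10


class TestBackwardSampler:
    def test_zero_noise_gives_deterministic_trajectory(self):
        toy = rbpf_toy(sd_log=0.0, seed=8)
        toy["Q"] = np.zeros((2, 2))
        toy["P0"] = np.zeros((2, 2))
        # consistent data: observe the deterministic trajectory itself
        T = len(toy["base"])
        x = toy["m0"].copy()
        traj = [x.copy()]
        for t in range(1, T):
            x = toy["A"] @ x + toy["base"][t - 1] * toy["b"]
            traj.append(x.copy())
        traj = np.array(traj)
        toy["y"] = traj[toy["obs_pos"]].sum(axis=1) + toy["offset"]
        res = run_rbpf(toy, 4, np.random.default_rng(1))
        for seed in (0, 1, 2):
            x_draw, u = rbpf_backward_sample(
                res, toy["A"], toy["Q"], toy["b"], np.random.default_rng(seed)
            )
            assert np.allclose(x_draw, traj, atol=1e-8)

    def test_matches_closed_form_smoother_moments(self):
        # deterministic inputs => exact linear-Gaussian smoothing law;
        # oracle = conditional of the brute-force stacked joint Gaussian
        rng = np.random.default_rng(9)
        toy = rbpf_toy(sd_log=0.0, seed=10, T=6, n_obs=3)
        T = len(toy["base"])
        d = 2
        sys = dict(
            A=toy["A"], Q=toy["Q"], H=np.ones((1, 2)), R=toy["R"],
            b_seq=toy["base"][: T - 1, None] * toy["b"][None, :],
            m0=toy["m0"], P0=toy["P0"], obs_pos=toy["obs_pos"],
        )
        # brute-force joint of stacked states and conditioning on y
        means = [sys["m0"]]
        for t in range(T - 1):
            means.append(sys["A"] @ means[-1] + sys["b_seq"][t])
        mu_x = np.concatenate(means)
        cov = np.zeros((T * d, T * d))
        cov[:d, :d] = sys["P0"]
        for t in range(1, T):
            cov[t*d:(t+1)*d, t*d:(t+1)*d] = (
                sys["A"] @ cov[(t-1)*d:t*d, (t-1)*d:t*d] @ sys["A"].T + sys["Q"]
            )
            for s in range(t):
                c = sys["A"] @ cov[(t-1)*d:t*d, s*d:(s+1)*d]
                cov[t*d:(t+1)*d, s*d:(s+1)*d] = c
                cov[s*d:(s+1)*d, t*d:(t+1)*d] = c.T
        k = toy["obs_pos"].size
        Hbig = np.zeros((k, T * d))
        for i, t in enumerate(toy["obs_pos"]):
            Hbig[i, t*d:(t+1)*d] = 1.0
        Syy = Hbig @ cov @ Hbig.T + toy["R"] * np.eye(k)
        Sxy = cov @ Hbig.T
        resid = toy["y"] - toy["offset"] - Hbig @ mu_x
        mu_post = mu_x + Sxy @ np.linalg.solve(Syy, resid)
        cov_post = cov - Sxy @ np.linalg.solve(Syy, Sxy.T)

        res = run_rbpf(toy, 3, rng)
        draws = np.array([
            rbpf_backward_sample(res, toy["A"], toy["Q"], toy["b"], rng)[0].ravel()
            for _ in range(4000)
        ])
        sd = np.sqrt(np.diag(cov_post))
        se = sd / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - mu_post) <= 4 * se + 1e-9)
        assert np.allclose(draws.var(axis=0, ddof=1), np.diag(cov_post), rtol=0.15, atol=1e-6)


class TestAuxiliaryBlock:
    def test_rho_zero_refresh_is_fresh_noise(self):
        rng1 = np.random.default_rng(11)
        block = AuxiliaryBlock.draw(rng1, 4, 2, 6)
        rng_a = np.random.default_rng(99)
        rng_b = np.random.default_rng(99)
        refreshed = block.refresh(0.0, rng_a)
        assert np.array_equal(refreshed.normals, rng_b.standard_normal((4, 2, 6)))

    def test_refresh_preserves_shape_and_determinism(self):
        rng = np.random.default_rng(12)
        block = AuxiliaryBlock.draw(rng, 8, 3, 10)
        a = block.refresh(0.99, np.random.default_rng(5))
        b = block.refresh(0.99, np.random.default_rng(5))
        assert np.array_equal(a.normals, b.normals)
        assert a.normals.shape == block.normals.shape

    def test_stratified_resample_preserves_heavy_weights(self):
        w = np.array([0.01, 0.01, 0.96, 0.01, 0.01])
        idx = stratified_resample(w, np.full(5, 0.5))
        assert np.sum(idx == 2) >= 4
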