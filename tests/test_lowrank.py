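import numpy as np
import pytest
from scipy import optimize

from popgate.lowrank import (
    GaussianPopulations,
    integrate_meanfield,
    latent_project,
)
from popgate.populations import build_three_pop_solution, three_pop_statistics
from popgate.rnn import RankOneNet, Trajectory, simulate
from popgate.task import TaskParams, generate_trials


def _gauss_pop(sigma_nm=0.0, sigma_nI=0.0):
    """Single zero-mean population over the 6 loading columns."""
    cov = np.eye(6)
    cov[0, 1] = cov[1, 0] = sigma_nm  # m-n overlap
    cov[1, 2] = cov[2, 1] = sigma_nI  # n-I_A overlap
    return GaussianPopulations(
        means=np.zeros((1, 6)), covs=cov[None], fractions=np.array([1.0])
    )


def test_latent_project_exact_member():
    net = RankOneNet.random(64, seed=0)
    x = np.tile(3.0 * net.m, (1, 5, 1))
    lat = latent_project(Trajectory(x=x), net)
    assert np.allclose(lat.kappa, 3.0, atol=1e-10)
    assert np.allclose(lat.v, 0.0, atol=1e-10)
    assert np.allclose(lat.residual, 0.0, atol=1e-8)
    assert lat.explained == pytest.approx(1.0)


def test_latent_project_orthogonal_state():
    net = RankOneNet.random(64, seed=1)
    basis = np.column_stack([net.m, net.I_A, net.I_B, net.I_xA, net.I_xB])
    rng = np.random.default_rng(2)
    y = rng.standard_normal(64)
    # remove the basis component to build a state orthogonal to the span
    y -= basis @ np.linalg.lstsq(basis, y, rcond=None)[0]
    lat = latent_project(Trajectory(x=y[None, None, :]), net)
    assert np.allclose(lat.kappa, 0.0, atol=1e-10)
    assert np.allclose(lat.v, 0.0, atol=1e-10)
    assert lat.residual[0, 0] == pytest.approx(np.linalg.norm(y))


def test_latent_project_matches_normal_equations():
    net, _ = build_three_pop_solution(N=256, seed=3, state_noise_sd=0.0)
    batch = generate_trials(TaskParams(stim_noise_sd=0.0), 8, seed=4)
    traj = simulate(net, batch, seed=5)
    lat = latent_project(traj, net)
    B = np.column_stack([net.m, net.I_A, net.I_B, net.I_xA, net.I_xB])
    # independent oracle: solve the normal equations directly
    G = B.T @ B
    for tr in (0, 3):
        for t in (2, 10):
            coef = np.linalg.solve(G, B.T @ traj.x[tr, t])
            assert lat.kappa[tr, t] == pytest.approx(coef[0], abs=1e-8)
            assert np.allclose(lat.v[tr, t], coef[1:], atol=1e-8)


def test_latent_project_collinear_basis_errors():
    net = RankOneNet.random(32, seed=6)
    net.I_A = net.m.copy()  # collinear with the output vector
    with pytest.raises(np.linalg.LinAlgError, match="ill-conditioned"):
        latent_project(Trajectory(x=np.zeros((1, 2, 32))), net)


def test_meanfield_pure_leak_decay():
    pops = _gauss_pop(0.0, 0.0)
    T, dt, tau = 30, 20.0, 100.0
    kappa, v = integrate_meanfield(pops, np.zeros((T, 4)), kappa0=2.0, dt=dt, tau=tau)
    expected = 2.0 * (1 - dt / tau) ** np.arange(T + 1)
    assert np.allclose(kappa, expected, atol=1e-12)
    assert np.allclose(v, 0.0)


def test_meanfield_small_signal_fixed_point():
    """kappa* ~ sigma_nI v / (1 - sigma_nm) in the linear regime, checked
    against a root-finding oracle on the full nonlinear self-consistency."""
    s_nm, s_nI, u = 0.3, 0.4, 0.1
    pops = _gauss_pop(s_nm, s_nI)
    T = 400  # long enough to reach the fixed point
    U = np.zeros((T, 4))
    U[:, 0] = u
    kappa, v = integrate_meanfield(pops, U, dt=20.0, tau=100.0)

    def gain_at(k, vv):
        g = np.random.default_rng(0).standard_normal((200_000, 2))
        x = k * g[:, 0] + vv * g[:, 1]
        return np.mean(1 - np.tanh(x) ** 2)

    def self_consistency(k):
        g = gain_at(k, u)
        return g * (s_nm * k + s_nI * u) - k

    k_star = optimize.brentq(self_consistency, 0.0, 1.0)
    linear = s_nI * u / (1 - s_nm)
    assert kappa[-1] == pytest.approx(k_star, rel=0.02)
    assert kappa[-1] == pytest.approx(linear, rel=0.05)  # small-signal regime


def test_noiseless_trajectories_low_dimensional():
    """Rank-one activity occupies at most 1 + n_inputs dimensions."""
    net, _ = build_three_pop_solution(N=300, seed=7, state_noise_sd=0.0)
    batch = generate_trials(TaskParams(stim_noise_sd=0.0), 16, seed=8)
    traj = simulate(net, batch, seed=9)
    X = traj.x.reshape(-1, net.N)
    s = np.linalg.svd(X - X.mean(0), compute_uv=False)
    floor = s[0] * 1e-8
    assert np.sum(s > floor) <= 5
    lat = latent_project(traj, net)
    assert lat.explained > 0.99


def test_meanfield_matches_full_network_three_pop():
    """Population mean-field latents track a large noiseless network.

    Context A with the go stimulus on feature A; the N = 4000 network
    trial average is the oracle.  The reduction uses the network's own
    per-population loading statistics (the Gaussian closure is the
    approximation under test, not overlap sampling noise).
    """
    from popgate.populations import loading_table

    params = TaskParams(stim_noise_sd=0.0)
    batch = generate_trials(params, 8, seed=10)
    sel = (batch.context == "A") & (batch.stimA_level == -1) & (batch.stimB_level == 1)
    net, labels = build_three_pop_solution(N=4000, seed=11, state_noise_sd=0.0)
    traj = simulate(net, batch, seed=12)
    kappa_full = latent_project(traj, net).kappa[sel].mean(axis=0)

    pops = GaussianPopulations.empirical(loading_table(net), labels)
    U = np.zeros((params.n_steps, 4))
    U[:, 2] = 1.0  # context A on throughout
    U[params.stim_window, 0] = -1.0  # go stimulus A
    U[params.stim_window, 1] = 1.0
    kappa_mf, _ = integrate_meanfield(pops, U)
    rms = np.linalg.norm(kappa_mf - kappa_full) / np.linalg.norm(kappa_full)
    assert rms < 0.05


def test_meanfield_accuracy_improves_with_network_size():
    params = TaskParams(stim_noise_sd=0.0)
    batch = generate_trials(params, 8, seed=13)
    sel = (batch.context == "A") & (batch.stimA_level == -1) & (batch.stimB_level == 1)
    stats = three_pop_statistics()
    pops = GaussianPopulations(
        means=stats.means[:, :6], covs=stats.covs[:, :6, :6],
        fractions=stats.fractions, n_mc=20_000,
    )
    U = np.zeros((params.n_steps, 4))
    U[:, 2] = 1.0
    U[params.stim_window, 0] = -1.0
    U[params.stim_window, 1] = 1.0
    kappa_mf, _ = integrate_meanfield(pops, U)

    rms = {}
    for N in (250, 4000):
        errs = []
        for seed in (0, 1, 2):
            net, _ = build_three_pop_solution(N=N, seed=100 + seed, state_noise_sd=0.0)
            traj = simulate(net, batch, seed=seed)
            kf = latent_project(traj, net).kappa[sel].mean(axis=0)
            errs.append(np.linalg.norm(kappa_mf - kf) / np.linalg.norm(kf))
        rms[N] = np.mean(errs)
    assert rms[4000] < rms[250]


def test_overlap_table_yaml_round_trip(tmp_path):
    from popgate.populations import three_pop_statistics

    stats = three_pop_statistics()
    p = tmp_path / "overlaps.yaml"
    stats.to_yaml(p)
    back = GaussianPopulations.from_yaml(p)
    assert back.columns == stats.columns
    assert np.allclose(back.means, stats.means)
    assert np.allclose(back.covs, stats.covs)
    assert np.allclose(back.fractions, stats.fractions)


def test_population_fraction_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        GaussianPopulations(
            means=np.zeros((2, 6)), covs=np.stack([np.eye(6)] * 2),
            fractions=np.array([0.5, 0.2]),
        )
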