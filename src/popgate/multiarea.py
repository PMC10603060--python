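"""Engineered two-area A1-PFC network with rank-one communication subspaces.

The connectivity of the joint network is block-structured, every block
rank-one: within-area recurrence m_A (x) n_A and m_P (x) n_P, a
feedforward block I_AP (x) n_AP from A1 to PFC and a feedback block
I_PA (x) n_PA from PFC to A1.  The across-area selection vectors are
aligned with the source area's output axis (n_AP = m_A, n_PA = m_P), so
each direction transmits exactly one scalar latent: A1 sends the
selected-stimulus latent kappa_A forward, PFC sends its context memory
kappa_P back.

Stimuli are delivered only to A1; the context cue (+1 for context A,
-1 for context B) is delivered transiently to PFC, which stores it in
persistent activity (bistable latent, self-overlap sigma_nm > 1).  A
fixed bias input I_k = (I_ctxA + I_ctxB)/2 plus the feedback signal
along I_x = (I_ctxA - I_ctxB)/2 reconstruct, inside A1, the net
contextual input I_ctxA or I_ctxB depending on the sign of kappa_P —
driving the same population-gating mechanism as in the single-area
network.  The behavioural response is read out from PFC along the
feedforward input direction.

Two scalar scales are self-calibrated at construction time from short
noiseless simulations: the feedback gain (so the fed-back context
signal has unit amplitude) and the PFC readout gain (so go responses
reach +-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lowrank import GaussianPopulations
from .populations import ThreePopParams, three_pop_statistics
from .rnn import SimulationDivergedError, decide
from .task import TaskParams, TrialBatch, generate_trials

__all__ = [
    "MultiAreaConfig",
    "MultiAreaNet",
    "MultiAreaSim",
    "build_multiarea",
    "simulate_multiarea",
    "accuracy_multiarea",
    "integrate_multiarea_meanfield",
    "pfc_statistics",
    "stimulus_latency",
]


@dataclass
class MultiAreaConfig:
    """Construction recipe for the two-area network."""

    N_A: int = 1500
    N_P: int = 1500
    a1: ThreePopParams = field(default_factory=ThreePopParams)
    #: PFC self-overlap sigma_nm; > 1 makes the context latent bistable.
    a_P: float = 1.6
    #: PFC context-input overlap sigma_nIx.
    b_P: float = 2.0
    #: residual SD of the PFC input-selection vector.
    nu_P: float = 0.5
    #: SD of the feedforward input loading I_AP; larger values raise the
    #: communicated-signal to finite-size-noise ratio of the PFC readout.
    sigma_ap: float = 1.5
    tau: float = 100.0
    dt: float = 20.0
    state_noise_sd: float = 0.05
    #: timesteps of the transient context pulse; None = pre-stimulus length.
    pulse_steps: int | None = None
    #: mean absolute readout at which go responses are calibrated.  The
    #: nearest-target decision rule penalises undershoot (misses at the
    #: +-0.5 boundary) but not overshoot, so go responses are aimed well
    #: past +-1 to pull their noise tails clear of the boundary.
    readout_target: float = 2.0


@dataclass
class MultiAreaNet:
    """Two rank-one areas joined by rank-one across-area blocks."""

    # A1
    m_A: np.ndarray
    n_A: np.ndarray
    I_A: np.ndarray
    I_B: np.ndarray
    I_ctxA: np.ndarray
    I_ctxB: np.ndarray
    labels_A: np.ndarray
    # PFC
    m_P: np.ndarray
    n_P: np.ndarray
    I_x: np.ndarray
    I_AP: np.ndarray
    # calibrated scales
    lam_fb: float
    gamma_P: float
    eps_fb: float = 0.0
    delta_P: float = 0.0
    bias_P: float = 0.0
    tau: float = 100.0
    dt: float = 20.0
    state_noise_sd: float = 0.05
    config: MultiAreaConfig | None = None

    @property
    def N_A_(self) -> int:
        return self.m_A.size

    @property
    def N_P_(self) -> int:
        return self.m_P.size

    @property
    def I_k(self) -> np.ndarray:
        """Constant bias input to A1.

        Average of the two context vectors, plus a small calibrated
        offset along the context axis that centres the two fed-back
        attractor levels at +-1.
        """
        return 0.5 * (self.I_ctxA + self.I_ctxB) + self.eps_fb * self.I_x_A1

    @property
    def I_x_A1(self) -> np.ndarray:
        """Context axis within A1: the fed-back signal moves A1 along it."""
        return 0.5 * (self.I_ctxA - self.I_ctxB)

    @property
    def I_PA(self) -> np.ndarray:
        """Feedback input vector (PFC -> A1), scaled context axis."""
        return self.lam_fb * self.I_x_A1

    @property
    def n_AP(self) -> np.ndarray:
        """Feedforward selection vector, aligned with A1's output axis."""
        return self.m_A

    @property
    def n_PA(self) -> np.ndarray:
        """Feedback selection vector, aligned with PFC's output axis."""
        return self.m_P

    @property
    def w_P(self) -> np.ndarray:
        """PFC readout vector.

        Dominated by the feedforward input direction; the calibrated
        m_P component (with the scalar ``bias_P``) cancels the
        context-dependent finite-size offset of the projection.
        """
        return self.gamma_P * (self.I_AP - self.delta_P * self.m_P)

    def check_alignment(self, tol: float = 1e-10) -> None:
        if np.max(np.abs(self.n_AP - self.m_A)) > tol:
            raise AssertionError("feedforward selection vector misaligned with m_A")
        if np.max(np.abs(self.n_PA - self.m_P)) > tol:
            raise AssertionError("feedback selection vector misaligned with m_P")


@dataclass
class MultiAreaSim:
    """States of both areas, (n_trials, n_steps + 1, N)."""

    x_A: np.ndarray
    x_P: np.ndarray

    def kappa_A(self, net: MultiAreaNet) -> np.ndarray:
        """Output-axis projection of A1 activity, (trials, steps+1)."""
        return np.tanh(self.x_A) @ net.m_A / net.N_A_

    def ff_projection(self, net: MultiAreaNet) -> np.ndarray:
        """PFC activity along the feedforward input direction."""
        return np.tanh(self.x_P) @ net.I_AP / net.N_P_

    def readout(self, net: MultiAreaNet) -> np.ndarray:
        return np.tanh(self.x_P) @ net.w_P / net.N_P_ + net.bias_P


def pfc_statistics(cfg: MultiAreaConfig) -> GaussianPopulations:
    """Gaussian loading statistics of the single PFC population."""
    # columns m, n, I_x, I_AP; factors g_m, g_n, g_x, g_ap
    L = np.zeros((4, 4))
    L[0, 0] = 1.0
    L[1, 0] = cfg.a_P
    L[1, 1] = cfg.nu_P
    L[1, 2] = cfg.b_P
    L[2, 2] = 1.0
    L[3, 3] = cfg.sigma_ap
    return GaussianPopulations(
        means=np.zeros((1, 4)),
        covs=(L @ L.T)[None],
        fractions=np.array([1.0]),
        columns=("m", "n", "I_x", "I_AP"),
    )


def multiarea_inputs(batch: TrialBatch, pulse_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Convert a task batch into per-area inputs.

    Returns (u_A, u_x): u_A (trials, T, 2) stimulus channels to A1;
    u_x (trials, T) context to PFC, +1 in context A / -1 in context B,
    nonzero only during the first ``pulse_steps`` timesteps.
    """
    u_A = batch.inputs[:, :, :2]
    T = batch.n_steps
    level = np.where(batch.context == "A", 1.0, -1.0)
    u_x = np.zeros((batch.n_trials, T))
    u_x[:, :pulse_steps] = level[:, None]
    return u_A, u_x


def _step_multiarea(net, xA, xP, uA_t, ux_t, a, rng, sd):
    rA, rP = np.tanh(xA), np.tanh(xP)
    kA = rA @ net.n_A / net.N_A_  # within-A1 recurrent latent drive
    kP = rP @ net.n_P / net.N_P_
    ff = rA @ net.n_AP / net.N_A_  # A1 -> PFC scalar
    fb = rP @ net.n_PA / net.N_P_  # PFC -> A1 scalar
    driveA = (
        np.outer(kA, net.m_A)
        + np.outer(fb, net.I_PA)
        + uA_t[:, 0:1] * net.I_A
        + uA_t[:, 1:2] * net.I_B
        + net.I_k
    )
    driveP = np.outer(kP, net.m_P) + np.outer(ff, net.I_AP) + ux_t[:, None] * net.I_x
    if sd > 0:
        driveA = driveA + rng.normal(0.0, sd, size=driveA.shape)
        driveP = driveP + rng.normal(0.0, sd, size=driveP.shape)
    return (1 - a) * xA + a * driveA, (1 - a) * xP + a * driveP


def simulate_multiarea(
    net: MultiAreaNet,
    batch: TrialBatch,
    seed: int | None = None,
    pulse_steps: int | None = None,
    noise_sd: float | None = None,
) -> MultiAreaSim:
    """Simulate both areas on task trials.

    Stimuli go to A1; the context cue is delivered to PFC transiently
    (default: during the pre-stimulus period) and must be held across
    the trial by PFC's persistent activity.
    """
    if pulse_steps is None:
        pulse_steps = (
            net.config.pulse_steps
            if net.config and net.config.pulse_steps is not None
            else batch.params.n_prestim if batch.params else 4
        )
    u_A, u_x = multiarea_inputs(batch, pulse_steps)
    B, T, _ = batch.inputs.shape
    a = net.dt / net.tau
    sd = net.state_noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    xA = np.zeros((B, T + 1, net.N_A_))
    xP = np.zeros((B, T + 1, net.N_P_))
    cA = np.zeros((B, net.N_A_))
    cP = np.zeros((B, net.N_P_))
    for t in range(T):
        cA, cP = _step_multiarea(net, cA, cP, u_A[:, t, :], u_x[:, t], a, rng, sd)
        if not (np.all(np.isfinite(cA)) and np.all(np.isfinite(cP))):
            raise SimulationDivergedError(f"non-finite state at timestep {t}")
        xA[:, t + 1], xP[:, t + 1] = cA, cP
    return MultiAreaSim(x_A=xA, x_P=xP)


def build_multiarea(
    config: MultiAreaConfig | None = None, seed: int | None = None
) -> MultiAreaNet:
    """Construct and self-calibrate the two-area network.

    All across-area overlaps vanish except the two mediating
    (selected stimulus -> PFC) and (context -> A1); the feedback and
    readout gains are calibrated from short noiseless simulations so
    that the fed-back context has unit amplitude (net contextual input
    I_ctxA / I_ctxB) and go responses reach +-1.
    """
    cfg = config or MultiAreaConfig()
    rng = np.random.default_rng(seed)

    a1_stats = three_pop_statistics(cfg.a1)
    XA, labels = a1_stats.sample_network(cfg.N_A, seed=int(rng.integers(2**31)))
    pfc = pfc_statistics(cfg)
    XP, _ = pfc.sample_network(cfg.N_P, seed=int(rng.integers(2**31)))

    net = MultiAreaNet(
        m_A=XA[:, 0], n_A=XA[:, 1], I_A=XA[:, 2], I_B=XA[:, 3],
        I_ctxA=XA[:, 4], I_ctxB=XA[:, 5], labels_A=labels,
        m_P=XP[:, 0], n_P=XP[:, 1], I_x=XP[:, 2], I_AP=XP[:, 3],
        lam_fb=1.0, gamma_P=1.0,
        tau=cfg.tau, dt=cfg.dt, state_noise_sd=cfg.state_noise_sd, config=cfg,
    )
    net.check_alignment()

    # calibrate the feedback gain: run PFC with a context pulse and no noise,
    # measure the persistent output-axis signal it would feed back
    task = TaskParams(n_prestim=8, n_stim=10, stim_noise_sd=0.0)
    probe = generate_trials(task, 8, balanced=True, seed=0)
    pulse = cfg.pulse_steps if cfg.pulse_steps is not None else task.n_prestim
    iso = MultiAreaNet(**{**net.__dict__, "lam_fb": 0.0})  # feedback off
    sim = simulate_multiarea(iso, probe, seed=0, pulse_steps=pulse, noise_sd=0.0)
    fb = np.tanh(sim.x_P[:, -1, :]) @ net.m_P / net.N_P_
    s_A = float(np.mean(fb[probe.context == "A"]))
    s_B = float(-np.mean(fb[probe.context == "B"]))
    if s_A < 1e-6 or s_B < 1e-6:
        raise RuntimeError(
            f"PFC context memory did not form (attractor levels {s_A:.3g}, {-s_B:.3g})"
        )
    # two-point calibration: lam*s_A + eps = +1 and -lam*s_B + eps = -1
    net.lam_fb = 2.0 / (s_A + s_B)
    net.eps_fb = (s_B - s_A) / (s_A + s_B)

    # calibrate the PFC readout under operating noise: fit the no-go
    # conditions' offset as a constant plus a context-memory (m_P)
    # component, then scale the offset-corrected go responses
    noisy_task = TaskParams(n_prestim=8, n_stim=10)
    noisy = generate_trials(noisy_task, 320, balanced=True, seed=1)
    sim = simulate_multiarea(net, noisy, seed=1, pulse_steps=pulse)
    pre = sim.ff_projection(net)[:, -1]
    fbr = np.tanh(sim.x_P[:, -1, :]) @ net.m_P / net.N_P_
    go = noisy.target != 0
    A = np.column_stack([np.ones(int((~go).sum())), fbr[~go]])
    b0, d = np.linalg.lstsq(A, pre[~go], rcond=None)[0]
    corrected = pre[go] - b0 - d * fbr[go]
    scale = float(np.mean(corrected * noisy.target[go])) / cfg.readout_target
    if scale <= 0:
        raise RuntimeError(
            "feedforward response has the wrong sign; construction failed "
            f"(mean signed response {scale:.4g})"
        )
    net.gamma_P = 1.0 / scale
    net.delta_P = float(d)
    net.bias_P = float(-b0 / scale)
    return net


def accuracy_multiarea(
    net: MultiAreaNet,
    task: TaskParams | None = None,
    n_trials: int = 512,
    seed: int | None = None,
) -> dict:
    """Behavioural accuracy of the two-area network (readout from PFC)."""
    task = task or TaskParams(n_prestim=8)
    rng = np.random.default_rng(seed)
    batch = generate_trials(task, n_trials, balanced=True, seed=int(rng.integers(2**31)))
    sim = simulate_multiarea(net, batch, seed=int(rng.integers(2**31)))
    choice = decide(sim.readout(net)[:, -1])
    ok = choice == batch.target
    out = {"overall": float(np.mean(ok))}
    for c in ("A", "B"):
        mask = batch.context == c
        out[c] = float(np.mean(ok[mask])) if mask.any() else np.nan
    return out


def integrate_multiarea_meanfield(
    pops_a1: GaussianPopulations,
    pops_pfc: GaussianPopulations,
    u_A: np.ndarray,
    u_x: np.ndarray,
    lam_fb: float,
    dt: float = 20.0,
    tau: float = 100.0,
) -> dict:
    """Mean-field latent dynamics of the two-area network.

    Latents: within-area kappa_A, kappa_P and the two communication
    latents v_AP (selected stimulus, A1 -> PFC) and v_PA (context,
    PFC -> A1), plus low-pass filtered external inputs.  ``u_A``:
    (T, 2) stimuli; ``u_x``: (T,) transient context.  With all
    across-area couplings zero the system factorises into two
    independent single-area reductions.

    Returns a dict of (T+1,) arrays.
    """
    u_A = np.asarray(u_A, dtype=float)
    u_x = np.asarray(u_x, dtype=float)
    T = u_A.shape[0]
    a = dt / tau
    out = {
        k: np.zeros(T + 1)
        for k in ("kappa_A", "kappa_P", "v_AP", "v_PA", "v_A", "v_B", "v_x", "v_k")
    }
    for t in range(T):
        kA, kP = out["kappa_A"][t], out["kappa_P"][t]
        vAP, vPA = out["v_AP"][t], out["v_PA"][t]
        vA, vB, vx, vk = out["v_A"][t], out["v_B"][t], out["v_x"][t], out["v_k"][t]
        drives_a1 = {
            "m": kA,
            "I_A": vA,
            "I_B": vB,
            # low-passed bias I_k plus fed-back context along I_x_A1,
            # expressed on the native context-vector columns
            "I_xA": 0.5 * vk + 0.5 * lam_fb * vPA,
            "I_xB": 0.5 * vk - 0.5 * lam_fb * vPA,
        }
        drives_pfc = {"m": kP, "I_x": vx, "I_AP": vAP}
        sA = pops_a1.activation_stats(drives_a1)
        sP = pops_pfc.activation_stats(drives_pfc)
        out["kappa_A"][t + 1] = (1 - a) * kA + a * pops_a1.projection("n", drives_a1, sA)
        out["kappa_P"][t + 1] = (1 - a) * kP + a * pops_pfc.projection("n", drives_pfc, sP)
        out["v_AP"][t + 1] = (1 - a) * vAP + a * pops_a1.projection("m", drives_a1, sA)
        out["v_PA"][t + 1] = (1 - a) * vPA + a * pops_pfc.projection("m", drives_pfc, sP)
        out["v_A"][t + 1] = (1 - a) * vA + a * u_A[t, 0]
        out["v_B"][t + 1] = (1 - a) * vB + a * u_A[t, 1]
        out["v_x"][t + 1] = (1 - a) * vx + a * u_x[t]
        out["v_k"][t + 1] = (1 - a) * vk + a * 1.0
        if not np.isfinite(out["kappa_A"][t + 1]):
            raise FloatingPointError(f"mean-field diverged at step {t}")
    return out


def stimulus_latency(
    sim: MultiAreaSim, net: MultiAreaNet, batch: TrialBatch, threshold: float = 1.0
) -> dict:
    """First timestep at which the relevant go stimulus separates from no-go.

    Separation is measured per area along its communicated dimension
    (A1: output axis m_A; PFC: feedforward input direction I_AP) as the
    absolute standardised mean difference between relevant-go and no-go
    trials, pooled over contexts with the response sign removed.
    Returns {'A1': t, 'PFC': t} (None if never above threshold).
    """
    sign = np.where(batch.context == "A", -1.0, 1.0)  # go response sign per context
    go = batch.target != 0
    out = {}
    for name, proj in (("A1", sim.kappa_A(net)), ("PFC", sim.ff_projection(net))):
        signed = proj * sign[:, None]  # go trials now deflect positively
        d = np.abs(signed[go].mean(0) - signed[~go].mean(0)) / np.sqrt(
            0.5 * (signed[go].var(0) + signed[~go].var(0)) + 1e-12
        )
        above = np.nonzero(d > threshold)[0]
        out[name] = int(above[0]) if above.size else None
    return out
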