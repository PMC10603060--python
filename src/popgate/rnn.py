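"""Continuous-time rank-one recurrent network: simulation and training.

The network has N units with pre-activations x_i obeying

    tau dx_i/dt = -x_i + (1/N) m_i (n . phi(x)) + sum_l u_l(t) I_i^l + eta_i(t)

with phi = tanh, integrated by forward Euler at step dt.  The recurrent
matrix is the rank-one outer product (1/N) m n^T and is never
materialised.  The readout is z = (1/N) w . phi(x) at the final
timestep of a trial.

Training optimises only the contextual input vectors (I_xA, I_xB) and
the connectivity vectors (m, n); stimulus inputs and readout stay at
their random initialisation.  Gradients are obtained by
backpropagation through the Euler unrolling, written out analytically
for this architecture, and applied with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .task import CHANNELS, TaskParams, TrialBatch, generate_trials

__all__ = [
    "RankOneNet",
    "LowRankNet",
    "Trajectory",
    "TrainingLog",
    "SimulationDivergedError",
    "TrainingFailedError",
    "gain",
    "simulate",
    "train_rank_one",
    "decide",
    "accuracy",
]


class SimulationDivergedError(RuntimeError):
    """Raised when the network state becomes non-finite."""


class TrainingFailedError(RuntimeError):
    """Raised when the loss fails to decrease over the patience window."""


def gain(x):
    """Single-unit gain phi'(x) = 1 - tanh(x)^2, in (0, 1]."""
    return 1.0 - np.tanh(x) ** 2


@dataclass
class RankOneNet:
    """A rank-one recurrent network.

    Vectors are length N: connectivity (m, n), one input vector per
    channel in :data:`popgate.task.CHANNELS` (I_A, I_B, I_xA, I_xB) and
    the readout w.  tau and dt are in ms.
    """

    m: np.ndarray
    n: np.ndarray
    I_A: np.ndarray
    I_B: np.ndarray
    I_xA: np.ndarray
    I_xB: np.ndarray
    w: np.ndarray
    tau: float = 100.0
    dt: float = 20.0
    state_noise_sd: float = 0.05
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.tau > self.dt > 0):
            raise ValueError("require tau > dt > 0")

    @property
    def N(self) -> int:
        return self.m.shape[0]

    @property
    def input_matrix(self) -> np.ndarray:
        """(N, 4) matrix of input vectors, channel order as CHANNELS."""
        return np.stack([self.I_A, self.I_B, self.I_xA, self.I_xB], axis=1)

    @classmethod
    def random(cls, N: int, seed: int | None = None, **kw) -> "RankOneNet":
        """I.i.d. standard-Gaussian initialisation of all vectors."""
        rng = np.random.default_rng(seed)
        v = {k: rng.standard_normal(N) for k in ("m", "n", "I_A", "I_B", "I_xA", "I_xB", "w")}
        return cls(**v, **kw)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for k in ("m", "n", "I_A", "I_B", "I_xA", "I_xB", "w"):
                f.create_dataset(k, data=getattr(self, k))
            f.attrs["tau"] = self.tau
            f.attrs["dt"] = self.dt
            f.attrs["state_noise_sd"] = self.state_noise_sd
            for k, v in self.meta.items():
                f.attrs[f"meta_{k}"] = v

    @classmethod
    def load(cls, path) -> "RankOneNet":
        with h5py.File(path, "r") as f:
            vecs = {k: f[k][()] for k in ("m", "n", "I_A", "I_B", "I_xA", "I_xB", "w")}
            meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
            return cls(
                **vecs,
                tau=float(f.attrs["tau"]),
                dt=float(f.attrs["dt"]),
                state_noise_sd=float(f.attrs["state_noise_sd"]),
                meta=meta,
            )


@dataclass
class LowRankNet(RankOneNet):
    """Rank-r generalisation: m and n have shape (N, r).

    Used for the rank-sufficiency comparison; all simulation, training
    and accuracy machinery accepts it.  The recurrent matrix is
    (1/N) sum_k m_k n_k^T.
    """

    @property
    def rank(self) -> int:
        return self.m.shape[1]

    @classmethod
    def random(cls, N: int, rank: int = 2, seed: int | None = None, **kw) -> "LowRankNet":
        rng = np.random.default_rng(seed)
        v = {k: rng.standard_normal(N) for k in ("I_A", "I_B", "I_xA", "I_xB", "w")}
        return cls(
            m=rng.standard_normal((N, rank)), n=rng.standard_normal((N, rank)), **v, **kw
        )


def _mn2d(net: RankOneNet):
    """(N, r) views of the connectivity vectors, r = 1 for rank-one nets."""
    N = net.N if net.m.ndim == 1 else net.m.shape[0]
    return net.m.reshape(N, -1), net.n.reshape(N, -1)


@dataclass
class Trajectory:
    """Simulated pre-activation states, shape (n_trials, n_steps + 1, N).

    Index 0 along time is the initial condition (zeros); index t+1 is the
    state after integrating input timestep t.
    """

    x: np.ndarray

    @property
    def rates(self) -> np.ndarray:
        return np.tanh(self.x)

    def readout(self, net: RankOneNet) -> np.ndarray:
        """Readout time series z(t) = (1/N) w . phi(x(t)), shape (n_trials, n_steps + 1)."""
        return np.tanh(self.x) @ net.w / net.N


@dataclass
class TrainingLog:
    loss: np.ndarray
    n_trials: int
    batch_size: int
    learning_rate: float
    seed: int | None


def _forward(net: RankOneNet, inputs: np.ndarray, rng, noise_sd: float | None = None):
    """Euler-integrate a batch; returns states x of shape (B, T+1, N)."""
    B, T, L = inputs.shape
    N = net.N
    a = net.dt / net.tau
    sd = net.state_noise_sd if noise_sd is None else noise_sd
    I = net.input_matrix  # (N, 4)
    m2, n2 = _mn2d(net)
    x = np.zeros((B, T + 1, N))
    xt = np.zeros((B, N))
    for t in range(T):
        r = np.tanh(xt)
        kappa = r @ n2 / N  # (B, rank)
        drive = kappa @ m2.T + inputs[:, t, :] @ I.T
        if sd > 0:
            drive = drive + rng.normal(0.0, sd, size=(B, N))
        xt = (1.0 - a) * xt + a * drive
        if not np.all(np.isfinite(xt)):
            raise SimulationDivergedError(
                f"non-finite state first encountered at timestep {t}"
            )
        x[:, t + 1, :] = xt
    return x


def simulate(net: RankOneNet, batch: TrialBatch, seed: int | None = None) -> Trajectory:
    """Simulate the network on a batch of trials (initial state zero)."""
    if batch.inputs.shape[2] != len(CHANNELS):
        raise ValueError(
            f"batch has {batch.inputs.shape[2]} input channels; expected {len(CHANNELS)}"
        )
    rng = np.random.default_rng(seed)
    return Trajectory(x=_forward(net, batch.inputs, rng))


def _bptt_grads(net: RankOneNet, inputs: np.ndarray, target: np.ndarray, rng):
    """Loss and gradients w.r.t. (m, n, I_xA, I_xB) for one batch.

    Backpropagates through the Euler unrolling of the forward dynamics;
    the state noise is treated as a constant additive input.  The loss
    is the mean over trials of (z_hat - z)^2 at the last timestep.
    """
    B, T, _ = inputs.shape
    N = net.N
    a = net.dt / net.tau
    m2, n2 = _mn2d(net)
    x = _forward(net, inputs, rng)
    rT = np.tanh(x[:, -1, :])
    z_hat = rT @ net.w / N
    err = z_hat - target
    loss = float(np.mean(err**2))

    # dL/dx_T
    g = (2.0 * err / B)[:, None] * (net.w[None, :] / N) * (1.0 - rT**2)

    gm = np.zeros_like(m2)
    gn = np.zeros_like(n2)
    gI = np.zeros((N, 2))  # columns: I_xA, I_xB (channels 2, 3)
    for t in range(T - 1, -1, -1):
        r = np.tanh(x[:, t, :])
        kappa = r @ n2 / N  # (B, rank)
        mg = g @ m2  # (B, rank)  m_k . g_{t+1}
        gm += a * (g.T @ kappa)
        gn += a * (r.T @ mg) / N
        gI += a * (g.T @ inputs[:, t, 2:4])
        # propagate to x_t
        g = (1.0 - a) * g + (a / N) * (mg @ n2.T) * (1.0 - r**2)
    return loss, {
        "m": gm.reshape(net.m.shape),
        "n": gn.reshape(net.n.shape),
        "I_xA": gI[:, 0],
        "I_xB": gI[:, 1],
    }


class _Adam:
    def __init__(self, shapes, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params, grads):
        self.t += 1
        for k, grad in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grad**2
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def train_rank_one(
    task: TaskParams,
    N: int = 512,
    n_trials: int = 320_000,
    batch_size: int = 160,
    learning_rate: float = 1e-3,
    seed: int | None = None,
    patience: int | None = None,
    init: RankOneNet | None = None,
    rank: int = 1,
) -> tuple[RankOneNet, TrainingLog]:
    """Train a low-rank network (rank one by default) on the go/no-go task.

    Only (m, n, I_xA, I_xB) are optimised; the stimulus input vectors
    and the readout stay at their random initialisation.  Fresh balanced
    trial batches are drawn at every step (Adam, moment decays
    0.9/0.999).  The default budget of 320k trials (2000 batches of
    160) is what reliably converges under this package's readout
    normalisation z = (1/N) w . phi(x).  ``patience``: if set, raise
    :class:`TrainingFailedError` when the running-min loss has not
    improved for that many steps.
    """
    if batch_size % 8:
        raise ValueError("batch_size must be divisible by 8 for balanced batches")
    rng = np.random.default_rng(seed)
    if init is not None:
        net = init
    elif rank == 1:
        net = RankOneNet.random(N, seed=int(rng.integers(2**31)))
    else:
        net = LowRankNet.random(N, rank=rank, seed=int(rng.integers(2**31)))
    params = {k: getattr(net, k).copy() for k in ("m", "n", "I_xA", "I_xB")}
    opt = _Adam({k: v.shape for k, v in params.items()}, lr=learning_rate)

    n_steps = n_trials // batch_size
    losses = np.empty(n_steps)
    best, since_best = np.inf, 0
    for step in range(n_steps):
        batch = generate_trials(task, batch_size, balanced=True, seed=int(rng.integers(2**31)))
        for k in params:
            setattr(net, k, params[k])
        loss, grads = _bptt_grads(net, batch.inputs, batch.target, rng)
        opt.step(params, grads)
        losses[step] = loss
        if loss < best - 1e-12:
            best, since_best = loss, 0
        else:
            since_best += 1
            if patience is not None and since_best >= patience:
                raise TrainingFailedError(
                    f"loss has not improved for {patience} steps "
                    f"(best {best:.4g} at step {step - since_best})"
                )
    for k in params:
        setattr(net, k, params[k])
    net.meta.update(
        {"trained": True, "n_trials": n_trials, "batch_size": batch_size, "seed": -1 if seed is None else seed}
    )
    return net, TrainingLog(losses, n_trials, batch_size, learning_rate, seed)


def decide(z: np.ndarray, rule: str = "nearest") -> np.ndarray:
    """Map readout values to the discrete actions {-1, 0, +1}.

    'nearest': nearest target (thresholds at +-0.5); 'threshold':
    |z - s| < 0.5 for s in {-1, +1}, else no-go (identical here, kept
    as an explicit alternative).
    """
    if rule == "nearest":
        return np.clip(np.round(z), -1, 1)
    if rule == "threshold":
        out = np.zeros_like(z)
        out[z <= -0.5] = -1
        out[z >= 0.5] = 1
        return out
    raise ValueError(f"unknown decision rule {rule!r}")


def accuracy(
    net: RankOneNet,
    task: TaskParams,
    n_trials: int = 512,
    seed: int | None = None,
    rule: str = "nearest",
    batch: TrialBatch | None = None,
) -> dict:
    """Fraction of trials answered correctly, overall and per context."""
    rng = np.random.default_rng(seed)
    if batch is None:
        batch = generate_trials(task, n_trials, balanced=True, seed=int(rng.integers(2**31)))
    traj = simulate(net, batch, seed=int(rng.integers(2**31)))
    z = traj.readout(net)[:, -1]
    choice = decide(z, rule)
    ok = choice == batch.target
    out = {"overall": float(np.mean(ok))}
    for c in ("A", "B"):
        mask = batch.context == c
        out[c] = float(np.mean(ok[mask])) if mask.any() else np.nan
    return out
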