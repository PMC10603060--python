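"""Latent reduction of rank-one networks and population mean-field dynamics.

A rank-one network driven by L input channels evolves in the span of
its connectivity and input vectors: x(t) = kappa(t) m + sum_l v_l(t) I_l,
where v_l is the low-pass filtered input u_l.  ``latent_project``
recovers (kappa, v) from simulated states by least squares.

In the large-N limit, when neurons form P populations with jointly
Gaussian connectivity loadings, the recurrent latent obeys

    tau dkappa/dt = -kappa + sum_p alpha_p <phi'>_p
                      [ sigma_nm^(p) kappa + sum_l sigma_nIl^(p) v_l ]
    tau dv_l/dt   = -v_l + u_l

where sigma_ab^(p) are within-population loading overlaps (second
moments) and <phi'>_p is the population-average gain at the current
latent state, evaluated self-consistently.  The product sigma * <phi'>
acts as the functional (gain-modulated) connectivity; contextual inputs
that push a population towards saturation switch its contribution off —
the population-gating mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rnn import RankOneNet, Trajectory

__all__ = [
    "LOADING_COLS",
    "LatentTrajectory",
    "GaussianPopulations",
    "latent_project",
    "integrate_meanfield",
]

#: Loading-space column order used across the package.
LOADING_COLS = ("m", "n", "I_A", "I_B", "I_xA", "I_xB")


@dataclass
class LatentTrajectory:
    """Latent coordinates of simulated activity.

    kappa: (n_trials, n_steps+1); v: (n_trials, n_steps+1, L) in input
    channel order; residual: norm of the component outside the
    (m, I_1..I_L) span at each timestep; explained: fraction of total
    squared state norm inside the span.
    """

    kappa: np.ndarray
    v: np.ndarray
    residual: np.ndarray
    explained: float


def latent_project(traj: Trajectory, net: RankOneNet) -> LatentTrajectory:
    """Least-squares projection of states onto span{m, I_A, I_B, I_xA, I_xB}."""
    basis = np.column_stack([net.m, net.I_A, net.I_B, net.I_xA, net.I_xB])
    cond = np.linalg.cond(basis)
    if cond > 1e8:
        raise np.linalg.LinAlgError(
            f"latent basis is ill-conditioned (cond={cond:.3g}); "
            "connectivity and input vectors are nearly collinear"
        )
    pinv = np.linalg.pinv(basis)  # (5, N)
    coeffs = traj.x @ pinv.T  # (trials, T+1, 5)
    recon = coeffs @ basis.T
    resid = np.linalg.norm(traj.x - recon, axis=-1)
    tot = float(np.sum(traj.x**2))
    explained = 1.0 - float(np.sum((traj.x - recon) ** 2)) / tot if tot > 0 else 1.0
    return LatentTrajectory(
        kappa=coeffs[..., 0], v=coeffs[..., 1:], residual=resid, explained=explained
    )


@dataclass
class GaussianPopulations:
    """Per-population Gaussian statistics of connectivity loadings.

    ``means``: (P, d) and ``covs``: (P, d, d) over the columns in
    ``columns`` (default :data:`LOADING_COLS`); ``fractions``: relative
    population sizes summing to 1.  Serves both as the parameterisation
    of hand-engineered networks and as empirical cluster moments
    extracted from trained ones.
    """

    means: np.ndarray
    covs: np.ndarray
    fractions: np.ndarray
    columns: tuple = LOADING_COLS
    n_mc: int = 10_000
    seed: int = 0
    #: optional per-population loading samples; when given, population
    #: averages (gains) are taken over these actual neurons instead of
    #: fresh Gaussian draws — the empirical reduction of a finite network.
    samples: list | None = None

    @classmethod
    def empirical(cls, loadings: np.ndarray, labels: np.ndarray,
                  columns: tuple = LOADING_COLS) -> "GaussianPopulations":
        """Empirical population statistics of a finite network.

        ``loadings``: (N, d) table over ``columns``; ``labels``: population
        assignment per neuron.  The returned object integrates the
        mean-field equations with the network's own per-population
        moments and computes gains over its actual neurons, which is
        the appropriate reduction of a given finite network (sampling
        error of the overlaps does not enter the comparison).
        """
        labs = np.unique(labels)
        means, covs, fracs, samples = [], [], [], []
        for lab in labs:
            X = loadings[labels == lab]
            means.append(X.mean(axis=0))
            covs.append(np.cov(X, rowvar=False, bias=True))
            fracs.append(X.shape[0] / loadings.shape[0])
            samples.append(X)
        return cls(
            means=np.stack(means), covs=np.stack(covs),
            fractions=np.asarray(fracs), columns=columns, samples=samples,
        )

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covs = np.asarray(self.covs, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if not np.isclose(self.fractions.sum(), 1.0):
            raise ValueError("population fractions must sum to 1")
        for c in self.covs:
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError("covariance matrices must be symmetric")
        self._samples = None

    @property
    def P(self) -> int:
        return len(self.fractions)

    def col(self, name: str) -> int:
        return self.columns.index(name)

    def second_moment(self, a: str, b: str) -> np.ndarray:
        """E[a*b] per population (the overlaps sigma_ab)."""
        i, j = self.col(a), self.col(b)
        return self.covs[:, i, j] + self.means[:, i] * self.means[:, j]

    # -- Monte-Carlo gain machinery (loadings drawn once, common random numbers) --

    def _draws(self):
        if self._samples is None:
            if self.samples is not None:
                self._samples = self.samples
            else:
                rng = np.random.default_rng(self.seed)
                self._samples = [
                    rng.multivariate_normal(mu, cov, size=self.n_mc, method="svd")
                    for mu, cov in zip(self.means, self.covs)
                ]
        return self._samples

    def activation_stats(self, drives: dict) -> dict:
        """Population averages <phi'(x)> and <phi(x)> at the latent state.

        ``drives`` maps column name -> scalar coefficient; the implied
        single-unit state is x_i = sum_c drives[c] * loading_{c,i}.
        """
        gains = np.empty(self.P)
        phis = np.empty(self.P)
        for p, S in enumerate(self._draws()):
            x = np.zeros(S.shape[0])
            for cname, s in drives.items():
                if s != 0.0:
                    x = x + s * S[:, self.col(cname)]
            th = np.tanh(x)
            gains[p] = np.mean(1.0 - th**2)
            phis[p] = np.mean(th)
        return {"gain": gains, "phi": phis}

    def gains(self, drives: dict) -> np.ndarray:
        """Population-average gain <phi'>_p at the latent state."""
        return self.activation_stats(drives)["gain"]

    def projection(self, onto: str, drives: dict, stats: dict | None = None) -> float:
        """Population-averaged E[onto * phi(x)].

        Evaluated per population via Stein's lemma for jointly Gaussian
        loadings, mu_onto <phi(x)> + <phi'(x)> sum_c Cov(onto, c) s_c,
        exact in the large-N limit.  Gives e.g. the recurrent latent
        drive (onto='n') or the mean-field readout (onto='m' or 'w') of
        the population dynamics.
        """
        if stats is None:
            stats = self.activation_stats(drives)
        i = self.col(onto)
        tot = 0.0
        for p in range(self.P):
            acc = self.means[p, i] * stats["phi"][p]
            for cname, s in drives.items():
                if s != 0.0:
                    acc += stats["gain"][p] * self.covs[p, i, self.col(cname)] * s
            tot += self.fractions[p] * acc
        return tot

    def to_yaml(self, path) -> None:
        """Write the population statistics as a YAML overlap table."""
        import yaml

        doc = {
            "columns": list(self.columns),
            "fractions": self.fractions.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covs.tolist(),
        }
        with open(path, "w") as f:
            yaml.safe_dump(doc, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GaussianPopulations":
        """Read population statistics from a YAML overlap table."""
        import yaml

        with open(path) as f:
            doc = yaml.safe_load(f)
        return cls(
            means=np.asarray(doc["means"]),
            covs=np.asarray(doc["covariances"]),
            fractions=np.asarray(doc["fractions"]),
            columns=tuple(doc["columns"]),
        )

    def sample_network(self, N: int, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Draw a finite network's loading table (N, d) honouring fractions.

        Population sizes are allocated by largest remainder so counts are
        deterministic given N.  Returns (loadings, population labels).
        """
        rng = np.random.default_rng(seed)
        raw = self.fractions * N
        counts = np.floor(raw).astype(int)
        rem = N - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
        blocks, labels = [], []
        for p, c in enumerate(counts):
            if c == 0:
                continue
            blocks.append(
                rng.multivariate_normal(self.means[p], self.covs[p], size=c, method="svd")
            )
            labels.append(np.full(c, p))
        return np.concatenate(blocks, axis=0), np.concatenate(labels)


def integrate_meanfield(
    pops: GaussianPopulations,
    u: np.ndarray,
    kappa0: float = 0.0,
    dt: float = 20.0,
    tau: float = 100.0,
    input_cols: tuple = ("I_A", "I_B", "I_xA", "I_xB"),
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-integrate the noiseless population mean-field latent dynamics.

    ``u``: (T, L) external inputs, channels matching ``input_cols``.
    Returns (kappa, v) with shapes (T+1,) and (T+1, L); index 0 is the
    initial condition.  Gains are re-evaluated self-consistently from
    the implied single-unit state distribution at every step.  Filtered
    inputs share the network time constant.
    """
    u = np.asarray(u, dtype=float)
    T, L = u.shape
    if L != len(input_cols):
        raise ValueError(f"u has {L} channels but input_cols names {len(input_cols)}")
    a = dt / tau
    kappa = np.empty(T + 1)
    v = np.zeros((T + 1, L))
    kappa[0] = kappa0
    for t in range(T):
        drives = {"m": kappa[t]}
        for l, cname in enumerate(input_cols):
            drives[cname] = v[t, l]
        stats = pops.activation_stats(drives)
        rec = pops.projection("n", drives, stats)
        kappa[t + 1] = (1 - a) * kappa[t] + a * rec
        v[t + 1] = (1 - a) * v[t] + a * u[t]
        if not np.isfinite(kappa[t + 1]):
            raise FloatingPointError(
                f"mean-field diverged at step {t}; last finite kappa={kappa[t]:.4g}"
            )
    return kappa, v
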