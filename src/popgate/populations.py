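"""Population structure of rank-one networks.

Trained rank-one networks that solve the context-dependent go/no-go
task rely on a small number of neuron populations, each defined by the
joint Gaussian statistics of its connectivity loadings
(m, n, I_A, I_B, I_xA, I_xB).  This module infers that structure by
mixture-model clustering in loading space, tests how many populations
are needed by resampling networks from per-cluster moments (which
destroys single-neuron identity but preserves within-population
correlations), and constructs an explicit three-population solution:

* population A integrates stimulus A into the recurrent latent, and is
  pushed into saturation (low gain) by the context-B input;
* population B mirrors it for stimulus B and context A;
* population 0 provides negative feedback on the latent, stabilising
  the no-go output at zero.

Gating works through the working point of single neurons: each gating
population's preferred-context input shifts its neurons to an offset
that the go level (-1) of its preferred stimulus cancels (high gain,
strong integration) and the no-go level (+1) doubles (saturation); the
non-preferred context input shifts the whole population far into
saturation, silencing its contribution to the latent dynamics — the
single-neuron gain modulation that implements output gating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import BayesianGaussianMixture, GaussianMixture

from .lowrank import LOADING_COLS, GaussianPopulations
from .rnn import RankOneNet, Trajectory

__all__ = [
    "RESAMPLE_COLS",
    "ThreePopParams",
    "PopulationPartition",
    "loading_table",
    "cluster_loadings",
    "resample_network",
    "min_populations",
    "build_three_pop_solution",
    "population_output_projection",
]

#: Columns used when clustering (the connectivity loadings).
CLUSTER_COLS = LOADING_COLS
#: Columns carried through resampling: clustering is done on the six
#: connectivity loadings, but per-cluster moments include the readout w
#: so that resampled networks preserve readout-connectivity correlations.
RESAMPLE_COLS = LOADING_COLS + ("w",)


def loading_table(net: RankOneNet, include_w: bool = False) -> np.ndarray:
    """(N, 6) (or (N, 7) with w) table of per-neuron loadings."""
    cols = [net.m, net.n, net.I_A, net.I_B, net.I_xA, net.I_xB]
    if include_w:
        cols.append(net.w)
    return np.column_stack(cols)


@dataclass
class PopulationPartition:
    """A clustering of neurons in loading space with per-cluster moments."""

    labels: np.ndarray
    means: np.ndarray  # (k, 7) over RESAMPLE_COLS
    covs: np.ndarray  # (k, 7, 7)
    k: int
    columns: tuple = RESAMPLE_COLS

    @property
    def fractions(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k) / self.labels.size


def cluster_loadings(
    net: RankOneNet,
    k: int,
    seed: int | None = None,
    n_init: int = 10,
    bayesian: bool = True,
    max_retries: int = 5,
) -> PopulationPartition:
    """Gaussian-mixture clustering of neurons in 6-D loading space.

    Full-covariance Bayesian Gaussian mixture by default (``bayesian=
    False`` switches to a plain maximum-likelihood mixture), ``n_init``
    restarts, best fit kept.  The Bayesian variant separates the
    population count of trained networks more cleanly: its weight prior
    shrinks clusters that do not earn their keep.  Per-cluster
    empirical moments are stored over the seven :data:`RESAMPLE_COLS`
    (clustering itself never sees w).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = loading_table(net)
    X7 = loading_table(net, include_w=True)
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        rs = int(rng.integers(2**31))
        if bayesian:
            gm = BayesianGaussianMixture(
                n_components=k, covariance_type="full", n_init=n_init,
                max_iter=500, random_state=rs,
            )
        else:
            gm = GaussianMixture(
                n_components=k, covariance_type="full", n_init=n_init,
                max_iter=500, random_state=rs,
            )
        labels = gm.fit_predict(X)
        counts = np.bincount(labels, minlength=k)
        if np.all(counts > 0):
            break
    # the Bayesian mixture may leave components empty when the data do
    # not support k populations: the partition then collapses to fewer
    # effective clusters (their fractions are zero and they are never
    # resampled)
    means = np.zeros((k, 7))
    covs = np.zeros((k, 7, 7))
    for j in range(k):
        if counts[j] > 0:
            means[j] = X7[labels == j].mean(axis=0)
            covs[j] = np.cov(X7[labels == j], rowvar=False, bias=True).reshape(7, 7)
    return PopulationPartition(labels=labels, means=means, covs=covs, k=k)


def _ensure_psd(cov: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(cov)
    if w.min() < -1e-10:
        import warnings

        warnings.warn("clipping negative covariance eigenvalues during resampling")
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def resample_network(
    partition: PopulationPartition,
    N_new: int,
    seed: int | None = None,
    template: RankOneNet | None = None,
) -> RankOneNet:
    """Sample a fresh network from per-cluster loading statistics.

    Neurons are drawn per cluster (sizes proportional to cluster
    fractions, largest-remainder rounding) from the cluster's
    multivariate Gaussian over :data:`RESAMPLE_COLS` — destroying
    single-neuron identity while keeping population-level correlations.
    """
    rng = np.random.default_rng(seed)
    frac = partition.fractions
    raw = frac * N_new
    counts = np.floor(raw).astype(int)
    rem = N_new - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    rows = []
    for j in range(partition.k):
        if counts[j] == 0:
            continue
        cov = _ensure_psd(partition.covs[j])
        rows.append(
            rng.multivariate_normal(partition.means[j], cov, size=counts[j], method="svd")
        )
    X = np.concatenate(rows, axis=0)
    kw = {}
    if template is not None:
        kw = dict(
            tau=template.tau, dt=template.dt, state_noise_sd=template.state_noise_sd
        )
    return RankOneNet(
        m=X[:, 0], n=X[:, 1], I_A=X[:, 2], I_B=X[:, 3], I_xA=X[:, 4], I_xB=X[:, 5],
        w=X[:, 6], **kw,
    )


def min_populations(
    net: RankOneNet,
    task,
    k_range=range(1, 5),
    threshold: float = 0.95,
    n_resamples: int = 10,
    seed: int | None = None,
    n_eval_trials: int = 512,
    n_cluster_seeds: int = 3,
) -> tuple[int | None, dict]:
    """Smallest number of populations whose resampled networks match the source.

    The question is existential — does *some* k-population Gaussian
    summary of the loadings reproduce the network's function? — so for
    each k the loadings are clustered ``n_cluster_seeds`` times
    (mixture fits have local optima), ``n_resamples`` networks are
    resampled from each partition's moments, and the best partition's
    median task accuracy is kept.  k qualifies when that accuracy
    reaches ``threshold`` x the source net's accuracy.  Returns
    (k_min, info) where info carries the accuracy-vs-k curve; k_min is
    None when no k in the range qualifies.
    """
    from .rnn import accuracy

    rng = np.random.default_rng(seed)
    base = accuracy(net, task, n_trials=n_eval_trials, seed=int(rng.integers(2**31)))["overall"]
    curve = {}
    k_min = None
    for k in k_range:
        medians = []
        for _ in range(n_cluster_seeds if k > 1 else 1):
            part = cluster_loadings(net, k, seed=int(rng.integers(2**31)))
            accs = [
                accuracy(
                    resample_network(part, net.N, seed=int(rng.integers(2**31)), template=net),
                    task, n_trials=n_eval_trials, seed=int(rng.integers(2**31)),
                )["overall"]
                for _ in range(n_resamples)
            ]
            medians.append(float(np.median(accs)))
        curve[k] = max(medians)
        if k_min is None and curve[k] >= threshold * base:
            k_min = k
    return k_min, {"curve": curve, "base_accuracy": base}


@dataclass
class ThreePopParams:
    """Parameters of the hand-engineered three-population solution.

    Per-population Gaussian loadings over (m, n, I_A, I_B, I_xA, I_xB, w);
    fractions are equal thirds.  Connectivity (m, n, w) is zero-mean;
    the input loadings of the gating populations have population means
    that implement gain gating by shifting the working point:

    * population A's preferred-context input (I_xA) has mean
      ``mu_stim`` and its preferred stimulus input (I_A) the same mean,
      so during context A the go level (-1) of stimulus A cancels the
      contextual shift (working point near 0: high gain, strong
      integration) while the no-go level (+1) doubles it (saturation:
      the stimulus is shut out of the latent);
    * its non-preferred context input (I_xB) has large mean ``mu_sup``,
      saturating the whole population in context B;
    * population B mirrors this; population 0 receives no net
      contextual shift and provides negative latent feedback.

    Defaults were fixed once by the coarse grid search in
    ``scripts/calibrate_three_pop.py`` and validated by simulation.

    sigma_s : SD of each stimulus-input loading (the sensory axes).
    beta : overlap sigma_nI between n and the preferred stimulus input.
    r_gate : self-feedback overlap sigma_nm of populations A, B.
    rho : magnitude of population 0's negative feedback (sigma_nm = -rho).
    mu_stim : working-point shift of the preferred context/stimulus pair.
    mu_sup : saturating shift from the non-preferred context input.
    sigma_ctx : SD of the context-input loadings around their means.
    nu : residual SD of n.
    gamma_w : readout scale; w = gamma_w * m in every population, so the
        output axis is exactly m.  Population A integrates stimulus A
        with positive overlap (go level -1 drives kappa negative,
        go-left) while population B integrates stimulus B with negative
        overlap (go level -1 drives kappa positive, go-right): the
        recurrent latent itself carries the signed response, which is
        what lets a single rank-one channel communicate it downstream.
    """

    sigma_s: float = 1.0
    beta: float = 12.0
    r_gate: float = 2.0
    rho: float = 1.0
    mu_stim: float = 1.5
    mu_sup: float = 6.5
    sigma_ctx: float = 0.3
    nu: float = 0.5
    gamma_w: float = 3.5
    fractions: tuple = (1 / 3, 1 / 3, 1 / 3)


def three_pop_statistics(params: ThreePopParams | None = None) -> GaussianPopulations:
    """Gaussian loading statistics of the three-population solution.

    Populations are ordered (A, B, 0).  Covariances are built from
    factor loadings so they are PSD by construction.
    """
    p = params or ThreePopParams()
    # column order: m, n, I_A, I_B, I_xA, I_xB, w
    # factor order: g_m, g_n, g_A, g_B, g_xA, g_xB
    def gate_pop(pref: str):
        L = np.zeros((7, 6))
        mu = np.zeros(7)
        L[0, 0] = 1.0  # m
        L[1, 0] = p.r_gate
        L[1, 1] = p.nu
        L[2, 2] = p.sigma_s  # I_A
        L[3, 3] = p.sigma_s  # I_B
        L[4, 4] = p.sigma_ctx  # I_xA
        L[5, 5] = p.sigma_ctx  # I_xB
        L[6, 0] = p.gamma_w  # w = gamma * m in every population
        if pref == "A":
            L[1, 2] = p.beta / p.sigma_s  # sigma_nIA = +beta: go A -> kappa < 0
            mu[2] = p.mu_stim  # I_A mean: go level cancels the context shift
            mu[4] = p.mu_stim  # I_xA mean: preferred-context working point
            mu[5] = p.mu_sup  # I_xB mean: saturated in context B
        else:
            L[1, 3] = -p.beta / p.sigma_s  # sigma_nIB = -beta: go B -> kappa > 0
            mu[3] = p.mu_stim
            mu[5] = p.mu_stim
            mu[4] = p.mu_sup
        return L, mu

    L0 = np.zeros((7, 6))
    L0[0, 0] = 1.0
    L0[1, 0] = -p.rho
    L0[1, 1] = p.nu
    L0[2, 2] = p.sigma_s
    L0[3, 3] = p.sigma_s
    L0[4, 4] = p.sigma_ctx
    L0[5, 5] = p.sigma_ctx
    L0[6, 0] = p.gamma_w

    LA, muA = gate_pop("A")
    LB, muB = gate_pop("B")
    covs = np.stack([L @ L.T for L in (LA, LB, L0)])
    means = np.stack([muA, muB, np.zeros(7)])
    return GaussianPopulations(
        means=means, covs=covs, fractions=np.asarray(p.fractions), columns=RESAMPLE_COLS
    )


def build_three_pop_solution(
    N: int = 1500,
    params: ThreePopParams | None = None,
    seed: int | None = None,
    tau: float = 100.0,
    dt: float = 20.0,
    state_noise_sd: float = 0.05,
) -> tuple[RankOneNet, np.ndarray]:
    """Draw a finite three-population network; returns (net, population labels).

    Labels: 0 = population A, 1 = population B, 2 = population 0.
    """
    stats = three_pop_statistics(params)
    X, labels = stats.sample_network(N, seed=seed)
    net = RankOneNet(
        m=X[:, 0], n=X[:, 1], I_A=X[:, 2], I_B=X[:, 3], I_xA=X[:, 4], I_xB=X[:, 5],
        w=X[:, 6], tau=tau, dt=dt, state_noise_sd=state_noise_sd,
    )
    return net, labels


def population_output_projection(
    traj: Trajectory, net: RankOneNet, labels: np.ndarray
) -> dict:
    """Per-population projection of activity on the output axis m.

    Returns {label: array (n_trials, n_steps+1)} with the restricted sum
    (1/N) sum_{i in p} m_i phi(x_i); the per-population projections add
    up exactly to the whole-network projection.
    """
    rates = traj.rates
    out = {}
    for lab in np.unique(labels):
        mask = labels == lab
        out[int(lab)] = rates[:, :, mask] @ net.m[mask] / net.N
    return out
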