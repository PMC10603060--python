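"""Communication subspaces between areas via cross-validated CCA.

Trial-to-trial (noise) activity is isolated by subtracting each
neuron's per-condition mean.  For each of many random half-splits the
residuals of both areas are reduced to their top principal components
(fitted on the training half only), canonical correlation analysis is
fitted on the training half, and the canonical-variate Pearson
correlations are evaluated on the held-out half.  The number of
leading dimensions whose fold-wise 95% interval of held-out
correlation excludes zero estimates the dimensionality of the
communication subspace.  Subspace alignment is quantified by the
smallest principal angle (arccos of the largest singular value of the
cross-Gram matrix of orthonormal bases).

The dimensionality estimate is known to be sensitive to the number of
principal components retained; ``pc_sweep`` reports it across
n_pcs in {5, 10, 20}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import CCA
from sklearn.decomposition import PCA

__all__ = [
    "CCAResult",
    "SubspaceAngle",
    "residualize",
    "estimate_cca",
    "subspace_angle",
    "pc_sweep",
    "context_channel_analysis",
]


def residualize(activity: np.ndarray, conditions: np.ndarray) -> np.ndarray:
    """Remove per-neuron condition means (noise activity).

    activity: (n_trials, n_neurons); conditions: condition label per
    trial.  Raises if any condition has a single trial.
    """
    activity = np.asarray(activity, dtype=float)
    out = activity.copy()
    conditions = np.asarray(conditions)
    singletons = []
    for c in np.unique(conditions):
        m = conditions == c
        if m.sum() < 2:
            singletons.append(c)
            continue
        out[m] -= activity[m].mean(axis=0)
    if singletons:
        raise ValueError(f"conditions with a single trial: {singletons}")
    return out


@dataclass
class CCAResult:
    """Cross-validated canonical correlations between two areas.

    corrs: (n_folds, n_dims) held-out Pearson correlations, dimensions
    ordered by training-set correlation; mean / ci_low / ci_high are
    fold-wise statistics; n_significant counts the leading dimensions
    whose 95% interval excludes zero; loadings_A / loadings_P are
    neuron-space canonical directions from a fit on all trials.
    """

    corrs: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_significant: int
    loadings_A: np.ndarray
    loadings_P: np.ndarray
    n_pcs: int


def _pca_cca_loadings(actA, actP, n_pcs, n_cca) -> tuple[np.ndarray, np.ndarray]:
    pA = PCA(n_components=n_pcs, svd_solver="randomized", random_state=0).fit(actA)
    pP = PCA(n_components=n_pcs, svd_solver="randomized", random_state=0).fit(actP)
    cca = CCA(n_components=n_cca, max_iter=1000).fit(pA.transform(actA), pP.transform(actP))
    return pA.components_.T @ cca.x_rotations_, pP.components_.T @ cca.y_rotations_


def estimate_cca(
    actA: np.ndarray,
    actP: np.ndarray,
    n_pcs: int = 10,
    n_folds: int = 250,
    seed: int | None = None,
    n_cca: int | None = None,
) -> CCAResult:
    """Cross-validated CCA between residual activity of two areas.

    actA, actP: (n_trials, n_neurons) residualized activity, trials
    aligned.  Per fold: random half split; PCA (top ``n_pcs``) and CCA
    fitted on the training half only; Pearson correlations of the
    canonical variates evaluated on the held-out half.
    """
    actA = np.asarray(actA, dtype=float)
    actP = np.asarray(actP, dtype=float)
    if actA.shape[0] != actP.shape[0]:
        raise ValueError("areas disagree on trial count")
    n_trials = actA.shape[0]
    half = n_trials // 2
    if n_pcs > half or n_pcs > min(actA.shape[1], actP.shape[1]):
        raise ValueError(f"n_pcs={n_pcs} exceeds trials/2 or neuron count")
    n_cca = n_pcs if n_cca is None else n_cca
    rng = np.random.default_rng(seed)
    corrs = np.empty((n_folds, n_cca))
    for f in range(n_folds):
        perm = rng.permutation(n_trials)
        tr, te = perm[:half], perm[half:]
        pA = PCA(n_components=n_pcs, svd_solver="randomized",
                 random_state=int(rng.integers(2**31))).fit(actA[tr])
        pP = PCA(n_components=n_pcs, svd_solver="randomized",
                 random_state=int(rng.integers(2**31))).fit(actP[tr])
        cca = CCA(n_components=n_cca, max_iter=1000)
        cca.fit(pA.transform(actA[tr]), pP.transform(actP[tr]))
        sA, sP = cca.transform(pA.transform(actA[te]), pP.transform(actP[te]))
        sA = sA - sA.mean(axis=0)
        sP = sP - sP.mean(axis=0)
        denom = np.linalg.norm(sA, axis=0) * np.linalg.norm(sP, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corrs[f] = np.where(denom > 0, (sA * sP).sum(axis=0) / denom, 0.0)
    lo = np.percentile(corrs, 2.5, axis=0)
    hi = np.percentile(corrs, 97.5, axis=0)
    n_sig = 0
    for d in range(n_cca):
        if lo[d] > 0:
            n_sig += 1
        else:
            break
    lA, lP = _pca_cca_loadings(actA, actP, n_pcs, n_cca)
    return CCAResult(
        corrs=corrs, mean=corrs.mean(axis=0), ci_low=lo, ci_high=hi,
        n_significant=n_sig, loadings_A=lA, loadings_P=lP, n_pcs=n_pcs,
    )


@dataclass
class SubspaceAngle:
    angle_deg: float
    basis_names: tuple = ("B", "B_hat")


def subspace_angle(B: np.ndarray, B_hat: np.ndarray) -> SubspaceAngle:
    """Smallest principal angle between two subspaces, in degrees.

    Bases are orthonormalized internally; the angle is the arccosine of
    the largest singular value of the cross-Gram matrix.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    B_hat = np.atleast_2d(np.asarray(B_hat, dtype=float))
    if B.shape[0] == 1:
        B = B.T
    if B_hat.shape[0] == 1:
        B_hat = B_hat.T
    for M, name in ((B, "B"), (B_hat, "B_hat")):
        if np.linalg.norm(M) == 0:
            raise ValueError(f"zero basis {name}")
    QB, _ = np.linalg.qr(B)
    QH, _ = np.linalg.qr(B_hat)
    s = np.linalg.svd(QB.T @ QH, compute_uv=False)
    return SubspaceAngle(angle_deg=float(np.degrees(np.arccos(np.clip(s.max(), -1, 1)))))


def pc_sweep(
    actA: np.ndarray,
    actP: np.ndarray,
    n_pcs_list=(5, 10, 20),
    n_folds: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Significant-dimension count as a function of retained PCs."""
    rows = []
    for npc in n_pcs_list:
        try:
            res = estimate_cca(actA, actP, n_pcs=npc, n_folds=n_folds, seed=seed)
            rows.append({"n_pcs": npc, "n_significant": res.n_significant})
        except ValueError as e:
            rows.append({"n_pcs": npc, "n_significant": np.nan, "note": str(e)})
    return pd.DataFrame(rows)


def context_channel_analysis(
    sim,
    net,
    batch,
    n_pcs: int = 10,
    n_folds: int = 100,
    seed: int | None = None,
    n_null: int = 200,
) -> dict:
    """Context dependence of the estimated A1-PFC communication subspace.

    Runs per-context cross-validated CCA on stimulus-window residual
    rates of an engineered two-area simulation and reports: the angle
    between the first canonical A1 dimensions of the two contexts;
    each dimension's angle to the output axis m_A (with a
    random-vector null); the per-population mean absolute canonical
    coefficient in each context; and the pooled-context first
    dimension's angle to m_A.
    """
    rng = np.random.default_rng(seed)
    win = slice(batch.params.n_prestim + 1, batch.n_steps + 1)
    rA = np.tanh(sim.x_A[:, win, :]).mean(axis=1)
    rP = np.tanh(sim.x_P[:, win, :]).mean(axis=1)
    ctx = batch.context
    cond = pd.Series(
        [f"{a}/{b}" for a, b in zip(batch.stimA_level, batch.stimB_level)]
    ).to_numpy()

    out = {"per_context": {}}
    first_dims = {}
    for c in ("A", "B"):
        m = ctx == c
        resA = residualize(rA[m], cond[m])
        resP = residualize(rP[m], cond[m])
        res = estimate_cca(resA, resP, n_pcs=n_pcs, n_folds=n_folds,
                           seed=int(rng.integers(2**31)))
        first_dims[c] = res.loadings_A[:, 0]
        out["per_context"][c] = res
    out["angle_between_contexts"] = subspace_angle(
        first_dims["A"], first_dims["B"]
    ).angle_deg
    out["angle_to_mA"] = {
        c: subspace_angle(first_dims[c], net.m_A).angle_deg for c in ("A", "B")
    }
    # random-vector null for angles to m_A
    null = np.empty(n_null)
    N = net.m_A.size
    for i in range(n_null):
        null[i] = subspace_angle(rng.standard_normal(N), net.m_A).angle_deg
    out["null_angle_mean"] = float(null.mean())
    out["null_angle_p5"] = float(np.percentile(null, 5))

    coef = pd.DataFrame(
        {
            "population": np.where(net.labels_A == 0, "A",
                                   np.where(net.labels_A == 1, "B", "0")),
            "ctx_A": np.abs(first_dims["A"]),
            "ctx_B": np.abs(first_dims["B"]),
        }
    )
    out["mean_abs_coef"] = coef.groupby("population")[["ctx_A", "ctx_B"]].mean()

    resA = residualize(rA, np.char.add(ctx.astype(str), cond.astype(str)))
    resP = residualize(rP, np.char.add(ctx.astype(str), cond.astype(str)))
    pooled = estimate_cca(resA, resP, n_pcs=n_pcs, n_folds=n_folds,
                          seed=int(rng.integers(2**31)))
    out["pooled"] = pooled
    out["pooled_angle_to_mA"] = subspace_angle(pooled.loadings_A[:, 0], net.m_A).angle_deg
    return out
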