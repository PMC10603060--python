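"""Population labelling and output-gating statistics on spike counts.

Neurons are grouped by their pre-stimulus context modulation: a
two-sided Mann-Whitney test compares each neuron's per-trial
pre-stimulus firing between the two contexts, p-values are adjusted
across neurons (Benjamini-Hochberg), and significantly modulated
neurons are labelled by the context in which they fire *less* (their
preferred context); the rest form population 0.

Output gating is quantified per population as the ratio of the
go/no-go separation along the population's output axis in its
preferred versus non-preferred context.  Its null distribution comes
from a permutation scheme that destroys the link between pre-stimulus
modulation and stimulus-epoch dynamics: per neuron, trial context
labels are shuffled, the labelling is recomputed, a matched-size
population is reselected by the permuted modulation statistic, and the
ratio is recomputed under the permuted labels.

Single-neuron selectivity is assessed by regressing stimulus-window
spike counts on the task variables (location, pitch, decision,
context); a slow-drift control distinguishes block-identity (context)
effects from monotone within-session drift.

Labelling uses only pre-stimulus bins and ratios only stimulus bins,
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .recordings import RecordingSet

__all__ = [
    "PopulationLabels",
    "GatingResult",
    "label_populations",
    "gating_ratio",
    "gating_permutation_test",
    "selectivity_regression",
    "drift_control",
]


@dataclass
class GatingResult:
    """Output-gating ratio with (optionally) its permutation null."""

    ratio: float
    population: str
    null: np.ndarray | None = None
    p_value: float | None = None
    n_resampled: int = 0  # permutations redrawn due to degenerate selections


def _mannwhitney_z(rates: np.ndarray, in_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided Mann-Whitney for many neurons at once.

    rates: (n_neurons, n_trials); in_a: boolean context-A mask, either
    (n_trials,) shared or (n_neurons, n_trials) per-neuron (used by the
    permutation scheme).  Returns (z, p) per neuron, normal
    approximation with tie correction; z > 0 means higher rates in
    context A.
    """
    rates = np.asarray(rates, dtype=float)
    n_neurons, n_trials = rates.shape
    if in_a.ndim == 1:
        in_a = np.broadcast_to(in_a, rates.shape)
    n_a = in_a.sum(axis=1).astype(float)
    n_b = n_trials - n_a
    ranks = stats.rankdata(rates, axis=1)
    U = (ranks * in_a).sum(axis=1) - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    # tie correction depends only on the data, not the grouping
    tie_term = np.empty(n_neurons)
    for i in range(n_neurons):
        _, t = np.unique(rates[i], return_counts=True)
        tie_term[i] = (t**3 - t).sum()
    sigma2 = n_a * n_b / 12.0 * ((n_trials + 1) - tie_term / (n_trials * (n_trials - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (U - mu - np.sign(U - mu) * 0.5) / sigma
    z = np.where(sigma > 0, z, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


@dataclass
class PopulationLabels:
    """Per-neuron population labels from pre-stimulus context modulation.

    table: DataFrame with columns label ('A', 'B', '0'), z (positive =
    higher firing in context A), p, p_adj, testable.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    def mask(self, population: str) -> np.ndarray:
        return self.labels == population


def label_populations(rec: RecordingSet, alpha: float = 0.05) -> PopulationLabels:
    """Label neurons by pre-stimulus context modulation.

    Mann-Whitney (two-sided) on per-trial pre-stimulus mean rates,
    BH-adjusted across neurons; significant neurons are labelled with
    the context in which they fire less (z > 0 means higher in context
    A, hence a context-B-preferring neuron).  Neurons with constant
    rates are untestable and assigned to population 0.
    """
    ctx = rec.meta["context"].to_numpy()
    n_a = int((ctx == "A").sum())
    if n_a < 2 or (len(ctx) - n_a) < 2:
        raise ValueError("need at least 2 trials per context")
    rates = rec.rates(rec.pre_window)
    testable = rates.ptp(axis=1) > 0 if hasattr(rates, "ptp") else np.ptp(rates, axis=1) > 0
    z, p = _mannwhitney_z(rates, ctx == "A")
    p = np.where(testable, p, 1.0)
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    label = np.full(rec.n_neurons, "0", dtype="U1")
    sig = (p_adj < alpha) & testable
    # lower firing in a context = that context preferred
    label[sig & (z < 0)] = "A"
    label[sig & (z > 0)] = "B"
    table = pd.DataFrame(
        {"label": label, "z": z, "p": p, "p_adj": p_adj, "testable": testable}
    )
    return PopulationLabels(table=table, alpha=alpha)


def _cell_means(stim_rates: np.ndarray, ctx_a: np.ndarray, go: np.ndarray) -> np.ndarray:
    """Per-neuron mean stimulus rates in the 4 (context x go) cells.

    ctx_a, go: (n_neurons, n_trials) boolean.  Returns (n_neurons, 4)
    ordered (A-go, A-nogo, B-go, B-nogo).
    """
    out = np.empty((stim_rates.shape[0], 4))
    for j, m in enumerate((ctx_a & go, ctx_a & ~go, ~ctx_a & go, ~ctx_a & ~go)):
        s = m.sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[:, j] = np.where(s > 0, (stim_rates * m).sum(axis=1) / np.maximum(s, 1), np.nan)
    return out


def _ratio_from_cells(cells: np.ndarray, sel: np.ndarray, preferred: str | None) -> float:
    """Output-gating ratio from per-neuron cell means.

    The output axis is the (normalised) go-minus-no-go difference of
    the selected neurons; separations are its dot product with the
    per-context go/no-go differences.  ``preferred=None`` (population
    0) uses the context with the larger separation as the 'preferred'
    one, which is conservative for detecting gating.
    """
    c = cells[sel]
    axis = (c[:, 0] + c[:, 2]) / 2 - (c[:, 1] + c[:, 3]) / 2
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        return np.nan
    axis = axis / nrm
    sep_a = float(axis @ (c[:, 0] - c[:, 1]))
    sep_b = float(axis @ (c[:, 2] - c[:, 3]))
    if preferred == "A":
        num, den = sep_a, sep_b
    elif preferred == "B":
        num, den = sep_b, sep_a
    else:
        num, den = max(abs(sep_a), abs(sep_b)), min(abs(sep_a), abs(sep_b))
    if abs(den) < 1e-12:
        import warnings

        warnings.warn("go/no-go separation vanishes in the non-preferred context; "
                      "returning an infinite gating ratio")
        return np.inf
    return abs(num) / abs(den)


def _go_mask(ctx_a: np.ndarray, loc: np.ndarray, pitch: np.ndarray) -> np.ndarray:
    """Go-trial mask given (possibly per-neuron) context assignment."""
    return np.where(ctx_a, loc == -1.0, pitch == -1.0)


def gating_ratio(
    rec: RecordingSet, labels: PopulationLabels, population: str
) -> GatingResult:
    """Observed output-gating ratio of one population (no null)."""
    if population not in ("A", "B", "0"):
        raise ValueError(f"unknown population {population!r}")
    sel = labels.mask(population)
    if not sel.any():
        raise ValueError(f"population {population!r} is empty")
    ctx_a = np.broadcast_to(
        (rec.meta["context"].to_numpy() == "A"), (rec.n_neurons, rec.n_trials)
    )
    loc = rec.meta["loc"].to_numpy()
    pitch = rec.meta["pitch"].to_numpy()
    go = _go_mask(ctx_a, loc, pitch)
    cells = _cell_means(rec.rates(rec.stim_window), ctx_a, go)
    pref = population if population in ("A", "B") else None
    return GatingResult(
        ratio=_ratio_from_cells(cells, sel, pref), population=population
    )


def gating_permutation_test(
    rec: RecordingSet,
    population: str,
    n_perm: int = 400,
    seed: int | None = None,
    alpha: float = 0.05,
    labels: PopulationLabels | None = None,
) -> GatingResult:
    """Permutation test of the output-gating ratio.

    Each permutation shuffles trial context labels independently per
    neuron, recomputes the pre-stimulus modulation statistic, reselects
    a matched-size population by that permuted statistic (most
    A-preferring / most B-preferring / least modulated for population
    0) and recomputes the ratio under the permuted labels.
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = labels or label_populations(rec, alpha=alpha)
    obs = gating_ratio(rec, labels, population)
    n_sel = int(labels.mask(population).sum())
    rng = np.random.default_rng(seed)
    pre = rec.rates(rec.pre_window)
    stim = rec.rates(rec.stim_window)
    loc = rec.meta["loc"].to_numpy()
    pitch = rec.meta["pitch"].to_numpy()
    ctx_a_true = rec.meta["context"].to_numpy() == "A"
    n_neurons, n_trials = pre.shape
    null = np.empty(n_perm)
    n_resampled = 0
    pref = population if population in ("A", "B") else None
    i = 0
    while i < n_perm:
        # independent per-neuron permutation of the context assignment
        perm = np.argsort(rng.random((n_neurons, n_trials)), axis=1)
        ctx_a = ctx_a_true[perm]
        z, _ = _mannwhitney_z(pre, ctx_a)
        # matched-size selection by the permuted modulation statistic
        if population == "A":
            order = np.argsort(z)  # most negative z = lower firing in A
        elif population == "B":
            order = np.argsort(-z)
        else:
            order = np.argsort(np.abs(z))
        sel = np.zeros(n_neurons, dtype=bool)
        sel[order[:n_sel]] = True
        go = _go_mask(ctx_a, loc[None, :], pitch[None, :])
        cells = _cell_means(stim, ctx_a, go)
        r = _ratio_from_cells(cells, sel, pref)
        if not np.isfinite(r):
            n_resampled += 1
            if n_resampled > 10 * n_perm:
                raise RuntimeError("too many degenerate permutations")
            continue
        null[i] = r
        i += 1
    p = (1.0 + np.sum(null >= obs.ratio)) / (1.0 + n_perm)
    return GatingResult(
        ratio=obs.ratio, population=population, null=null, p_value=float(p),
        n_resampled=n_resampled,
    )


def selectivity_regression(rec: RecordingSet, alpha: float = 0.05) -> pd.DataFrame:
    """Per-neuron linear regression of stimulus-window counts on task variables.

    Design: location, pitch, decision (correct response) and context
    (+1 = A, -1 = B) plus intercept, fitted jointly across contexts
    (which leaves the design full rank even though decision is a
    deterministic function of the relevant feature within a context).
    Neurons with exactly one significant weight (two-sided t-test,
    no within-neuron multiplicity correction) are classed 'pure', more
    than one 'mixed', none 'none'.
    """
    y_all = rec.counts[:, :, rec.stim_window].sum(axis=2)
    X = np.column_stack(
        [
            rec.meta["loc"].to_numpy(),
            rec.meta["pitch"].to_numpy(),
            rec.meta["response"].to_numpy(),
            np.where(rec.meta["context"].to_numpy() == "A", 1.0, -1.0),
        ]
    )
    Xd = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        raise np.linalg.LinAlgError(
            f"collinear design (rank {rank} < {Xd.shape[1]}); "
            "fit jointly across contexts or drop a column"
        )
    names = ["location", "pitch", "decision", "context"]
    rows = []
    for i in range(rec.n_neurons):
        fit = sm.OLS(y_all[i].astype(float), Xd).fit()
        pv = fit.pvalues[1:]
        n_sig = int((pv < alpha).sum())
        cls = "none" if n_sig == 0 else ("pure" if n_sig == 1 else "mixed")
        row = {"class": cls}
        for j, nm in enumerate(names):
            row[f"w_{nm}"] = fit.params[1 + j]
            row[f"p_{nm}"] = pv[j]
        rows.append(row)
    return pd.DataFrame(rows)


def drift_control(rec: RecordingSet, alpha: float = 0.05) -> pd.DataFrame:
    """Distinguish block-identity (context) effects from slow drift.

    Per neuron, regresses the stimulus-window counts on block number
    (monotone within-session drift) and block identity; a neuron whose
    apparent context effect is explained by drift has a significant
    block-number term without a significant identity term.
    """
    if "block" not in rec.meta:
        raise ValueError("recording has no block metadata")
    blocks = rec.meta["block"].to_numpy().astype(float)
    if np.unique(blocks).size < 2:
        return pd.DataFrame(
            {"drift_flag": np.zeros(rec.n_neurons, bool),
             "testable": np.zeros(rec.n_neurons, bool)}
        )
    y_all = rec.counts[:, :, rec.stim_window].sum(axis=2)
    ident = np.where(rec.meta["block_identity"].to_numpy() == "A", 1.0, -1.0)
    Xd = sm.add_constant(np.column_stack([blocks, ident]))
    rows = []
    for i in range(rec.n_neurons):
        y = y_all[i].astype(float)
        if np.ptp(y) == 0:
            rows.append({"p_block": 1.0, "p_identity": 1.0,
                         "drift_flag": False, "testable": False})
            continue
        fit = sm.OLS(y, Xd).fit()
        p_block, p_ident = fit.pvalues[1], fit.pvalues[2]
        rows.append(
            {"p_block": p_block, "p_identity": p_ident,
             "drift_flag": bool(p_block < alpha and p_ident >= alpha),
             "testable": True}
        )
    return pd.DataFrame(rows)
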