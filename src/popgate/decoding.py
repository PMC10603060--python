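"""Pseudo-population decoding and coding-axis estimation.

Decoders are linear (L2-regularised logistic regression) and run on
pseudo-populations: for every fold, each neuron's trials of each
condition are independently resampled with replacement into a fixed
number of pseudo-trials, which are split in halves for training and
testing.  Across-context decoding trains in one context and tests in
the other (both on half the pseudo-trials, keeping comparisons fair),
probing whether a stimulus feature is encoded in the same format when
it is relevant and when it is irrelevant.

The irrelevant-context decoder defines the sensory axis; the component
of the relevant-context decoder orthogonal to it (QR decomposition)
defines the selection axis.  Projections of condition-averaged
activity onto this orthogonalised pair visualise the selection code:
movement along the sensory axis in both contexts, along the selection
axis only when the feature is relevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .recordings import RecordingSet

__all__ = [
    "PseudoPopulationFold",
    "DecodingResult",
    "AxisSet",
    "build_folds",
    "decode",
    "estimate_axes",
    "project_activity",
    "output_axis",
]

_VARIABLES = ("location", "pitch", "context", "output")


def _binary_labels(meta: pd.DataFrame, variable: str) -> np.ndarray:
    if variable == "location":
        return (meta["loc"].to_numpy() > 0).astype(int)
    if variable == "pitch":
        return (meta["pitch"].to_numpy() > 0).astype(int)
    if variable == "context":
        return (meta["context"].to_numpy() == "A").astype(int)
    if variable == "output":
        return (meta["response"].to_numpy() != 0).astype(int)
    raise ValueError(f"unknown variable {variable!r}; expected one of {_VARIABLES}")


@dataclass
class PseudoPopulationFold:
    """One resampled pseudo-simultaneous population.

    counts: (n_neurons, n_pseudo_trials, n_bins); meta: one row per
    pseudo-trial; train: boolean mask of the training half.
    """

    counts: np.ndarray
    meta: pd.DataFrame
    train: np.ndarray


def build_folds(
    rec: RecordingSet, n_folds: int, seed: int | None = None, n_pseudo: int = 50
):
    """Yield independently resampled pseudo-population folds.

    Per fold, each neuron's source trials of every condition are first
    split into disjoint halves (independently per neuron and fold);
    ``n_pseudo`` pseudo-trials per condition are then drawn with
    replacement, half from the training sources and half from the
    held-out sources, so no source trial is shared between the training
    and testing pseudo-trials.  Raises if a condition has fewer than 2
    trials.
    """
    if n_pseudo % 2:
        raise ValueError("n_pseudo must be even (split in halves)")
    rng = np.random.default_rng(seed)
    conds = rec.meta.groupby(["context", "loc", "pitch"], sort=True).indices
    short = [k for k, idx in conds.items() if len(idx) < 2]
    if short:
        raise ValueError(f"conditions with fewer than 2 trials: {short}")
    cond_items = sorted(conds.items(), key=lambda kv: str(kv[0]))
    from .task import correct_response

    meta_rows = []
    train = np.zeros(len(cond_items) * n_pseudo, dtype=bool)
    half = n_pseudo // 2
    for c, (key, _) in enumerate(cond_items):
        train[c * n_pseudo : c * n_pseudo + half] = True
        ctx, loc, pitch = key
        meta_rows += [
            {"context": ctx, "loc": loc, "pitch": pitch,
             "response": correct_response(loc, pitch, ctx)}
        ] * n_pseudo
    meta = pd.DataFrame(meta_rows)
    n_neurons = rec.n_neurons
    rows = np.arange(n_neurons)[:, None]
    for _ in range(n_folds):
        counts = np.empty((n_neurons, len(meta), rec.counts.shape[2]), rec.counts.dtype)
        for c, (key, idx) in enumerate(cond_items):
            idx = np.asarray(idx)
            h_src = idx.size // 2
            # independent per-neuron permutation of source trials
            perm = np.argsort(rng.random((n_neurons, idx.size)), axis=1)
            src = idx[perm]
            tr_draw = src[rows, rng.integers(0, h_src, size=(n_neurons, half))]
            te_draw = src[rows, h_src + rng.integers(0, idx.size - h_src, size=(n_neurons, half))]
            block = slice(c * n_pseudo, (c + 1) * n_pseudo)
            counts[:, block, :] = rec.counts[
                rows, np.concatenate([tr_draw, te_draw], axis=1), :
            ]
        yield PseudoPopulationFold(counts=counts, meta=meta, train=train.copy())


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracy with fold variability.

    accuracy: (n_folds,) or (n_folds, n_bins); mean / ci_low / ci_high
    are bootstrap statistics over folds; weights is the mean decoder
    weight vector (window-averaged features).
    """

    accuracy: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    weights: np.ndarray
    variable: str
    train_ctx: str | None
    test_ctx: str | None


def _bootstrap_ci(acc: np.ndarray, n_boot: int, rng) -> tuple:
    draws = acc[rng.integers(0, acc.shape[0], size=(n_boot, acc.shape[0]))]
    bm = draws.mean(axis=1)
    return np.percentile(bm, 2.5, axis=0), np.percentile(bm, 97.5, axis=0)


def decode(
    rec: RecordingSet,
    variable: str,
    train_ctx: str | None = None,
    test_ctx: str | None = None,
    n_folds: int = 500,
    seed: int | None = None,
    window: slice | None = None,
    per_bin: bool = False,
    C: float = 1.0,
    n_pseudo: int = 50,
    n_boot: int = 1000,
) -> DecodingResult:
    """Linear decoding of a task variable from pseudo-populations.

    ``train_ctx``/``test_ctx`` restrict training/testing trials to one
    context ('A' or 'B'); None uses all trials (required for
    ``variable='context'``).  Training always uses the training half of
    the pseudo-trials and testing the held-out half, also when contexts
    differ (both halves, so within- and across-context accuracies are
    computed from equally many trials).  Features are counts averaged
    over ``window`` (default: the stimulus window); ``per_bin=True``
    instead fits one decoder per time bin and returns an accuracy time
    course (weights are then averaged over the stimulus window).
    """
    if variable == "context" and (train_ctx or test_ctx):
        raise ValueError("context decoding cannot be restricted by context")
    window = rec.stim_window if window is None else window
    rng = np.random.default_rng(seed)
    accs, weights = [], []
    stim_bins = range(rec.stim_window.start, rec.stim_window.stop)
    for fold in build_folds(rec, n_folds, seed=int(rng.integers(2**31)), n_pseudo=n_pseudo):
        y = _binary_labels(fold.meta, variable)
        ctx = fold.meta["context"].to_numpy()
        tr = fold.train & ((ctx == train_ctx) if train_ctx else True)
        te = ~fold.train & ((ctx == test_ctx) if test_ctx else True)
        for name, mask in (("training", tr), ("testing", te)):
            if np.unique(y[mask]).size < 2:
                raise ValueError(
                    f"single-class {name} labels for variable={variable!r}, "
                    f"train_ctx={train_ctx!r}, test_ctx={test_ctx!r}"
                )
        if per_bin:
            acc_t = np.empty(rec.counts.shape[2])
            w_stim = []
            for b in range(rec.counts.shape[2]):
                X = fold.counts[:, :, b].T.astype(float)
                clf = LogisticRegression(C=C, max_iter=1000)
                clf.fit(X[tr], y[tr])
                acc_t[b] = clf.score(X[te], y[te])
                if b in stim_bins:
                    w_stim.append(clf.coef_[0])
            accs.append(acc_t)
            weights.append(np.mean(w_stim, axis=0))
        else:
            X = fold.counts[:, :, window].mean(axis=2).T.astype(float)
            clf = LogisticRegression(C=C, max_iter=1000)
            clf.fit(X[tr], y[tr])
            accs.append(clf.score(X[te], y[te]))
            weights.append(clf.coef_[0])
    acc = np.asarray(accs)
    lo, hi = _bootstrap_ci(acc, n_boot, rng)
    return DecodingResult(
        accuracy=acc,
        mean=acc.mean(axis=0),
        ci_low=lo,
        ci_high=hi,
        weights=np.mean(weights, axis=0),
        variable=variable,
        train_ctx=train_ctx,
        test_ctx=test_ctx,
    )


@dataclass
class AxisSet:
    """Orthogonalised sensory/selection axis pair.

    sensory: unit vector along the irrelevant-context decoder;
    selection: unit residual of the relevant-context decoder after QR
    orthogonalisation (None when degenerate); angle_deg: angle between
    the two decoders before orthogonalisation; null_angles: angles
    after shuffling the relevant weights across neurons.
    """

    sensory: np.ndarray
    selection: np.ndarray | None
    angle_deg: float
    null_angles: np.ndarray
    degenerate: bool
    provenance: dict

    def __post_init__(self):
        if not self.degenerate:
            assert abs(float(self.sensory @ self.selection)) < 1e-10


def estimate_axes(
    weights_irrelevant: np.ndarray,
    weights_relevant: np.ndarray,
    n_shuffle: int = 1000,
    seed: int | None = None,
    provenance: dict | None = None,
) -> AxisSet:
    """Sensory and selection axes from the two context decoders."""
    w_irr = np.asarray(weights_irrelevant, dtype=float)
    w_rel = np.asarray(weights_relevant, dtype=float)
    if w_irr.shape != w_rel.shape:
        raise ValueError("weight vectors must have equal length")
    ni, nr = np.linalg.norm(w_irr), np.linalg.norm(w_rel)
    if ni == 0 or nr == 0:
        raise ValueError("zero-norm decoder weights")
    cosang = float(np.clip(w_irr @ w_rel / (ni * nr), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    Q, R = np.linalg.qr(np.column_stack([w_irr, w_rel]))
    sensory = Q[:, 0] * np.sign(R[0, 0])
    degenerate = abs(R[1, 1]) < 1e-8 * nr
    selection = None if degenerate else Q[:, 1] * np.sign(R[1, 1])
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffle)
    for s in range(n_shuffle):
        perm = rng.permutation(w_rel.size)
        c = float(np.clip(w_irr @ w_rel[perm] / (ni * nr), -1.0, 1.0))
        null[s] = np.degrees(np.arccos(c))
    return AxisSet(
        sensory=sensory,
        selection=selection,
        angle_deg=angle,
        null_angles=null,
        degenerate=degenerate,
        provenance=provenance or {},
    )


def project_activity(
    rec: RecordingSet, axes: AxisSet, variable: str = "location"
) -> dict:
    """Condition-averaged trajectories in the (sensory, selection) plane.

    Returns {(context, level): (n_bins, 2)} — the mean activity of
    trials with that feature level in that context, grand-mean
    centred per bin, projected on the orthogonalised axes.
    """
    if axes.degenerate:
        raise ValueError("cannot project onto a degenerate axis set")
    feat = {"location": "loc", "pitch": "pitch"}[variable]
    counts = rec.counts.astype(float)
    grand = counts.mean(axis=1)  # (neurons, bins)
    out = {}
    for ctx in ("A", "B"):
        for level in (-1.0, 1.0):
            m = ((rec.meta["context"] == ctx) & (rec.meta[feat] == level)).to_numpy()
            avg = counts[:, m, :].mean(axis=1) - grand  # (neurons, bins)
            out[(ctx, level)] = np.column_stack(
                [avg.T @ axes.sensory, avg.T @ axes.selection]
            )
    return out


def output_axis(
    rec: RecordingSet, mask: np.ndarray | None = None, window: slice | None = None
) -> np.ndarray:
    """Go/no-go difference-of-means axis over the stimulus window.

    Restricted to the neurons in ``mask``; returned as a unit vector of
    length mask.sum().
    """
    window = rec.stim_window if window is None else window
    mask = np.ones(rec.n_neurons, dtype=bool) if mask is None else np.asarray(mask)
    if mask.dtype != bool:
        m = np.zeros(rec.n_neurons, dtype=bool)
        m[mask] = True
        mask = m
    if not mask.any():
        raise ValueError("empty neuron mask")
    go = (rec.meta["response"].to_numpy() != 0)
    if go.all() or not go.any():
        raise ValueError("both go and no-go trials are required")
    X = rec.counts[mask][:, :, window].mean(axis=2)
    diff = X[:, go].mean(axis=1) - X[:, ~go].mean(axis=1)
    nrm = np.linalg.norm(diff)
    return diff / nrm if nrm > 0 else diff
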