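"""Synthetic spike-count recordings with planted population structure.

Generates single-unit spike counts (50 ms bins) for a context-dependent
auditory go/no-go task with two stimulus features (location, pitch) and
two contexts, emulating the statistical structure the population
analyses assume:

* three latent neuron populations — a location population and a pitch
  population whose pre-stimulus firing is reduced in their preferred
  context, and an unmodulated population 0;
* mixed stimulus selectivity: every neuron carries signed tuning to
  both features along a context-independent sensory direction;
* a selection code: an extra response to the go level of the relevant
  feature, expressed only by the population preferring the ongoing
  context — go stimuli are thereby enhanced along a direction
  (the selection axis) separate from the sensory one.

Emission is Poisson per bin around the rectified condition rate
(negative-binomial optional for over-dispersion checks).  The epoch
layout is 1 s pre-stimulus + 250 ms stimulus.  Trials are organised in
alternating context blocks so that slow-drift controls can be run; an
optional per-neuron linear drift term plants a pure block-number
effect.

The generator also converts simulated network rates into spike counts
so that the same analyses run on model activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .task import TrialBatch, correct_response

__all__ = [
    "EffectSizes",
    "NeuronSpec",
    "RecordingSet",
    "sample_neurons",
    "generate_recording",
    "recording_from_rnn",
]

BIN_S = 0.05
N_PRE_BINS = 20  # 1 s pre-stimulus
N_STIM_BINS = 5  # 250 ms stimulus

GO_LEVEL = -1.0


@dataclass
class EffectSizes:
    """Default effect sizes of the generator (rates in Hz).

    Chosen to sit in the regime the analyses assume: pre-stimulus
    context modulation detectable from ~200 trials/context of 1 s
    counts; sensory tuning giving strong but imperfect population
    decoding; gating responses clearly stronger than sensory ones so
    that relevant-context decoders lean on the selection axis.
    """

    baseline_mean_hz: float = 8.0
    baseline_shape: float = 4.0  # gamma shape of the baseline-rate distribution
    ctx_mod_mean: float = 0.35  # fractional pre-stimulus reduction, preferred context
    ctx_mod_sd: float = 0.10
    sensory_sd_hz: float = 1.2  # SD of signed per-feature tuning
    gate_sd_hz: float = 8.0  # SD of signed go-stimulus gating response


@dataclass
class NeuronSpec:
    """Rate model of one synthetic neuron."""

    baseline_hz: float
    ctx_mod: float  # signed fractional change of pre-stimulus rate in preferred ctx
    w_loc: float  # Hz per unit location level
    w_pitch: float  # Hz per unit pitch level
    gate_hz: float  # extra go-stimulus response, preferred context only
    pop: str  # 'A' (location), 'B' (pitch) or '0'
    drift_hz_per_block: float = 0.0

    def __post_init__(self):
        if self.baseline_hz < 0:
            raise ValueError("baseline_hz must be >= 0")
        if self.pop not in ("A", "B", "0"):
            raise ValueError(f"invalid population label {self.pop!r}")
        if self.pop == "0" and self.ctx_mod != 0.0:
            raise ValueError("population 0 must have zero context modulation")

    @property
    def preferred_context(self) -> str | None:
        return self.pop if self.pop in ("A", "B") else None


@dataclass
class RecordingSet:
    """Spike counts (neuron x trial x time bin) with trial metadata.

    Metadata columns: context ('A' = location block, 'B' = pitch
    block), loc and pitch levels (+-1, -1 is the go level), response
    (correct response in {-1, 0, +1}), block and block_identity.
    """

    counts: np.ndarray
    meta: pd.DataFrame
    bin_s: float = BIN_S
    n_pre_bins: int = N_PRE_BINS
    n_stim_bins: int = N_STIM_BINS
    specs: list | None = None

    def __post_init__(self):
        if self.counts.shape[1] != len(self.meta):
            raise ValueError("counts and metadata disagree on trial count")

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    @property
    def pre_window(self) -> slice:
        return slice(0, self.n_pre_bins)

    @property
    def stim_window(self) -> slice:
        return slice(self.n_pre_bins, self.n_pre_bins + self.n_stim_bins)

    def rates(self, window: slice) -> np.ndarray:
        """Mean firing rate (Hz) per neuron and trial over a bin window."""
        return self.counts[:, :, window].mean(axis=2) / self.bin_s

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts, compression="gzip")
            f.attrs["bin_s"] = self.bin_s
            f.attrs["n_pre_bins"] = self.n_pre_bins
            f.attrs["n_stim_bins"] = self.n_stim_bins
            g = f.create_group("meta")
            for c in self.meta.columns:
                v = self.meta[c].to_numpy()
                if v.dtype.kind in ("U", "O"):
                    v = np.char.encode(v.astype(str))
                g.create_dataset(c, data=v)

    @classmethod
    def load(cls, path) -> "RecordingSet":
        with h5py.File(path, "r") as f:
            cols = {}
            for c in f["meta"]:
                v = f["meta"][c][()]
                if v.dtype.kind == "S":
                    v = np.char.decode(v)
                cols[c] = v
            return cls(
                counts=f["counts"][()],
                meta=pd.DataFrame(cols),
                bin_s=float(f.attrs["bin_s"]),
                n_pre_bins=int(f.attrs["n_pre_bins"]),
                n_stim_bins=int(f.attrs["n_stim_bins"]),
            )


def sample_neurons(
    n: int = 130,
    fractions: tuple = (1 / 3, 1 / 3, 1 / 3),
    effects: EffectSizes | None = None,
    seed: int | None = None,
    preset: str = "a1",
) -> list[NeuronSpec]:
    """Draw neuron specifications.

    Population labels are allocated deterministically (largest
    remainder) in the order (A, B, 0); tuning coefficients are i.i.d.
    The 'pfc' preset zeroes the sensory coefficients while keeping the
    gating (selection) responses, so only the relevant stimulus is
    represented.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    eff = effects or EffectSizes()
    for name in ("baseline_mean_hz", "ctx_mod_sd", "sensory_sd_hz", "gate_sd_hz"):
        if getattr(eff, name) < 0:
            raise ValueError(f"effect size {name} must be >= 0")
    if preset not in ("a1", "pfc"):
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(seed)
    raw = np.asarray(fractions) * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    counts[order[: n - counts.sum()]] += 1
    labels = sum(([lab] * c for lab, c in zip(("A", "B", "0"), counts)), [])

    specs = []
    scale = eff.baseline_mean_hz / eff.baseline_shape if eff.baseline_shape > 0 else 0.0
    for lab in labels:
        base = rng.gamma(eff.baseline_shape, scale) if scale > 0 else 0.0
        mod = (
            -abs(rng.normal(eff.ctx_mod_mean, eff.ctx_mod_sd)) if lab in ("A", "B") else 0.0
        )
        mod = max(mod, -1.0)
        sens = 0.0 if preset == "pfc" else eff.sensory_sd_hz
        specs.append(
            NeuronSpec(
                baseline_hz=base,
                ctx_mod=mod,
                w_loc=rng.normal(0.0, sens),
                w_pitch=rng.normal(0.0, sens),
                gate_hz=rng.normal(0.0, eff.gate_sd_hz) if lab in ("A", "B") else 0.0,
                pop=lab,
            )
        )
    return specs


def _trial_table(n_per_condition: int, n_blocks: int) -> pd.DataFrame:
    """Balanced trial metadata arranged in alternating context blocks."""
    rows = []
    for ctx in ("A", "B"):
        for loc in (-1.0, 1.0):
            for pitch in (-1.0, 1.0):
                resp = correct_response(loc, pitch, ctx)
                rows += [(ctx, loc, pitch, resp)] * n_per_condition
    df = pd.DataFrame(rows, columns=["context", "loc", "pitch", "response"])
    # alternate blocks A, B, A, B ... assigning each context's trials
    # round-robin to its blocks
    blocks_per_ctx = max(n_blocks // 2, 1)
    block = np.zeros(len(df), dtype=int)
    for ctx, offset in (("A", 0), ("B", 1)):
        idx = np.nonzero((df["context"] == ctx).to_numpy())[0]
        block[idx] = offset + 2 * (np.arange(idx.size) % blocks_per_ctx)
    df["block"] = block
    df["block_identity"] = df["context"]
    return df


def condition_rate(
    spec: NeuronSpec, ctx: str, loc: float, pitch: float, epoch: str, block: int = 0
) -> float:
    """Mean firing rate (Hz) of a neuron in one condition and epoch."""
    r = spec.baseline_hz * (1.0 + (spec.ctx_mod if ctx == spec.pop else 0.0))
    r += spec.drift_hz_per_block * block
    if epoch == "stim":
        r += spec.w_loc * loc + spec.w_pitch * pitch
        relevant = loc if ctx == "A" else pitch
        if ctx == spec.pop and relevant == GO_LEVEL:
            r += spec.gate_hz
    return max(r, 0.0)


def generate_recording(
    specs: list[NeuronSpec],
    n_trials_per_condition: int = 50,
    seed: int | None = None,
    n_blocks: int = 8,
    dispersion: float | None = None,
    n_post_bins: int = 0,
) -> RecordingSet:
    """Generate Poisson spike counts for all neurons and conditions.

    ``dispersion``: if set, negative-binomial emission with that shape
    parameter (variance = mu + mu^2/dispersion) instead of Poisson.
    """
    if n_trials_per_condition < 1:
        raise ValueError("n_trials_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    meta = _trial_table(n_trials_per_condition, n_blocks)
    n_bins = N_PRE_BINS + N_STIM_BINS + n_post_bins
    counts = np.zeros((len(specs), len(meta), n_bins), dtype=np.int64)
    ctx = meta["context"].to_numpy()
    loc = meta["loc"].to_numpy()
    pitch = meta["pitch"].to_numpy()
    block = meta["block"].to_numpy()
    for i, spec in enumerate(specs):
        mu = np.empty((len(meta), n_bins))
        for tr in range(len(meta)):
            r_pre = condition_rate(spec, ctx[tr], loc[tr], pitch[tr], "pre", block[tr])
            r_stim = condition_rate(spec, ctx[tr], loc[tr], pitch[tr], "stim", block[tr])
            mu[tr, :N_PRE_BINS] = r_pre * BIN_S
            mu[tr, N_PRE_BINS : N_PRE_BINS + N_STIM_BINS] = r_stim * BIN_S
            if n_post_bins:
                mu[tr, N_PRE_BINS + N_STIM_BINS :] = r_pre * BIN_S
        if dispersion is None:
            counts[i] = rng.poisson(mu)
        else:
            lam = rng.gamma(dispersion, mu / dispersion)
            counts[i] = rng.poisson(lam)
    return RecordingSet(counts=counts, meta=meta, specs=list(specs))


def recording_from_rnn(
    rates: np.ndarray,
    batch: TrialBatch,
    n_prestim: int,
    rate_scale: float = 40.0,
    bin_s: float = 0.02,
    seed: int | None = None,
) -> RecordingSet:
    """Poisson counts from simulated unit rates.

    ``rates``: (trials, steps, N) tanh rates in [-1, 1]; each model
    timestep becomes one count bin of width ``bin_s``.  The mean count
    is ``rate_scale`` * (rate + 1)/2 * bin_s (rectified shift of the
    signed rate onto a firing-rate scale).  Metadata is taken from the
    task batch (stimulus A -> location, stimulus B -> pitch).
    """
    rng = np.random.default_rng(seed)
    lam = rate_scale * (np.transpose(rates, (2, 0, 1)) + 1.0) / 2.0 * bin_s
    counts = rng.poisson(np.clip(lam, 0.0, None))
    resp = np.array(
        [
            correct_response(a, b, c)
            for a, b, c in zip(batch.stimA_level, batch.stimB_level, batch.context)
        ]
    )
    meta = pd.DataFrame(
        {
            "context": batch.context,
            "loc": batch.stimA_level,
            "pitch": batch.stimB_level,
            "response": resp,
            "block": np.zeros(batch.n_trials, dtype=int),
            "block_identity": batch.context,
        }
    )
    return RecordingSet(
        counts=counts,
        meta=meta,
        bin_s=bin_s,
        n_pre_bins=n_prestim,
        n_stim_bins=rates.shape[1] - n_prestim,
    )
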