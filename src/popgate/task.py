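"""Abstract context-dependent go/no-go task.

Each trial presents two stimulus features, A and B, at one of two levels
(-1 or +1), together with a contextual cue signalling which feature is
currently relevant.  The correct response depends only on the relevant
feature: the "go" level (-1) of feature A demands response -1 (go-left)
in context A, the go level of feature B demands +1 (go-right) in context
B, and every other combination is a no-go (response 0).  The irrelevant
feature never affects the correct response.

Inputs are four channels: the two stimulus features and the two context
cues.  Context cues are on for the whole trial; stimuli appear only
during the stimulus window, corrupted by i.i.d. Gaussian noise at every
timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "TaskParams",
    "TrialBatch",
    "correct_response",
    "generate_trials",
    "CHANNELS",
]

#: Input-channel order used throughout the package.
CHANNELS = ("stimA", "stimB", "ctxA", "ctxB")

GO_LEVEL = -1.0  # stimulus level that demands a go response for the relevant feature


@dataclass
class TaskParams:
    """Parameters of the abstract go/no-go task.

    Attributes
    ----------
    n_prestim : int
        Timesteps before stimulus onset (context cues already on).
    n_stim : int
        Timesteps of stimulus presentation.
    stim_noise_sd : float
        SD of per-timestep Gaussian noise added to the stimulus channels
        during the stimulus window only.
    stim_levels : tuple
        The two admissible stimulus levels.
    ctx_levels : tuple
        (inactive, active) values carried by the context channels.
    go_sign : dict
        Response sign of the go action in each context.  Context A's go
        action maps to -1 (go-left) and context B's to +1 (go-right),
        mirroring location -> go-left, pitch -> go-right in the rodent
        task this abstracts; configurable.
    """

    n_prestim: int = 4
    n_stim: int = 10
    stim_noise_sd: float = 1.0
    stim_levels: tuple = (-1.0, 1.0)
    ctx_levels: tuple = (0.0, 1.0)
    go_sign: dict = field(default_factory=lambda: {"A": -1.0, "B": 1.0})
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_prestim < 1 or self.n_stim < 1:
            raise ValueError("n_prestim and n_stim must be >= 1")
        if self.stim_noise_sd < 0:
            raise ValueError("stim_noise_sd must be >= 0")

    @property
    def n_steps(self) -> int:
        return self.n_prestim + self.n_stim

    @property
    def stim_window(self) -> slice:
        """Timestep slice during which the stimulus is on."""
        return slice(self.n_prestim, self.n_prestim + self.n_stim)


@dataclass
class TrialBatch:
    """A batch of task trials.

    ``inputs`` has shape (n_trials, n_steps, 4) with channels ordered as
    :data:`CHANNELS`.  ``target`` is the correct response in {-1, 0, +1};
    ``context`` holds 'A'/'B' labels.
    """

    inputs: np.ndarray
    target: np.ndarray
    context: np.ndarray
    stimA_level: np.ndarray
    stimB_level: np.ndarray
    params: TaskParams | None = None

    @property
    def n_trials(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[1]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("inputs", data=self.inputs)
            f.create_dataset("target", data=self.target)
            f.create_dataset("context", data=np.char.encode(self.context.astype(str)))
            f.create_dataset("stimA_level", data=self.stimA_level)
            f.create_dataset("stimB_level", data=self.stimB_level)

    @classmethod
    def load(cls, path) -> "TrialBatch":
        with h5py.File(path, "r") as f:
            return cls(
                inputs=f["inputs"][()],
                target=f["target"][()],
                context=np.char.decode(f["context"][()]).astype("U1"),
                stimA_level=f["stimA_level"][()],
                stimB_level=f["stimB_level"][()],
            )


def correct_response(
    stimA_level: float, stimB_level: float, context: str, go_sign: dict | None = None
) -> float:
    """Correct response for one trial: go iff the relevant feature is at its go level.

    Context A: response go_sign['A'] iff stimA is at the go level (-1), else 0.
    Context B: response go_sign['B'] iff stimB is at the go level (-1), else 0.
    The irrelevant feature never matters.
    """
    if go_sign is None:
        go_sign = {"A": -1.0, "B": 1.0}
    for lvl in (stimA_level, stimB_level):
        if lvl not in (-1.0, 1.0, -1, 1):
            raise ValueError(f"invalid stimulus level {lvl!r}; must be -1 or +1")
    if context not in ("A", "B"):
        raise ValueError(f"invalid context {context!r}; must be 'A' or 'B'")
    relevant = stimA_level if context == "A" else stimB_level
    return float(go_sign[context]) if relevant == GO_LEVEL else 0.0


def _condition_grid():
    """All 8 (stimA, stimB, context) conditions in fixed order."""
    return [
        (a, b, c)
        for c in ("A", "B")
        for a in (-1.0, 1.0)
        for b in (-1.0, 1.0)
    ]


def generate_trials(
    params: TaskParams,
    n_trials: int,
    balanced: bool = True,
    seed: int | None = None,
) -> TrialBatch:
    """Generate a batch of task trials.

    With ``balanced=True`` all 8 (stimA x stimB x context) conditions
    appear equally often, so ``n_trials`` must be divisible by 8.
    Otherwise conditions are drawn uniformly at random.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    conds = _condition_grid()
    if balanced:
        if n_trials % 8:
            raise ValueError(
                f"balanced=True requires n_trials divisible by 8, got {n_trials}; "
                "pass balanced=False or round the trial count"
            )
        idx = np.repeat(np.arange(8), n_trials // 8)
        rng.shuffle(idx)
    else:
        idx = rng.integers(0, 8, size=n_trials)

    T = params.n_steps
    lo, hi = params.ctx_levels
    inputs = np.zeros((n_trials, T, 4))
    stimA = np.array([conds[i][0] for i in idx])
    stimB = np.array([conds[i][1] for i in idx])
    context = np.array([conds[i][2] for i in idx])

    # context cues on for the whole trial
    inputs[:, :, 2] = np.where(context == "A", hi, lo)[:, None]
    inputs[:, :, 3] = np.where(context == "B", hi, lo)[:, None]
    # stimuli with per-timestep noise during the stimulus window only
    win = params.stim_window
    n_win = params.n_stim
    noise = rng.normal(0.0, params.stim_noise_sd, size=(n_trials, n_win, 2))
    inputs[:, win, 0] = stimA[:, None] + noise[:, :, 0]
    inputs[:, win, 1] = stimB[:, None] + noise[:, :, 1]

    target = np.array(
        [correct_response(a, b, c, params.go_sign) for a, b, c in zip(stimA, stimB, context)]
    )
    return TrialBatch(
        inputs=inputs,
        target=target,
        context=context,
        stimA_level=stimA,
        stimB_level=stimB,
        params=params,
    )
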