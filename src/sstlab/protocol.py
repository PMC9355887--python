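"""Stop-signal task protocol: session schedules and the SSD staircase.

The task is a choice-reaction-time task in which 75% of trials are go
trials (respond to a left/right arrow) and 25% are stop trials (an
additional stop-signal image appears after a variable stop-signal delay,
SSD, and the response must be withheld).  Two stop-stimulus conditions
(an emotional and a neutral image) appear in equal proportion, and each
condition owns an independent one-up/one-down staircase on its SSD: a
successful stop raises the SSD by one step, a failed stop lowers it,
clamped to a fixed range.  The staircase drives each condition towards
~50% successful inhibition, which is what makes the integration-method
SSRT estimate well defined.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ProtocolError

__all__ = [
    "SessionConfig",
    "StaircaseState",
    "TrialPlan",
    "build_session",
    "staircase_update",
    "schedule_to_frame",
]

#: Longest run of consecutive stop trials allowed by the schedule shuffle.
MAX_STOP_RUN = 4


@dataclass(frozen=True)
class SessionConfig:
    """Composition and timing of one stop-signal task session.

    Durations are in milliseconds.  The defaults reproduce the protocol
    this package models: 4 experimental blocks of 128 trials (96 go /
    32 stop, stop stimuli in equal proportion), SSD staircase starting
    at 150 ms moving in 50 ms steps within [50, 650] ms, preceded by a
    32-trial practice block.
    """

    n_blocks: int = 4
    trials_per_block: int = 128
    go_fraction: float = 0.75
    stop_stimuli: tuple[str, ...] = ("emotional", "neutral")
    ssd_initial: float = 150.0
    ssd_step: float = 50.0
    ssd_min: float = 50.0
    ssd_max: float = 650.0
    fixation_ms: float = 800.0
    stop_signal_ms: float = 70.0
    iti_ms: float = 1600.0
    practice_trials: int = 32
    rng_seed: int | None = None

    def __post_init__(self):
        if self.n_blocks < 0 or self.trials_per_block <= 0:
            raise ConfigError("n_blocks must be >= 0 and trials_per_block > 0")
        if not 0.0 < self.go_fraction < 1.0:
            raise ConfigError("go_fraction must lie strictly between 0 and 1")
        if len(self.stop_stimuli) < 1 or len(set(self.stop_stimuli)) != len(self.stop_stimuli):
            raise ConfigError("stop_stimuli must be distinct, non-empty labels")
        self._split_block(self.trials_per_block)
        if self.practice_trials:
            self._split_block(self.practice_trials)
        if not (self.ssd_min <= self.ssd_initial <= self.ssd_max):
            raise ConfigError("require ssd_min <= ssd_initial <= ssd_max")
        if self.ssd_step <= 0:
            raise ConfigError("ssd_step must be positive")

    def _split_block(self, n_trials: int) -> tuple[int, int, int]:
        """Return (go, stop, stop-per-condition) counts for a block of
        ``n_trials``, raising :class:`ConfigError` on non-integer splits."""
        go = n_trials * self.go_fraction
        if abs(go - round(go)) > 1e-9:
            raise ConfigError(
                f"{n_trials} trials x go_fraction {self.go_fraction} is not an integer"
            )
        go = round(go)
        stop = n_trials - go
        per_cond, rem = divmod(stop, len(self.stop_stimuli))
        if rem:
            raise ConfigError(
                f"{stop} stop trials do not divide evenly over {len(self.stop_stimuli)} conditions"
            )
        return go, stop, per_cond

    @property
    def go_per_block(self) -> int:
        return self._split_block(self.trials_per_block)[0]

    @property
    def stop_per_block(self) -> int:
        return self._split_block(self.trials_per_block)[1]

    @property
    def stop_per_condition_per_block(self) -> int:
        return self._split_block(self.trials_per_block)[2]


@dataclass(frozen=True)
class TrialPlan:
    """One scheduled trial.  ``block`` 0 is the practice block;
    experimental blocks are numbered from 1."""

    block: int
    trial: int
    trial_type: str  # "go" | "stop"
    condition: str  # stop-stimulus label, or "none" for go trials
    arrow: str  # "left" | "right"
    practice: bool = False


@dataclass(frozen=True)
class StaircaseState:
    """Independent per-condition SSD tracks.

    ``ssd`` maps each stop-stimulus condition to the SSD that the *next*
    stop trial of that condition will use.  ``history`` records, per
    condition, the (SSD used, inhibited) pairs of past stop trials.
    The state is immutable; :func:`staircase_update` returns a new one.
    """

    ssd: dict[str, float]
    history: dict[str, tuple[tuple[float, bool], ...]] = field(default_factory=dict)
    step: float = 50.0
    lo: float = 50.0
    hi: float = 650.0

    @classmethod
    def from_config(cls, config: SessionConfig) -> "StaircaseState":
        return cls(
            ssd={c: float(config.ssd_initial) for c in config.stop_stimuli},
            history={c: () for c in config.stop_stimuli},
            step=float(config.ssd_step),
            lo=float(config.ssd_min),
            hi=float(config.ssd_max),
        )


def staircase_update(state: StaircaseState, condition: str, inhibited: bool) -> StaircaseState:
    """Advance one condition's staircase after a stop trial.

    A successful inhibition raises that condition's SSD by one step and a
    failed stop lowers it, clamped to [lo, hi].  The other conditions'
    tracks are untouched.  The trial just played (at the pre-update SSD)
    is appended to the condition's history.
    """
    if condition not in state.ssd:
        raise ProtocolError(f"unknown stop condition {condition!r}")
    used = state.ssd[condition]
    delta = state.step if inhibited else -state.step
    new = min(state.hi, max(state.lo, used + delta))
    ssd = dict(state.ssd)
    ssd[condition] = new
    history = dict(state.history)
    history[condition] = history.get(condition, ()) + ((used, bool(inhibited)),)
    return dataclasses.replace(state, ssd=ssd, history=history)


def _shuffled_types(rng: np.random.Generator, n_go: int, n_stop: int) -> np.ndarray:
    """Shuffle go/stop labels, avoiding runs of more than MAX_STOP_RUN
    consecutive stop trials when the counts make that possible."""
    types = np.array(["go"] * n_go + ["stop"] * n_stop)
    # shortest achievable maximum stop run given the counts
    feasible = n_go + 1 >= int(np.ceil(n_stop / MAX_STOP_RUN))
    for _ in range(10_000):
        perm = rng.permutation(types)
        if not feasible:
            return perm
        run = longest = 0
        for t in perm:
            run = run + 1 if t == "stop" else 0
            longest = max(longest, run)
        if longest <= MAX_STOP_RUN:
            return perm
    return perm  # pragma: no cover - astronomically unlikely for valid configs


def _balanced(labels: list[str], n: int, rng: np.random.Generator) -> np.ndarray:
    """n items drawn from ``labels`` as evenly as possible, shuffled."""
    reps = np.array((labels * (n // len(labels) + 1))[:n])
    return rng.permutation(reps)


def build_session(config: SessionConfig, rng: np.random.Generator | None = None) -> list[TrialPlan]:
    """Build the full ordered trial schedule for one session.

    Returns the practice block (block 0, if configured) followed by the
    experimental blocks.  Within each block go/stop counts are exact,
    stop conditions appear in equal proportion, arrow directions are
    balanced 50/50 within each trial type (and within each stop
    condition), and the order is a seeded shuffle constrained to at most
    ``MAX_STOP_RUN`` consecutive stop trials.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    plans: list[TrialPlan] = []
    blocks: list[tuple[int, int, bool]] = []
    if config.practice_trials:
        blocks.append((0, config.practice_trials, True))
    blocks.extend((b, config.trials_per_block, False) for b in range(1, config.n_blocks + 1))
    for block, n_trials, practice in blocks:
        n_go, n_stop, per_cond = config._split_block(n_trials)
        types = _shuffled_types(rng, n_go, n_stop)
        conditions = _balanced(list(config.stop_stimuli), n_stop, rng)
        go_arrows = _balanced(["left", "right"], n_go, rng)
        # balance arrows within each stop condition
        stop_arrows = np.empty(n_stop, dtype=object)
        for cond in config.stop_stimuli:
            idx = np.flatnonzero(conditions == cond)
            stop_arrows[idx] = _balanced(["left", "right"], len(idx), rng)
        gi = si = 0
        for trial, ttype in enumerate(types):
            if ttype == "go":
                plans.append(
                    TrialPlan(block, trial, "go", "none", str(go_arrows[gi]), practice)
                )
                gi += 1
            else:
                plans.append(
                    TrialPlan(
                        block, trial, "stop", str(conditions[si]), str(stop_arrows[si]), practice
                    )
                )
                si += 1
    return plans


def schedule_to_frame(plans: list[TrialPlan]):
    """Schedule as a pandas DataFrame (block, trial, trial_type,
    condition, arrow, practice), e.g. for CSV export."""
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(p) for p in plans])
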