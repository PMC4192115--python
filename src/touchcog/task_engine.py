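"""Deterministic state machines for the staged touchscreen protocol.

The apparatus is an operant chamber with a two-window touch-sensitive
screen and a liquid-reward tray.  Animals pass through five shaping
steps (habituation, screen interaction, must-touch, trial initiation,
error signalling) before entering the pairwise visual discrimination
task (PD) and its reversal (PDR).  This module simulates those task
loops against an arbitrary agent: given per-trial choices and
latencies it produces complete session logs with a simulated clock, so
a session's duration is a deterministic function of its event log.

Within PD/PDR sessions the rewarded stimulus appears on a constrained
pseudo-random side schedule: 15 left / 15 right per 30-trial session,
never more than three consecutive trials on the same side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "Phase",
    "Side",
    "BLANK",
    "ScheduleSpec",
    "TaskConfig",
    "TrialRecord",
    "SessionLog",
    "TrialContext",
    "TrialResponse",
    "Agent",
    "UnsatisfiableScheduleError",
    "generate_side_sequence",
    "max_run_length",
    "run_session",
    "training_advance",
]


class Phase(str, Enum):
    """Protocol phases, in order of traversal."""

    STEP1 = "STEP1"  # habituation to the chamber
    STEP2 = "STEP2"  # initial training: touch or auto-reward after 30 s
    STEP3 = "STEP3"  # must touch the single image
    STEP4 = "STEP4"  # must initiate the trial at the reward tray
    STEP5 = "STEP5"  # incorrect responses signalled (tone + 15 s ITI)
    PD = "PD"        # pairwise discrimination
    PDR = "PDR"      # reversal of the PD contingency


class Side(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


#: Window content for an empty response window (step 3 onward).
BLANK = "BLANK"

_CHOICE_PHASES = (Phase.STEP5, Phase.PD, Phase.PDR)


class UnsatisfiableScheduleError(ValueError):
    """No side sequence can satisfy the requested constraints."""


@dataclass(frozen=True)
class ScheduleSpec:
    """Constraints on the pseudo-random side sequence of one session."""

    n_trials: int = 30
    n_left: int = 15
    n_right: int = 15
    max_run: int = 3

    def __post_init__(self) -> None:
        if self.n_left < 0 or self.n_right < 0:
            raise ValueError("side counts must be non-negative")
        if self.n_left + self.n_right != self.n_trials:
            raise ValueError("n_left + n_right must equal n_trials")
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")


@dataclass(frozen=True)
class TaskConfig:
    """Timing, reward and criterion parameters of one protocol phase.

    Durations are seconds unless noted; reward volumes are microlitres.
    The 2 kHz / 500 ms error tone is an event marker only — it is logged
    but produces no audio.
    """

    phase: Phase
    iti_correct: float = 10.0
    iti_incorrect: float = 15.0   # applied in STEP5/PD/PDR only
    stimulus_timeout: float = 30.0  # STEP2 only: auto-reward after this
    session_cap_trials: int = 30
    session_cap_minutes: float = 30.0
    step2_fast_minutes: float = 20.0  # STEP2 strategy-1 criterion bound
    accuracy_criterion: float = 0.80
    criterion_window: int = 2
    reward_touch_ul: float = 25.0   # 75 in STEP2
    reward_auto_ul: float = 25.0    # STEP2 auto-reward only
    tone_hz: float = 2000.0
    tone_ms: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 < self.accuracy_criterion <= 1.0:
            raise ValueError("accuracy_criterion must be in (0, 1]")
        if self.criterion_window < 1:
            raise ValueError("criterion_window must be >= 1")
        for name in ("iti_correct", "iti_incorrect", "stimulus_timeout",
                     "session_cap_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def for_phase(cls, phase: Phase) -> "TaskConfig":
        cfg = cls(phase=phase)
        if phase is Phase.STEP2:
            cfg = replace(cfg, reward_touch_ul=75.0)
        return cfg


@dataclass(slots=True)
class TrialRecord:
    """One touchscreen trial as written to the trial-log CSV."""

    subject_id: str
    phase: Phase
    session_index: int   # 1-based, within phase
    trial_index: int     # 1-based, within session
    rewarded_side: Side | None
    positive_stimulus: str
    chosen_stimulus: str | None  # None = STEP2 timeout (no touch)
    correct: bool
    initiated: bool
    response_latency: float
    reward_latency: float | None  # None iff not rewarded
    n_blank_touches: int = 0     # STEP3/4: logged, trial continues
    tone: bool = False           # error tone marker (STEP5/PD/PDR)
    iti_s: float = 10.0
    reward_ul: float = 0.0
    auto_rewarded: bool = False  # STEP2 timeout reward
    t_start: float = 0.0         # seconds since session start
    t_end: float = 0.0

    def __post_init__(self) -> None:
        if self.response_latency < 0:
            raise ValueError("response_latency must be >= 0")
        if self.reward_latency is not None and self.reward_latency < 0:
            raise ValueError("reward_latency must be >= 0")


@dataclass(slots=True)
class SessionLog:
    """Ordered trials of one daily session (one session per day)."""

    subject_id: str
    phase: Phase
    session_index: int
    trials: list[TrialRecord] = field(default_factory=list)
    duration_min: float = 0.0
    truncated_mid_trial: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_correct(self) -> int:
        return sum(t.correct for t in self.trials)

    @property
    def n_errors(self) -> int:
        return self.n_trials - self.n_correct

    @property
    def accuracy(self) -> float:
        if not self.trials:
            return float("nan")
        return self.n_correct / self.n_trials

    def is_complete(self, cap_trials: int = 30) -> bool:
        return self.n_trials >= cap_trials

    def replay_duration(self, config: TaskConfig) -> float:
        """Recompute the session duration (minutes) from the event log.

        The simulated clock is a pure function of the logged events, so
        replaying the log must reproduce ``duration_min``.
        """
        if self.phase is Phase.STEP1:
            return 20.0  # fixed habituation period; no trial events
        clock = 0.0
        for t in self.trials:
            clock = t.t_end
            if t.reward_latency is not None:
                clock += t.reward_latency
            clock += t.iti_s
        if self.truncated_mid_trial:
            return config.session_cap_minutes
        return min(clock, config.session_cap_minutes * 60.0) / 60.0


def max_run_length(sides: Sequence[Side]) -> int:
    """Length of the longest run of identical sides (0 for empty)."""
    best = run = 0
    prev: Side | None = None
    for s in sides:
        run = run + 1 if s == prev else 1
        prev = s
        best = max(best, run)
    return best


def _satisfiable(n_left: int, n_right: int, max_run: int) -> bool:
    # A sequence with counts a >= b exists iff a <= max_run * (b + 1):
    # the b minority items split the majority into b + 1 runs.
    a, b = max(n_left, n_right), min(n_left, n_right)
    return a <= max_run * (b + 1)


def generate_side_sequence(
    spec: ScheduleSpec, rng: np.random.Generator
) -> list[Side]:
    """Draw one valid rewarded-side sequence, uniformly over the valid set.

    Uniformity is achieved by rejection sampling: uniformly random
    permutations of the fixed left/right multiset are drawn until one
    satisfies the maximum-run constraint.  Every valid sequence is a
    permutation with equal probability, so acceptance preserves
    uniformity exactly.

    Raises
    ------
    UnsatisfiableScheduleError
        If no sequence with the requested counts can avoid a run longer
        than ``max_run`` (e.g. 30 left / 0 right with max_run 3).
    """
    if not _satisfiable(spec.n_left, spec.n_right, spec.max_run):
        raise UnsatisfiableScheduleError(
            f"no sequence with {spec.n_left} left / {spec.n_right} right "
            f"avoids runs longer than {spec.max_run}"
        )
    base = np.array(
        [0] * spec.n_left + [1] * spec.n_right, dtype=np.int8
    )
    while True:
        perm = rng.permutation(base)
        # vectorised run-length check
        if perm.size == 0:
            return []
        changes = np.flatnonzero(np.diff(perm) != 0)
        bounds = np.concatenate(([-1], changes, [perm.size - 1]))
        if np.diff(bounds).max() <= spec.max_run:
            return [Side.LEFT if v == 0 else Side.RIGHT for v in perm]


@dataclass(frozen=True)
class TrialContext:
    """What the animal sees on one trial."""

    phase: Phase
    trial_index: int
    left: str            # content of the left response window
    right: str           # content of the right response window
    positive_stimulus: str
    rewarded_side: Side | None


@dataclass(frozen=True)
class TrialResponse:
    """An agent's behaviour on one trial.

    ``chosen`` is the window content the final touch landed on, or
    ``None`` for no touch (STEP2 only; elsewhere a touch is required).
    ``n_blank_touches`` counts touches of the blank window before the
    image touch in STEP3/4, where blank touches do not end the trial.
    ``latency`` is the time from stimulus onset to the trial-ending
    touch (or to abstention in STEP2).
    """

    chosen: str | None
    latency: float
    n_blank_touches: int = 0


class Agent(Protocol):
    """Choice-and-latency callback driving :func:`run_session`."""

    def respond(
        self, ctx: TrialContext, rng: np.random.Generator
    ) -> TrialResponse: ...

    def reward_collect_latency(self, rng: np.random.Generator) -> float: ...

    def initiation_latency(self, rng: np.random.Generator) -> float: ...

    def observe(self, ctx: TrialContext, chosen: str | None,
                rewarded: bool) -> None:
        """Learning hook; scripted agents may ignore it."""


def _window_contents(
    phase: Phase, side: Side | None, stimulus: str, partner: str
) -> tuple[str, str]:
    """Left/right window contents for one trial.

    STEP2 shows the stimulus in both windows; STEP3–5 show it opposite
    a blank; PD/PDR show the positive stimulus opposite its partner,
    with the positive stimulus on the scheduled side.
    """
    if phase is Phase.STEP2:
        return stimulus, stimulus
    other = BLANK if phase in (Phase.STEP3, Phase.STEP4, Phase.STEP5) else partner
    if side is Side.LEFT:
        return stimulus, other
    return other, stimulus


def run_session(
    config: TaskConfig,
    schedule: Sequence[Side | None],
    agent: Agent,
    rng: np.random.Generator,
    *,
    subject_id: str = "SUBJ",
    session_index: int = 1,
    positive_stimulus: str = "image",
    negative_stimulus: str = "partner",
) -> SessionLog:
    """Run one simulated session and return its log.

    The session ends at ``session_cap_trials`` completed trials or at
    the ``session_cap_minutes`` clock cap, whichever comes first.  A
    trial still awaiting its response when the cap strikes is discarded
    (the log then carries ``truncated_mid_trial``), so incomplete
    sessions with fewer than 30 trials are representable.

    Per-phase trial loops:

    * STEP1 — habituation; no trials, 20 minutes of free exploration.
    * STEP2 — two identical images for up to 30 s; a touch earns 75 µl,
      otherwise the images vanish and 25 µl is auto-delivered.
    * STEP3 — one image vs. a blank window; blank touches are logged as
      incorrect responses but the trial only ends on an image touch.
    * STEP4 — as STEP3, plus the animal initiates each trial by a head
      entry into the empty reward tray.
    * STEP5 / PD / PDR — an incorrect touch immediately ends the trial,
      marked by the error tone, and lengthens the ITI to 15 s.
    """
    log = SessionLog(subject_id=subject_id, phase=config.phase,
                     session_index=session_index)
    if config.phase is Phase.STEP1:
        log.duration_min = 20.0
        return log

    cap_s = config.session_cap_minutes * 60.0
    needs_init = config.phase in (Phase.STEP4, Phase.STEP5, Phase.PD, Phase.PDR)
    clock = 0.0
    trial_i = 0
    while trial_i < config.session_cap_trials and clock < cap_s:
        if trial_i >= len(schedule):
            raise ValueError(
                f"schedule of length {len(schedule)} exhausted at trial "
                f"{trial_i + 1}"
            )
        side = schedule[trial_i]
        left, right = _window_contents(config.phase, side, positive_stimulus,
                                       negative_stimulus)
        ctx = TrialContext(
            phase=config.phase,
            trial_index=trial_i + 1,
            left=left,
            right=right,
            positive_stimulus=positive_stimulus,
            rewarded_side=side,
        )
        t_start = clock
        t_onset = t_start + (agent.initiation_latency(rng) if needs_init else 0.0)
        resp = agent.respond(ctx, rng)

        if config.phase is Phase.STEP2:
            timed_out = resp.chosen is None or resp.latency > config.stimulus_timeout
            latency = config.stimulus_timeout if timed_out else resp.latency
            chosen = None if timed_out else resp.chosen
            correct, rewarded, tone = not timed_out, True, False
            reward_ul = config.reward_auto_ul if timed_out else config.reward_touch_ul
            auto = timed_out
            blanks = 0
        else:
            chosen, latency, blanks = resp.chosen, resp.latency, resp.n_blank_touches
            valid = {ctx.left, ctx.right}
            if chosen not in valid:
                raise ValueError(
                    f"agent chose {chosen!r}; on-screen options are {valid}"
                )
            if config.phase in (Phase.STEP3, Phase.STEP4):
                if chosen == BLANK:
                    raise ValueError(
                        "STEP3/4 trials end only on an image touch; report "
                        "blank touches via n_blank_touches"
                    )
                correct = blanks == 0
                rewarded, tone, auto = True, False, False
                reward_ul = config.reward_touch_ul
            else:  # STEP5 / PD / PDR
                correct = chosen == positive_stimulus
                rewarded = correct
                tone = not correct
                auto = False
                reward_ul = config.reward_touch_ul if correct else 0.0

        t_touch = t_onset + latency
        if t_touch > cap_s:
            log.truncated_mid_trial = True
            log.duration_min = config.session_cap_minutes
            return log

        collect = agent.reward_collect_latency(rng) if rewarded else None
        iti = (config.iti_incorrect
               if (tone and config.phase in _CHOICE_PHASES)
               else config.iti_correct)
        log.trials.append(TrialRecord(
            subject_id=subject_id,
            phase=config.phase,
            session_index=session_index,
            trial_index=trial_i + 1,
            rewarded_side=side,
            positive_stimulus=positive_stimulus,
            chosen_stimulus=chosen,
            correct=correct,
            initiated=needs_init,
            response_latency=latency,
            reward_latency=collect,
            n_blank_touches=blanks,
            tone=tone,
            iti_s=iti,
            reward_ul=reward_ul,
            auto_rewarded=auto,
            t_start=t_start,
            t_end=t_touch,
        ))
        agent.observe(ctx, chosen, rewarded)
        clock = t_touch + (collect or 0.0) + iti
        trial_i += 1

    log.duration_min = min(clock, cap_s) / 60.0
    return log


def training_advance(phase: Phase, session_history: Sequence[SessionLog]) -> bool:
    """Decide, after each session, whether the animal leaves ``phase``.

    Advancement rules, evaluated on the most recent session(s):

    * STEP1 — one habituation session suffices.
    * STEP2 — either strategy 1 (30 trials completed within 20 minutes
      in a single session, i.e. active screen interaction) or strategy 2
      (30 trials within 30 minutes in 3 consecutive sessions, the
      passive auto-reward route).
    * STEP3 / STEP4 — 30 trials in under 30 minutes in one session.
    * STEP5 — two consecutive sessions, each 30 trials within 30
      minutes at >= 80 % correct.

    Returns True to advance, False to repeat the phase.
    """
    if not session_history:
        raise ValueError("session history is empty")
    if any(s.phase is not phase for s in session_history):
        raise ValueError("history must contain sessions of the current phase only")
    cap = 30

    def full(s: SessionLog, minutes: float, strict: bool = False) -> bool:
        ok_time = s.duration_min < minutes if strict else s.duration_min <= minutes
        return s.n_trials >= cap and ok_time

    last = session_history[-1]
    if phase is Phase.STEP1:
        return True
    if phase is Phase.STEP2:
        if full(last, 20.0):
            return True
        return (len(session_history) >= 3
                and all(full(s, 30.0) for s in session_history[-3:]))
    if phase in (Phase.STEP3, Phase.STEP4):
        return full(last, 30.0, strict=True)
    if phase is Phase.STEP5:
        if len(session_history) < 2:
            return False
        return all(full(s, 30.0) and s.accuracy >= 0.80
                   for s in session_history[-2:])
    raise ValueError(f"{phase} is not a training phase")
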