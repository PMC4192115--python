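import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from touchcog.task_engine import (
    BLANK,
    Phase,
    SessionLog,
    Side,
    TrialContext,
    TrialRecord,
    TrialResponse,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


class ScriptedAgent:
    """Deterministic agent for timeline and scoring tests.

    ``pick`` maps a TrialContext to the chosen window content; by
    default it always touches the positive stimulus.
    """

    def __init__(self, pick=None, response_latency=1.0, collect_latency=1.0,
                 initiation=0.0, blank_touches=0):
        self.pick = pick or (lambda ctx: ctx.positive_stimulus)
        self.response_latency = response_latency
        self.collect_latency = collect_latency
        self.initiation = initiation
        self.blank_touches = blank_touches
        self.trial_count = 0

    def respond(self, ctx: TrialContext, rng) -> TrialResponse:
        self.trial_count += 1
        chosen = self.pick(ctx)
        return TrialResponse(chosen=chosen, latency=self.response_latency,
                             n_blank_touches=self.blank_touches)

    def reward_collect_latency(self, rng) -> float:
        return self.collect_latency

    def initiation_latency(self, rng) -> float:
        return self.initiation

    def observe(self, ctx, chosen, rewarded) -> None:
        pass


class NeverTouchAgent(ScriptedAgent):
    """STEP2 agent that waits out every trial (auto-reward route)."""

    def respond(self, ctx, rng) -> TrialResponse:
        return TrialResponse(chosen=None, latency=float("inf"))


def build_session(
    corrects,
    phase=Phase.PDR,
    session_index=1,
    subject_id="SUBJ",
    response_latency=2.0,
    reward_latency=1.0,
):
    """Construct a SessionLog directly from a list of per-trial correctness."""
    log = SessionLog(subject_id=subject_id, phase=phase,
                     session_index=session_index)
    for i, ok in enumerate(corrects):
        log.trials.append(TrialRecord(
            subject_id=subject_id, phase=phase, session_index=session_index,
            trial_index=i + 1,
            rewarded_side=Side.LEFT if i % 2 == 0 else Side.RIGHT,
            positive_stimulus="marble",
            chosen_stimulus="marble" if ok else "fan",
            correct=bool(ok), initiated=True,
            response_latency=response_latency,
            reward_latency=reward_latency if ok else None,
            tone=not ok, iti_s=10.0 if ok else 15.0,
            reward_ul=25.0 if ok else 0.0,
        ))
    log.duration_min = len(corrects) * 0.5
    return log


def session_with_errors(n_errors, n_trials=30, **kw):
    """Session whose first ``n_errors`` trials are incorrect."""
    return build_session([False] * n_errors + [True] * (n_trials - n_errors),
                         **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4/2 default-parameter cohort shared across tests."""
    from touchcog.cohort import CohortSpec, make_cohort

    return make_cohort(CohortSpec(n_young=4, n_aged=2, seed=11))
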