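"""Per-animal performance measures for PD / reversal touchscreen data.

Implements the standard analysis of pairwise-discrimination (PD) and
reversal (PDR) logs: an exact binomial screen for first-session
stimulus bias, sessions/trials/errors to the 80 %-in-2-consecutive-
sessions learning criterion, the binomial-criterion perseveration
phase of reversal learning, the 50 %-criterion perseverance measures,
and pooled latency summaries.  The output mirrors one row of a
per-animal cohort summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .task_engine import Phase, SessionLog

__all__ = [
    "ScoringConfig",
    "BiasResult",
    "CriterionPoint",
    "PerseverationSummary",
    "AnimalSummary",
    "binomial_bias_test",
    "criterion_point",
    "criterion_point_from_logs",
    "perseveration_binomial",
    "fifty_percent_point",
    "latency_summary",
    "summarize_animal",
]

#: Age (years) separating young from aged grey mouse lemurs; the study
#: cohorts span 1.1-4.1 (young) and 6.9-9.5 (aged) years.
AGED_THRESHOLD_YEARS = 5.0


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds of the scoring rules.

    ``accuracy_criterion`` over ``criterion_window`` consecutive
    sessions ends PD/PDR acquisition; ``fifty_criterion`` over two
    complete consecutive sessions ends the perseverance phase of the
    reversal; ``bias_alpha`` is the level of the exact binomial screen
    against ``chance_p``.
    """

    accuracy_criterion: float = 0.80
    criterion_window: int = 2
    bias_alpha: float = 0.05
    chance_p: float = 0.5
    fifty_criterion: float = 0.50
    complete_session_trials: int = 30
    #: perseveration scope: every biased session, or only the initial
    #: contiguous run of biased sessions
    perseveration_scope: Literal["all", "contiguous"] = "all"
    #: latency pooling: trial-level pool, or mean of per-session means
    latency_pooling: Literal["trials", "sessions"] = "trials"

    def __post_init__(self) -> None:
        for name in ("accuracy_criterion", "bias_alpha", "chance_p",
                     "fifty_criterion"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.criterion_window < 1:
            raise ValueError("criterion_window must be >= 1")


@dataclass(frozen=True)
class BiasResult:
    k: int
    n: int
    p_value: float
    biased: bool
    direction: Literal["toward", "against", "none"]


def binomial_bias_test(
    k: int, n: int, p0: float = 0.5, alpha: float = 0.05
) -> BiasResult:
    """Exact two-sided binomial test for a response bias.

    ``k`` counts choices of the focal stimulus out of ``n`` trials.
    The two-sided p-value sums the probabilities of all outcomes no
    more likely than the observed one (minimum-likelihood method; at
    p0 = 0.5 this equals doubling the smaller tail).  The subject is
    flagged biased at ``p < alpha``, toward the focal stimulus if
    k > n * p0, against it if k < n * p0.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    p = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
    biased = bool(p < alpha)
    if not biased:
        direction: Literal["toward", "against", "none"] = "none"
    else:
        direction = "toward" if k > n * p0 else "against"
    return BiasResult(k=k, n=n, p_value=float(p), biased=biased,
                      direction=direction)


@dataclass(frozen=True)
class CriterionPoint:
    n_sessions: int
    n_trials: int
    n_errors: int


def criterion_point(
    session_accuracies: Sequence[float],
    session_trial_counts: Sequence[int],
    config: ScoringConfig = ScoringConfig(),
) -> CriterionPoint | None:
    """Locate the learning criterion in a session-level accuracy series.

    The criterion is met at the first session ``i`` (1-based) such that
    sessions ``i - w + 1 .. i`` (w = ``criterion_window``) all reach
    ``accuracy_criterion``.  Counts are cumulative from session 1
    through session ``i`` inclusive — the criterion sessions themselves
    are counted.  Returns None when the criterion is never met.
    """
    if len(session_accuracies) == 0:
        raise ValueError("empty session series")
    if len(session_accuracies) != len(session_trial_counts):
        raise ValueError("accuracies and trial counts must be parallel")
    acc = np.asarray(session_accuracies, dtype=float)
    cnt = np.asarray(session_trial_counts, dtype=int)
    if np.any((acc < 0) | (acc > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    errors = cnt - np.rint(acc * cnt).astype(int)
    w = config.criterion_window
    for i in range(w - 1, len(acc)):
        if np.all(acc[i - w + 1: i + 1] >= config.accuracy_criterion):
            return CriterionPoint(
                n_sessions=i + 1,
                n_trials=int(cnt[: i + 1].sum()),
                n_errors=int(errors[: i + 1].sum()),
            )
    return None


def criterion_point_from_logs(
    logs: Sequence[SessionLog], config: ScoringConfig = ScoringConfig()
) -> CriterionPoint | None:
    """:func:`criterion_point` on the accuracies of a list of session logs."""
    if not logs:
        raise ValueError("empty session series")
    acc = [s.accuracy for s in logs]
    cnt = [s.n_trials for s in logs]
    return criterion_point(acc, cnt, config)


@dataclass(frozen=True)
class PerseverationSummary:
    """Reversal perseveration, under both scoring rules."""

    flagged_sessions: tuple[int, ...]  # session indices (1-based)
    persev_errors_binomial: int
    trials_to_50: int | None
    persev_errors_50: int | None


def perseveration_binomial(
    pdr_sessions: Sequence[SessionLog],
    config: ScoringConfig = ScoringConfig(),
) -> tuple[tuple[int, ...], int]:
    """Binomial-criterion perseveration phase of a reversal.

    In the reversal an error *is* a touch of the formerly positive
    stimulus, so each session's error count is tested against chance
    with the exact binomial screen.  Sessions with a significant bias
    toward the formerly positive stimulus form the perseveration
    phase; the perseverative-error count totals the errors inside it.

    With ``perseveration_scope = "contiguous"`` only the initial
    unbroken run of biased sessions counts (the stricter reading of
    the perseveration-phase definition); the default counts every
    biased session.
    """
    if not pdr_sessions:
        raise ValueError("empty session list")
    flagged: list[int] = []
    for s in pdr_sessions:
        if s.n_trials == 0:
            continue
        res = binomial_bias_test(s.n_errors, s.n_trials,
                                 config.chance_p, config.bias_alpha)
        if res.biased and res.direction == "toward":
            flagged.append(s.session_index)
    if config.perseveration_scope == "contiguous":
        run: list[int] = []
        expected = pdr_sessions[0].session_index
        for idx in flagged:
            if idx != expected:
                break
            run.append(idx)
            expected += 1
        flagged = run
    flagged_set = set(flagged)
    errors = sum(s.n_errors for s in pdr_sessions
                 if s.session_index in flagged_set)
    return tuple(flagged), errors


def fifty_percent_point(
    pdr_sessions: Sequence[SessionLog],
    config: ScoringConfig = ScoringConfig(),
) -> tuple[int, int] | None:
    """Trials and errors to the 50 %-in-2-complete-sessions criterion.

    The definite end of reversal perseverance: the first pair of
    *complete* (30-trial) consecutive sessions both at or above chance
    accuracy.  Incomplete sessions can never serve as criterion
    sessions, but their trials and errors still accumulate.  Returns
    ``(trials_to_50, persev_errors_50)`` summed over sessions 1 through
    the second criterion session inclusive, or None if never reached.
    """
    if not pdr_sessions:
        raise ValueError("empty session list")
    n = config.complete_session_trials
    ok = [s.is_complete(n) and s.accuracy >= config.fifty_criterion
          for s in pdr_sessions]
    for i in range(1, len(pdr_sessions)):
        if ok[i - 1] and ok[i]:
            trials = sum(s.n_trials for s in pdr_sessions[: i + 1])
            errors = sum(s.n_errors for s in pdr_sessions[: i + 1])
            return trials, errors
    return None


def latency_summary(
    logs: Sequence[SessionLog],
    phase: Phase | None = None,
    config: ScoringConfig = ScoringConfig(),
) -> tuple[float, float]:
    """Mean response latency and mean reward-collection latency.

    Response latencies pool every trial of the phase; reward latencies
    pool rewarded trials only (collection happens only after a correct
    answer).  The default pools at trial level across all sessions;
    ``latency_pooling = "sessions"`` instead averages per-session
    means.  Returns NaN for a latency with no contributing trials.
    """
    sel = [s for s in logs if phase is None or s.phase is phase]
    if not any(s.trials for s in sel):
        raise ValueError("no trials in the requested phase")

    def pool(values_per_session: list[list[float]]) -> float:
        if config.latency_pooling == "sessions":
            means = [float(np.mean(v)) for v in values_per_session if v]
            return float(np.mean(means)) if means else math.nan
        flat = [x for v in values_per_session for x in v]
        return float(np.mean(flat)) if flat else math.nan

    resp = pool([[t.response_latency for t in s.trials] for s in sel])
    rew = pool([[t.reward_latency for t in s.trials
                 if t.reward_latency is not None] for s in sel])
    return resp, rew


@dataclass
class AnimalSummary:
    """One row of the per-animal cohort summary table."""

    subject_id: str
    sex: str
    age_years: float
    age_group: Literal["YOUNG", "AGED"] = field(init=False)
    training_days: int | None = None
    positive_image: str | None = None
    bias_flag: bool = False
    bias_toward: str | None = None
    pd_sessions: int | None = None
    pd_trials: int | None = None
    pd_response_latency: float | None = None
    pd_reward_latency: float | None = None
    pdr_sessions: int | None = None
    pdr_trials: int | None = None
    pdr_response_latency: float | None = None
    pdr_reward_latency: float | None = None
    persev_errors_binomial: int | None = None
    persev_errors_50: int | None = None
    trials_to_50: int | None = None
    pd_truncated: bool = False
    pdr_truncated: bool = False

    def __post_init__(self) -> None:
        self.age_group = (
            "AGED" if self.age_years >= AGED_THRESHOLD_YEARS else "YOUNG"
        )


def summarize_animal(
    logs_by_phase: dict[Phase, list[SessionLog]],
    *,
    subject_id: str,
    sex: str,
    age_years: float,
    positive_image: str | None = None,
    negative_image: str | None = None,
    config: ScoringConfig = ScoringConfig(),
) -> AnimalSummary:
    """Assemble the full per-animal summary from phase-grouped logs.

    Missing phases leave the corresponding fields as None.  Training
    days count the sessions of steps 1-5.  The stimulus-bias screen is
    applied to the first PD session: a significant excess of touches
    of either stimulus flags the animal, recording which image the
    bias favoured.
    """
    out = AnimalSummary(subject_id=subject_id, sex=sex, age_years=age_years,
                        positive_image=positive_image)
    training = [Phase.STEP1, Phase.STEP2, Phase.STEP3, Phase.STEP4, Phase.STEP5]
    t_days = sum(len(logs_by_phase.get(p, [])) for p in training)
    if t_days:
        out.training_days = t_days

    pd = logs_by_phase.get(Phase.PD, [])
    if pd and pd[0].n_trials:
        first = pd[0]
        res = binomial_bias_test(first.n_correct, first.n_trials,
                                 config.chance_p, config.bias_alpha)
        out.bias_flag = res.biased
        if res.biased:
            out.bias_toward = (positive_image if res.direction == "toward"
                               else negative_image)
        cp = criterion_point_from_logs(pd, config)
        if cp is None:
            out.pd_truncated = True
            out.pd_sessions = len(pd)
            out.pd_trials = sum(s.n_trials for s in pd)
        else:
            out.pd_sessions, out.pd_trials = cp.n_sessions, cp.n_trials
        out.pd_response_latency, out.pd_reward_latency = latency_summary(
            pd, Phase.PD, config)

    pdr = logs_by_phase.get(Phase.PDR, [])
    if pdr and any(s.n_trials for s in pdr):
        cp = criterion_point_from_logs(pdr, config)
        if cp is None:
            out.pdr_truncated = True
            out.pdr_sessions = len(pdr)
            out.pdr_trials = sum(s.n_trials for s in pdr)
        else:
            out.pdr_sessions, out.pdr_trials = cp.n_sessions, cp.n_trials
        out.pdr_response_latency, out.pdr_reward_latency = latency_summary(
            pdr, Phase.PDR, config)
        _, out.persev_errors_binomial = perseveration_binomial(pdr, config)
        fp = fifty_percent_point(pdr, config)
        if fp is not None:
            out.trials_to_50, out.persev_errors_50 = fp
    return out
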