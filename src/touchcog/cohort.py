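"""Synthetic young/aged cohorts traversing the full touchscreen protocol.

No trial-level raw data were ever published for this paradigm, so the
analysis pipeline is exercised against simulated cohorts.  Each
synthetic animal is a small reinforcement-learning agent: a delta rule
with separate learning rates for rewarded and unrewarded outcomes
feeding a logistic (softmax) choice rule with a lateral bias term, a
lapse rate, and log-normal response/reward-collection latencies.
This is deliberately the minimal mechanism that produces the
phenomena the scoring layer must detect — sigmoid learning curves that
cross the 80 %/2-session criterion, first-session stimulus bias in a
minority of animals, below-chance accuracy immediately after reversal
(values carry over unreset), slow unlearning (= perseveration), and
age effects implemented as lower learning rates and slower responses.
It is emphatically not offered as a cognitive model of mouse lemurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import scoring
from .task_engine import (
    BLANK,
    Agent,
    Phase,
    ScheduleSpec,
    SessionLog,
    Side,
    TaskConfig,
    TrialContext,
    TrialResponse,
    generate_side_sequence,
    run_session,
    training_advance,
)

__all__ = [
    "AgentParams",
    "GroupParamDist",
    "CohortSpec",
    "RLAgent",
    "AnimalRun",
    "Cohort",
    "agent_choose",
    "agent_update",
    "simulate_animal",
    "make_cohort",
    "YOUNG_DEFAULTS",
    "AGED_DEFAULTS",
]

#: discrimination stimuli; one is assigned as each animal's rewarded
#: image, counterbalanced across the cohort
STIMULI = ("marble", "fan")

TRAINING_PHASES = (Phase.STEP1, Phase.STEP2, Phase.STEP3, Phase.STEP4,
                   Phase.STEP5)


@dataclass(frozen=True)
class AgentParams:
    """Parameters of one synthetic subject.

    alpha_pos / alpha_neg — delta-rule learning rates after rewarded /
    unrewarded outcomes, in (0, 1].  Setting alpha_neg far below
    alpha_pos produces strong perseveration.
    beta — inverse temperature of the logistic choice rule (> 0).
    side_bias — additive logit bias toward the left window.
    stim_bias — initial value offset carried by ``bias_stimulus``;
    models a spontaneous image preference (positive) or aversion
    (negative), the ground for first-session bias exclusions.
    lapse — probability of an attention lapse (uniform random choice).
    latency_* / reward_latency_* — log-normal parameters (log-seconds)
    of the response and reward-collection latencies.
    """

    alpha_pos: float = 0.011
    alpha_neg: float = 0.011
    beta: float = 2.2
    side_bias: float = 0.0
    stim_bias: float = 0.0
    bias_stimulus: str | None = None
    lapse: float = 0.10
    latency_mu: float = math.log(2.0)
    latency_sigma: float = 0.6
    reward_latency_mu: float = math.log(1.4)
    reward_latency_sigma: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_pos <= 1.0:
            raise ValueError("alpha_pos must be in (0, 1]")
        if not 0.0 <= self.alpha_neg <= 1.0:
            raise ValueError("alpha_neg must be in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")
        if self.latency_sigma <= 0 or self.reward_latency_sigma <= 0:
            raise ValueError("latency sigmas must be > 0")


def agent_choose(
    values: tuple[float, float],
    side_of_a: Side,
    params: AgentParams,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """Choose between stimulus A and B; returns (0 for A / 1 for B, latency).

    With probability ``lapse`` the choice is uniform; otherwise
    P(choose A) = logistic(beta * (V_A - V_B) + side_bias * s), where
    s is +1 when A sits in the left window and -1 on the right.  The
    response latency is drawn log-normal.
    """
    v_a, v_b = values
    latency = float(rng.lognormal(params.latency_mu, params.latency_sigma))
    if params.lapse > 0 and rng.random() < params.lapse:
        return (0 if rng.random() < 0.5 else 1), latency
    s = 1.0 if side_of_a is Side.LEFT else -1.0
    logit = params.beta * (v_a - v_b) + params.side_bias * s
    p_a = 1.0 / (1.0 + math.exp(-logit))
    return (0 if rng.random() < p_a else 1), latency


def agent_update(
    values: tuple[float, float],
    chosen: int,
    reward: float,
    params: AgentParams,
) -> tuple[float, float]:
    """Delta-rule update of the chosen stimulus value; the unchosen
    value is untouched.  V <- V + alpha * (reward - V), with
    alpha_pos after reward and alpha_neg otherwise."""
    if chosen not in (0, 1):
        raise ValueError("chosen must be 0 (A) or 1 (B)")
    alpha = params.alpha_pos if reward > 0 else params.alpha_neg
    v = list(values)
    v[chosen] = v[chosen] + alpha * (reward - v[chosen])
    return (v[0], v[1])


class RLAgent(Agent):
    """Stateful agent driving :func:`touchcog.task_engine.run_session`.

    During training steps the agent learns a single "image" value
    against the blank window; at PD entry fresh values are opened for
    the two discrimination stimuli (plus any spontaneous ``stim_bias``
    offset) and carried unreset into the reversal — the carry-over is
    what makes the first reversal session fall below chance.
    """

    #: seconds of extra response time added per blank touch (step 3/4)
    BLANK_TOUCH_COST = 1.5

    def __init__(self, params: AgentParams) -> None:
        self.params = params
        self.values: dict[str, float] = {"image": 0.0, BLANK: 0.0}

    def open_discrimination(self, stimuli: Sequence[str]) -> None:
        """Initialise stimulus values at PD entry (with any image bias)."""
        p = self.params
        self.values = {s: 0.0 for s in stimuli}
        if p.bias_stimulus is not None and p.stim_bias != 0.0:
            self.values[p.bias_stimulus] = p.stim_bias

    # -- Agent protocol -------------------------------------------------
    def respond(self, ctx: TrialContext,
                rng: np.random.Generator) -> TrialResponse:
        p = self.params
        if ctx.phase is Phase.STEP2:
            lat = float(rng.lognormal(p.latency_mu, p.latency_sigma))
            return TrialResponse(chosen=ctx.left, latency=lat)
        if ctx.phase in (Phase.STEP3, Phase.STEP4):
            image = ctx.left if ctx.left != BLANK else ctx.right
            v_img = self.values.setdefault("image", 0.0)
            logit = p.beta * (v_img - self.values[BLANK])
            p_img = 1.0 / (1.0 + math.exp(-logit))
            p_img = p.lapse * 0.5 + (1.0 - p.lapse) * p_img
            n_blank = int(rng.geometric(max(p_img, 1e-6))) - 1
            lat = float(rng.lognormal(p.latency_mu, p.latency_sigma))
            lat += self.BLANK_TOUCH_COST * n_blank
            return TrialResponse(chosen=image, latency=lat,
                                 n_blank_touches=n_blank)
        # STEP5 / PD / PDR: a genuine two-window choice
        a, b = ctx.left, ctx.right
        va = self.values.setdefault(a, 0.0)
        vb = self.values.setdefault(b, 0.0)
        idx, lat = agent_choose((va, vb), Side.LEFT, p, rng)
        return TrialResponse(chosen=a if idx == 0 else b, latency=lat)

    def reward_collect_latency(self, rng: np.random.Generator) -> float:
        p = self.params
        return float(rng.lognormal(p.reward_latency_mu,
                                   p.reward_latency_sigma))

    def initiation_latency(self, rng: np.random.Generator) -> float:
        # tray entry resembles reward approach; reuse that latency model
        p = self.params
        return float(rng.lognormal(p.reward_latency_mu,
                                   p.reward_latency_sigma))

    def observe(self, ctx: TrialContext, chosen: str | None,
                rewarded: bool) -> None:
        if chosen is None:
            return
        key = ("image" if ctx.phase in (Phase.STEP3, Phase.STEP4,
                                        Phase.STEP5) and chosen != BLANK
               else chosen)
        p = self.params
        alpha = p.alpha_pos if rewarded else p.alpha_neg
        v = self.values.get(key, 0.0)
        self.values[key] = v + alpha * ((1.0 if rewarded else 0.0) - v)


@dataclass(frozen=True)
class GroupParamDist:
    """(mean, sd) of each agent parameter within one age group.

    Draws are normal, truncated into each parameter's valid range.
    The aged defaults differ from the young ones only in lower
    learning rates (slower acquisition *and* slower unlearning, hence
    more perseveration) and slower responses.
    """

    alpha_pos: tuple[float, float] = (0.011, 0.002)
    alpha_neg: tuple[float, float] = (0.011, 0.002)
    beta: tuple[float, float] = (2.2, 0.3)
    side_bias: tuple[float, float] = (0.0, 0.25)
    lapse: tuple[float, float] = (0.10, 0.02)
    latency_mu: tuple[float, float] = (math.log(2.0), 0.25)
    latency_sigma: tuple[float, float] = (0.6, 0.1)
    reward_latency_mu: tuple[float, float] = (math.log(1.4), 0.15)
    reward_latency_sigma: tuple[float, float] = (0.4, 0.05)
    stim_bias_magnitude: tuple[float, float] = (1.5, 0.3)
    age_range: tuple[float, float] = (1.1, 4.1)

    def draw(self, rng: np.random.Generator,
             bias_stimulus: str | None) -> AgentParams:
        def tn(ms: tuple[float, float], lo: float, hi: float) -> float:
            m, s = ms
            for _ in range(100):
                v = rng.normal(m, s)
                if lo < v < hi:
                    return float(v)
            return float(min(max(m, lo + 1e-9), hi - 1e-9))

        stim_bias = 0.0
        if bias_stimulus is not None:
            mag = tn(self.stim_bias_magnitude, 0.0, 10.0)
            stim_bias = mag if rng.random() < 0.5 else -mag
        return AgentParams(
            alpha_pos=tn(self.alpha_pos, 0.001, 1.0),
            alpha_neg=tn(self.alpha_neg, 0.0005, 1.0),
            beta=tn(self.beta, 0.5, 50.0),
            side_bias=float(rng.normal(*self.side_bias)),
            stim_bias=stim_bias,
            bias_stimulus=bias_stimulus,
            lapse=tn(self.lapse, 0.0, 0.45),
            latency_mu=float(rng.normal(*self.latency_mu)),
            latency_sigma=tn(self.latency_sigma, 0.05, 3.0),
            reward_latency_mu=float(rng.normal(*self.reward_latency_mu)),
            reward_latency_sigma=tn(self.reward_latency_sigma, 0.05, 3.0),
        )


YOUNG_DEFAULTS = GroupParamDist()
AGED_DEFAULTS = GroupParamDist(
    alpha_pos=(0.004, 0.001),
    alpha_neg=(0.004, 0.001),
    latency_mu=(math.log(3.0), 0.3),
    age_range=(6.9, 9.5),
)


@dataclass(frozen=True)
class CohortSpec:
    """Composition and behavioural parameters of a simulated cohort."""

    n_young: int = 20
    n_aged: int = 10
    young_param_dist: GroupParamDist = YOUNG_DEFAULTS
    aged_param_dist: GroupParamDist = AGED_DEFAULTS
    p_stim_bias: float = 0.2
    seed: int = 0
    session_cap_per_phase: int = 100

    def __post_init__(self) -> None:
        if self.n_young < 0 or self.n_aged < 0:
            raise ValueError("group sizes must be >= 0")
        if not 0.0 <= self.p_stim_bias <= 1.0:
            raise ValueError("p_stim_bias must be in [0, 1]")


@dataclass
class AnimalRun:
    """Everything one simulated animal produced."""

    subject_id: str
    sex: str
    age_years: float
    params: AgentParams
    positive_image: str
    seed: int
    logs_by_phase: dict[Phase, list[SessionLog]] = field(default_factory=dict)
    truncated_phases: list[str] = field(default_factory=list)

    @property
    def truncated(self) -> bool:
        return bool(self.truncated_phases)

    def all_logs(self) -> list[SessionLog]:
        return [s for p in list(TRAINING_PHASES) + [Phase.PD, Phase.PDR]
                for s in self.logs_by_phase.get(p, [])]

    def summarize(self, config: scoring.ScoringConfig = scoring.ScoringConfig()
                  ) -> scoring.AnimalSummary:
        negative = next(s for s in STIMULI if s != self.positive_image)
        return scoring.summarize_animal(
            self.logs_by_phase,
            subject_id=self.subject_id, sex=self.sex,
            age_years=self.age_years,
            positive_image=self.positive_image,
            negative_image=negative,
            config=config,
        )


def simulate_animal(
    params: AgentParams,
    seed: int | np.random.SeedSequence,
    *,
    subject_id: str = "SIM",
    sex: str = "f",
    age_years: float = 2.5,
    positive_image: str = STIMULI[0],
    schedule_spec: ScheduleSpec = ScheduleSpec(),
    session_cap_per_phase: int = 100,
    configs: dict[Phase, TaskConfig] | None = None,
) -> AnimalRun:
    """Run one agent through STEP1 -> ... -> STEP5 -> PD -> PDR.

    Training steps advance via :func:`training_advance`; PD and PDR end
    at the 80 %/2-consecutive-sessions criterion.  At the reversal the
    stimulus-reward contingency flips while the agent's learned values
    carry over.  A phase that exhausts ``session_cap_per_phase``
    sessions is recorded as truncated (never an exception) and the
    animal still proceeds, so downstream scoring can handle the
    partial record.
    """
    rng = np.random.default_rng(seed)
    agent = RLAgent(params)
    run = AnimalRun(subject_id=subject_id, sex=sex, age_years=age_years,
                    params=params, positive_image=positive_image,
                    seed=int(seed) if isinstance(seed, (int, np.integer)) else -1)
    negative = next(s for s in STIMULI if s != positive_image)
    cfg = {p: (configs or {}).get(p, TaskConfig.for_phase(p))
           for p in list(TRAINING_PHASES) + [Phase.PD, Phase.PDR]}

    def phase_schedule(phase: Phase) -> list[Side | None]:
        if phase in (Phase.STEP1, Phase.STEP2):
            return [None] * schedule_spec.n_trials
        return list(generate_side_sequence(schedule_spec, rng))

    for phase in TRAINING_PHASES:
        logs: list[SessionLog] = []
        run.logs_by_phase[phase] = logs
        while len(logs) < session_cap_per_phase:
            logs.append(run_session(
                cfg[phase], phase_schedule(phase), agent, rng,
                subject_id=subject_id, session_index=len(logs) + 1,
                positive_stimulus="image", negative_stimulus=BLANK,
            ))
            if training_advance(phase, logs):
                break
        else:
            run.truncated_phases.append(phase.value)

    for phase, pos in ((Phase.PD, positive_image), (Phase.PDR, negative)):
        if phase is Phase.PD:
            agent.open_discrimination(STIMULI)
        neg = next(s for s in STIMULI if s != pos)
        logs = []
        run.logs_by_phase[phase] = logs
        crit = scoring.ScoringConfig(
            accuracy_criterion=cfg[phase].accuracy_criterion,
            criterion_window=cfg[phase].criterion_window,
        )
        while len(logs) < session_cap_per_phase:
            logs.append(run_session(
                cfg[phase], phase_schedule(phase), agent, rng,
                subject_id=subject_id, session_index=len(logs) + 1,
                positive_stimulus=pos, negative_stimulus=neg,
            ))
            if scoring.criterion_point_from_logs(logs, crit) is not None:
                break
        else:
            run.truncated_phases.append(phase.value)
    return run


@dataclass
class Cohort:
    spec: CohortSpec
    animals: list[AnimalRun]

    def manifest(self) -> dict:
        """Ground-truth record of the cohort: every agent's true
        parameters, seed and truncation flags."""
        return {
            "seed": self.spec.seed,
            "n_young": self.spec.n_young,
            "n_aged": self.spec.n_aged,
            "p_stim_bias": self.spec.p_stim_bias,
            "animals": [
                {
                    "subject_id": a.subject_id,
                    "sex": a.sex,
                    "age_years": round(a.age_years, 2),
                    "positive_image": a.positive_image,
                    "seed": a.seed,
                    "truncated_phases": list(a.truncated_phases),
                    "params": {k: v for k, v in asdict(a.params).items()},
                }
                for a in self.animals
            ],
        }

    def summaries(self, config: scoring.ScoringConfig = scoring.ScoringConfig()):
        import pandas as pd

        return pd.DataFrame([asdict(a.summarize(config))
                             for a in self.animals])


def make_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a full young/aged cohort, reproducibly from ``spec.seed``.

    Each animal gets an independent child seed of the cohort seed, so
    the cohort is reproducible as a whole and per animal.  Rewarded
    images alternate across animals (counterbalancing) and sexes
    alternate within each age group.
    """
    n = spec.n_young + spec.n_aged
    # integer child seeds (recorded in the manifest) derived from the
    # single cohort seed; each stays below 2**31
    state = np.random.SeedSequence(spec.seed).generate_state(n + 1)
    children = [int(s) % (2 ** 31) for s in state]
    meta_rng = np.random.default_rng(children[0])
    animals: list[AnimalRun] = []
    for i in range(n):
        young = i < spec.n_young
        dist = spec.young_param_dist if young else spec.aged_param_dist
        group = "Y" if young else "A"
        j = i if young else i - spec.n_young
        bias_stim = (STIMULI[int(meta_rng.integers(2))]
                     if meta_rng.random() < spec.p_stim_bias else None)
        params = dist.draw(meta_rng, bias_stim)
        age = float(meta_rng.uniform(*dist.age_range))
        animals.append(simulate_animal(
            params,
            children[i + 1],
            subject_id=f"{group}{j + 1:02d}",
            sex="m" if j % 2 == 0 else "f",
            age_years=age,
            positive_image=STIMULI[i % 2],
            session_cap_per_phase=spec.session_cap_per_phase,
        ))
    return Cohort(spec=spec, animals=animals)
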