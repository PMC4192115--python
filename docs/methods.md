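# Methods

This note documents the models, scoring rules, numerical choices and
limitations behind `touchcog`. Nothing here is a measured result; all
empirical claims are computed by the test suite or by
`scripts/acceptance.py`.

## The task protocol being modelled

One animal is tested once per day (one *session*). Training proceeds
through five shaping steps before the cognitive tasks:

1. **Habituation** — 20 minutes of free exploration; one session.
2. **Initial training** — two identical images for up to 30 s per
   trial; a touch earns 75 µl of juice immediately, otherwise 25 µl is
   auto-delivered at timeout. Advancement by either of two routes:
   30 trials within 20 minutes in one session (the animal interacts
   with the screen), or 30 trials within 30 minutes in 3 consecutive
   sessions (the animal passively collects the auto-reward).
3. **Must touch** — one image vs. a blank window; blank touches are
   logged as incorrect responses but only an image touch ends the
   trial. Criterion: 30 trials in under 30 minutes.
4. **Trial initiation** — as step 3 plus a head entry into the reward
   tray to start each trial. Same criterion.
5. **Error signalling** — incorrect touches end the trial with a
   2 kHz/500 ms tone and a 15 s ITI (10 s after correct). Criterion:
   two consecutive 30-trial/30-minute sessions at ≥80 % correct.

**PD** then presents two unfamiliar images ("marble" / "fan"); one is
rewarded, counterbalanced across animals. **PDR** swaps the
contingency. Both end at ≥80 % correct in 2 consecutive sessions.
Within each 30-trial session the rewarded image appears 15× left and
15× right, never more than 3 consecutive trials on one side.

## Side scheduler

`generate_side_sequence` draws uniformly random permutations of the
15 L / 15 R multiset and rejects those with a run longer than
`max_run`. Every valid sequence is an equally probable permutation, so
acceptance sampling is exactly uniform over the valid set — the
property the uniformity acceptance test verifies against a
dynamic-programming enumeration of that set. A spec is satisfiable iff
`max(n_L, n_R) ≤ max_run · (min(n_L, n_R) + 1)`; unsatisfiable specs
raise immediately. Rejection rates are negligible at the protocol's
geometry (most 15/15 permutations satisfy max-run 3).

## Simulated clock and session termination

Sessions are event-driven: per trial the clock advances by the
(optional) initiation latency, the response latency, the
reward-collection latency if rewarded, and the ITI. A session ends at
30 completed trials or at the 30-minute cap. A trial whose response
has not occurred when the cap strikes is discarded and the session
marked `truncated_mid_trial`; this makes incomplete sessions (trial
counts that are not multiples of 30) representable, which the scoring
rules require. Replaying a log through its recorded events reproduces
the stored duration exactly (a tested invariant).

Timing conventions the protocol leaves open, fixed here: the
habituation step has no trial events and a fixed 20-minute duration;
tray-entry initiation time is drawn from the agent's
reward-collection latency model (both are approaches to the tray);
each blank touch in steps 3–4 adds a fixed 1.5 s to the trial's
response time in the simulator.

## The synthetic agent

Each simulated animal is a two-learning-rate delta rule with logistic
choice:

* value update for the chosen option only:
  `V ← V + α⁺ (1 − V)` after reward, `V ← V + α⁻ (0 − V)` otherwise;
* choice: with probability `lapse`, uniform; otherwise
  `P(choose A) = σ(β (V_A − V_B) + b·s)` where `b` is a lateral bias
  and `s = ±1` encodes which window holds A;
* response and reward-collection latencies are log-normal;
* a minority of agents carry an initial value offset (`stim_bias`) on
  one image — a spontaneous preference or aversion that the
  first-session binomial screen is designed to catch;
* at the reversal, values carry over unreset.

During training the agent learns a single "image" value against the
blank window; at PD entry fresh values are opened for the two
discrimination stimuli.

This is the minimal mechanism producing the phenomena the analysis
must detect; it is not proposed as a cognitive model of mouse lemurs.

### Default parameters (the simulated study conditions)

Cohorts default to 20 young and 10 aged agents, images
counterbalanced, sexes alternating within group, and a 0.2 probability
of a spontaneous stimulus bias (matching the 6-of-30 incidence in the
motivating cohort study). Group parameter distributions (normal,
truncated to valid ranges):

| parameter | young | aged | rationale |
|---|---|---|---|
| α⁺ = α⁻ | 0.011 ± 0.002 | 0.004 ± 0.001 | sets trials-to-criterion at the study's scale (medians ≈ 270 vs 510 PD trials; the study printed 210 vs 420) with the aged group slower at both learning and unlearning |
| β | 2.2 ± 0.3 | same | asymptotic accuracy ≈ 0.86 with lapse, comfortably above the 0.80 criterion but low enough that the criterion reflects learning, not lucky sessions |
| lapse | 0.10 ± 0.02 | same | keeps first-session accuracy near chance and caps asymptotes realistically |
| side bias | 0 ± 0.25 | same | mild lateral preferences |
| response latency | log-normal, median 2 s | median 3 s | Table-scale latencies; right-skewed |
| reward latency | log-normal, median 1.4 s | same | collection is fast and less variable |
| stim-bias magnitude | 1.5 ± 0.3, random sign | same | strong enough that the binomial screen flags it in session 1 |

Under these defaults the first reversal session averages ≈ 20 %
correct (the study reported 20.3 ± 1.8 %) and aged groups exceed young
groups in PD trials, PDR trials and perseverative errors in ≥95 % of
simulated 20/10 cohorts — both properties are enforced by the
acceptance suite. Phase simulation is capped at 100 sessions (the
slowest real animal needed 60 reversal sessions); hitting the cap sets
a truncation flag rather than raising.

A deliberate modelling consequence: agents with *fast* unlearning
(α⁻ ≳ 0.2) reverse within their first 30-trial session, so their
first-session reversal accuracy is *above* chance — below-chance first
sessions are a signature of unlearning that is slow relative to
session length, as in the animals. Similarly, trials-to-criterion is
quantised in units of 30, so group differences smaller than a session
vanish in medians.

## Scoring rules

* **Bias screen** — exact two-sided binomial test (minimum-likelihood
  summation; at p₀ = ½ this equals doubling the smaller tail) of
  first-PD-session touches of the rewarded image against chance,
  α = 0.05. At 30 trials the flagging cutoffs are ≥21 and ≤9. The
  two-sided form catches both preference and aversion; the flagged
  image and direction are recorded. A perfect first session *is*
  flagged — the screen is purely statistical. Sidedness and α are not
  dictated by the protocol; 0.05 two-sided is the package's choice.
* **Learning criterion** — first session `i` such that sessions
  `i−1, i` both reach 80 %. Sessions, trials and errors are cumulative
  through session `i` (criterion sessions included — this matches the
  arithmetic of the published per-animal table, e.g. 5 sessions =
  150 trials). Incomplete sessions count as sessions and contribute
  their trials; they may also serve as criterion sessions (the
  protocol caps, but does not require, 30 trials).
* **Perseveration phase (binomial criterion)** — per reversal session,
  the same binomial test on errors (an error in the reversal *is* a
  touch of the formerly rewarded image); the phase comprises all
  sessions significantly biased toward the former image, and the
  perseverative-error count totals errors within it. The default scope
  is *every* flagged session; `perseveration_scope="contiguous"`
  restricts to the initial unbroken run for the stricter reading.
* **50 % criterion** — first pair of consecutive *complete* (30-trial)
  sessions at ≥50 %; trials and errors accumulate from the first
  reversal session through the second criterion session. Incomplete
  sessions can never serve as criterion sessions here (completeness is
  part of the definition) but their trials and errors still count.
* **Latencies** — trial-level pooling across all sessions of a phase
  (not a mean of session means; `latency_pooling="sessions"` offers
  the alternative). Reward latency pools correct trials only and is
  NaN for an animal with no correct trials.

## Exact Mann-Whitney U

With n = 30 animals and session-quantised counts, ties are the rule,
and asymptotic p-values are unreliable at these sizes, so the test is
exact and tie-aware:

* `U₁ = Σ_{i,j} [x_i > y_j] + ½[x_i = y_j]`, reported `U = min(U₁, U₂)`;
* the exact null distribution of the rank sum is computed by a shift
  (convolution) DP over midranks doubled to integers — an implicit
  enumeration of all `C(n, n₁)` group assignments that respects the
  observed tie pattern;
* two-sided p doubles the smaller exact tail, capped at 1 (the common
  convention of exact-test software; the DP's tail probabilities make
  other conventions easy to add);
* exact computation is used whenever `n₁·n₂ ≤ 400` (covering 20×10 and
  15×9 with huge margin); beyond that a tie-corrected,
  continuity-corrected normal approximation is used and the `method`
  field says so.

The exact p equals full enumeration on every partition with
`n₁ + n₂ ≤ 10` (a tested property), and coincides with standard
implementations on tie-free data.

Medians use the standard order-statistic convention (mean of the two
central values at even n). Note that a few medians printed in the
motivating study (e.g. reversal trials 390/617) differ slightly from
the standard medians of its own per-animal columns (385.5/608.5),
presumably a software-specific convention; this package implements and
reports the standard convention.

The cohort report applies the study's exclusion logic: animals flagged
by the first-session bias screen are excluded from PD comparisons
(including PD latencies) but retained everywhere else; the PD-PDR
correlation uses the screened animals. Sex contrasts within the aged
group are computed but labelled underpowered (4 vs 6). No
multiple-testing correction is applied, matching the reported
analysis; the report states this.

## What the synthetic validation does and does not show

Passing tests on simulated cohorts show that the pipeline *detects
what the generator puts in*: criterion crossing, carried-over values,
slower aged learning, spontaneous image biases. The generator does not
emulate motivational drift across weeks, session-to-session latency
autocorrelation, stimulus-specific salience differences, partial
attrition, or any within-group age gradient — so agreement with the
simulator cannot certify those aspects of real data. Conversely, the
fixture-based statistics are computed from the real per-animal table
and are independent of the simulator. No trial-level raw data exist
for the original cohort, so simulator parameters are matched to
group-level magnitudes only, never calibrated per animal.

## Problem sizes used in validation

Simulation-based acceptance uses 100 independent 20/10 cohorts for the
directional age effects, the first 20 of them (~600 animals) for the
below-chance first-reversal property, 15 seed-matched pairs for the
α⁻→0 perseveration contrast (one-sided sign test), and 10⁵ scheduler
draws on the 10-trial/5-left instance (252-member valid set,
chi-square uniformity at p > 0.01). These sizes give the binomial
assertions comfortable power while keeping the full suite to a few
minutes on one core.
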