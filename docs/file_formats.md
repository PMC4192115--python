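# File formats

All files are plain text: comma-separated, UTF-8, LF line endings,
`.` decimal separator, empty field for a missing value. Session and
trial indices are 1-based. Latencies and the clock are in seconds,
session durations in minutes, reward volumes in microlitres.

## Trial log (`trials.csv`)

One row per completed trial, ordered within a session.

| column | type | meaning |
|---|---|---|
| `subject_id` | str | animal identifier |
| `phase` | enum | `STEP1`…`STEP5`, `PD`, `PDR` |
| `session_index` | int | daily session number within the phase |
| `trial_index` | int | trial number within the session, contiguous from 1 |
| `rewarded_side` | enum | `LEFT`/`RIGHT`; empty in steps 1–2 |
| `positive_stimulus` | str | currently rewarded window content |
| `chosen_stimulus` | str | content the trial-ending touch landed on; empty = no touch (step-2 timeout) |
| `correct` | 0/1 | touch of the positive stimulus (steps 3–4: no blank touches) |
| `initiated` | 0/1 | trial started by tray entry (step 4 onward) |
| `response_latency` | float | stimulus onset → trial-ending touch (or timeout) |
| `reward_latency` | float | correct touch → reward collection; empty iff unrewarded |
| `n_blank_touches` | int | blank-window touches before the image touch (steps 3–4) |
| `tone` | 0/1 | error tone marker (step 5 / PD / PDR incorrect trials) |
| `iti_s` | float | inter-trial interval that followed (10 correct / 15 incorrect) |
| `reward_ul` | float | delivered volume; 0 if unrewarded |
| `auto_rewarded` | 0/1 | step-2 timeout auto-delivery |
| `t_start`, `t_end` | float | trial start / touch time on the session clock |

Validation on read: all columns present; no duplicate
(subject, phase, session, trial) keys; trial indices contiguous from
1; latencies non-negative; correct choice-trials name the positive
stimulus and carry a reward latency. The first violation raises an
error with the offending file line number.

## Session metadata (`sessions.csv`)

One row per session; needed to round-trip durations and zero-trial
sessions (habituation).

`subject_id, phase, session_index, n_trials, duration_min,
truncated_mid_trial`

## Subject metadata (`subjects.csv`)

`subject_id, sex, age_years, positive_image` — consumed by
`touchcog score` to fill summary fields the logs do not carry.

## Animal summary (`summaries.csv`)

One row per animal; the columns of
`touchcog.scoring.AnimalSummary`, mirroring the per-animal table of
the motivating study: identity and age group, training days, the
bias-screen outcome, sessions/trials to criterion and pooled
latencies for PD and PDR, and the three perseveration measures.

## Packaged table (`touchcog/data/table1.csv`)

The 30-animal summary table shipped with the package (SHA-256
checked on load). Column `first_session_bias` names the image the
animal preferred in its first PD session (empty = none);
`pd_bias_excluded` marks the six animals excluded from PD group
comparisons.

## Cohort manifest (`cohort_manifest.yaml`)

Ground truth of a simulated cohort: cohort seed, group sizes, and per
animal its identity, true agent parameters, child seed and truncation
flags. A manifest plus the package version suffices to regenerate the
cohort byte-identically.
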