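"""File formats: trial-log / session CSVs, cohort manifests, fixture.

All CSVs are comma-separated, UTF-8, LF line endings, "." decimal
separator, with empty fields for missing values.  Session indices are
1-based throughout (a "session" is one daily testing bout).

Trial-log schema (one row per trial)
------------------------------------
subject_id, phase, session_index, trial_index, rewarded_side,
positive_stimulus, chosen_stimulus, correct, initiated,
response_latency, reward_latency, n_blank_touches, tone, iti_s,
reward_ul, auto_rewarded, t_start, t_end

Session-metadata schema (one row per session)
---------------------------------------------
subject_id, phase, session_index, n_trials, duration_min,
truncated_mid_trial
"""

from __future__ import annotations

import hashlib
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .task_engine import Phase, SessionLog, Side, TrialRecord

__all__ = [
    "TrialLogError",
    "write_trial_logs",
    "read_trial_logs",
    "load_table1_fixture",
    "write_manifest",
    "read_manifest",
    "summaries_to_csv",
]

TRIAL_COLUMNS = [
    "subject_id", "phase", "session_index", "trial_index",
    "rewarded_side", "positive_stimulus", "chosen_stimulus", "correct",
    "initiated", "response_latency", "reward_latency",
    "n_blank_touches", "tone", "iti_s", "reward_ul", "auto_rewarded",
    "t_start", "t_end",
]
SESSION_COLUMNS = [
    "subject_id", "phase", "session_index", "n_trials", "duration_min",
    "truncated_mid_trial",
]

#: SHA-256 of the packaged per-animal summary fixture; guards against
#: accidental edits of the transcribed values
_TABLE1_SHA256 = (
    "bedb55902f44a5b6014a668b80aeb3969f94a5d982bd98ad6193ee993756f5fa"
)


class TrialLogError(ValueError):
    """A trial-log file violates the documented schema."""


def _trial_row(t: TrialRecord) -> dict:
    return {
        "subject_id": t.subject_id,
        "phase": t.phase.value,
        "session_index": t.session_index,
        "trial_index": t.trial_index,
        "rewarded_side": t.rewarded_side.value if t.rewarded_side else "",
        "positive_stimulus": t.positive_stimulus,
        "chosen_stimulus": "" if t.chosen_stimulus is None else t.chosen_stimulus,
        "correct": int(t.correct),
        "initiated": int(t.initiated),
        "response_latency": repr(t.response_latency),
        "reward_latency": ("" if t.reward_latency is None
                           else repr(t.reward_latency)),
        "n_blank_touches": t.n_blank_touches,
        "tone": int(t.tone),
        "iti_s": repr(t.iti_s),
        "reward_ul": repr(t.reward_ul),
        "auto_rewarded": int(t.auto_rewarded),
        "t_start": repr(t.t_start),
        "t_end": repr(t.t_end),
    }


def write_trial_logs(
    logs: Iterable[SessionLog], trials_path: str | Path,
    sessions_path: str | Path | None = None,
) -> None:
    """Serialise session logs to the trial-log CSV (and, optionally, the
    session-metadata CSV, needed to round-trip durations of sessions
    with zero trials)."""
    logs = list(logs)
    trial_rows = [_trial_row(t) for s in logs for t in s.trials]
    df = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    df.to_csv(trials_path, index=False, lineterminator="\n")
    if sessions_path is not None:
        srows = [{
            "subject_id": s.subject_id,
            "phase": s.phase.value,
            "session_index": s.session_index,
            "n_trials": s.n_trials,
            "duration_min": repr(s.duration_min),
            "truncated_mid_trial": int(s.truncated_mid_trial),
        } for s in logs]
        pd.DataFrame(srows, columns=SESSION_COLUMNS).to_csv(
            sessions_path, index=False, lineterminator="\n")


def _parse_trial(row: pd.Series, line_no: int) -> TrialRecord:
    def bad(msg: str) -> TrialLogError:
        return TrialLogError(f"line {line_no}: {msg}")

    try:
        phase = Phase(row["phase"])
    except ValueError:
        raise bad(f"unknown phase {row['phase']!r}") from None
    side_raw = row["rewarded_side"]
    side = None if side_raw in ("", None) or (isinstance(side_raw, float)
                                              and math.isnan(side_raw)) \
        else Side(side_raw)
    rl = row["reward_latency"]
    reward_latency = None if rl in ("", None) or (
        isinstance(rl, float) and math.isnan(rl)) else float(rl)
    resp = float(row["response_latency"])
    if resp < 0 or (reward_latency is not None and reward_latency < 0):
        raise bad("negative latency")
    correct = bool(int(row["correct"]))
    chosen_raw = row["chosen_stimulus"]
    chosen = None if chosen_raw in ("", None) or (
        isinstance(chosen_raw, float) and math.isnan(chosen_raw)) \
        else str(chosen_raw)
    if correct and phase in (Phase.STEP5, Phase.PD, Phase.PDR) \
            and chosen != row["positive_stimulus"]:
        raise bad("correct trial whose chosen stimulus is not the "
                  "positive stimulus")
    if reward_latency is None and correct and phase in (
            Phase.STEP5, Phase.PD, Phase.PDR):
        raise bad("correct trial without a reward latency")
    return TrialRecord(
        subject_id=str(row["subject_id"]),
        phase=phase,
        session_index=int(row["session_index"]),
        trial_index=int(row["trial_index"]),
        rewarded_side=side,
        positive_stimulus=str(row["positive_stimulus"]),
        chosen_stimulus=chosen,
        correct=correct,
        initiated=bool(int(row["initiated"])),
        response_latency=resp,
        reward_latency=reward_latency,
        n_blank_touches=int(row["n_blank_touches"]),
        tone=bool(int(row["tone"])),
        iti_s=float(row["iti_s"]),
        reward_ul=float(row["reward_ul"]),
        auto_rewarded=bool(int(row["auto_rewarded"])),
        t_start=float(row["t_start"]),
        t_end=float(row["t_end"]),
    )


def read_trial_logs(
    trials_path: str | Path, sessions_path: str | Path | None = None,
) -> list[SessionLog]:
    """Parse and validate a trial-log CSV into grouped session logs.

    Rows are validated one by one; the first malformed row raises
    :class:`TrialLogError` carrying its file line number.  Duplicate
    (subject, phase, session, trial) keys and non-contiguous trial
    indices within a session are rejected.  If a session-metadata CSV
    is given, durations, truncation flags and zero-trial sessions are
    restored from it.
    """
    df = pd.read_csv(trials_path, dtype=object, keep_default_na=False,
                     float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise TrialLogError(f"missing columns: {sorted(missing)}")

    sessions: dict[tuple, SessionLog] = {}
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        t = _parse_trial(row, line_no)
        key = (t.subject_id, t.phase, t.session_index, t.trial_index)
        if key in seen:
            raise TrialLogError(f"line {line_no}: duplicate trial key {key}")
        seen.add(key)
        skey = key[:3]
        log = sessions.get(skey)
        if log is None:
            log = sessions[skey] = SessionLog(
                subject_id=t.subject_id, phase=t.phase,
                session_index=t.session_index)
        if t.trial_index != log.n_trials + 1:
            raise TrialLogError(
                f"line {line_no}: trial_index {t.trial_index} breaks the "
                f"1-based contiguous order (expected {log.n_trials + 1})")
        log.trials.append(t)

    if sessions_path is not None:
        sdf = pd.read_csv(sessions_path, float_precision="round_trip")
        for _, r in sdf.iterrows():
            skey = (str(r.subject_id), Phase(r.phase), int(r.session_index))
            log = sessions.get(skey)
            if log is None:
                log = sessions[skey] = SessionLog(
                    subject_id=skey[0], phase=skey[1], session_index=skey[2])
            log.duration_min = float(r.duration_min)
            log.truncated_mid_trial = bool(int(r.truncated_mid_trial))

    order = {p: i for i, p in enumerate(Phase)}
    return sorted(sessions.values(),
                  key=lambda s: (s.subject_id, order[s.phase], s.session_index))


def load_table1_fixture(verify_checksum: bool = True) -> pd.DataFrame:
    """The packaged 30-animal per-animal summary table.

    Columns mirror the cohort summary: subject, sex, age, training
    days, rewarded image, first-session image bias (empty if none),
    the PD-exclusion flag it implies, sessions/trials to criterion and
    latencies for PD and the reversal, and the three perseveration
    measures.  Raises if the packaged file's checksum does not match
    the transcription (tamper guard).
    """
    ref = resources.files("touchcog.data").joinpath("table1.csv")
    raw = ref.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE1_SHA256:
            raise ValueError(
                "packaged table1.csv checksum mismatch: fixture was modified")
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), keep_default_na=False)
    df["first_session_bias"] = df["first_session_bias"].replace("", np.nan)
    df["pd_bias_excluded"] = df["pd_bias_excluded"].astype(bool)
    df["age_group"] = np.where(df["age_years"] >= 5.0, "AGED", "YOUNG")
    return df


def fixture_as_summaries(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fixture reshaped to the column names of the cohort summary table
    (bias flag naming, etc.), for direct use by the stats layer."""
    if df is None:
        df = load_table1_fixture()
    out = df.rename(columns={
        "subject": "subject_id",
        "first_session_bias": "bias_toward",
        "pd_bias_excluded": "bias_flag",
    }).copy()
    return out


def summaries_to_csv(summaries: pd.DataFrame, path: str | Path) -> None:
    summaries.to_csv(path, index=False, lineterminator="\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
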