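"""Integration-method SSRT estimation and per-subject task summaries.

The stop-signal reaction time (SSRT) is the latent latency of the
stopping process; it is estimated, never observed.  The estimator here
is the consensus *integration method with go-omission replacement*:

1. Pool every go trial with a response (choice errors and premature go
   responses included); go omissions are assigned the subject's maximum
   observed go RT.
2. Per stop condition, compute p(respond|signal) — the fraction of stop
   trials with a response, premature responses counted as failures to
   stop.
3. The stop process is assumed to finish at the p(respond|signal)
   quantile of the go-RT distribution: the nth smallest RT with
   n = ceil(N * p).  SSRT = nth RT - mean SSD over all stop trials of
   the condition (premature trials' SSDs included).

The race-model sanity check (mean RT on unsuccessful stop trials must
be shorter than mean go RT, a consequence of censoring) and the
Table-style per-subject summaries live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationUndefinedError

__all__ = [
    "SSRTEstimate",
    "RaceCheckReport",
    "SSTSummary",
    "estimate_ssrt_integration",
    "verify_race_assumption",
    "summarize_subject",
    "summarize_cohort",
    "ssrt_index",
]


def _experimental(records: pd.DataFrame, include_practice: bool) -> pd.DataFrame:
    if include_practice or "practice" not in records.columns:
        return records
    return records[~records["practice"].astype(bool)]


def _responded(frame: pd.DataFrame) -> pd.Series:
    return frame["response"].astype(str) != "none"


@dataclass(frozen=True)
class SSRTEstimate:
    """Integration-method SSRT with its audit trail."""

    ssrt: float
    condition: str
    n_go: int  # go trials with a response
    n_go_omissions: int  # omissions replaced by the max RT
    n_stop: int
    p_respond_signal: float
    rank: int
    nth_rt: float
    mean_ssd: float


@dataclass(frozen=True)
class RaceCheckReport:
    """Race-model assumption check for one subject.

    ``assumption_met`` is None when the subject has no unsuccessful stop
    trial, in which case the check is undetermined.
    """

    subject: str
    mean_unsuccessful_stop_rt: float
    mean_go_rt: float
    assumption_met: bool | None


@dataclass(frozen=True)
class ConditionSummary:
    inhibition_rate: float
    mean_ssd: float
    p_respond_signal: float
    ssrt: float | None
    unsuccessful_stop_rt: float | None


@dataclass(frozen=True)
class SSTSummary:
    """Per-subject descriptive task performance, one entry per stop
    condition plus overall go measures."""

    subject: str
    group: str
    conditions: dict[str, ConditionSummary]
    go_rt: float
    correct_go: float
    go_omissions: int


def _go_rt_pool(records: pd.DataFrame) -> tuple[np.ndarray, int]:
    """(omission-augmented sorted go-RT array, omission count).

    All responded go trials enter, choice errors and premature responses
    included; each omission contributes one copy of the max observed RT.
    """
    go = records[records["trial_type"] == "go"]
    rts = go.loc[_responded(go), "rt"].to_numpy(float)
    rts = rts[np.isfinite(rts)]
    if rts.size == 0:
        raise EstimationUndefinedError("no go trials with a response")
    n_omit = int(len(go) - rts.size)
    if n_omit:
        rts = np.concatenate([rts, np.full(n_omit, rts.max())])
    return np.sort(rts), n_omit


def estimate_ssrt_integration(
    records: pd.DataFrame,
    condition: str,
    rank_mode: str = "ceil",
    include_practice: bool = False,
) -> SSRTEstimate:
    """Estimate one condition's SSRT by the integration method.

    ``rank_mode`` selects the integer rank from N * p(respond|signal):
    "ceil" (default), "floor" or "round"; the rank is clamped to
    [1, N] either way.  Raises :class:`EstimationUndefinedError` when
    p(respond|signal) is 0 or 1, where the quantile is degenerate.
    """
    records = _experimental(records, include_practice)
    rts, n_omit = _go_rt_pool(records)
    stops = records[(records["trial_type"] == "stop") & (records["condition"] == condition)]
    if len(stops) == 0:
        raise EstimationUndefinedError(f"no stop trials for condition {condition!r}")
    p_respond = float(_responded(stops).mean())
    if p_respond <= 0.0 or p_respond >= 1.0:
        raise EstimationUndefinedError(
            f"p(respond|signal) = {p_respond:g} for condition {condition!r}; "
            "SSRT is undefined at 0 or 1"
        )
    n_total = rts.size
    pick = {"ceil": math.ceil, "floor": math.floor, "round": round}[rank_mode]
    rank = int(min(max(pick(n_total * p_respond), 1), n_total))
    nth_rt = float(rts[rank - 1])
    mean_ssd = float(stops["ssd"].mean())
    return SSRTEstimate(
        ssrt=nth_rt - mean_ssd,
        condition=condition,
        n_go=int(n_total - n_omit),
        n_go_omissions=n_omit,
        n_stop=int(len(stops)),
        p_respond_signal=p_respond,
        rank=rank,
        nth_rt=nth_rt,
        mean_ssd=mean_ssd,
    )


def verify_race_assumption(
    records: pd.DataFrame, include_practice: bool = False
) -> RaceCheckReport:
    """Check that unsuccessful-stop RTs are faster on average than go RTs.

    Under an independent race, responses that escape the stop signal are
    a censored (fast) subset of the go distribution, so their mean must
    be strictly below the mean go RT.  Premature stop responses count as
    unsuccessful-stop RTs.
    """
    records = _experimental(records, include_practice)
    subject = str(records["subject"].iloc[0]) if "subject" in records.columns else ""
    go = records[records["trial_type"] == "go"]
    go_rts = go.loc[_responded(go), "rt"].to_numpy(float)
    stops = records[records["trial_type"] == "stop"]
    stop_rts = stops.loc[_responded(stops), "rt"].to_numpy(float)
    if go_rts.size == 0:
        raise EstimationUndefinedError("no go trials with a response")
    mean_go = float(np.mean(go_rts))
    if stop_rts.size == 0:
        return RaceCheckReport(subject, float("nan"), mean_go, None)
    mean_stop = float(np.mean(stop_rts))
    return RaceCheckReport(subject, mean_stop, mean_go, mean_stop < mean_go)


def summarize_subject(
    records: pd.DataFrame,
    rank_mode: str = "ceil",
    include_practice: bool = False,
) -> SSTSummary:
    """Descriptive per-subject summary across all stop conditions.

    Conditions where every stop trial was inhibited (or none was) get
    ``ssrt = None`` rather than an error, so whole-cohort summaries
    survive degenerate subjects.
    """
    frame = _experimental(records, include_practice)
    subject = str(frame["subject"].iloc[0]) if "subject" in frame.columns else ""
    group = str(frame["group"].iloc[0]) if "group" in frame.columns else ""
    go = frame[frame["trial_type"] == "go"]
    go_resp = go[_responded(go)]
    conditions: dict[str, ConditionSummary] = {}
    for cond in sorted(frame.loc[frame["trial_type"] == "stop", "condition"].unique()):
        stops = frame[(frame["trial_type"] == "stop") & (frame["condition"] == cond)]
        responded = _responded(stops)
        p_respond = float(responded.mean())
        try:
            ssrt = estimate_ssrt_integration(
                frame, cond, rank_mode=rank_mode, include_practice=True
            ).ssrt
        except EstimationUndefinedError:
            ssrt = None
        stop_rts = stops.loc[responded, "rt"].to_numpy(float)
        conditions[cond] = ConditionSummary(
            inhibition_rate=1.0 - p_respond,
            mean_ssd=float(stops["ssd"].mean()),
            p_respond_signal=p_respond,
            ssrt=ssrt,
            unsuccessful_stop_rt=float(np.mean(stop_rts)) if stop_rts.size else None,
        )
    return SSTSummary(
        subject=subject,
        group=group,
        conditions=conditions,
        go_rt=float(go_resp["rt"].mean()) if len(go_resp) else float("nan"),
        correct_go=float(go["correct"].mean()) if len(go) else float("nan"),
        go_omissions=int(len(go) - len(go_resp)),
    )


def ssrt_index(summary: SSTSummary) -> float:
    """Emotional-minus-neutral SSRT; negative values mean an emotional
    stopping advantage.  Raises when either condition is undefined."""
    try:
        emo = summary.conditions["emotional"].ssrt
        neu = summary.conditions["neutral"].ssrt
    except KeyError as err:
        raise EstimationUndefinedError(f"missing condition {err} in summary") from err
    if emo is None or neu is None:
        raise EstimationUndefinedError("SSRT undefined for at least one condition")
    return emo - neu


def summarize_cohort(
    records: pd.DataFrame,
    rank_mode: str = "ceil",
    include_practice: bool = False,
) -> pd.DataFrame:
    """One summary row per subject (wide layout, Table-style columns).

    Columns per condition ``c``: ``inhibition_rate_c``, ``mean_ssd_c``,
    ``p_respond_signal_c``, ``ssrt_c``, ``unsucc_rt_c``; plus overall
    ``go_rt``, ``correct_go``, ``go_omissions``, ``ssrt_index`` (NaN when
    undefined) and the race-check columns.
    """
    rows = []
    for subject, frame in records.groupby("subject", sort=True):
        summ = summarize_subject(frame, rank_mode=rank_mode, include_practice=include_practice)
        race = verify_race_assumption(frame, include_practice=include_practice)
        row: dict = {"subject": subject, "group": summ.group}
        for cond, cs in summ.conditions.items():
            row[f"inhibition_rate_{cond}"] = cs.inhibition_rate
            row[f"mean_ssd_{cond}"] = cs.mean_ssd
            row[f"p_respond_signal_{cond}"] = cs.p_respond_signal
            row[f"ssrt_{cond}"] = np.nan if cs.ssrt is None else cs.ssrt
            row[f"unsucc_rt_{cond}"] = (
                np.nan if cs.unsuccessful_stop_rt is None else cs.unsuccessful_stop_rt
            )
        row["go_rt"] = summ.go_rt
        row["correct_go"] = summ.correct_go
        row["go_omissions"] = summ.go_omissions
        try:
            row["ssrt_index"] = ssrt_index(summ)
        except EstimationUndefinedError:
            row["ssrt_index"] = np.nan
        row["mean_unsuccessful_stop_rt"] = race.mean_unsuccessful_stop_rt
        row["mean_go_rt"] = race.mean_go_rt
        row["race_assumption_met"] = race.assumption_met
        rows.append(row)
    return pd.DataFrame(rows)
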