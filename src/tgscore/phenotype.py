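"""Training loads from session-RPE diaries and Cooper-test response phenotypes.

Training load uses the session-RPE method: each session's load (sTL, in
arbitrary units) is running duration in minutes times estimated intensity as
a percentage of VO2max, where intensity is mapped from the Borg CR-10
session rating of perceived exertion (default linear, sRPE x 10).  Weekly
load (wTL) multiplies the mean session load by the number of sessions that
week; total load (tTL) aggregates weekly loads over the program.

The response phenotype is the percent change in Cooper 12-minute run
distance from week 0 to week 8, computed per participant (the group summary
is the mean of individual percent changes, not the percent change of group
means).  Training-group participants whose percent improvement strictly
exceeds the group mean are "responders"; the control arm is never
classified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Group = Literal["EG", "CG"]


@dataclass(frozen=True)
class CooperRecord:
    """One Cooper 12-minute run test: distance covered and session RPE."""

    participant_id: str
    week: int
    distance_km: float
    srpe: float | None = None

    def __post_init__(self) -> None:
        if self.week not in (0, 4, 8):
            raise ValueError(f"week must be 0, 4 or 8, got {self.week}")
        if self.distance_km <= 0:
            raise ValueError(f"distance must be positive, got {self.distance_km}")
        if self.srpe is not None and not 0 <= self.srpe <= 10:
            raise ValueError(f"sRPE {self.srpe} outside CR-10 range [0,10]")


@dataclass(frozen=True)
class TrainingSession:
    """One diary entry: duration, sRPE, and the derived intensity."""

    participant_id: str
    week: int
    duration_min: float
    srpe: float
    intensity_pct: float

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError(f"duration must be positive, got {self.duration_min}")
        if not 0 < self.intensity_pct <= 100:
            raise ValueError(f"intensity {self.intensity_pct}% outside (0,100]")


@dataclass(frozen=True)
class TrainingLoadSummary:
    """Session / weekly / total loads in arbitrary units (A.U.)."""

    sTL: float
    wTL: float
    tTL: float
    sessions_per_week: float
    weeks: int


@dataclass(frozen=True)
class ResponseRecord:
    """Per-participant training response over the 8-week program."""

    participant_id: str
    group: Group
    baseline_km: float
    delta_km: float
    pct_change: float
    responder: bool | None = None  # defined only within EG


def srpe_to_intensity(
    srpe: float, mapping: Callable[[float], float] | None = None
) -> float:
    """Map a CR-10 session RPE to estimated %VO2max.

    Default mapping is linear (sRPE x 10), so the prescribed sRPE band of
    6-7 corresponds to 60-70% VO2max.  A custom callable may be supplied.
    """
    if not 0 <= srpe <= 10:
        raise ValueError(f"sRPE {srpe} outside CR-10 range [0,10]")
    return (mapping or (lambda s: s * 10.0))(srpe)


def session_load(duration_min: float, intensity_pct: float) -> float:
    """Session training load: duration (min) x intensity (%VO2max), in A.U."""
    if duration_min <= 0:
        raise ValueError(f"duration must be positive, got {duration_min}")
    if intensity_pct <= 0:
        raise ValueError(f"intensity must be positive, got {intensity_pct}")
    return duration_min * intensity_pct


def weekly_load(session_loads: Sequence[float], sessions_per_week: int | None = None) -> float:
    """Weekly load: mean session load x number of sessions that week.

    With uniform sessions this reduces to the plain product sTL x count; the
    mean-based form also covers weeks whose sessions differ in duration.
    """
    if len(session_loads) == 0:
        raise ValueError("empty diary: no sessions in week")
    n = sessions_per_week if sessions_per_week is not None else len(session_loads)
    return float(np.mean(session_loads)) * n


def total_load(weekly_loads: Sequence[float], weeks: int | None = None) -> float:
    """Total program load.

    For a uniform program this is wTL x number of weeks; when weekly loads
    differ (taper weeks around test sessions) it sums the actual weekly
    loads, which coincides with the product in the uniform case.
    """
    if len(weekly_loads) == 0:
        raise ValueError("empty diary: no weeks")
    if weeks is not None and len(weekly_loads) == 1:
        return float(weekly_loads[0]) * weeks
    return float(np.sum(weekly_loads))


def training_load_summary(
    sessions: Iterable[TrainingSession],
    aggregate: Literal["per-participant", "pooled"] = "per-participant",
) -> TrainingLoadSummary:
    """Summarize a diary into mean sTL, mean wTL and tTL.

    ``per-participant`` (default) averages within each participant first and
    reports the mean of participant means; ``pooled`` pools all sessions.
    """
    df = pd.DataFrame(
        [
            {
                "pid": s.participant_id,
                "week": s.week,
                "load": session_load(s.duration_min, s.intensity_pct),
            }
            for s in sessions
        ]
    )
    if df.empty:
        raise ValueError("empty diary")

    def _one(sub: pd.DataFrame) -> tuple[float, float, float]:
        stl = sub["load"].mean()
        wtls = sub.groupby("week")["load"].agg(lambda x: x.mean() * len(x))
        return stl, wtls.mean(), wtls.sum()

    if aggregate == "pooled":
        stl, wtl, ttl = _one(df)
        n_weeks = df["week"].nunique()
    else:
        parts = [_one(sub) for _, sub in df.groupby("pid")]
        stl = float(np.mean([p[0] for p in parts]))
        wtl = float(np.mean([p[1] for p in parts]))
        ttl = float(np.mean([p[2] for p in parts]))
        n_weeks = df["week"].nunique()
    spw = len(df) / max(df["pid"].nunique() * n_weeks, 1)
    return TrainingLoadSummary(stl, wtl, ttl, sessions_per_week=spw, weeks=n_weeks)


def percent_change(baseline_km: float, followup_km: float) -> float:
    """Percent change from baseline: 100 x (followup - baseline) / baseline."""
    if baseline_km <= 0:
        raise ValueError(f"baseline must be positive, got {baseline_km}")
    return 100.0 * (followup_km - baseline_km) / baseline_km


def compute_responses(
    records: Iterable[CooperRecord],
    groups: dict[str, Group],
    baseline_week: int = 0,
    followup_week: int = 8,
) -> list[ResponseRecord]:
    """Build per-participant response records from Cooper-test records.

    Requires both a baseline and a follow-up record per participant;
    participants missing either are skipped with a warning.  Responder flags
    are filled in by :func:`dichotomize_responders`.
    """
    by_pid: dict[str, dict[int, CooperRecord]] = {}
    for rec in records:
        weeks = by_pid.setdefault(rec.participant_id, {})
        if rec.week in weeks:
            raise ValueError(f"duplicate Cooper record for {rec.participant_id} week {rec.week}")
        weeks[rec.week] = rec
    out = []
    for pid, weeks in by_pid.items():
        if pid not in groups:
            raise KeyError(f"participant {pid} has no group assignment")
        if baseline_week not in weeks or followup_week not in weeks:
            warnings.warn(f"participant {pid}: incomplete Cooper records, skipped", stacklevel=2)
            continue
        base = weeks[baseline_week].distance_km
        post = weeks[followup_week].distance_km
        out.append(
            ResponseRecord(
                participant_id=pid,
                group=groups[pid],
                baseline_km=base,
                delta_km=post - base,
                pct_change=percent_change(base, post),
            )
        )
    return dichotomize_responders(out)


def dichotomize_responders(responses: Sequence[ResponseRecord]) -> list[ResponseRecord]:
    """Classify training-group participants as responders / non-responders.

    A responder's percent Cooper improvement is strictly greater than the
    training-group mean of individual percent changes; ties and values at or
    below the mean are non-responders.  Control participants are never
    classified (``responder`` stays ``None``).
    """
    eg = [r for r in responses if r.group == "EG"]
    if len(eg) < 2:
        raise ValueError(f"need >=2 training-group participants to dichotomize, got {len(eg)}")
    mean_pct = float(np.mean([r.pct_change for r in eg]))
    if all(r.pct_change == eg[0].pct_change for r in eg):
        warnings.warn("all training-group changes identical: no responders", stacklevel=2)
    out = []
    for r in responses:
        if r.group == "EG":
            out.append(
                ResponseRecord(
                    r.participant_id, r.group, r.baseline_km, r.delta_km, r.pct_change,
                    responder=r.pct_change > mean_pct,
                )
            )
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# CSV interfaces


def read_phenotypes(path: str | Path) -> tuple[list[CooperRecord], dict[str, Group]]:
    """Phenotype CSV: participant_id,group,week,distance_km,srpe."""
    df = pd.read_csv(path, float_precision="round_trip")
    records = []
    groups: dict[str, Group] = {}
    for _, row in df.iterrows():
        pid = str(row["participant_id"])
        groups[pid] = row["group"]
        records.append(
            CooperRecord(
                participant_id=pid,
                week=int(row["week"]),
                distance_km=float(row["distance_km"]),
                srpe=float(row["srpe"]) if not pd.isna(row.get("srpe")) else None,
            )
        )
    return records, groups


def read_diary(path: str | Path) -> list[TrainingSession]:
    """Diary CSV: participant_id,week,session_index,duration_min,srpe."""
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        TrainingSession(
            participant_id=str(row["participant_id"]),
            week=int(row["week"]),
            duration_min=float(row["duration_min"]),
            srpe=float(row["srpe"]),
            intensity_pct=srpe_to_intensity(float(row["srpe"])),
        )
        for _, row in df.iterrows()
    ]
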