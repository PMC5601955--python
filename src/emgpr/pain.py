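"""Pain-outcome scoring: NRS, pain rating index, weighted pain
distribution, sleep, and longitudinal change summaries.

The pain rating index (PRI) is the sum of the per-descriptor scores of a
short-form pain questionnaire (15 descriptors by default, each scored 0-5
here; the scale maximum is configurable). The weighted pain distribution
(WPD) weights the pain levels 0-5 by the fraction of awake time spent at
each level: sum_k k * p_k, a scalar in [0, 5].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_DESCRIPTORS = 15
DESCRIPTOR_SCALE_MAX = 5
N_PAIN_LEVELS = 6  # levels 0..5


@dataclass
class PainAssessment:
    """One session's (or follow-up's) questionnaire-derived measurements."""

    tag: str  # session number or follow-up tag, e.g. "s01", "fu_1m"
    nrs: int
    descriptor_scores: list[int]
    wpd_distribution: list[float]  # proportions of awake time at levels 0..5
    hours_slept: float | None = None
    notes: str = ""
    scale_max: int = DESCRIPTOR_SCALE_MAX

    def __post_init__(self) -> None:
        if not (0 <= self.nrs <= 10):
            raise ValueError(f"nrs={self.nrs} outside [0, 10]")
        for s in self.descriptor_scores:
            if not (0 <= s <= self.scale_max):
                raise ValueError(f"descriptor score {s} outside [0, {self.scale_max}]")
        dist = np.asarray(self.wpd_distribution, dtype=float)
        if dist.size != N_PAIN_LEVELS:
            raise ValueError(f"wpd_distribution needs {N_PAIN_LEVELS} proportions")
        if (dist < 0).any():
            raise ValueError("wpd_distribution proportions must be >= 0")
        total = dist.sum()
        if abs(total - 1.0) > 1e-9:
            # accept percentages (or unnormalized input) and renormalize
            if total <= 0:
                raise ValueError("wpd_distribution must have positive mass")
            logger.info("normalizing wpd_distribution of %s (sum %.6g)", self.tag, total)
            dist = dist / total
        self.wpd_distribution = list(dist)
        if self.hours_slept is not None and not (0 <= self.hours_slept <= 24):
            raise ValueError(f"hours_slept={self.hours_slept} outside [0, 24]")


def pri(assessment: PainAssessment) -> int:
    """Pain rating index: sum of the individual descriptor scores."""
    if not assessment.descriptor_scores:
        raise ValueError("assessment has no descriptor scores")
    return int(sum(assessment.descriptor_scores))


def wpd(assessment: PainAssessment) -> float:
    """Weighted pain distribution: sum_k k * p_k over pain levels 0..5."""
    dist = np.asarray(assessment.wpd_distribution)
    return float(np.dot(np.arange(N_PAIN_LEVELS), dist))


@dataclass
class PainTimeline:
    """Ordered per-session assessments, follow-ups last."""

    sessions: list[PainAssessment]
    followups: list[PainAssessment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValueError("timeline needs at least one session")

    @property
    def all_assessments(self) -> list[PainAssessment]:
        return self.sessions + self.followups

    def series(self, metric: str) -> pd.Series:
        funcs = {"nrs": lambda a: a.nrs, "pri": pri, "wpd": wpd,
                 "hours_slept": lambda a: a.hours_slept}
        f = funcs[metric]
        return pd.Series({a.tag: f(a) for a in self.all_assessments}, name=metric)


def _one_change(first: float, last: float) -> dict[str, float | None]:
    change = first - last
    pct = 100.0 * change / first if first > 0 else None
    return {
        "first": first,
        "last": last,
        "change": change,
        "percent_change": pct,
        "percent_change_rounded": round(pct) if pct is not None else None,
    }


def change_summary(
    timeline: PainTimeline, metrics: tuple[str, ...] = ("nrs", "pri", "wpd")
) -> dict[str, dict[str, dict[str, float | None]]]:
    """Absolute and percent change per metric: first session vs last
    session, and first session vs each follow-up.

    Percent change is stored unrounded (rounded value included for
    presentation only); a zero baseline yields a missing percent.
    """
    if len(timeline.all_assessments) < 2:
        raise ValueError("need at least two assessments")
    out: dict[str, dict[str, dict[str, float | None]]] = {}
    for metric in metrics:
        s = timeline.series(metric)
        first_tag = timeline.sessions[0].tag
        last_tag = timeline.sessions[-1].tag
        entry = {}
        if len(timeline.sessions) >= 2:
            entry["last_session"] = _one_change(s[first_tag], s[last_tag])
        for fu in timeline.followups:
            entry[fu.tag] = _one_change(s[first_tag], s[fu.tag])
        out[metric] = entry
    return out


# --- CSV interchange --------------------------------------------------------

def _descriptor_cols(n: int) -> list[str]:
    return [f"descr_{i + 1}" for i in range(n)]


def _level_cols() -> list[str]:
    return [f"p_level_{k}" for k in range(N_PAIN_LEVELS)]


def timeline_to_csv(timeline: PainTimeline, path: str | Path) -> None:
    rows = []
    for a in timeline.all_assessments:
        row: dict = {"tag": a.tag, "followup": a in timeline.followups, "nrs": a.nrs}
        for col, s in zip(_descriptor_cols(len(a.descriptor_scores)), a.descriptor_scores):
            row[col] = s
        for col, p in zip(_level_cols(), a.wpd_distribution):
            row[col] = p
        row["hours_slept"] = a.hours_slept
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def timeline_from_csv(path: str | Path) -> PainTimeline:
    df = pd.read_csv(path)
    descr_cols = [c for c in df.columns if c.startswith("descr_")]
    sessions, followups = [], []
    for _, row in df.iterrows():
        a = PainAssessment(
            tag=str(row["tag"]),
            nrs=int(row["nrs"]),
            descriptor_scores=[int(row[c]) for c in descr_cols],
            wpd_distribution=[float(row[c]) for c in _level_cols()],
            hours_slept=None if pd.isna(row.get("hours_slept")) else float(row["hours_slept"]),
        )
        (followups if bool(row.get("followup", False)) else sessions).append(a)
    return PainTimeline(sessions=sessions, followups=followups)


def timeline_report(timeline: PainTimeline, path: str | Path) -> None:
    """JSON report: per-assessment derived metrics plus change summaries."""
    payload = {
        "per_assessment": [
            {"tag": a.tag, "nrs": a.nrs, "pri": pri(a), "wpd": wpd(a),
             "hours_slept": a.hours_slept}
            for a in timeline.all_assessments
        ],
        "changes": change_summary(timeline),
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=float))
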