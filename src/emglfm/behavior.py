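"""Behavioral outcomes of the chopsticks reach-to-place task.

Three session-level scores are extracted from the video-coded trial log:

* **GA** (grasping attempts): every chopstick–marble contact while trying to
  grab, including the successful one, so an ideal trial scores GA equal to
  the number of marbles and anything above that indexes inaccuracy.
* **FL** (failed liftings): marbles dropped during transport.
* **MD** (mean duration, s): the sum of the mean per-phase durations of the
  reach-to-place action.  Time spent failing to grasp (between the first
  contact and the successful grasp) and aborted transports are excluded, so
  MD is independent of GA and FL.

Improvement scores: per-session baseline correction (subtract S1) and the
standardized pre/post delta Δ = (S6 − S1)/(S6 + S1), a scale-free change
score that is negative when an error/duration metric improves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emg_processing import MarbleEvents, PhaseAnnotation

METRICS = ("ga", "fl", "md")


@dataclass
class TrialLog:
    """One subject's execution of one session: ordered per-marble events."""

    subject: str
    group: str
    session: int
    marbles: list = field(default_factory=list)

    def annotation(self) -> PhaseAnnotation:
        return PhaseAnnotation(self.marbles)

    def to_json_dict(self) -> dict:
        return {
            "subject": self.subject,
            "group": self.group,
            "session": self.session,
            "marbles": [
                {
                    "reach_start": m.reach_start,
                    "grasp_contact": m.grasp_contact,
                    "lift": m.lift,
                    "place": m.place,
                    "attempt_contacts": list(m.attempt_contacts),
                    "drops": list(m.drops),
                    "aborted_lifts": list(m.aborted_lifts),
                }
                for m in self.marbles
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TrialLog":
        return cls(
            subject=d["subject"],
            group=d["group"],
            session=int(d["session"]),
            marbles=[
                MarbleEvents(
                    reach_start=m["reach_start"],
                    grasp_contact=m["grasp_contact"],
                    lift=m["lift"],
                    place=m["place"],
                    attempt_contacts=list(m.get("attempt_contacts", [])),
                    drops=list(m.get("drops", [])),
                    aborted_lifts=list(m.get("aborted_lifts", [])),
                )
                for m in d["marbles"]
            ],
        )


@dataclass(frozen=True)
class SessionScores:
    subject: str
    group: str
    session: int
    ga: int
    fl: int
    md: float
    phase_means: dict

    def __post_init__(self) -> None:
        if self.fl < 0:
            raise ValueError("fl must be non-negative")
        if self.md <= 0:
            raise ValueError("md must be positive")


def compute_session_scores(log: TrialLog) -> SessionScores:
    """GA, FL and MD for one session's trial log.

    Per-marble phase durations: reaching runs from reach_start to the *first*
    contact (failed-grasp time is excluded), holding from the successful
    grasp to the first lifting, transport over the final successful
    lift-to-place interval.  MD is the sum of the three phase means.
    """
    if not log.marbles:
        raise ValueError("trial log contains no marbles")
    ga = 0
    fl = 0
    reach, hold, transport = [], [], []
    for m in log.marbles:
        ga += max(1, len(m.attempt_contacts))  # the successful contact counts
        fl += len(m.drops)
        reach.append(m.first_contact - m.reach_start)
        first_lift = min([m.lift] + list(m.aborted_lifts))
        hold.append(first_lift - m.grasp_contact)
        transport.append(m.place - m.lift)
    phase_means = {
        "reaching": float(np.mean(reach)),
        "holding": float(np.mean(hold)),
        "transport": float(np.mean(transport)),
    }
    md = float(sum(phase_means.values()))
    return SessionScores(log.subject, log.group, log.session, ga, fl, md, phase_means)


def session_table(logs) -> pd.DataFrame:
    """Tidy table (subject, group, session, ga, fl, md, per-phase means)."""
    rows = []
    for log in logs:
        s = compute_session_scores(log)
        rows.append(
            {
                "subject": s.subject,
                "group": s.group,
                "session": s.session,
                "ga": s.ga,
                "fl": s.fl,
                "md": s.md,
                **{f"mean_{k}_s": v for k, v in s.phase_means.items()},
            }
        )
    return pd.DataFrame(rows)


def baseline_correct(scores: pd.DataFrame, metrics=METRICS, baseline_session: int = 1) -> pd.DataFrame:
    """Subtract each subject's S1 score from every session's score.

    Returns a copy with added ``<metric>_corrected`` columns; the corrected
    baseline session is identically zero.
    """
    out = scores.copy()
    base = scores[scores["session"] == baseline_session].set_index("subject")
    if base.empty:
        raise ValueError(f"baseline session {baseline_session} missing")
    missing = set(scores["subject"]) - set(base.index)
    if missing:
        raise ValueError(f"subjects without baseline session: {sorted(missing)}")
    for metric in metrics:
        out[f"{metric}_corrected"] = (
            scores[metric].to_numpy()
            - base.loc[scores["subject"], metric].to_numpy()
        ).astype(float)
    return out


def standardized_improvement(s1_score: float, s6_score: float) -> float:
    """Standardized pre/post change Δ = (S6 − S1)/(S6 + S1).

    Bounded in [−1, 1] for non-negative metrics; negative values mean
    improvement for error counts and durations.
    """
    total = s1_score + s6_score
    if total <= 0:
        raise ValueError("Δ undefined: S1 + S6 must be positive")
    return (s6_score - s1_score) / total


def delta_table(scores: pd.DataFrame, metrics=METRICS, first: int = 1, last: int = 6) -> pd.DataFrame:
    """Per-subject standardized Δ for each behavioral metric."""
    wide = scores.pivot_table(index=["subject", "group"], columns="session", values=list(metrics))
    rows = []
    for (subject, group), row in wide.iterrows():
        rec = {"subject": subject, "group": group}
        for metric in metrics:
            s1, s6 = row[(metric, first)], row[(metric, last)]
            if np.isnan(s1) or np.isnan(s6):
                raise ValueError(f"{subject}: missing session {first} or {last} for {metric}")
            total = s1 + s6
            rec[f"delta_{metric}"] = np.nan if total <= 0 else (s6 - s1) / total
        rows.append(rec)
    return pd.DataFrame(rows)
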