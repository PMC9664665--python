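"""Serial risk tracking across BPA sessions.

A cohort is carried as two tidy tables: an *assessments* table (one row per
patient, session, pre/post timing) and an *events* table (one row per
clinical-worsening event). Scoring every assessment under all six policies
yields a *risk table*; the operations here consume that risk table to
produce transition matrices, improvement fractions, stratum-elimination
sessions, endpoint attainment and sessions-to-endpoint summaries.

Time is measured in months from the first BPA session, converting dates at
30.4375 days per month; administrative censoring is at the configured study
end date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyCohort,
    PolicyError,
    TimelineError,
    ValidationError,
)
from .scoring import Assessment, round_half_up, score_assessment
from .stratification import (
    POLICY_NAMES,
    StratumPolicy,
    load_policies,
    stratum_rank,
)

__all__ = [
    "EventRecord",
    "PatientTimeline",
    "TransitionMatrix",
    "score_cohort",
    "detect_unsatisfactory_response",
    "first_clinical_worsening",
    "build_survival_table",
    "transition_matrix",
    "stratum_elimination_session",
    "sessions_to_endpoint",
    "contingency_percentages",
]

EVENT_TYPES = ("death", "ph_hospitalization", "unsatisfactory_response", "rhf_worsening")


@dataclass(frozen=True)
class EventRecord:
    patient_id: str
    type: str
    time: float  # months from first BPA session
    observed: bool = True

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.type!r}")


@dataclass
class PatientTimeline:
    """Events and follow-up horizon for one patient."""

    patient_id: str
    events: list[EventRecord] = field(default_factory=list)
    follow_up_months: float | None = None


def months_between(start: str | pd.Timestamp, end: str | pd.Timestamp,
                   days_per_month: float = 30.4375) -> float:
    return (pd.Timestamp(end) - pd.Timestamp(start)).days / days_per_month


# ---------------------------------------------------------------------------
# Cohort scoring
# ---------------------------------------------------------------------------

def score_cohort(assessments: pd.DataFrame, config: Mapping[str, Any]) -> pd.DataFrame:
    """Score every assessment row under both granularities and all policies.

    Returns the risk table: one row per (patient, session, timing) with
    ``score_3s``/``score_4s`` mean scores and a label plus rank column per
    policy (``original-4S`` / ``rank_original-4S`` ...).
    """
    policies = load_policies(config)
    dup = assessments.duplicated(subset=["patient_id", "session_index", "timing"])
    if dup.any():
        raise ValidationError("duplicate (patient, session, timing) assessment rows")
    opt_cols = [c for c in ("nt_probnp", "bnp", "mpap", "date") if c in assessments.columns]
    rows = []
    for rec in assessments.to_dict("records"):
        a = Assessment(
            patient_id=str(rec["patient_id"]),
            session_index=int(rec["session_index"]),
            timing=str(rec["timing"]),
            who_fc=None if pd.isna(rec.get("who_fc")) else int(rec["who_fc"]),
            six_mwd=None if pd.isna(rec.get("six_mwd")) else float(rec["six_mwd"]),
            nt_probnp=None if pd.isna(rec.get("nt_probnp")) else float(rec["nt_probnp"]),
            bnp=None if pd.isna(rec.get("bnp")) else float(rec.get("bnp")),
        )
        s3 = score_assessment(a, config, 3)
        s4 = score_assessment(a, config, 4)
        row = {
            "patient_id": a.patient_id,
            "session_index": a.session_index,
            "timing": a.timing,
            "score_3s": s3.mean_score,
            "score_4s": s4.mean_score,
            "peptide_used": s4.peptide_used,
        }
        for c in opt_cols:
            row[c] = rec.get(c)
        for name, pol in policies.items():
            score = s3 if pol.granularity == 3 else s4
            from .stratification import stratify

            label = stratify(score, pol)
            row[name] = label
            row[f"rank_{name}"] = stratum_rank(label, pol.granularity)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Endpoints
# ---------------------------------------------------------------------------

def detect_unsatisfactory_response(
    baseline_ntprobnp: float,
    followup_ntprobnp: float,
    *,
    relative_factor: float = 2.0,
    absolute_threshold: float = 1800.0,
) -> bool:
    """Unsatisfactory long-term clinical response: NT-proBNP rose by 100%
    or to >= 1800 ng/L from baseline to follow-up."""
    if baseline_ntprobnp <= 0 or followup_ntprobnp <= 0:
        raise ValidationError("NT-proBNP values must be positive")
    return (
        followup_ntprobnp >= relative_factor * baseline_ntprobnp
        or followup_ntprobnp >= absolute_threshold
    )


def first_clinical_worsening(timeline: PatientTimeline) -> tuple[float, bool]:
    """Time to the first clinical-worsening event, or censoring at study end.

    Returns ``(time_months, observed)``.
    """
    if timeline.follow_up_months is None:
        raise TimelineError(f"{timeline.patient_id}: no baseline/follow-up horizon")
    horizon = float(timeline.follow_up_months)
    if horizon < 0:
        raise TimelineError(f"{timeline.patient_id}: negative follow-up horizon")
    obs_times = []
    for ev in timeline.events:
        if ev.time < 0:
            raise TimelineError(f"{timeline.patient_id}: event at negative time")
        if ev.observed and ev.time <= horizon:
            obs_times.append(ev.time)
    if obs_times:
        return (min(obs_times), True)
    return (horizon, False)


def build_survival_table(
    events: pd.DataFrame,
    follow_up: Mapping[str, float],
) -> pd.DataFrame:
    """Per-patient (time, observed) for the composite endpoint.

    ``events`` needs columns patient_id, event_type, time_months;
    ``follow_up`` maps every patient to the administrative censoring time.
    """
    timelines: dict[str, PatientTimeline] = {
        str(pid): PatientTimeline(str(pid), [], float(h)) for pid, h in follow_up.items()
    }
    for rec in events.to_dict("records"):
        pid = str(rec["patient_id"])
        if pid not in timelines:
            continue
        timelines[pid].events.append(
            EventRecord(pid, str(rec["event_type"]), float(rec["time_months"]))
        )
    rows = []
    for pid, tl in timelines.items():
        t, obs = first_clinical_worsening(tl)
        rows.append({"patient_id": pid, "time_months": t, "observed": obs})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionMatrix:
    """Counts of patients flowing between strata across two timepoints."""

    policy: str
    labels: tuple[str, ...]
    counts: pd.DataFrame  # rows = stratum at A, columns = stratum at B
    n: int
    improved: int
    unchanged: int
    worsened: int
    improved_multi: int  # moves of 2+ strata downward

    def to_edges(self) -> pd.DataFrame:
        """Sankey-ready (source, target, count) edge list."""
        rows = [
            {"source": a, "target": b, "count": int(self.counts.loc[a, b])}
            for a in self.labels
            for b in self.labels
            if self.counts.loc[a, b] > 0
        ]
        return pd.DataFrame(rows, columns=["source", "target", "count"])


def _timepoint_frame(risk: pd.DataFrame, timepoint: tuple[int, str]) -> pd.DataFrame:
    session, timing = timepoint
    sub = risk[(risk["session_index"] == session) & (risk["timing"] == timing)]
    return sub.set_index("patient_id")


def transition_matrix(
    risk: pd.DataFrame,
    policy_name: str,
    timepoint_a: tuple[int, str],
    timepoint_b: tuple[int, str],
) -> TransitionMatrix:
    """Stratum flows between two timepoints under one policy.

    Patients lacking either timepoint are excluded (complete-case per
    timepoint). ``improved`` counts any decrease in stratum rank.
    """
    if policy_name not in POLICY_NAMES:
        raise PolicyError(f"unknown policy {policy_name!r}")
    gran = 3 if policy_name.endswith("3S") else 4
    labels = ("low", "intermediate", "high") if gran == 3 else (
        "low", "intermediate-low", "intermediate-high", "high")
    fa = _timepoint_frame(risk, timepoint_a)
    fb = _timepoint_frame(risk, timepoint_b)
    common = fa.index.intersection(fb.index)
    if len(common) == 0:
        raise EmptyCohort(
            f"no patients with both timepoints {timepoint_a} and {timepoint_b}"
        )
    la = fa.loc[common, policy_name]
    lb = fb.loc[common, policy_name]
    counts = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)
    for a, b in zip(la, lb):
        counts.loc[a, b] += 1
    ra = la.map(lambda s: stratum_rank(s, gran)).to_numpy()
    rb = lb.map(lambda s: stratum_rank(s, gran)).to_numpy()
    return TransitionMatrix(
        policy=policy_name,
        labels=labels,
        counts=counts,
        n=len(common),
        improved=int(np.sum(rb < ra)),
        unchanged=int(np.sum(rb == ra)),
        worsened=int(np.sum(rb > ra)),
        improved_multi=int(np.sum(ra - rb >= 2)),
    )


def stratum_elimination_session(
    risk: pd.DataFrame,
    policy_name: str,
    stratum: str,
    *,
    mode: str = "evaluated_only",
) -> int | None:
    """Smallest session index whose pre-session evaluation has no patient in
    ``stratum``; ``None`` if the stratum persists through every session.

    ``mode='evaluated_only'`` counts only patients assessed at that session;
    ``mode='carry_last'`` carries each patient's last known stratum forward
    to sessions they did not attend.
    """
    if policy_name not in POLICY_NAMES:
        raise PolicyError(f"unknown policy {policy_name!r}")
    gran = 3 if policy_name.endswith("3S") else 4
    stratum_rank(stratum, gran)  # validates the label
    if mode not in ("evaluated_only", "carry_last"):
        raise ValidationError(f"unknown mode {mode!r}")

    pre = risk[risk["timing"] == "pre"]
    if pre.empty:
        raise EmptyCohort("no pre-session assessments")
    max_session = int(pre["session_index"].max())
    last_label: dict[str, str] = {}
    for session in range(1, max_session + 1):
        here = pre[pre["session_index"] == session]
        observed = dict(zip(here["patient_id"], here[policy_name]))
        if mode == "carry_last":
            last_label.update(observed)
            labels = last_label.values()
        else:
            labels = observed.values()
        if labels and stratum not in labels:
            return session
    return None


# ---------------------------------------------------------------------------
# Sessions to endpoint
# ---------------------------------------------------------------------------

def sessions_to_endpoint(
    risk: pd.DataFrame,
    policy_name: str,
    endpoint: str,
    *,
    mpap_threshold: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Number of BPA sessions needed to reach an endpoint, by baseline stratum.

    ``endpoint='low_risk'``: first time the patient scores low risk at any
    assessment after the first BPA (post of session k counts as k sessions,
    pre of session k as k-1). Only patients above low risk at baseline are
    eligible.

    ``endpoint='mpap_lt_threshold'``: first pre-session right-heart
    catheterization (session k >= 2, i.e. k-1 sessions received) with mPAP
    below the threshold. Only patients with baseline mPAP >= threshold are
    eligible.

    Returns ``(per_patient, summary)``; the summary holds n, attainment
    count and median/IQR sessions per baseline stratum, with non-attainers
    reported separately.
    """
    if policy_name not in POLICY_NAMES:
        raise PolicyError(f"unknown policy {policy_name!r}")
    if endpoint not in ("low_risk", "mpap_lt_threshold"):
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    gran = 3 if policy_name.endswith("3S") else 4

    baseline = _timepoint_frame(risk, (1, "pre"))
    if baseline.empty:
        raise EmptyCohort("no baseline (pre session 1) assessments")

    per_patient_rows = []
    for pid, base in baseline.iterrows():
        base_label = base[policy_name]
        follow = risk[(risk["patient_id"] == pid)]
        if endpoint == "low_risk":
            if base_label == "low":
                continue  # already at target; not eligible
            hits = []
            for rec in follow.to_dict("records"):
                if rec["session_index"] == 1 and rec["timing"] == "pre":
                    continue
                if rec[policy_name] == "low":
                    k = rec["session_index"] - (1 if rec["timing"] == "pre" else 0)
                    hits.append(max(k, 1))
        else:
            if "mpap" not in risk.columns or pd.isna(base.get("mpap")):
                continue
            if float(base["mpap"]) < mpap_threshold:
                continue
            reassessed = follow[
                (follow["timing"] == "pre")
                & (follow["session_index"] >= 2)
                & follow["mpap"].notna()
            ]
            if reassessed.empty:
                continue  # never returned for reevaluation
            hits = [
                int(rec["session_index"]) - 1
                for rec in reassessed.to_dict("records")
                if float(rec["mpap"]) < mpap_threshold
            ]
        per_patient_rows.append(
            {
                "patient_id": pid,
                "baseline_stratum": base_label,
                "attained": bool(hits),
                "sessions": min(hits) if hits else np.nan,
            }
        )
    per_patient = pd.DataFrame(
        per_patient_rows,
        columns=["patient_id", "baseline_stratum", "attained", "sessions"],
    )
    if per_patient.empty:
        raise EmptyCohort(f"no eligible patients for endpoint {endpoint!r}")

    labels = ("low", "intermediate", "high") if gran == 3 else (
        "low", "intermediate-low", "intermediate-high", "high")
    summary_rows = []
    for lab in labels:
        grp = per_patient[per_patient["baseline_stratum"] == lab]
        if grp.empty:
            continue
        att = grp[grp["attained"]]
        summary_rows.append(
            {
                "baseline_stratum": lab,
                "n": len(grp),
                "n_attained": len(att),
                "pct_attained": contingency_percentages([(len(att), len(grp))])[0],
                "median_sessions": float(att["sessions"].median()) if len(att) else np.nan,
                "q1_sessions": float(att["sessions"].quantile(0.25)) if len(att) else np.nan,
                "q3_sessions": float(att["sessions"].quantile(0.75)) if len(att) else np.nan,
                "n_non_attainers": int(len(grp) - len(att)),
            }
        )
    return per_patient, pd.DataFrame(summary_rows)


def contingency_percentages(counts: Sequence[tuple[int, int]]) -> list[float]:
    """100*events/n, rounded half-up to one decimal, per (events, n) pair."""
    out = []
    for events, n in counts:
        if n <= 0:
            raise ValidationError("denominator must be positive")
        if not 0 <= events <= n:
            raise ValidationError(f"events {events} outside [0, {n}]")
        out.append(round_half_up(100.0 * events / n, 1))
    return out
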