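"""Cohort I/O, validation, and end-to-end report assembly.

Tables travel as plain CSV. The pipeline reproduces the analysis sequence
of a serial risk-stratification study: scoring, stratification under all
six policies, baseline mixture, first-session transition matrices,
discrimination (Harrell's C on stratum rank and on the continuous mean
score), crude proportional-hazards tables, endpoint attainment and
sessions-to-endpoint summaries. Every percentage is reported next to its
numerator and denominator.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import longitudinal as lg
from . import survstats as ss
from .config import config_hash, default_config
from .errors import ComperaError, FitError, ParseError, ValidationError
from .stratification import POLICY_NAMES, load_policies
from .synthetic_cohort import SyntheticCohort

__all__ = [
    "read_assessments",
    "read_events",
    "read_patients",
    "write_table",
    "validate_cohort",
    "run_pipeline",
    "render_report",
]

_ASSESSMENT_COLS = ("patient_id", "session_index", "timing")
_EVENT_COLS = ("patient_id", "event_type")
_DISPLAY = {"who_fc": "WHO-FC", "six_mwd": "6MWD", "peptide": "NT-proBNP"}


def _read_csv(path: str, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}", line=1)
    return df


def read_assessments(path: str) -> pd.DataFrame:
    df = _read_csv(path, _ASSESSMENT_COLS)
    dup = df.duplicated(subset=["patient_id", "session_index", "timing"])
    if dup.any():
        raise ParseError(
            "duplicate (patient, session, timing) assessment row",
            line=int(dup.idxmax()) + 2,  # header + 1-based
        )
    bad = ~df["timing"].isin(["pre", "post"])
    if bad.any():
        raise ParseError("timing must be 'pre' or 'post'", line=int(bad.idxmax()) + 2)
    return df


def read_events(path: str) -> pd.DataFrame:
    return _read_csv(path, _EVENT_COLS)


def read_patients(path: str) -> pd.DataFrame:
    return _read_csv(path, ("patient_id",))


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation / eligibility
# ---------------------------------------------------------------------------

def validate_cohort(
    assessments: pd.DataFrame,
    events: pd.DataFrame | None = None,
    patients: pd.DataFrame | None = None,
    config: Mapping[str, Any] | None = None,
) -> dict[str, Any]:
    """Per-patient eligibility flags with exclusion reasons.

    Exclusion rules mirror a registry analysis: a missing scored variable
    at baseline, no baseline assessment, no follow-up information, surgery
    (PEA) during follow-up, or procedural in-hospital death (the latter two
    via optional boolean columns on the patients table).
    """
    cfg = config or default_config()
    ids: list[str] = list(
        pd.unique(
            pd.concat(
                [
                    assessments["patient_id"].astype(str),
                    (patients["patient_id"].astype(str) if patients is not None else pd.Series(dtype=str)),
                ]
            )
        )
    )
    baseline = assessments[
        (assessments["session_index"] == 1) & (assessments["timing"] == "pre")
    ].set_index(assessments.loc[
        (assessments["session_index"] == 1) & (assessments["timing"] == "pre"),
        "patient_id",
    ].astype(str))

    pmeta = patients.set_index(patients["patient_id"].astype(str)) if patients is not None else None

    per_patient: dict[str, list[str]] = {}
    for pid in ids:
        reasons: list[str] = []
        if pid not in baseline.index:
            reasons.append("no_baseline")
        else:
            row = baseline.loc[pid]
            for var in ("who_fc", "six_mwd"):
                if var not in baseline.columns or pd.isna(row.get(var)):
                    reasons.append(f"missing_variable:{_DISPLAY[var]}")
            has_nt = "nt_probnp" in baseline.columns and not pd.isna(row.get("nt_probnp"))
            has_bnp = "bnp" in baseline.columns and not pd.isna(row.get("bnp"))
            if not (has_nt or has_bnp):
                reasons.append(f"missing_variable:{_DISPLAY['peptide']}")
        if pmeta is not None and pid in pmeta.index:
            prow = pmeta.loc[pid]
            if "follow_up_months" in pmeta.columns and pd.isna(prow.get("follow_up_months")):
                reasons.append("no_followup")
            if bool(prow.get("pea_at_followup", False)):
                reasons.append("pea_at_followup")
            if bool(prow.get("in_hospital_death", False)):
                reasons.append("in_hospital_death")
        per_patient[pid] = reasons

    excluded = {pid: r for pid, r in per_patient.items() if r}
    counts: dict[str, int] = {}
    for reasons in excluded.values():
        for r in reasons:
            counts[r] = counts.get(r, 0) + 1
    return {
        "n_total": len(ids),
        "eligible": sorted(pid for pid, r in per_patient.items() if not r),
        "excluded": excluded,
        "exclusion_counts": counts,
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, ComperaError):
                raise type(exc)(f"[stage: {name}] {exc}") from exc
            return False

    return _Ctx()


def _follow_up_map(
    patients: pd.DataFrame | None,
    assessments: pd.DataFrame,
    cfg: Mapping[str, Any],
) -> dict[str, float]:
    """Months from first BPA session to administrative study end."""
    if patients is not None and "follow_up_months" in patients.columns:
        return {
            str(pid): float(m)
            for pid, m in zip(patients["patient_id"], patients["follow_up_months"])
            if not pd.isna(m)
        }
    if "date" not in assessments.columns:
        raise ValidationError("need patients.follow_up_months or assessment dates")
    base = assessments[
        (assessments["session_index"] == 1) & (assessments["timing"] == "pre")
    ]
    end = cfg["endpoints"]["study_end"]
    dpm = cfg["endpoints"]["days_per_month"]
    return {
        str(pid): lg.months_between(d, end, dpm)
        for pid, d in zip(base["patient_id"], base["date"])
    }


def run_pipeline(
    assessments: pd.DataFrame,
    events: pd.DataFrame,
    patients: pd.DataFrame | None = None,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Score, stratify and analyze a cohort; return the report bundle."""
    cfg = dict(config) if config is not None else default_config()
    report: dict[str, Any] = {
        "provenance": {
            "config_hash": config_hash(cfg),
            "input_hashes": {
                "assessments": _df_hash(assessments),
                "events": _df_hash(events),
                "patients": _df_hash(patients) if patients is not None else None,
            },
            "seed": seed,
        }
    }

    with _stage("validation"):
        validation = validate_cohort(assessments, events, patients, cfg)
        report["validation"] = {
            "n_total": validation["n_total"],
            "n_eligible": len(validation["eligible"]),
            "exclusion_counts": validation["exclusion_counts"],
        }
        eligible = set(validation["eligible"])
        assessments = assessments[assessments["patient_id"].astype(str).isin(eligible)]
        events = events[events["patient_id"].astype(str).isin(eligible)]
        if patients is not None:
            patients = patients[patients["patient_id"].astype(str).isin(eligible)]

    with _stage("scoring"):
        risk = lg.score_cohort(assessments, cfg)

    with _stage("baseline"):
        base = risk[(risk["session_index"] == 1) & (risk["timing"] == "pre")]
        n_base = len(base)
        baseline_tab = {}
        for pol in POLICY_NAMES:
            counts = base[pol].value_counts().to_dict()
            labels = load_policies(cfg)[pol].labels
            baseline_tab[pol] = {
                lab: {
                    "n": int(counts.get(lab, 0)),
                    "denominator": n_base,
                    "pct": lg.contingency_percentages(
                        [(int(counts.get(lab, 0)), n_base)]
                    )[0],
                }
                for lab in labels
            }
        report["baseline"] = {"n": n_base, "by_policy": baseline_tab}

    with _stage("survival_table"):
        fu = _follow_up_map(patients, assessments, cfg)
        fu = {pid: m for pid, m in fu.items() if pid in set(base["patient_id"].astype(str))}
        if "time_months" not in events.columns:
            first_dates = _first_session_dates(assessments)
            dpm = cfg["endpoints"]["days_per_month"]
            events = events.assign(
                time_months=[
                    lg.months_between(first_dates[str(p)], d, dpm)
                    for p, d in zip(events["patient_id"], events["date"])
                ]
            )
        surv = lg.build_survival_table(events, fu)
        n_events = int(surv["observed"].sum())
        report["clinical_worsening"] = {
            "n": len(surv),
            "events": n_events,
            "pct": lg.contingency_percentages([(n_events, len(surv))])[0]
            if len(surv)
            else None,
        }

    with _stage("transitions"):
        trans = {}
        for pol in POLICY_NAMES:
            try:
                tm = lg.transition_matrix(risk, pol, (1, "pre"), (1, "post"))
            except ComperaError:
                continue
            trans[pol] = {
                "n": tm.n,
                "improved": tm.improved,
                "improved_pct": lg.contingency_percentages([(tm.improved, tm.n)])[0],
                "unchanged": tm.unchanged,
                "worsened": tm.worsened,
                "improved_multi": tm.improved_multi,
                "matrix": {a: {b: int(tm.counts.loc[a, b]) for b in tm.labels} for a in tm.labels},
                "edges": tm.to_edges().to_dict("records"),
            }
        report["first_session_transitions"] = trans

    with _stage("discrimination"):
        merged = surv.merge(
            base[["patient_id"] + [f"rank_{p}" for p in POLICY_NAMES] + ["score_3s", "score_4s"]],
            on="patient_id",
        )
        post1 = risk[(risk["session_index"] == 1) & (risk["timing"] == "post")]
        merged_post = surv.merge(
            post1[["patient_id"] + [f"rank_{p}" for p in POLICY_NAMES] + ["score_3s", "score_4s"]],
            on="patient_id",
        )
        cindex: dict[str, Any] = {}
        for pol in POLICY_NAMES:
            entry = {}
            for label, frame in (("baseline", merged), ("after_first_bpa", merged_post)):
                try:
                    on_rank = ss.harrell_c(
                        frame["time_months"], frame["observed"], frame[f"rank_{pol}"]
                    ).c_index
                    score_col = "score_3s" if pol.endswith("3S") else "score_4s"
                    on_score = ss.harrell_c(
                        frame["time_months"], frame["observed"], frame[score_col]
                    ).c_index
                    entry[label] = {
                        "c_on_stratum_rank": round(on_rank, 3),
                        "c_on_mean_score": round(on_score, 3),
                        "n": len(frame),
                    }
                except ComperaError:
                    entry[label] = None
            cindex[pol] = entry
        report["harrell_c"] = cindex

    with _stage("cox"):
        cox = {}
        for pol in ("original-4S", "hybrid-4S"):
            try:
                tab = ss.fit_proportional_hazards(
                    merged.rename(columns={f"rank_{pol}": "stratum_rank"}),
                    "time_months",
                    "observed",
                    "stratum_rank",
                )
                cox[pol] = tab.to_dict("records")
            except (FitError, ValidationError) as exc:
                cox[pol] = {"error": str(exc)}
        report["cox_baseline"] = cox

    with _stage("attainment"):
        att = {}
        for pol in ("original-4S", "hybrid-4S"):
            entry = {}
            for endpoint in ("low_risk", "mpap_lt_threshold"):
                try:
                    per_patient, summary = lg.sessions_to_endpoint(
                        risk, pol, endpoint,
                        mpap_threshold=cfg["endpoints"]["mpap_threshold"],
                    )
                    n_elig = len(per_patient)
                    n_att = int(per_patient["attained"].sum())
                    entry[endpoint] = {
                        "n_eligible": n_elig,
                        "n_attained": n_att,
                        "pct_attained": lg.contingency_percentages([(n_att, n_elig)])[0],
                        "by_baseline_stratum": summary.replace({np.nan: None}).to_dict("records"),
                    }
                except ComperaError as exc:
                    entry[endpoint] = {"error": str(exc)}
            att[pol] = entry
        report["attainment"] = att

    with _stage("elimination"):
        elim = {}
        for pol in POLICY_NAMES:
            try:
                elim[pol] = {
                    "evaluated_only": lg.stratum_elimination_session(
                        risk, pol, "high", mode="evaluated_only"
                    ),
                    "carry_last": lg.stratum_elimination_session(
                        risk, pol, "high", mode="carry_last"
                    ),
                }
            except ComperaError:
                elim[pol] = None
        report["high_risk_elimination_session"] = elim

    return report


def _first_session_dates(assessments: pd.DataFrame) -> dict[str, str]:
    base = assessments[
        (assessments["session_index"] == 1) & (assessments["timing"] == "pre")
    ]
    return {str(p): d for p, d in zip(base["patient_id"], base["date"])}


def _df_hash(df: pd.DataFrame | None) -> str | None:
    if df is None:
        return None
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.Timestamp,)):
        return o.isoformat()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def report_to_json(report: Mapping[str, Any]) -> str:
    return json.dumps(report, indent=2, default=_json_default, allow_nan=True)


def render_report(report: Mapping[str, Any]) -> str:
    """Human-readable text summary of a pipeline report."""
    lines = []
    prov = report["provenance"]
    lines.append("COMPERA 2.0 serial risk-stratification report")
    lines.append(f"config {prov['config_hash']}  seed {prov['seed']}")
    v = report["validation"]
    lines.append(
        f"patients: {v['n_eligible']}/{v['n_total']} eligible; "
        f"exclusions: {v['exclusion_counts'] or 'none'}"
    )
    cw = report["clinical_worsening"]
    lines.append(
        f"clinical worsening: {cw['events']}/{cw['n']} ({cw['pct']}%)"
    )
    lines.append("")
    lines.append("baseline strata (n/denominator, %):")
    for pol, tab in report["baseline"]["by_policy"].items():
        cells = ", ".join(
            f"{lab} {d['n']}/{d['denominator']} ({d['pct']}%)" for lab, d in tab.items()
        )
        lines.append(f"  {pol}: {cells}")
    lines.append("")
    lines.append("improvement after the first BPA session:")
    for pol, t in report["first_session_transitions"].items():
        lines.append(
            f"  {pol}: improved {t['improved']}/{t['n']} ({t['improved_pct']}%), "
            f"unchanged {t['unchanged']}, worsened {t['worsened']}"
        )
    lines.append("")
    lines.append("Harrell's C (on stratum rank / on mean score):")
    for pol, entry in report["harrell_c"].items():
        cells = []
        for tp in ("baseline", "after_first_bpa"):
            d = entry.get(tp)
            cells.append(
                f"{tp} {d['c_on_stratum_rank']:.3f}/{d['c_on_mean_score']:.3f}"
                if d
                else f"{tp} n/a"
            )
        lines.append(f"  {pol}: " + ", ".join(cells))
    return "\n".join(lines) + "\n"


def write_cohort(cohort: SyntheticCohort, out_dir: str) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)
    write_table(cohort.assessments, os.path.join(out_dir, "assessments.csv"))
    write_table(cohort.events, os.path.join(out_dir, "events.csv"))
    write_table(cohort.patients, os.path.join(out_dir, "patients.csv"))
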