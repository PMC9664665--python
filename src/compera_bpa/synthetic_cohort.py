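"""Synthetic BPA cohort generator.

Emulates the statistical structure the analysis pipeline assumes for a
serially assessed CTEPH cohort treated with staged balloon pulmonary
angioplasty:

* a baseline mixture over the four original-4S risk strata;
* per-stratum covariate models — WHO-FC categorical weights, 6MWD normal,
  NT-proBNP log-normal (parameterized from a median and IQR), mPAP normal;
* covariates drawn *stratum-first*: a point combination consistent with the
  target stratum is chosen with probability proportional to its mass under
  the stratum's covariate distributions, then each covariate is drawn from
  its distribution truncated to the chosen cutoff bin. The generated
  assessment therefore scores into its target stratum by construction, and
  the generating stratum is recoverable;
* per-session stratum dynamics: each BPA session improves the stratum by
  one rank with probability ``p_improve`` (two ranks with a further
  conditional probability), worsens it with probability ``p_worsen``,
  otherwise leaves it unchanged;
* clinical-worsening events from a piecewise-exponential hazard that
  follows the *current* (time-varying) stratum, strictly increasing in
  stratum rank; administrative censoring at the configured study-end date;
* an mPAP trajectory dropping roughly linearly per session with noise (a
  generator convention — the hemodynamic response endpoint needs one).

A single global seed drives per-patient substreams
(``SeedSequence(seed, spawn_key=(i,))``), so subsetting patients does not
perturb the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import default_config
from .errors import ConfigError, DegenerateSample
from .scoring import round_half_up
from .stratification import StratumPolicy, stratify

__all__ = ["SyntheticCohort", "generate_cohort", "recover_parameters"]

_Z75 = 0.6744897501960817  # 75th normal percentile; IQR -> sigma


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated tables: serial assessments, events, per-patient metadata."""

    assessments: pd.DataFrame
    events: pd.DataFrame
    patients: pd.DataFrame
    config: dict


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    if not 0 < q1 < median < q3:
        raise ConfigError(f"inconsistent median/IQR: {median} ({q1}, {q3})")
    mu = np.log(median)
    sigma = np.log(q3 / q1) / (2.0 * _Z75)
    return mu, sigma


def _bin_bounds(b: Mapping[str, Any]) -> tuple[float, float]:
    lo = -np.inf if b["min"] is None else float(b["min"])
    hi = np.inf if b["max"] is None else float(b["max"])
    return lo, hi


class _StratumSampler:
    """Draws one stratum's covariate triple consistent with its bins."""

    def __init__(self, config: Mapping[str, Any], stratum_idx: int,
                 policy: StratumPolicy):
        gen = config["generator"]
        cov = gen["covariates"]
        cut = config["cutoffs"]["4"] if "4" in config["cutoffs"] else config["cutoffs"][4]
        self.target = policy.labels[stratum_idx]

        fc_w = {int(k): float(v) for k, v in cov["who_fc_weights"][stratum_idx].items()}
        total = sum(fc_w.values())
        if total <= 0:
            raise ConfigError(f"no WHO-FC mass for stratum {self.target}")
        self.fc_weights = {k: v / total for k, v in fc_w.items()}

        # values are emitted at one-decimal resolution; draws keep this
        # margin inside each bin so rounding cannot cross a cutoff
        self.margin = 0.06
        m6 = cov["six_mwd_normal"][stratum_idx]
        self.mwd = (float(m6["mean"]), float(m6["sd"]))
        nt = cov["nt_probnp_lognormal_median_iqr"][stratum_idx]
        self.nt = _lognormal_params(nt["median"], nt["q1"], nt["q3"])
        mp = cov["mpap_normal"][stratum_idx]
        self.mpap = (float(mp["mean"]), float(mp["sd"]))

        # per-variable: bin bounds and probability mass per point value
        self.fc_bins: dict[int, list[int]] = {}
        fc_mass: dict[int, float] = {}
        for b in cut["who_fc"]["bins"]:
            lo, hi = _bin_bounds(b)
            classes = [c for c in self.fc_weights if lo <= c < hi]
            self.fc_bins[b["points"]] = classes
            fc_mass[b["points"]] = sum(self.fc_weights[c] for c in classes)

        self.mwd_bins: dict[int, tuple[float, float]] = {}
        mwd_mass: dict[int, float] = {}
        mu, sd = self.mwd
        for b in cut["six_mwd"]["bins"]:
            lo, hi = _bin_bounds(b)
            lo = max(lo, 0.0)
            hi = min(hi, 1000.0)
            self.mwd_bins[b["points"]] = (lo, hi)
            mwd_mass[b["points"]] = max(
                sps.norm.cdf(hi, mu, sd) - sps.norm.cdf(lo, mu, sd), 0.0
            )

        self.nt_bins: dict[int, tuple[float, float]] = {}
        nt_mass: dict[int, float] = {}
        mu, sg = self.nt
        for b in cut["nt_probnp"]["bins"]:
            lo, hi = _bin_bounds(b)
            lo = max(lo, 1.0)
            hi = min(hi, 2.0e5)
            llo, lhi = np.log(lo), np.log(hi)
            self.nt_bins[b["points"]] = (llo, lhi)
            nt_mass[b["points"]] = max(
                sps.norm.cdf(lhi, mu, sg) - sps.norm.cdf(llo, mu, sg), 0.0
            )

        # point combinations whose rounded mean lands in the target stratum
        combos, weights = [], []
        for pf, wf in fc_mass.items():
            for p6, w6 in mwd_mass.items():
                for pn, wn in nt_mass.items():
                    mean = round_half_up((pf + p6 + pn) / 3, 1)
                    if stratify(mean, policy) != self.target:
                        continue
                    w = wf * w6 * wn
                    if w > 0:
                        combos.append((pf, p6, pn))
                        weights.append(w)
        if not combos:
            raise ConfigError(
                f"covariate model for stratum {self.target!r} has no mass in "
                "any point combination of that stratum"
            )
        self.combos = combos
        self.combo_p = np.asarray(weights) / sum(weights)

    def draw(self, rng: np.random.Generator) -> tuple[int, float, float]:
        pf, p6, pn = self.combos[rng.choice(len(self.combos), p=self.combo_p)]
        # WHO-FC from the stratum weights restricted to the chosen bin
        classes = self.fc_bins[pf]
        w = np.asarray([self.fc_weights[c] for c in classes])
        fc = int(rng.choice(classes, p=w / w.sum()))
        lo6, hi6 = self.mwd_bins[p6]
        six_mwd = self._trunc_normal(
            rng, *self.mwd, lo6 + self.margin, hi6 - self.margin
        )
        mu, sg = self.nt
        llo, lhi = self.nt_bins[pn]
        llo = np.log(np.exp(llo) + self.margin)
        lhi = np.log(max(np.exp(lhi) - self.margin, np.exp(llo) + 1e-9)) if np.isfinite(lhi) else lhi
        nt = float(np.exp(self._trunc_normal(rng, mu, sg, llo, lhi)))
        return fc, six_mwd, nt

    @staticmethod
    def _trunc_normal(rng, mu, sd, lo, hi) -> float:
        a, b = sps.norm.cdf(lo, mu, sd), sps.norm.cdf(hi, mu, sd)
        u = rng.uniform(a, b)
        u = min(max(u, 1e-12), 1 - 1e-12)
        return float(sps.norm.ppf(u, mu, sd))


def _piecewise_event_time(
    rng: np.random.Generator,
    intervals: list[tuple[float, float, int]],
    hazards: list[float],
) -> float | None:
    """Draw one event time on a piecewise-constant hazard; None if it falls
    beyond the last interval (administrative censoring)."""
    target = rng.exponential(1.0)
    acc = 0.0
    for start, end, stratum in intervals:
        lam = hazards[stratum]
        span = max(end - start, 0.0)
        if acc + lam * span >= target:
            return start + (target - acc) / lam
        acc += lam * span
    return None


def generate_cohort(
    config: Mapping[str, Any] | None = None,
    *,
    n_patients: int | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate a synthetic serially assessed BPA cohort.

    The output is deterministic given the seed. Keyword overrides take
    precedence over the config values.
    """
    if config is None:
        cfg = default_config()
    else:
        from .config import merge_config

        cfg = merge_config(default_config(), dict(config))
    gen = cfg["generator"]
    n = gen["n_patients"] if n_patients is None else int(n_patients)
    if n < 0:
        raise ConfigError("n_patients must be >= 0")
    seed = int(gen["seed"]) if seed is None else int(seed)

    policy = StratumPolicy.from_config("original-4S", cfg["policies"]["original-4S"])
    samplers = [_StratumSampler(cfg, s, policy) for s in range(4)]

    mixture = np.asarray(gen["stratum_mixture"], dtype=float)
    hazards = list(gen["hazards_per_month"])
    p_imp, p_two, p_wor = gen["p_improve"], gen["p_improve_two_step"], gen["p_worsen"]
    ns_weights = np.asarray(gen["n_sessions_weights"], dtype=float)
    gap_mu, gap_sigma = gen["gap_lognormal"]["mu"], gen["gap_lognormal"]["sigma"]
    drop = gen["mpap_per_session_drop"]
    ev_types = list(gen["event_type_weights"])
    ev_w = np.asarray([gen["event_type_weights"][k] for k in ev_types], dtype=float)
    ev_w = ev_w / ev_w.sum()
    dpm = cfg["endpoints"]["days_per_month"]
    study_end = pd.Timestamp(cfg["endpoints"]["study_end"])
    enroll_start = pd.Timestamp(gen["enrollment_start"])
    enroll_days = (pd.Timestamp(gen["enrollment_end"]) - enroll_start).days

    a_rows, e_rows, p_rows = [], [], []
    width = max(4, len(str(max(n, 1))))
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        pid = f"P{i + 1:0{width}d}"
        s0 = int(rng.choice(4, p=mixture))
        first_date = enroll_start + pd.Timedelta(days=int(rng.integers(0, enroll_days + 1)))
        censor_months = (study_end - first_date).days / dpm

        k_sessions = int(rng.choice(len(ns_weights), p=ns_weights)) + 1
        times = [0.0]
        for _ in range(k_sessions - 1):
            times.append(times[-1] + float(rng.lognormal(gap_mu, gap_sigma)))
        times = [t for t in times if t <= censor_months]
        k_sessions = len(times)

        # stratum trajectory and mPAP trajectory across sessions
        cur = s0
        mpap = float(np.clip(rng.normal(*samplers[s0].mpap), 5.0, 130.0))
        sessions = []  # (session_idx, t_months, pre_stratum, post_stratum, pre_mpap, post_mpap)
        for k in range(1, k_sessions + 1):
            pre_s = cur
            u = rng.uniform()
            if u < p_imp:
                if cur > 0:
                    cur -= 1
                    if cur > 0 and rng.uniform() < p_two:
                        cur -= 1
            elif u < p_imp + p_wor and cur < 3:
                cur += 1
            post_s = cur
            pre_mpap = mpap
            mpap = max(mpap - rng.normal(drop["mean"], drop["sd"]), drop["floor"])
            sessions.append((k, times[k - 1], pre_s, post_s, pre_mpap, mpap))

        # event on the time-varying post-session stratum
        intervals = []
        for j, (k, t, _pre, post, _pm, _qm) in enumerate(sessions):
            end = sessions[j + 1][1] if j + 1 < len(sessions) else censor_months
            intervals.append((t, end, post))
        ev_time = (
            _piecewise_event_time(rng, intervals, hazards) if sessions else None
        )
        ev_type = None
        if ev_time is not None:
            ev_type = str(rng.choice(ev_types, p=ev_w))
            if ev_type == "death":
                sessions = [s for s in sessions if s[1] <= ev_time]

        for k, t, pre_s, post_s, pre_mpap, post_mpap in sessions:
            session_date = first_date + pd.Timedelta(days=round(t * dpm))
            pre_date = session_date - pd.Timedelta(days=int(rng.integers(0, 8)))
            post_date = session_date + pd.Timedelta(days=int(rng.integers(1, 8)))
            for timing, strat, mp, date in (
                ("pre", pre_s, pre_mpap, pre_date),
                ("post", post_s, post_mpap, post_date),
            ):
                fc, mwd, nt = samplers[strat].draw(rng)
                a_rows.append(
                    {
                        "patient_id": pid,
                        "session_index": k,
                        "timing": timing,
                        "date": date.date().isoformat(),
                        "who_fc": fc,
                        "six_mwd": round(mwd, 1),
                        "nt_probnp": round(nt, 1),
                        "bnp": np.nan,
                        "mpap": round(mp, 1),
                    }
                )

        if ev_time is not None:
            e_rows.append(
                {
                    "patient_id": pid,
                    "event_type": ev_type,
                    "time_months": round(ev_time, 3),
                    "date": (first_date + pd.Timedelta(days=round(ev_time * dpm)))
                    .date()
                    .isoformat(),
                }
            )
        p_rows.append(
            {
                "patient_id": pid,
                "first_session_date": first_date.date().isoformat(),
                "follow_up_months": round(censor_months, 3),
                "n_sessions": k_sessions,
                "true_baseline_stratum": policy.labels[s0],
            }
        )

    a_cols = ["patient_id", "session_index", "timing", "date", "who_fc",
              "six_mwd", "nt_probnp", "bnp", "mpap"]
    e_cols = ["patient_id", "event_type", "time_months", "date"]
    p_cols = ["patient_id", "first_session_date", "follow_up_months",
              "n_sessions", "true_baseline_stratum"]
    return SyntheticCohort(
        assessments=pd.DataFrame(a_rows, columns=a_cols),
        events=pd.DataFrame(e_rows, columns=e_cols),
        patients=pd.DataFrame(p_rows, columns=p_cols),
        config=cfg,
    )


def recover_parameters(cohort: SyntheticCohort) -> dict[str, Any]:
    """Re-estimate the generating parameters from a generated cohort.

    Returns the empirical baseline stratum mixture (original 4-S), the
    per-session improvement probability (pooled over improvable pre-session
    strata at session 1), per-stratum exponential event rates from
    person-time at the time-varying stratum, their adjacent-stratum ratios,
    and a pooled adjacent hazard ratio from a rank-linear Poisson fit.
    Strata with zero events are flagged inestimable.
    """
    from .longitudinal import score_cohort

    if cohort.assessments.empty:
        raise DegenerateSample("empty cohort")
    cfg = cohort.config
    risk = score_cohort(cohort.assessments, cfg)

    base = risk[(risk["session_index"] == 1) & (risk["timing"] == "pre")]
    labels = ("low", "intermediate-low", "intermediate-high", "high")
    n_base = len(base)
    mixture = [float((base["original-4S"] == lab).sum()) / n_base for lab in labels]

    # pooled one-session improvement probability among improvable patients
    s1 = risk[risk["session_index"] == 1].pivot(
        index="patient_id", columns="timing", values="rank_original-4S"
    )
    s1 = s1.dropna()
    improvable = s1[s1["pre"] > 1]
    if len(improvable):
        p_improve = float((improvable["post"] < improvable["pre"]).mean())
    else:
        p_improve = np.nan

    # person-time and events at the time-varying (post-session) stratum
    post = risk[risk["timing"] == "post"].copy()
    fu = cohort.patients.set_index("patient_id")["follow_up_months"]
    ev = cohort.events.set_index("patient_id")["time_months"] if len(cohort.events) else pd.Series(dtype=float)
    persontime = np.zeros(4)
    events = np.zeros(4)
    dpm = cfg["endpoints"]["days_per_month"]
    for pid, grp in post.groupby("patient_id"):
        grp = grp.sort_values("session_index")
        first = cohort.patients.set_index("patient_id").loc[pid, "first_session_date"]
        t_sessions = [
            (pd.Timestamp(d) - pd.Timestamp(first)).days / dpm for d in grp["date"]
        ]
        ranks = [int(r) - 1 for r in grp["rank_original-4S"]]
        ev_time = float(ev[pid]) if pid in ev.index else None
        horizon = ev_time if ev_time is not None else float(fu.loc[pid])
        attributed = False
        for j, (t0, r) in enumerate(zip(t_sessions, ranks)):
            t1 = t_sessions[j + 1] if j + 1 < len(t_sessions) else float(fu.loc[pid])
            t1 = min(t1, horizon)
            if t1 > t0:
                persontime[r] += t1 - t0
            if ev_time is not None and not attributed and t0 <= ev_time <= t1:
                events[r] += 1
                attributed = True
        if ev_time is not None and not attributed and ranks:
            # event preceded the first post-session assessment date
            events[ranks[0]] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(persontime > 0, events / persontime, np.nan)
    inestimable = [labels[i] for i in range(4) if events[i] == 0]
    adjacent = [
        float(rates[i + 1] / rates[i])
        if rates[i] and np.isfinite(rates[i]) and np.isfinite(rates[i + 1]) and rates[i] > 0
        else np.nan
        for i in range(3)
    ]

    pooled = np.nan
    mask = persontime > 0
    if events[mask].sum() >= 2 and mask.sum() >= 2:
        import statsmodels.api as sm

        X = sm.add_constant(np.arange(4, dtype=float)[mask])
        try:
            fit = sm.GLM(
                events[mask], X,
                family=sm.families.Poisson(),
                offset=np.log(persontime[mask]),
            ).fit()
            pooled = float(np.exp(fit.params[1]))
        except Exception:
            pooled = np.nan

    return {
        "mixture": mixture,
        "p_improve": p_improve,
        "event_rates_per_month": [float(r) for r in rates],
        "person_months": [float(t) for t in persontime],
        "events_by_stratum": [int(e) for e in events],
        "adjacent_hazard_ratios": adjacent,
        "pooled_adjacent_hazard_ratio": pooled,
        "inestimable_strata": inestimable,
    }
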