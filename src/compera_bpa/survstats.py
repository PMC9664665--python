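"""Censored-data statistics for the risk-stratification analyses.

``km_estimate``, ``logrank_test``, ``harrell_c`` and ``spearman_corr`` are
implemented from first principles — they carry the headline model
comparisons and are cross-checked against brute-force oracles in the test
suite. Proportional-hazards and logistic fits are standard model fits and
delegate to statsmodels behind the contracts defined here.

Conventions
-----------
* Kaplan–Meier: subjects censored exactly at an event time are counted at
  risk for that event time (the standard convention).
* Harrell's C: a pair is usable iff it is orderable under censoring (the
  shorter time carries an observed event, or both times are equal with at
  least one event and differing status). Concordant means the higher
  predictor has the shorter time; predictor ties count 0.5. Pairs with equal
  times and both events count 0.5 when predictors differ.
* Cox ties: Breslow by default (Efron via ``ties=``).
* All p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateSample,
    FitError,
    GroupingError,
    ValidationError,
)

__all__ = [
    "KMCurve",
    "CIndexResult",
    "LogrankResult",
    "km_estimate",
    "logrank_test",
    "harrell_c",
    "spearman_corr",
    "fit_proportional_hazards",
    "fit_logistic",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with Greenwood variance."""

    times: np.ndarray        # distinct event times, ascending
    at_risk: np.ndarray      # n_i at each event time
    events: np.ndarray       # d_i at each event time
    survival: np.ndarray     # S(t_i+)
    variance: np.ndarray     # Greenwood Var[S(t_i)]

    def evaluate(self, t: float) -> float:
        """S(t): right-continuous step function, 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_survival_arrays(times, observed) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(observed, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValidationError("times and observed flags must be equal-length 1-d")
    if t.size == 0:
        raise ValidationError("empty survival sample")
    if not np.all(np.isfinite(t)):
        raise ValidationError("non-finite survival times")
    return t, e


def km_estimate(times, observed) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    ``observed`` is True for events, False for right-censored subjects.
    With no censoring this reduces exactly to the empirical survival
    function.
    """
    t, e = _as_survival_arrays(times, observed)
    if np.all(t <= 0):
        raise ValidationError("all survival times are <= 0")
    event_times = np.unique(t[e])
    n = t.size
    at_risk, d, surv, var = [], [], [], []
    s = 1.0
    gw = 0.0  # running Greenwood sum
    for et in event_times:
        ni = int(np.sum(t >= et))  # censored-at-event-time counted at risk
        di = int(np.sum((t == et) & e))
        s *= 1.0 - di / ni
        if ni > di:
            gw += di / (ni * (ni - di))
        at_risk.append(ni)
        d.append(di)
        surv.append(s)
        var.append(s * s * gw if ni > di else 0.0)
    return KMCurve(
        times=np.asarray(event_times, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
        events=np.asarray(d, dtype=int),
        survival=np.asarray(surv, dtype=float),
        variance=np.asarray(var, dtype=float),
    )


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(times, observed, groups) -> LogrankResult:
    """k-group log-rank test (chi-square, df = k-1).

    At each distinct event time the observed events per group are compared
    with their hypergeometric expectation given the risk sets; the statistic
    is the quadratic form of the first k-1 group O-E sums in their
    estimated covariance.
    """
    t, e = _as_survival_arrays(times, observed)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValidationError("groups must align with times")
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise GroupingError("log-rank test needs at least two groups")
    if not e.any():
        raise DegenerateSample("log-rank test needs at least one event")

    event_times = np.unique(t[e])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        d = int(((t == et) & e).sum())
        if n <= 0 or d == 0:
            continue
        nj = np.array([(at_risk & (g == lab)).sum() for lab in labels], dtype=float)
        dj = np.array([((t == et) & e & (g == lab)).sum() for lab in labels], dtype=float)
        O += dj
        E += d * nj / n
        if n > 1:
            frac = nj / n
            vmat = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            V += vmat
    u = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(u @ np.linalg.solve(Vsub, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(Vsub) @ u)
    df = k - 1
    p = float(sps.chi2.sf(stat, df))
    return LogrankResult(statistic=stat, df=df, p_value=p, observed=O, expected=E)


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CIndexResult:
    concordant: float
    discordant: float
    tied_predictions: float
    usable_pairs: float
    c_index: float


def harrell_c(times, observed, predictor) -> CIndexResult:
    """Harrell's concordance index for a numeric risk predictor.

    Higher predictor values are taken to mean higher risk, so concordance
    means the higher-predictor subject fails earlier. Vectorized over all
    n(n-1)/2 pairs; the test suite checks it pairwise against an explicit
    enumeration oracle.
    """
    t, e = _as_survival_arrays(times, observed)
    x = np.asarray(predictor, dtype=float)
    if x.shape != t.shape:
        raise ValidationError("predictor must align with times")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite predictor values")

    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None], e[None, :]
    xi, xj = x[:, None], x[None, :]

    # pair (i, j) usable with i the earlier failure
    earlier = (ti < tj) & ei
    # equal times: both events -> usable (counts 0.5 unless predictors tie);
    # one event, one censored -> the event subject is "earlier"
    tie_both = (ti == tj) & ei & ej
    tie_one = (ti == tj) & ei & ~ej

    upper = np.triu(np.ones_like(earlier, dtype=bool), k=1)

    # orderable pairs, i failing first (both orientations via transpose)
    ordered_ij = (earlier | tie_one) & upper
    ordered_ji = (earlier | tie_one).T & upper
    conc = np.sum(ordered_ij & (xi > xj)) + np.sum(ordered_ji & (xj > xi))
    disc = np.sum(ordered_ij & (xi < xj)) + np.sum(ordered_ji & (xj < xi))
    # half-credit pairs: tied predictors among orderable pairs, plus
    # both-event time ties (no failure order exists)
    tied = np.sum((ordered_ij | ordered_ji) & (xi == xj))
    tied += np.sum(tie_both & upper & ~(ordered_ij | ordered_ji))

    usable = float(conc + disc + tied)
    if usable == 0:
        raise DegenerateSample("no usable (orderable) pairs for the c-index")
    c = (conc + 0.5 * tied) / usable
    return CIndexResult(
        concordant=float(conc),
        discordant=float(disc),
        tied_predictions=float(tied),
        usable_pairs=usable,
        c_index=float(c),
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation with midranks
# ---------------------------------------------------------------------------

def _midranks(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size, dtype=float)
    sv = v[order]
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_corr(x, y) -> float:
    """Spearman rank correlation with midrank tie handling."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d")
    if xv.size < 3:
        raise ValidationError("spearman_corr needs n >= 3")
    if np.unique(xv).size < 2 or np.unique(yv).size < 2:
        raise DegenerateSample("constant vector has no rank correlation")
    rx, ry = _midranks(xv), _midranks(yv)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


# ---------------------------------------------------------------------------
# Regression contracts (delegated fits)
# ---------------------------------------------------------------------------

def _check_epv(n_events: int, n_coef: int, on_violation: str) -> bool:
    """Events-per-variable guard (>= 5 events per fitted coefficient)."""
    ok = n_coef == 0 or n_events >= 5 * n_coef
    if not ok:
        msg = (
            f"event-per-variable ratio below 5:1 "
            f"({n_events} events for {n_coef} coefficients)"
        )
        if on_violation == "error":
            raise ValidationError(msg)
        warnings.warn(msg, UserWarning, stacklevel=3)
    return ok


def _level_table(df: pd.DataFrame, predictor: str, event_col: str) -> pd.DataFrame:
    tab = (
        df.groupby(predictor, observed=True)[event_col]
        .agg(n="size", events="sum")
        .reset_index()
    )
    return tab


def fit_proportional_hazards(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    predictor: str,
    adjustment: list[str] | None = None,
    *,
    ties: str = "breslow",
    epv_action: str = "warn",
) -> pd.DataFrame:
    """Cox proportional-hazards fit of an ordinal/categorical predictor.

    The lowest observed level is the reference. Levels with zero events are
    flagged (``estimable = False``) and excluded from the fit — their hazard
    ratio cannot be computed. Returns a Table-4-shaped frame with one row
    per level: n, events, HR, CI bounds, p.
    """
    import statsmodels.api as sm

    adjustment = adjustment or []
    data = df.dropna(subset=[duration_col, event_col, predictor, *adjustment]).copy()
    levels = sorted(data[predictor].unique())
    if len(levels) < 2:
        raise ValidationError("predictor needs at least two observed levels")
    tab = _level_table(data, predictor, event_col).set_index(predictor)

    inestimable = [lv for lv in levels[1:] if tab.loc[lv, "events"] == 0]
    fit_levels = [lv for lv in levels if lv not in inestimable]
    fit_data = data[data[predictor].isin(fit_levels)]

    dummies = pd.get_dummies(fit_data[predictor], prefix="lvl", dtype=float)
    dummy_cols = [f"lvl_{lv}" for lv in fit_levels[1:]]
    X = pd.concat([dummies[dummy_cols], fit_data[adjustment]], axis=1).astype(float)

    _check_epv(int(fit_data[event_col].sum()), X.shape[1], epv_action)

    try:
        model = sm.PHReg(
            fit_data[duration_col].to_numpy(dtype=float),
            X.to_numpy(),
            status=fit_data[event_col].to_numpy(dtype=int),
            ties=ties,
        )
        res = model.fit(disp=False)
    except Exception as exc:  # non-convergence, singular information...
        raise FitError(f"Cox fit failed: {exc}", trace=exc) from exc

    params = dict(zip(X.columns, res.params))
    ses = dict(zip(X.columns, res.bse))
    pvals = dict(zip(X.columns, res.pvalues))

    rows = []
    for lv in levels:
        row = {
            "level": lv,
            "n": int(tab.loc[lv, "n"]),
            "events": int(tab.loc[lv, "events"]),
            "estimable": lv not in inestimable,
        }
        col = f"lvl_{lv}"
        if lv == levels[0]:
            row.update(hr=1.0, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                       reference=True)
        elif lv in inestimable:
            row.update(hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                       reference=False)
        else:
            b, se = params[col], ses[col]
            row.update(
                hr=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.959963984540054 * se)),
                ci_high=float(np.exp(b + 1.959963984540054 * se)),
                p=float(pvals[col]),
                reference=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def fit_logistic(
    df: pd.DataFrame,
    outcome_col: str,
    predictor: str,
    adjustment: list[str] | None = None,
    *,
    epv_action: str = "warn",
) -> pd.DataFrame:
    """Logistic fit of a categorical predictor; odds ratios per level.

    Reference is the lowest observed level. Levels where the outcome is
    constant (all or no events) are flagged inestimable (separation) and
    excluded from the fit.
    """
    import statsmodels.api as sm

    adjustment = adjustment or []
    data = df.dropna(subset=[outcome_col, predictor, *adjustment]).copy()
    levels = sorted(data[predictor].unique())
    if len(levels) < 2:
        raise ValidationError("predictor needs at least two observed levels")
    tab = _level_table(data, predictor, outcome_col).set_index(predictor)

    separated = [
        lv
        for lv in levels[1:]
        if tab.loc[lv, "events"] in (0, tab.loc[lv, "n"])
    ]
    fit_levels = [lv for lv in levels if lv not in separated]
    fit_data = data[data[predictor].isin(fit_levels)]

    dummies = pd.get_dummies(fit_data[predictor], prefix="lvl", dtype=float)
    dummy_cols = [f"lvl_{lv}" for lv in fit_levels[1:]]
    X = pd.concat([dummies[dummy_cols], fit_data[adjustment]], axis=1).astype(float)
    X = sm.add_constant(X, has_constant="add")

    _check_epv(int(fit_data[outcome_col].sum()), X.shape[1] - 1, epv_action)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(
                fit_data[outcome_col].to_numpy(dtype=float), X.to_numpy()
            ).fit(disp=False)
        if not res.mle_retvals.get("converged", True):
            raise FitError("logistic fit did not converge", trace=res.mle_retvals)
    except FitError:
        raise
    except Exception as exc:
        raise FitError(f"logistic fit failed: {exc}", trace=exc) from exc

    names = list(X.columns)
    params = dict(zip(names, res.params))
    ses = dict(zip(names, res.bse))
    pvals = dict(zip(names, res.pvalues))

    rows = []
    for lv in levels:
        row = {
            "level": lv,
            "n": int(tab.loc[lv, "n"]),
            "events": int(tab.loc[lv, "events"]),
            "estimable": lv not in separated,
        }
        col = f"lvl_{lv}"
        if lv == levels[0]:
            row.update(odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                       reference=True)
        elif lv in separated:
            row.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p=np.nan, reference=False)
        else:
            b, se = params[col], ses[col]
            row.update(
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.959963984540054 * se)),
                ci_high=float(np.exp(b + 1.959963984540054 * se)),
                p=float(pvals[col]),
                reference=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)
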