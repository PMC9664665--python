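"""Point assignment and mean risk-score computation.

The COMPERA 2.0 score grades three noninvasive variables — WHO functional
class, 6-min walk distance and NT-proBNP (or BNP) — on an integer point
scale (1..4 for the 4-stratum tables, 1..3 for the 3-stratum tables) and
averages them::

    mean_score = sum(points) / n_variables

rounded half-up to one decimal. Patients missing any scored variable are
rejected by default, mirroring the exclusion rule of the clinical cohorts
the score was built on; a config flag enables mean-over-available scoring
with a minimum variable count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Mapping

from .errors import EmptyScore, MissingVariable, ValidationError

__all__ = ["Assessment", "RiskScore", "assign_points", "compute_risk_score"]

#: variables that carry points; one of nt_probnp / bnp stands in for "peptide"
SCORED_VARIABLES = ("who_fc", "six_mwd", "peptide")


@dataclass(frozen=True)
class Assessment:
    """One timed measurement set anchored to a BPA session (pre or post)."""

    patient_id: str
    session_index: int
    timing: str  # "pre" | "post"
    who_fc: int | None = None
    six_mwd: float | None = None
    nt_probnp: float | None = None
    bnp: float | None = None
    mpap: float | None = None
    date: str | None = None
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timing not in ("pre", "post"):
            raise ValidationError(f"timing must be 'pre' or 'post', got {self.timing!r}")
        if self.session_index < 1:
            raise ValidationError("session_index must be >= 1")


@dataclass(frozen=True)
class RiskScore:
    """Per-variable points plus their mean, kept for audit."""

    points: dict[str, int]
    n_variables: int
    mean_score: float
    peptide_used: str | None = None

    def __post_init__(self) -> None:
        if self.n_variables < 1:
            raise EmptyScore("risk score needs at least one variable")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at a fixed decimal, immune to binary float
    artifacts (2.25 -> 2.3, not banker's 2.2)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _check_bounds(name: str, value: float, bounds: Mapping[str, Any] | None) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{name} is not finite: {value}")
    if bounds and name in bounds:
        lo, hi = bounds[name]
        if not lo <= value <= hi:
            raise ValidationError(f"{name}={value} outside admissible range [{lo}, {hi}]")


def lookup_points(value: float, variable_spec: Mapping[str, Any]) -> int:
    """Map one value into its half-open cutoff bin.

    Bins are closed on the worse side: with ``higher_worse`` membership is
    ``min <= v < max``, with ``lower_worse`` it is ``min < v <= max``
    (``None`` bounds are infinite).
    """
    direction = variable_spec["direction"]
    for b in variable_spec["bins"]:
        lo = -math.inf if b["min"] is None else float(b["min"])
        hi = math.inf if b["max"] is None else float(b["max"])
        if direction == "higher_worse":
            inside = lo <= value < hi
        else:
            inside = lo < value <= hi
        if inside:
            return int(b["points"])
    raise ValidationError(f"value {value} not covered by any cutoff bin")


def assign_points(
    assessment: Assessment,
    cutoffs: Mapping[str, Any],
    granularity: int,
    *,
    peptide_preference: str = "nt_probnp",
    allow_partial: bool = False,
    min_variables: int = 3,
    bounds: Mapping[str, Any] | None = None,
) -> tuple[dict[str, int], str | None]:
    """Assign 1..granularity points to each scored variable.

    Parameters
    ----------
    cutoffs
        The cutoff tables for both granularities, as held under the
        ``cutoffs`` key of the package config.
    granularity
        3 or 4, selecting the 3- or 4-stratum point tables.
    peptide_preference
        Which natriuretic peptide to score when both are present.

    Returns
    -------
    (points, peptide_used)
        ``points`` maps ``who_fc``, ``six_mwd`` and the peptide actually
        used to their point values; ``peptide_used`` names that peptide
        (``None`` if scoring proceeded without one under partial scoring).

    Raises
    ------
    MissingVariable
        If a required variable is absent and partial scoring is off (or
        fewer than ``min_variables`` are available).
    ValidationError
        If a value is non-finite or outside its admissible range.
    """
    if granularity not in (3, 4):
        raise ValidationError(f"granularity must be 3 or 4, got {granularity}")
    table = cutoffs[str(granularity)] if str(granularity) in cutoffs else cutoffs[granularity]

    peptide_used: str | None = None
    pep_order = (
        ("nt_probnp", "bnp") if peptide_preference == "nt_probnp" else ("bnp", "nt_probnp")
    )
    for pep in pep_order:
        if getattr(assessment, pep) is not None:
            peptide_used = pep
            break

    available: dict[str, tuple[str, float]] = {}
    if assessment.who_fc is not None:
        available["who_fc"] = ("who_fc", float(assessment.who_fc))
    if assessment.six_mwd is not None:
        available["six_mwd"] = ("six_mwd", float(assessment.six_mwd))
    if peptide_used is not None:
        available["peptide"] = (peptide_used, float(getattr(assessment, peptide_used)))

    missing = [v for v in SCORED_VARIABLES if v not in available]
    if missing and not allow_partial:
        name = missing[0]
        raise MissingVariable("nt_probnp/bnp" if name == "peptide" else name)
    if len(available) < (min_variables if allow_partial else 3):
        raise MissingVariable(",".join(missing))

    points: dict[str, int] = {}
    for _, (var_name, value) in available.items():
        _check_bounds(var_name, value, bounds)
        points[var_name] = lookup_points(value, table[var_name])
    return points, peptide_used


def compute_risk_score(
    points: Mapping[str, int], peptide_used: str | None = None
) -> RiskScore:
    """Mean of the per-variable points, rounded half-up to one decimal."""
    if not points:
        raise EmptyScore("empty points map")
    n = len(points)
    mean = round_half_up(sum(points.values()) / n, 1)
    return RiskScore(points=dict(points), n_variables=n, mean_score=mean,
                     peptide_used=peptide_used)


def score_assessment(
    assessment: Assessment, config: Mapping[str, Any], granularity: int
) -> RiskScore:
    """Convenience wrapper: points + mean score straight from a config."""
    sc = config["scoring"]
    points, pep = assign_points(
        assessment,
        config["cutoffs"],
        granularity,
        peptide_preference=sc["peptide_preference"],
        allow_partial=sc["allow_partial_scores"],
        min_variables=sc["min_variables"],
        bounds=sc["bounds"],
    )
    return compute_risk_score(points, peptide_used=pep)
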