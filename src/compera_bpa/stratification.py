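"""Stratum assignment from the mean risk score.

Six policies are supported — original, modified and hybrid versions, each in
a 3-stratum and a 4-stratum form. The three versions differ only in how the
decimal of the mean score is handled (nearest-integer rounding, ceiling, or
a fusion of the two below/above a switch point); here each policy is carried
as an explicit interval table over the one-decimal score grid, which is the
authoritative representation. The equivalent rounding rules live in the test
suite as an independent oracle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Any, Iterable, Mapping

import pandas as pd

from .errors import PolicyError, RangeError
from .scoring import RiskScore, round_half_up

__all__ = [
    "StratumPolicy",
    "RiskResult",
    "POLICY_NAMES",
    "stratum_rank",
    "stratify",
    "stratify_all",
    "enumerate_policy_diffs",
    "score_grid",
]

POLICY_NAMES = (
    "original-3S",
    "modified-3S",
    "hybrid-3S",
    "original-4S",
    "modified-4S",
    "hybrid-4S",
)

_LABELS_3S = ("low", "intermediate", "high")
_LABELS_4S = ("low", "intermediate-low", "intermediate-high", "high")


@dataclass(frozen=True)
class StratumPolicy:
    """One version x granularity interval table."""

    name: str
    version: str
    granularity: int
    intervals: tuple[tuple[float, float, str], ...]

    @classmethod
    def from_config(cls, name: str, spec: Mapping[str, Any]) -> "StratumPolicy":
        intervals = tuple(
            (float(iv["lo"]), float(iv["hi"]), str(iv["label"]))
            for iv in spec["intervals"]
        )
        policy = cls(
            name=name,
            version=spec["version"],
            granularity=int(spec["granularity"]),
            intervals=intervals,
        )
        policy.validate()
        return policy

    @property
    def labels(self) -> tuple[str, ...]:
        return _LABELS_3S if self.granularity == 3 else _LABELS_4S

    @property
    def max_score(self) -> float:
        return float(self.granularity)

    def validate(self) -> None:
        """Intervals must partition the one-decimal grid in label order."""
        if self.granularity not in (3, 4):
            raise PolicyError(f"granularity must be 3 or 4, got {self.granularity}")
        if tuple(iv[2] for iv in self.intervals) != self.labels:
            raise PolicyError(
                f"{self.name}: intervals must carry labels {self.labels} in order"
            )
        grid = score_grid(self.granularity)
        seen = {}
        for g in grid:
            hits = [lab for lo, hi, lab in self.intervals if lo <= g <= hi]
            if len(hits) != 1:
                raise PolicyError(
                    f"{self.name}: grid score {g} maps to {len(hits)} intervals"
                )
            seen[g] = hits[0]
        ranks = [self.labels.index(seen[g]) for g in grid]
        if ranks != sorted(ranks):
            raise PolicyError(f"{self.name}: labels not monotone in score")

    def table_hash(self) -> str:
        blob = json.dumps(self.intervals, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def score_grid(granularity: int) -> list[float]:
    """The attainable one-decimal score grid 1.0 .. granularity."""
    top = 30 if granularity == 3 else 40
    return [round(k / 10, 1) for k in range(10, top + 1)]


def stratum_rank(label: str, granularity: int) -> int:
    """Ordinal rank of a stratum label (1 = low)."""
    labels = _LABELS_3S if granularity == 3 else _LABELS_4S
    if label not in labels:
        raise PolicyError(f"unknown stratum label {label!r} for {granularity}-S")
    return labels.index(label) + 1


def stratify(score: RiskScore | float, policy: StratumPolicy) -> str:
    """Look up the unique stratum whose interval contains the mean score."""
    mean = score.mean_score if isinstance(score, RiskScore) else float(score)
    mean = round_half_up(mean, 1)
    if not 1.0 <= mean <= policy.max_score:
        raise RangeError(
            f"mean score {mean} outside [1.0, {policy.max_score}] for {policy.name}"
        )
    for lo, hi, label in policy.intervals:
        if lo <= mean <= hi:
            return label
    raise RangeError(f"score {mean} not covered by {policy.name}")  # pragma: no cover


def load_policies(config: Mapping[str, Any]) -> dict[str, StratumPolicy]:
    return {
        name: StratumPolicy.from_config(name, spec)
        for name, spec in config["policies"].items()
    }


@dataclass(frozen=True)
class RiskResult:
    """A scored assessment with its stratum under every policy."""

    patient_id: str
    session_index: int
    timing: str
    score_3s: RiskScore
    score_4s: RiskScore
    strata: dict[str, str]  # policy name -> label
    policy_hashes: dict[str, str]

    def rank(self, policy_name: str) -> int:
        gran = 3 if policy_name.endswith("3S") else 4
        return stratum_rank(self.strata[policy_name], gran)


def stratify_all(
    score_3s: RiskScore, score_4s: RiskScore, policies: Mapping[str, StratumPolicy]
) -> dict[str, str]:
    """Stratum label under each policy, given both granularities' scores."""
    out = {}
    for name, pol in policies.items():
        score = score_3s if pol.granularity == 3 else score_4s
        out[name] = stratify(score, pol)
    return out


def enumerate_policy_diffs(
    policy_a: StratumPolicy, policy_b: StratumPolicy
) -> pd.DataFrame:
    """Exhaustively list grid scores where two same-granularity policies
    disagree (the stratification "incoherence" between versions)."""
    if policy_a.granularity != policy_b.granularity:
        raise PolicyError(
            f"granularity mismatch: {policy_a.name} vs {policy_b.name}"
        )
    rows = []
    for g in score_grid(policy_a.granularity):
        la, lb = stratify(g, policy_a), stratify(g, policy_b)
        if la != lb:
            rows.append({"mean_score": g, policy_a.name: la, policy_b.name: lb})
    return pd.DataFrame(rows, columns=["mean_score", policy_a.name, policy_b.name])
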