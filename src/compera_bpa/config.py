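"""Configuration: point-cutoff tables, stratum interval tables, thresholds,
and synthetic-generator parameters.

The defaults transcribe the published COMPERA 2.0 scoring tables. Cutoff bins
are half-open and closed on the *worse* side: a value exactly at a cutoff
receives the higher (worse) point. Bin semantics by direction:

* ``higher_worse`` (WHO-FC, NT-proBNP, BNP): a value ``v`` is in the bin when
  ``min <= v < max``;
* ``lower_worse`` (6MWD): a value ``v`` is in the bin when ``min < v <= max``.

``min``/``max`` of ``null`` mean unbounded. Any override supplied at run time
is validated with :func:`validate_cutoff_table` so no admissible value can
fall through the bins or land in two of them.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from typing import Any

import yaml

from .errors import ConfigError

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "merge_config",
    "config_hash",
    "validate_cutoff_table",
]

# Points per variable. 4-S tables score 1-4, 3-S tables 1-3. WHO-FC is
# categorical (class I..IV handled numerically); the 4-S scale assigns no
# 2-point FC bin, so FC points are {1, 3, 4}.
_CUTOFFS: dict[str, Any] = {
    "4": {
        "who_fc": {
            "direction": "higher_worse",
            "bins": [
                {"points": 1, "min": 1, "max": 3},
                {"points": 3, "min": 3, "max": 4},
                {"points": 4, "min": 4, "max": 5},
            ],
        },
        "six_mwd": {
            "direction": "lower_worse",
            "bins": [
                {"points": 1, "min": 440, "max": None},
                {"points": 2, "min": 320, "max": 440},
                {"points": 3, "min": 165, "max": 320},
                {"points": 4, "min": None, "max": 165},
            ],
        },
        "nt_probnp": {
            "direction": "higher_worse",
            "bins": [
                {"points": 1, "min": 0, "max": 300},
                {"points": 2, "min": 300, "max": 650},
                {"points": 3, "min": 650, "max": 1100},
                {"points": 4, "min": 1100, "max": None},
            ],
        },
        "bnp": {
            "direction": "higher_worse",
            "bins": [
                {"points": 1, "min": 0, "max": 50},
                {"points": 2, "min": 50, "max": 200},
                {"points": 3, "min": 200, "max": 800},
                {"points": 4, "min": 800, "max": None},
            ],
        },
    },
    "3": {
        "who_fc": {
            "direction": "higher_worse",
            "bins": [
                {"points": 1, "min": 1, "max": 3},
                {"points": 2, "min": 3, "max": 4},
                {"points": 3, "min": 4, "max": 5},
            ],
        },
        "six_mwd": {
            "direction": "lower_worse",
            "bins": [
                {"points": 1, "min": 440, "max": None},
                {"points": 2, "min": 165, "max": 440},
                {"points": 3, "min": None, "max": 165},
            ],
        },
        "nt_probnp": {
            "direction": "higher_worse",
            "bins": [
                {"points": 1, "min": 0, "max": 300},
                {"points": 2, "min": 300, "max": 1400},
                {"points": 3, "min": 1400, "max": None},
            ],
        },
        "bnp": {
            "direction": "higher_worse",
            "bins": [
                {"points": 1, "min": 0, "max": 50},
                {"points": 2, "min": 50, "max": 300},
                {"points": 3, "min": 300, "max": None},
            ],
        },
    },
}

# Stratum interval tables (closed decimal intervals at one-decimal
# resolution) for the six version x granularity policies.
_POLICIES: dict[str, Any] = {
    "original-3S": {
        "version": "original",
        "granularity": 3,
        "intervals": [
            {"lo": 1.0, "hi": 1.4, "label": "low"},
            {"lo": 1.5, "hi": 2.4, "label": "intermediate"},
            {"lo": 2.5, "hi": 3.0, "label": "high"},
        ],
    },
    "modified-3S": {
        "version": "modified",
        "granularity": 3,
        "intervals": [
            {"lo": 1.0, "hi": 1.0, "label": "low"},
            {"lo": 1.1, "hi": 2.0, "label": "intermediate"},
            {"lo": 2.1, "hi": 3.0, "label": "high"},
        ],
    },
    "hybrid-3S": {
        "version": "hybrid",
        "granularity": 3,
        "intervals": [
            {"lo": 1.0, "hi": 1.4, "label": "low"},
            {"lo": 1.5, "hi": 2.0, "label": "intermediate"},
            {"lo": 2.1, "hi": 3.0, "label": "high"},
        ],
    },
    "original-4S": {
        "version": "original",
        "granularity": 4,
        "intervals": [
            {"lo": 1.0, "hi": 1.4, "label": "low"},
            {"lo": 1.5, "hi": 2.4, "label": "intermediate-low"},
            {"lo": 2.5, "hi": 3.4, "label": "intermediate-high"},
            {"lo": 3.5, "hi": 4.0, "label": "high"},
        ],
    },
    "modified-4S": {
        "version": "modified",
        "granularity": 4,
        "intervals": [
            {"lo": 1.0, "hi": 1.0, "label": "low"},
            {"lo": 1.1, "hi": 2.0, "label": "intermediate-low"},
            {"lo": 2.1, "hi": 3.0, "label": "intermediate-high"},
            {"lo": 3.1, "hi": 4.0, "label": "high"},
        ],
    },
    "hybrid-4S": {
        "version": "hybrid",
        "granularity": 4,
        "intervals": [
            {"lo": 1.0, "hi": 1.4, "label": "low"},
            {"lo": 1.5, "hi": 2.4, "label": "intermediate-low"},
            {"lo": 2.5, "hi": 3.0, "label": "intermediate-high"},
            {"lo": 3.1, "hi": 4.0, "label": "high"},
        ],
    },
}

_DEFAULT: dict[str, Any] = {
    "cutoffs": _CUTOFFS,
    "policies": _POLICIES,
    "scoring": {
        # which peptide wins when both are present
        "peptide_preference": "nt_probnp",
        # hard failure on missing variables by default (excluded patients);
        # set min_variables to 2 to allow mean-over-available scoring
        "allow_partial_scores": False,
        "min_variables": 3,
        # physiological sanity bounds; values outside raise ValidationError
        "bounds": {
            "who_fc": [1, 4],
            "six_mwd": [0, 1000],
            "nt_probnp": [1, 200000],
            "bnp": [1, 50000],
            "mpap": [5, 130],
            "mrap": [0, 40],
            "ci": [0.5, 8],
            "pvr": [0, 40],
            "svo2": [20, 100],
            "pawp": [0, 40],
            "rved_lved": [0.2, 3],
            "trv": [0.5, 8],
        },
    },
    "endpoints": {
        # unsatisfactory long-term response: NT-proBNP doubling or >= this
        "ntprobnp_absolute_threshold": 1800.0,
        "ntprobnp_relative_factor": 2.0,
        # positive hemodynamic response: mPAP below this at reassessment
        "mpap_threshold": 30.0,
        "study_end": "2021-12-25",
        "days_per_month": 30.4375,
        # assessments should fall within this many days of the session
        "assessment_window_days": 7,
    },
    "generator": {
        "n_patients": 175,
        "seed": 0,
        # baseline mixture over original 4-S strata: low, intermediate-low,
        # intermediate-high, high
        "stratum_mixture": [0.21, 0.30, 0.42, 0.07],
        # per-stratum covariate models (index order as above)
        "covariates": {
            "who_fc_weights": [
                {"1": 1, "2": 36, "3": 0, "4": 0},
                {"1": 0, "2": 24, "3": 28, "4": 0},
                {"1": 0, "2": 1, "3": 72, "4": 1},
                {"1": 0, "2": 0, "3": 8, "4": 4},
            ],
            "six_mwd_normal": [
                {"mean": 451.7, "sd": 74.6},
                {"mean": 375.9, "sd": 88.6},
                {"mean": 312.3, "sd": 84.2},
                {"mean": 163.0, "sd": 78.3},
            ],
            "nt_probnp_lognormal_median_iqr": [
                {"median": 106.6, "q1": 52.5, "q3": 223.6},
                {"median": 379.0, "q1": 178.0, "q3": 974.5},
                {"median": 1491.5, "q1": 823.5, "q3": 2671.3},
                {"median": 2502.0, "q1": 1831.3, "q3": 2738.0},
            ],
            "mpap_normal": [
                {"mean": 43.1, "sd": 9.9},
                {"mean": 45.3, "sd": 12.6},
                {"mean": 54.8, "sd": 9.5},
                {"mean": 53.2, "sd": 9.9},
            ],
        },
        # probability that one BPA session moves the patient down one
        # stratum / up one stratum (otherwise unchanged); an extra step
        # down happens with p_improve_two_step conditional on improving
        "p_improve": 0.6,
        "p_improve_two_step": 0.10,
        "p_worsen": 0.03,
        # per-month exponential event hazard by current stratum rank;
        # strictly increasing, adjacent ratio 3.0
        "hazards_per_month": [0.002, 0.006, 0.018, 0.054],
        # event-type mix for the composite endpoint: death, PH
        # hospitalization, unsatisfactory response, RHF worsening
        "event_type_weights": {
            "death": 2,
            "ph_hospitalization": 7,
            "unsatisfactory_response": 6,
            "rhf_worsening": 11,
        },
        # number of BPA sessions per patient (support 1..8)
        "n_sessions_weights": [0.12, 0.22, 0.26, 0.18, 0.10, 0.06, 0.04, 0.02],
        # inter-session gap, lognormal in months (median 3, IQR 1.25-5)
        "gap_lognormal": {"mu": 1.0986, "sigma": 1.028},
        # mPAP drops roughly linearly per session with noise (generator
        # convention, not an estimate)
        "mpap_per_session_drop": {"mean": 4.0, "sd": 3.0, "floor": 15.0},
        # first-session dates drawn uniformly over the enrollment window
        "enrollment_start": "2018-05-01",
        "enrollment_end": "2021-10-31",
        "max_rejection_draws": 10000,
    },
}


def default_config() -> dict[str, Any]:
    """Return a deep copy of the built-in default configuration."""
    return copy.deepcopy(_DEFAULT)


def merge_config(base: dict[str, Any], override: dict[str, Any]) -> dict[str, Any]:
    """Recursively merge ``override`` into a copy of ``base``."""
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | None = None) -> dict[str, Any]:
    """Load a YAML config file and merge it over the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path!r} does not hold a mapping")
        cfg = merge_config(cfg, user)
    for gran, table in cfg["cutoffs"].items():
        for var, spec in table.items():
            validate_cutoff_table(spec, name=f"cutoffs[{gran}][{var}]")
    _validate_generator(cfg["generator"])
    return cfg


def save_config(cfg: dict[str, Any], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable short hash of a config for report provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def validate_cutoff_table(spec: dict[str, Any], name: str = "cutoff") -> None:
    """Check that a variable's bins are disjoint, exhaustive and monotone.

    Bins must tile the admissible range without gaps, and points must be
    monotone in the direction of worsening.
    """
    direction = spec.get("direction")
    if direction not in ("higher_worse", "lower_worse"):
        raise ConfigError(f"{name}: unknown direction {direction!r}")
    bins = spec.get("bins", [])
    if not bins:
        raise ConfigError(f"{name}: no bins")
    lo = lambda b: -math.inf if b["min"] is None else float(b["min"])
    hi = lambda b: math.inf if b["max"] is None else float(b["max"])
    ordered = sorted(bins, key=lambda b: (lo(b), hi(b)))
    for b in ordered:
        if lo(b) >= hi(b):
            raise ConfigError(f"{name}: empty bin {b}")
    for a, b in zip(ordered, ordered[1:]):
        if hi(a) != lo(b):
            raise ConfigError(
                f"{name}: bins do not tile the range at {hi(a)} vs {lo(b)}"
            )
    points = [b["points"] for b in ordered]
    expect = sorted(points, reverse=(direction == "lower_worse"))
    if points != expect:
        raise ConfigError(f"{name}: points not monotone in worsening direction")


def _validate_generator(gen: dict[str, Any]) -> None:
    mix = gen["stratum_mixture"]
    if abs(sum(mix) - 1.0) > 1e-9 or any(w < 0 for w in mix):
        raise ConfigError("stratum_mixture must be nonnegative and sum to 1")
    haz = gen["hazards_per_month"]
    if any(h <= 0 for h in haz) or any(a >= b for a, b in zip(haz, haz[1:])):
        raise ConfigError("hazards_per_month must be positive and strictly increasing")
    for key in ("p_improve", "p_worsen", "p_improve_two_step"):
        if not 0.0 <= gen[key] <= 1.0:
            raise ConfigError(f"{key} must be a probability")
    if gen["p_improve"] + gen["p_worsen"] > 1.0:
        raise ConfigError("p_improve + p_worsen must not exceed 1")
    nsw = gen["n_sessions_weights"]
    if abs(sum(nsw) - 1.0) > 1e-9 or any(w < 0 for w in nsw):
        raise ConfigError("n_sessions_weights must be a probability vector")
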