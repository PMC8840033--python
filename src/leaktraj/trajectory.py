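"""Per-patient trajectory statistics and binary rise rules.

A marker's trajectory is summarised two ways: the ordinary-least-squares slope
of value on day over the whole observation window ("average linear trend"),
and the raw differences between consecutive scheduled days. A rise rule flags
a patient when any consecutive-day increase strictly exceeds a marker-specific
threshold (50 mg/L for CRP, 0.5 ng/mL for PCT, 1.0 x1000/mm3 for WBC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MARKER_DAYS, MARKERS, validate_cohort
from .errors import ConfigurationError, DegenerateDesignError, InsufficientDataError

#: Rise thresholds in marker units.
DEFAULT_THRESHOLDS = {"CRP": 50.0, "PCT": 0.5, "WBC": 1.0}

#: Observation windows: include the preoperative draw, or postoperative only.
WINDOWS = {"0-5": (0, 1, 2, 3, 4, 5), "1-5": (1, 2, 3, 4, 5)}


@dataclass(frozen=True)
class RuleConfig:
    """Rise-rule thresholds per marker; ``strict`` keeps the '>' comparison
    (a delta exactly at the threshold does not trigger)."""

    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    strict: bool = True

    def __post_init__(self) -> None:
        for marker, thr in self.thresholds.items():
            if thr <= 0:
                raise ConfigurationError(f"threshold for {marker} must be > 0")

    def threshold(self, marker: str) -> float:
        try:
            return self.thresholds[marker]
        except KeyError:
            raise ConfigurationError(f"no rise threshold configured for {marker!r}")


def fit_linear_trend(days, values) -> float:
    """OLS slope of value on day index, in marker units per day."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size < 2 or values.size < 2:
        raise InsufficientDataError("need at least 2 points for a trend")
    if days.size != values.size:
        raise ConfigurationError("days and values must have equal length")
    if np.ptp(days) == 0:
        raise DegenerateDesignError("all day indices identical")
    d = days - days.mean()
    return float(d @ (values - values.mean()) / (d @ d))


def consecutive_deltas(days, values) -> list[tuple[int, int, float]]:
    """Differences between adjacent scheduled days, as (day, next_day, delta).

    Pairs follow the actual schedule: for WBC they are (0,1), (1,3), (3,5) —
    missing days are not interpolated.
    """
    days = np.asarray(days)
    values = np.asarray(values, dtype=float)
    if days.size < 2:
        raise InsufficientDataError("need at least 2 points for deltas")
    if days.size != values.size:
        raise ConfigurationError("days and values must have equal length")
    order = np.argsort(days)
    days, values = days[order], values[order]
    return [
        (int(days[i]), int(days[i + 1]), float(values[i + 1] - values[i]))
        for i in range(days.size - 1)
    ]


def apply_rise_rule(
    deltas: list[tuple[int, int, float]], marker: str, rule: RuleConfig | None = None
) -> tuple[bool, dict[tuple[int, int], bool]]:
    """Evaluate the rise rule on a patient's consecutive-day deltas.

    Returns ``(flag_any, per_pair_flags)`` where ``flag_any`` is the OR over
    pairs. Strict comparison by default: delta must exceed, not meet, the
    threshold.
    """
    rule = rule or RuleConfig()
    thr = rule.threshold(marker)
    flags = {
        (a, b): (d > thr if rule.strict else d >= thr) for a, b, d in deltas
    }
    return any(flags.values()), flags


def compute_features(
    cohort: pd.DataFrame,
    window: str = "0-5",
    rule: RuleConfig | None = None,
) -> pd.DataFrame:
    """Trajectory features for every (patient, marker) in a cohort table.

    One row per (patient, marker) with the window slope, each consecutive-day
    delta (``delta_<d>_<d'>``), each per-pair rise flag (``rise_<d>_<d'>``)
    and the any-pair flag ``rise_any``. Delta/flag columns are the union over
    markers; cells for pairs a marker does not measure are left missing.
    """
    if window not in WINDOWS:
        raise ConfigurationError(f"window must be one of {sorted(WINDOWS)}")
    validate_cohort(cohort)
    rule = rule or RuleConfig()
    keep_days = set(WINDOWS[window])

    rows: list[dict] = []
    sub = cohort[cohort["day"].isin(keep_days)]
    for (pid, marker), grp in sub.groupby(["patient_id", "marker"], sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        values = grp["value"].to_numpy()
        row: dict = {
            "patient_id": pid,
            "al_label": int(grp["al_label"].iloc[0]),
            "marker": marker,
            "slope": fit_linear_trend(days, values),
        }
        deltas = consecutive_deltas(days, values)
        flag_any, flags = apply_rise_rule(deltas, str(marker), rule)
        for a, b, d in deltas:
            row[f"delta_{a}_{b}"] = d
        for (a, b), f in flags.items():
            row[f"rise_{a}_{b}"] = f
        row["rise_any"] = flag_any
        rows.append(row)

    features = pd.DataFrame(rows)
    lead = ["patient_id", "al_label", "marker", "slope"]
    pair_cols = sorted(
        (c for c in features.columns if c.startswith(("delta_", "rise_")) and c != "rise_any"),
        key=lambda c: (c.split("_")[0], int(c.split("_")[1]), int(c.split("_")[2])),
    )
    return features[lead + pair_cols + ["rise_any"]]


def marker_pairs(marker: str, window: str = "0-5") -> list[tuple[int, int]]:
    """Consecutive scheduled-day pairs for a marker within a window."""
    if marker not in MARKERS:
        raise ConfigurationError(f"unknown marker {marker!r}")
    days = [d for d in MARKER_DAYS[marker] if d in WINDOWS[window]]
    return [(days[i], days[i + 1]) for i in range(len(days) - 1)]
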