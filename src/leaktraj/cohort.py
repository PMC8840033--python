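"""Synthetic longitudinal biomarker cohorts.

The study population this package targets — patients monitored after colorectal
anastomosis — is described only through group-wise summary statistics: for each
marker (CRP, PCT, WBC) and each scheduled day, a mean and standard deviation in
the leak and no-leak groups. This module turns those summaries into simulated
patient-level cohorts: each patient receives a binary anastomotic-leak (AL)
label and one value per scheduled (marker, day) cell, drawn from the labelled
group's Gaussian (or moment-matched lognormal) marginal, with day-to-day
dependence induced by a shared per-patient latent factor.

Measurement schedule: CRP and PCT are drawn daily (day 0 = preoperative,
days 1-5 = postoperative days 1-5); WBC only on days 0, 1, 3 and 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

MARKERS = ("CRP", "PCT", "WBC")

MARKER_UNITS = {
    "CRP": "mg/L",
    "PCT": "ng/mL",
    "WBC": "x1000/mm3",
}

#: Measurement days per marker; day 0 is the preoperative draw.
MARKER_DAYS = {
    "CRP": (0, 1, 2, 3, 4, 5),
    "PCT": (0, 1, 2, 3, 4, 5),
    "WBC": (0, 1, 3, 5),
}

GROUPS = ("noAL", "AL")

# Group-wise mean (SD) of each marker at each scheduled day, no-leak vs leak,
# in marker units. These are the study conditions every default cohort is
# simulated from.
GROUP_PARAMS: dict[tuple[str, int, str], tuple[float, float]] = {
    # CRP mg/L
    ("CRP", 0, "noAL"): (3.8, 1.8), ("CRP", 0, "AL"): (3.69, 2.09),
    ("CRP", 1, "noAL"): (19.80, 8.25), ("CRP", 1, "AL"): (19.91, 8.16),
    ("CRP", 2, "noAL"): (44.96, 28.45), ("CRP", 2, "AL"): (66.03, 24.77),
    ("CRP", 3, "noAL"): (56.40, 45.02), ("CRP", 3, "AL"): (111.13, 51.00),
    ("CRP", 4, "noAL"): (61.02, 56.90), ("CRP", 4, "AL"): (142.14, 81.60),
    ("CRP", 5, "noAL"): (58.61, 65.57), ("CRP", 5, "AL"): (150.90, 120.17),
    # PCT ng/mL
    ("PCT", 0, "noAL"): (0.57, 0.34), ("PCT", 0, "AL"): (0.61, 0.30),
    ("PCT", 1, "noAL"): (0.84, 0.45), ("PCT", 1, "AL"): (1.28, 0.55),
    ("PCT", 2, "noAL"): (1.32, 0.58), ("PCT", 2, "AL"): (2.22, 1.15),
    ("PCT", 3, "noAL"): (1.68, 0.92), ("PCT", 3, "AL"): (3.39, 1.49),
    ("PCT", 4, "noAL"): (1.99, 0.95), ("PCT", 4, "AL"): (4.75, 2.21),
    ("PCT", 5, "noAL"): (2.21, 1.08), ("PCT", 5, "AL"): (6.31, 2.65),
    # WBC x1000/mm3
    ("WBC", 0, "noAL"): (6.41, 1.60), ("WBC", 0, "AL"): (5.85, 0.88),
    ("WBC", 1, "noAL"): (6.96, 1.44), ("WBC", 1, "AL"): (6.98, 0.84),
    ("WBC", 3, "noAL"): (7.99, 1.57), ("WBC", 3, "AL"): (8.79, 1.13),
    ("WBC", 5, "noAL"): (8.34, 3.34), ("WBC", 5, "AL"): (10.01, 1.51),
}

#: Log-scale scatter of per-patient SDs around the power law SD = a*mean**x
#: in heteroscedastic mode; keeps the (mean, SD) cloud noisy but unattenuated.
HETEROSCEDASTIC_SCATTER = 0.2

#: Observed leak prevalence: 22 of 205 patients.
DEFAULT_N_PATIENTS = 205
DEFAULT_N_AL = 22
DEFAULT_PREVALENCE = DEFAULT_N_AL / DEFAULT_N_PATIENTS

COHORT_COLUMNS = ["patient_id", "al_label", "marker", "day", "value"]


@dataclass(frozen=True)
class MarkerSchedule:
    """A marker's name, unit and ordered measurement days."""

    marker: str
    unit: str
    days: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ConfigurationError(f"unknown marker {self.marker!r}")
        if list(self.days) != sorted(set(self.days)):
            raise ConfigurationError("days must be strictly increasing")
        if any(d < 0 or d > 5 for d in self.days):
            raise ConfigurationError("day indices must lie in [0, 5]")


def marker_schedule(marker: str) -> MarkerSchedule:
    """Return the measurement schedule for ``marker``."""
    if marker not in MARKERS:
        raise ConfigurationError(f"unknown marker {marker!r}")
    return MarkerSchedule(marker, MARKER_UNITS[marker], MARKER_DAYS[marker])


@dataclass
class SimulationConfig:
    """Everything needed to draw one synthetic cohort.

    Parameters
    ----------
    n_patients
        Cohort size.
    prevalence
        Probability that a patient carries the AL label (ignored when
        ``fixed_group_sizes`` is set).
    group_params
        Map ``(marker, day, group)`` -> ``(mean, sd)`` in marker units, with
        ``group`` in ``{"noAL", "AL"}``. Must cover both groups at every
        scheduled day of every marker it mentions.
    within_patient_correlation
        rho in [0, 1): fraction of each standardized measurement's variance
        contributed by a single per-patient latent factor, so any two
        measurements of one patient correlate at rho while marginals stay
        exactly Gaussian(mean, sd).
    heteroscedastic_power
        Optional map ``marker -> (a, x)``. When set for a marker, each
        patient's within-window mean and SD are controlled directly: a level
        m_i is sampled uniformly across the span of the group's configured
        day means, a target SD a * m_i**x picks up a lognormal scatter of
        ``HETEROSCEDASTIC_SCATTER`` on the log scale, and the day values are
        a random standardized pattern rescaled so the patient's sample mean
        and sample SD equal m_i and the target exactly. The per-patient
        (mean, SD) cloud therefore follows SD = a * mean**x up to that
        scatter, which is what the variability-index machinery estimates.
    floor_at_zero
        Clip negative draws to 0 (concentrations cannot be negative). Disable
        to test estimators against the untruncated Gaussian model.
    family
        "gaussian" or "lognormal"; the latter moment-matches each cell's
        (mean, sd), for right-skewed marker distributions.
    fixed_group_sizes
        Optional ``(n_AL, n_noAL)`` to reproduce the study's exact 22/183
        split instead of Bernoulli assignment.
    seed
        RNG seed; identical configs reproduce identical cohorts bit-for-bit.
    """

    n_patients: int = DEFAULT_N_PATIENTS
    prevalence: float = DEFAULT_PREVALENCE
    group_params: dict[tuple[str, int, str], tuple[float, float]] = field(
        default_factory=lambda: dict(GROUP_PARAMS)
    )
    within_patient_correlation: float = 0.3
    heteroscedastic_power: dict[str, tuple[float, float]] | None = None
    floor_at_zero: bool = True
    family: str = "gaussian"
    fixed_group_sizes: tuple[int, int] | None = None
    seed: int = 0

    def markers(self) -> list[str]:
        """Markers mentioned in ``group_params``, in canonical order."""
        present = {m for (m, _, _) in self.group_params}
        return [m for m in MARKERS if m in present]

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError("prevalence must lie in [0, 1]")
        if not 0.0 <= self.within_patient_correlation < 1.0:
            raise ConfigurationError("within_patient_correlation must lie in [0, 1)")
        if self.family not in ("gaussian", "lognormal"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.fixed_group_sizes is not None:
            n_al, n_no = self.fixed_group_sizes
            if n_al < 0 or n_no < 0 or n_al + n_no != self.n_patients:
                raise ConfigurationError(
                    "fixed_group_sizes must be non-negative and sum to n_patients"
                )
        if not self.group_params:
            raise ConfigurationError("group_params is empty")
        for (marker, day, group), (mean, sd) in self.group_params.items():
            if marker not in MARKERS:
                raise ConfigurationError(f"unknown marker {marker!r}")
            if group not in GROUPS:
                raise ConfigurationError(f"unknown group {group!r}")
            if day not in MARKER_DAYS[marker]:
                raise ConfigurationError(
                    f"day {day} is not on the {marker} schedule {MARKER_DAYS[marker]}"
                )
            if sd < 0:
                raise ConfigurationError(f"negative sd for {(marker, day, group)}")
            if self.family == "lognormal" and mean <= 0:
                raise ConfigurationError("lognormal family requires positive means")
        for marker in self.markers():
            for day in MARKER_DAYS[marker]:
                for group in GROUPS:
                    if (marker, day, group) not in self.group_params:
                        raise ConfigurationError(
                            f"missing parameters for {(marker, day, group)}"
                        )


def table2_default_config(**overrides) -> SimulationConfig:
    """Config pre-filled with the study's group-wise means/SDs and prevalence.

    Keyword overrides are applied on top (e.g. ``n_patients=20_000, seed=7``).
    """
    return replace(SimulationConfig(), **overrides)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment-matched latent normal: exp(mu + sigma Z) has the given mean/sd
    if mean <= 0:
        raise ConfigurationError("lognormal family requires positive means")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a cohort; long format, one row per (patient, marker, scheduled day).

    Columns: ``patient_id, al_label, marker, day, value``. The draw order is
    fixed (labels, shared factors, then markers in canonical order, days
    ascending), so a given config is bit-for-bit reproducible.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    if config.fixed_group_sizes is not None:
        n_al, n_no = config.fixed_group_sizes
        labels = np.zeros(n, dtype=np.int64)
        labels[rng.permutation(n)[:n_al]] = 1
    else:
        labels = (rng.random(n) < config.prevalence).astype(np.int64)

    rho = config.within_patient_correlation
    shared = rng.standard_normal(n)  # per-patient latent factor

    frames: list[pd.DataFrame] = []
    hp = config.heteroscedastic_power or {}
    for marker in config.markers():
        days = MARKER_DAYS[marker]
        if marker in hp:
            a, x = hp[marker]
            lo = np.empty(n)
            hi = np.empty(n)
            for g_idx, group in enumerate(GROUPS):
                means = [config.group_params[(marker, d, group)][0] for d in days]
                lo[labels == g_idx] = min(means)
                hi[labels == g_idx] = max(means)
            level = rng.uniform(lo, hi)
            sd_i = a * np.power(level, x) * np.exp(
                HETEROSCEDASTIC_SCATTER * rng.standard_normal(n)
            )
            # standardized day pattern => sample mean/SD hit the targets exactly
            z = rng.standard_normal((n, len(days)))
            z = z - z.mean(axis=1, keepdims=True)
            z /= np.maximum(z.std(axis=1, ddof=1, keepdims=True), 1e-12)
            vals_by_day = level[:, None] + sd_i[:, None] * z
            for j, day in enumerate(days):
                vals = vals_by_day[:, j]
                if config.floor_at_zero:
                    vals = np.maximum(vals, 0.0)
                frames.append(_day_frame(labels, marker, day, vals))
            continue

        for day in days:
            eps = rng.standard_normal(n)
            z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * eps
            mean = np.where(
                labels == 1,
                config.group_params[(marker, day, "AL")][0],
                config.group_params[(marker, day, "noAL")][0],
            )
            sd = np.where(
                labels == 1,
                config.group_params[(marker, day, "AL")][1],
                config.group_params[(marker, day, "noAL")][1],
            )
            if config.family == "lognormal":
                mu = np.empty(n)
                sig = np.empty(n)
                for g_idx, group in enumerate(GROUPS):
                    m, s = config.group_params[(marker, day, group)]
                    mu_g, sig_g = _lognormal_params(m, s)
                    mu[labels == g_idx] = mu_g
                    sig[labels == g_idx] = sig_g
                vals = np.exp(mu + sig * z)
            else:
                vals = mean + sd * z
            if config.floor_at_zero:
                vals = np.maximum(vals, 0.0)
            frames.append(_day_frame(labels, marker, day, vals))

    cohort = pd.concat(frames, ignore_index=True)
    cohort = cohort.sort_values(["patient_id", "marker", "day"], kind="stable")
    return cohort.reset_index(drop=True)


def _day_frame(labels: np.ndarray, marker: str, day: int, vals: np.ndarray) -> pd.DataFrame:
    n = len(labels)
    return pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=np.int64),
            "al_label": labels,
            "marker": marker,
            "day": np.full(n, day, dtype=np.int64),
            "value": vals,
        }
    )


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the cohort-table contract: columns, schedule completeness, labels."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"cohort table missing columns {missing}")
    if not set(cohort["al_label"].unique()) <= {0, 1}:
        raise ConfigurationError("al_label must be 0/1")
    labels_per_patient = cohort.groupby("patient_id")["al_label"].nunique()
    if (labels_per_patient != 1).any():
        raise ConfigurationError("each patient must have exactly one al_label")
    for marker, grp in cohort.groupby("marker"):
        days = set(grp["day"].unique())
        if not days <= set(MARKER_DAYS[str(marker)]):
            raise ConfigurationError(
                f"{marker} measured on days outside its schedule: {sorted(days)}"
            )
        counts = grp.groupby(["patient_id", "day"]).size()
        if (counts != 1).any():
            raise ConfigurationError(f"duplicate (patient, day) values for {marker}")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (UTF-8, header row, full float precision)."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV produced by :func:`write_cohort`."""
    cohort = pd.read_csv(
        path,
        dtype={"patient_id": np.int64, "al_label": np.int64, "day": np.int64,
               "marker": str, "value": np.float64},
    )
    validate_cohort(cohort)
    return cohort
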