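"""Intra-individual (visit-to-visit) variability indices.

Three per-patient indices summarise how much a marker fluctuates across a
patient's scheduled measurements:

- within-individual SD: sample standard deviation (n-1 denominator);
- CV: SD divided by the within-individual mean;
- VIM (variability independent of the mean): SD / mean**x * cohort_mean**x,
  where the exponent x comes from fitting SD = a * mean**x across patients by
  nonlinear least squares.

Raw SD rises with the level of the marker; CV over-corrects when SD grows
more slowly than the mean. VIM rescales SD by the fitted mean-dependence so
that, when the power law holds, the index is uncorrelated with the patient's
level — that decorrelation is its defining property. VIM keeps the marker's
units, and the exponent is estimated once per marker on the pooled cohort
(both outcome groups together).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, InsufficientDataError, SingleClassError
from .trajectory import WINDOWS
from .cohort import validate_cohort

__all__ = [
    "PowerLawFit", "GroupComparison", "within_subject_stats", "fit_power_law",
    "vim", "compute_variability", "compare_groups", "variability_comparison",
]

INDEX_NAMES = ("SD", "CV", "VIM")


@dataclass
class PowerLawFit:
    """Least-squares fit of SD = a * mean**x across patients."""

    a: float
    x: float
    cohort_mean: float
    n_points: int
    rss: float
    converged: bool


@dataclass
class GroupComparison:
    """One Table-style row: group means, Welch CI on the difference, MW p."""

    index: str
    mean_no_al: float
    sd_no_al: float
    mean_al: float
    sd_al: float
    diff: float            # AL minus no-AL
    ci_low: float
    ci_high: float
    p_value: float


def within_subject_stats(values) -> tuple[float, float, float]:
    """(mean, SD, CV) of one patient's repeated measurements.

    SD uses the n-1 denominator; CV = SD/mean, NaN when the mean is 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("need at least 2 measurements")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cv = sd / mean if mean != 0 else float("nan")
    return mean, sd, cv


def fit_power_law(means, sds, cohort_mean: float | None = None) -> PowerLawFit:
    """Fit SD = a * mean**x over the per-patient (mean, SD) cloud.

    Nonlinear least squares on the raw scale, initialised from log-log OLS on
    the points with positive SD. Requires >= 3 points with positive means
    that are not all equal.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.size != sds.size:
        raise ConfigurationError("means and sds must have equal length")
    ok = means > 0
    means, sds = means[ok], sds[ok]
    if means.size < 3:
        raise InsufficientDataError("need >= 3 points with positive means")
    if np.ptp(means) == 0:
        raise ConfigurationError("all means equal; exponent not identifiable")
    if cohort_mean is None:
        cohort_mean = float(means.mean())

    pos = sds > 0
    if pos.sum() >= 2 and np.ptp(means[pos]) > 0:
        slope, intercept = np.polyfit(np.log(means[pos]), np.log(sds[pos]), 1)
        p0 = (float(np.exp(intercept)), float(slope))
    else:
        p0 = (max(float(sds.mean()), 1e-8), 0.0)

    converged = True
    try:
        with warnings.catch_warnings():
            # the parameter covariance is unused; it degenerates at exact fits
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            (a_hat, x_hat), _ = optimize.curve_fit(
                lambda m, a, x: a * np.power(m, x), means, sds, p0=p0, maxfev=10000
            )
    except RuntimeError:
        a_hat, x_hat = p0
        converged = False
    rss = float(np.sum((sds - a_hat * np.power(means, x_hat)) ** 2))
    return PowerLawFit(float(a_hat), float(x_hat), cohort_mean,
                       int(means.size), rss, converged)


def vim(within_sd: float, within_mean: float, fit: PowerLawFit) -> float:
    """VIM = SD / mean**x * cohort_mean**x; NaN for non-positive means."""
    if within_mean <= 0:
        return float("nan")
    return within_sd / within_mean ** fit.x * fit.cohort_mean ** fit.x


def compute_variability(
    cohort: pd.DataFrame,
    window: str = "0-5",
    min_points: int = 3,
) -> tuple[pd.DataFrame, dict[str, PowerLawFit]]:
    """Per-patient SD/CV/VIM for every marker, plus the per-marker power fits.

    Patients contributing fewer than ``min_points`` measurements in the window
    are dropped for that marker. The cohort mean entering VIM is the mean of
    all of the marker's measurements in the window.
    """
    if window not in WINDOWS:
        raise ConfigurationError(f"window must be one of {sorted(WINDOWS)}")
    if min_points < 2:
        raise ConfigurationError("min_points must be >= 2")
    validate_cohort(cohort)
    sub = cohort[cohort["day"].isin(WINDOWS[window])]

    rows: list[dict] = []
    fits: dict[str, PowerLawFit] = {}
    for marker, grp in sub.groupby("marker", sort=True):
        per_patient = []
        for (pid, label), g in grp.groupby(["patient_id", "al_label"], sort=True):
            vals = g["value"].to_numpy()
            if vals.size < min_points:
                continue
            mean, sd, cv = within_subject_stats(vals)
            per_patient.append(
                {"patient_id": pid, "al_label": int(label), "marker": marker,
                 "within_mean": mean, "within_sd": sd, "cv": cv}
            )
        if not per_patient:
            continue
        dfm = pd.DataFrame(per_patient)
        fit = fit_power_law(
            dfm["within_mean"], dfm["within_sd"],
            cohort_mean=float(grp["value"].mean()),
        )
        fits[str(marker)] = fit
        dfm["vim"] = [
            vim(s, m, fit) for s, m in zip(dfm["within_sd"], dfm["within_mean"])
        ]
        rows.extend(dfm.to_dict("records"))
    return pd.DataFrame(rows), fits


def compare_groups(values, labels, index: str = "") -> GroupComparison:
    """Compare an index between leak and no-leak patients.

    Point estimate and 95% CI of the mean difference come from the Welch
    (unequal-variance) t construction; the p-value is a tie-corrected
    asymptotic Mann-Whitney U test, the study's stated test for continuous
    comparisons.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    al = values[labels == 1]
    no = values[labels == 0]
    if al.size == 0 or no.size == 0:
        raise SingleClassError("both groups must be non-empty")
    mw = stats.mannwhitneyu(al, no, alternative="two-sided", method="asymptotic")
    welch = stats.ttest_ind(al, no, equal_var=False)
    ci = welch.confidence_interval(0.95)
    return GroupComparison(
        index=index,
        mean_no_al=float(no.mean()),
        sd_no_al=float(no.std(ddof=1)) if no.size > 1 else 0.0,
        mean_al=float(al.mean()),
        sd_al=float(al.std(ddof=1)) if al.size > 1 else 0.0,
        diff=float(al.mean() - no.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(mw.pvalue),
    )


def variability_comparison(indices: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of SD, CV and VIM for each marker (one tidy row each)."""
    col_for = {"SD": "within_sd", "CV": "cv", "VIM": "vim"}
    rows = []
    for marker, grp in indices.groupby("marker", sort=True):
        for index in INDEX_NAMES:
            vals = grp[col_for[index]].to_numpy()
            keep = ~np.isnan(vals)
            comp = compare_groups(vals[keep], grp["al_label"].to_numpy()[keep], index)
            row = {"marker": marker, **vars(comp)}
            rows.append(row)
    return pd.DataFrame(rows)
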