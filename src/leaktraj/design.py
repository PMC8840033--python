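"""Study-design arithmetic: finite-population sample size and descriptives."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "SampleSizeSpec", "finite_population_sample_size", "round_half_up",
    "percentage", "describe_categorical", "describe_continuous",
]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the finite-population (Cochran-corrected) sample size.

    ``population_size``: yearly eligible population N; ``margin_of_error``:
    half-width e of the CI as a fraction; ``confidence``: two-sided level;
    ``response_fraction``: anticipated proportion p (0.5 is the conservative
    maximum-variance choice).
    """

    population_size: int = 420
    margin_of_error: float = 0.05
    confidence: float = 0.95
    response_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ConfigurationError("population_size must be >= 1")
        if not 0.0 < self.margin_of_error < 1.0:
            raise ConfigurationError("margin_of_error must lie in (0, 1)")
        if not 0.0 < self.confidence < 1.0:
            raise ConfigurationError("confidence must lie in (0, 1)")
        if not 0.0 < self.response_fraction < 1.0:
            raise ConfigurationError("response_fraction must lie in (0, 1)")


def finite_population_sample_size(spec: SampleSizeSpec | None = None, **kwargs) -> int:
    """Minimum n = ceil(N q / ((N-1) e^2 + q)) with q = z^2 p (1-p).

    z is the two-sided normal quantile for the confidence level. The result
    never exceeds the population size.
    """
    spec = spec or SampleSizeSpec(**kwargs)
    z = stats.norm.ppf(0.5 + spec.confidence / 2.0)
    p = spec.response_fraction
    q = z * z * p * (1.0 - p)
    n_float = spec.population_size * q / (
        (spec.population_size - 1) * spec.margin_of_error ** 2 + q
    )
    return int(math.ceil(n_float - 1e-12))


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (reporting convention)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """count/total as a percentage, half-up rounded (e.g. 22/205 -> 10.7)."""
    if total <= 0:
        raise ConfigurationError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


def describe_categorical(series: pd.Series) -> pd.DataFrame:
    """Frequency (%) table for one categorical attribute."""
    counts = series.value_counts(sort=False)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "category": counts.index.astype(str),
            "count": counts.to_numpy(),
            "pct": [percentage(int(c), total) for c in counts],
        }
    )


def describe_continuous(series: pd.Series) -> dict[str, float]:
    """mean, SD (n-1), min and max of one continuous attribute."""
    vals = np.asarray(series, dtype=float)
    if vals.size == 0:
        raise ConfigurationError("empty series")
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "min": float(vals.min()),
        "max": float(vals.max()),
    }
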