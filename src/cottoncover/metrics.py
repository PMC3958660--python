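"""Validation statistics: RMSE, R-squared and a linear-fit utility.

Two R-squared conventions are used deliberately. Model validation (observed
vs. model-simulated values) uses the residual-based definition
1 - SS_res/SS_tot, which penalizes bias and can be negative for a model
worse than the observed mean. The linear-fit utility, used for comparing
camera canopy cover against handheld-sensor indices (NDVI, RVI), reports
the squared Pearson correlation of the regression, the usual quantity for
a scatterplot fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["PairedSeries", "rmse", "r_squared", "linear_fit"]


@dataclass(frozen=True)
class PairedSeries:
    """Paired observed (O_m) and simulated (S_m) values, same units."""

    observed: np.ndarray
    simulated: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.observed, dtype=np.float64)
        s = np.asarray(self.simulated, dtype=np.float64)
        if o.ndim != 1 or s.ndim != 1:
            raise ValueError("observed and simulated must be 1-D sequences")
        if o.size != s.size:
            raise ValueError(
                f"length mismatch: {o.size} observed vs {s.size} simulated"
            )
        if o.size == 0:
            raise ValueError("paired series must be non-empty")
        object.__setattr__(self, "observed", o)
        object.__setattr__(self, "simulated", s)

    @property
    def n(self) -> int:
        return int(self.observed.size)


def _as_series(
    series: PairedSeries | None,
    observed: Sequence[float] | None,
    simulated: Sequence[float] | None,
) -> PairedSeries:
    if series is not None:
        return series
    return PairedSeries(np.asarray(observed), np.asarray(simulated))


def rmse(
    series: PairedSeries | None = None,
    observed: Sequence[float] | None = None,
    simulated: Sequence[float] | None = None,
) -> float:
    """Root mean square error sqrt(sum((O_m - S_m)^2) / n).

    Accepts either a :class:`PairedSeries` or two sequences. Zero exactly
    when the series are identical; symmetric in its two arguments.
    """
    s = _as_series(series, observed, simulated)
    return float(np.sqrt(np.mean((s.observed - s.simulated) ** 2)))


def r_squared(
    series: PairedSeries | None = None,
    observed: Sequence[float] | None = None,
    simulated: Sequence[float] | None = None,
) -> float:
    """Residual-based coefficient of determination.

    1 - sum((O - S)^2) / sum((O - mean(O))^2). Requires n >= 2 and a
    non-constant observed series (otherwise SS_tot = 0 and the ratio is
    undefined).
    """
    s = _as_series(series, observed, simulated)
    if s.n < 2:
        raise ValueError("r_squared requires at least 2 pairs")
    ss_tot = float(np.sum((s.observed - s.observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r_squared undefined for a constant observed series")
    ss_res = float(np.sum((s.observed - s.simulated) ** 2))
    return 1.0 - ss_res / ss_tot


def linear_fit(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Ordinary least squares line y = slope*x + intercept.

    Returns (slope, intercept, r_squared) where r_squared is the squared
    Pearson correlation. A constant ``y`` gives a flat line with
    r_squared = 0 by convention (no variance to explain). A constant
    ``x`` is a domain error.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ValueError("linear_fit requires two equal-length series, n >= 2")
    if np.ptp(x) == 0.0:
        raise ValueError("linear_fit undefined for constant x")
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
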