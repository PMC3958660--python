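"""Fitting the exponential canopy-cover calibration model y = k * e^(b*CC).

``k`` is the curve's initial value (the predicted property at zero cover,
in the property's units) and ``b`` the unitless shaping parameter. The fit
minimizes squared error on the original y scale by nonlinear least
squares, initialized from the closed-form ordinary least squares fit of
ln(y) on CC; on noiseless exponential data the two coincide. Fitting on
the original scale matches how goodness of fit (RMSE, R^2) is reported:
in the property's units, not log units.

Datasets can be grouped (e.g. by cultivar or by N fertilizer rate) and
fitted per group; higher N rates shift both k and b upward in cotton, so
per-group parameters are the norm rather than the exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import metrics

__all__ = [
    "PROPERTIES",
    "CalibrationDataset",
    "ExpModel",
    "FitReport",
    "SkippedGroup",
    "InsufficientDataError",
    "ConvergenceError",
    "fit_exponential",
    "fit_by_group",
    "log_linear_fit",
]

#: Crop properties the calibration targets, with their units.
PROPERTIES = {
    "total_N": "g m-2",   # aboveground total N content
    "LAI": "m2 m-2",      # leaf area index
    "biomass": "g m-2",   # aboveground dry biomass
}


class InsufficientDataError(ValueError):
    """Fewer records than the fit requires (n >= 3)."""


class ConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the log-linear fallback."""

    def __init__(self, message: str, fallback: "ExpModel"):
        super().__init__(message)
        self.fallback = fallback


@dataclass(frozen=True)
class ExpModel:
    """Parameters of y = k * e^(b * CC) for one crop property."""

    k: float
    b: float
    property: str = "total_N"
    group: str = "pooled"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")


@dataclass(frozen=True)
class FitReport:
    """A fitted model with its goodness of fit on the training data."""

    model: ExpModel
    rmse: float
    r_squared: float
    pearson_r_squared: float
    n: int


@dataclass(frozen=True)
class SkippedGroup:
    """A group that could not be fitted, with the reason."""

    group: str
    reason: str


@dataclass
class CalibrationDataset:
    """(CC, y) records for calibration, optionally labeled by group.

    All y must be positive (the exponential model's range) and all cc in
    [0, 1]. Construct directly from arrays or via :meth:`from_frame` /
    :meth:`from_csv` for tables with columns cc, y and optionally
    property, group.
    """

    cc: np.ndarray
    y: np.ndarray
    group: np.ndarray = field(default=None)  # type: ignore[assignment]
    property: str = "total_N"

    def __post_init__(self) -> None:
        cc = np.asarray(self.cc, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if cc.shape != y.shape or cc.ndim != 1:
            raise ValueError("cc and y must be equal-length 1-D arrays")
        bad_cc = np.flatnonzero((cc < 0) | (cc > 1))
        if bad_cc.size:
            raise ValueError(
                f"cc out of [0, 1] at record {bad_cc[0]}: {cc[bad_cc[0]]}"
            )
        bad_y = np.flatnonzero(y <= 0)
        if bad_y.size:
            raise ValueError(
                f"non-positive y at record {bad_y[0]}: {y[bad_y[0]]} "
                "(exponential model requires y > 0)"
            )
        if self.group is None:
            group = np.full(cc.shape, "pooled", dtype=object)
        else:
            group = np.asarray(self.group, dtype=object)
            if group.shape != cc.shape:
                raise ValueError("group labels must match record count")
        self.cc, self.y, self.group = cc, y, group

    def __len__(self) -> int:
        return int(self.cc.size)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, property: str | None = None) -> "CalibrationDataset":
        prop = property or (
            str(df["property"].iloc[0]) if "property" in df.columns else "total_N"
        )
        group = df["group"].to_numpy(dtype=object) if "group" in df.columns else None
        return cls(
            cc=df["cc"].to_numpy(), y=df["y"].to_numpy(), group=group, property=prop
        )

    @classmethod
    def from_csv(cls, path, property: str | None = None) -> "CalibrationDataset":
        return cls.from_frame(pd.read_csv(path), property=property)

    def subset(self, group: str) -> "CalibrationDataset":
        mask = self.group == group
        return CalibrationDataset(
            cc=self.cc[mask], y=self.y[mask],
            group=self.group[mask], property=self.property,
        )


def log_linear_fit(cc: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Closed-form OLS of ln(y) on cc; returns (k, b).

    Solves the normal equations directly. Exact for noiseless exponential
    data; used as the nonlinear fit's initializer and as an independent
    oracle in tests.
    """
    cc = np.asarray(cc, dtype=np.float64)
    ly = np.log(np.asarray(y, dtype=np.float64))
    design = np.column_stack([np.ones_like(cc), cc])
    (intercept, slope), *_ = np.linalg.lstsq(design, ly, rcond=None)
    return float(np.exp(intercept)), float(slope)


def fit_exponential(
    data: CalibrationDataset,
    group: Optional[str] = None,
    max_iterations: int = 200,
    tol: float = 1e-10,
) -> FitReport:
    """Fit y = k * e^(b * CC) to ``data`` by nonlinear least squares.

    Parameters
    ----------
    data : CalibrationDataset
    group : str, optional
        Restrict the fit to one group label.
    max_iterations, tol
        Iteration cap and parameter-change tolerance of the optimizer.

    Returns a :class:`FitReport` with RMSE and the residual-based R^2 of
    observed against fitted y (squared Pearson correlation is reported
    alongside). Raises :class:`InsufficientDataError` for n < 3 and
    :class:`ConvergenceError` (carrying the log-linear fit) if the
    optimizer fails.
    """
    if group is not None:
        data = data.subset(group)
    n = len(data)
    if n < 3:
        raise InsufficientDataError(
            f"exponential fit requires at least 3 records, got {n}"
            + (f" in group {group!r}" if group else "")
        )
    if np.ptp(data.cc) == 0.0:
        raise ValueError("cc values are all identical; model is unidentifiable")

    k0, b0 = log_linear_fit(data.cc, data.y)
    group_label = group if group is not None else (
        str(data.group[0]) if np.all(data.group == data.group[0]) else "pooled"
    )
    try:
        popt, _ = curve_fit(
            lambda cc, k, b: k * np.exp(b * cc),
            data.cc,
            data.y,
            p0=(k0, b0),
            bounds=([1e-12, -np.inf], [np.inf, np.inf]),
            xtol=tol,
            max_nfev=max_iterations * 3,  # ~3 evaluations per iteration
        )
    except RuntimeError as exc:
        fallback = ExpModel(k=k0, b=b0, property=data.property, group=group_label)
        raise ConvergenceError(
            f"nonlinear fit did not converge within {max_iterations} iterations; "
            "log-linear initializer attached", fallback,
        ) from exc

    model = ExpModel(
        k=float(popt[0]), b=float(popt[1]),
        property=data.property, group=group_label,
    )
    fitted = model.k * np.exp(model.b * data.cc)
    series = metrics.PairedSeries(data.y, fitted)
    return FitReport(
        model=model,
        rmse=metrics.rmse(series),
        r_squared=metrics.r_squared(series),
        pearson_r_squared=float(np.corrcoef(data.y, fitted)[0, 1] ** 2),
        n=n,
    )


def fit_by_group(
    data: CalibrationDataset,
) -> tuple[list[FitReport], list[SkippedGroup]]:
    """Fit the exponential model separately for every group label.

    Returns (reports, skipped): one report per fittable group, sorted by
    label; groups violating the fit preconditions are recorded as skipped
    rather than aborting the whole run.
    """
    if len(data) == 0:
        raise InsufficientDataError("empty dataset")
    reports: list[FitReport] = []
    skipped: list[SkippedGroup] = []
    for label in sorted(set(data.group)):
        try:
            reports.append(fit_exponential(data, group=str(label)))
        except (InsufficientDataError, ValueError, ConvergenceError) as exc:
            skipped.append(SkippedGroup(group=str(label), reason=str(exc)))
    return reports, skipped
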