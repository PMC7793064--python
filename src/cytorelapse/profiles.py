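"""Per-patient marker expression representations.

Three representations of a marker's per-cell intensity distribution:

* summary statistics — median (MFI), mean and sample standard deviation;
* the *percentile vector* — empirical quantiles on a fixed grid (default
  5th to 95th in steps of 5, P=19), the feature representation the
  Fisher's-Ratio analysis operates on;
* a generalized-logistic fit of the cumulative intensity curve,

      F(I) = K / (1 + A exp(-alpha I))^(1/gamma),   K = 1,

  where ``alpha`` is the growth rate and ``gamma`` locates the point of
  maximum growth (gamma=1 is the logistic curve; gamma -> 0 approaches the
  Gompertz curve).  ``A`` is not free: the curve is anchored to pass through
  the first percentile of the distribution, i.e. F(I_p1) = 0.01, which
  determines ``A`` in closed form given (alpha, gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_GRID", "PercentileMatrix", "LogisticFit",
    "percentile_vector", "percentile_matrix", "summaries", "summary_table",
    "generalized_logistic", "gompertz", "fit_logistic",
]

DEFAULT_GRID: tuple[float, ...] = tuple(range(5, 100, 5))   # 5, 10, ..., 95

_ANCHOR_LEVEL = 0.01   # F at the first percentile of the distribution


@dataclass
class PercentileMatrix:
    """M markers x P percentile levels for one patient."""

    values: np.ndarray                  # (M, P)
    markers: list[str]
    grid: tuple[float, ...]
    patient_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.markers), len(self.grid)):
            raise ValueError("percentile matrix shape must be (markers, grid levels)")

    def row(self, marker: str) -> np.ndarray:
        return self.values[self.markers.index(marker)]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (patient, marker, level)."""
        m, p = self.values.shape
        return pd.DataFrame({
            "patient_id": self.patient_id,
            "label": self.label,
            "marker": np.repeat(self.markers, p),
            "level": np.tile(self.grid, m),
            "value": self.values.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "list[PercentileMatrix]":
        out = []
        for pid, sub in df.groupby("patient_id", sort=True):
            wide = sub.pivot(index="marker", columns="level", values="value")
            grid = tuple(float(g) for g in wide.columns)
            label = sub["label"].iloc[0]
            out.append(cls(values=wide.to_numpy(), markers=list(wide.index),
                           grid=grid, patient_id=str(pid),
                           label=None if pd.isna(label) else str(label)))
        return out


def percentile_vector(values: np.ndarray, grid=DEFAULT_GRID) -> np.ndarray:
    """Empirical percentiles at the grid levels (linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute percentiles of an empty event set")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) or grid.min() <= 0 or grid.max() >= 100:
        raise ValueError("percentile grid must be strictly increasing within (0, 100)")
    return np.percentile(values, grid, method="linear")


def percentile_matrix(events: np.ndarray, markers: list[str], grid=DEFAULT_GRID,
                      patient_id: str = "", label: str | None = None) -> PercentileMatrix:
    """Percentile vectors of every marker column of an event matrix."""
    events = np.asarray(events, dtype=float)
    vals = np.stack([percentile_vector(events[:, j], grid) for j in range(events.shape[1])])
    return PercentileMatrix(values=vals, markers=list(markers), grid=tuple(grid),
                            patient_id=patient_id, label=label)


def summaries(events: np.ndarray, markers: list[str]) -> pd.DataFrame:
    """Per-marker median (MFI), mean and sample (n-1) standard deviation."""
    events = np.asarray(events, dtype=float)
    if events.shape[0] < 2:
        raise ValueError("summaries require at least two events")
    return pd.DataFrame({
        "marker": list(markers),
        "median": np.median(events, axis=0),
        "mean": np.mean(events, axis=0),
        "sd": np.std(events, axis=0, ddof=1),
    })


# ---------------------------------------------------------------------------
# generalized-logistic fitting
# ---------------------------------------------------------------------------

def generalized_logistic(intensity, A: float, alpha: float, gamma: float,
                         K: float = 1.0) -> np.ndarray:
    i = np.asarray(intensity, dtype=float)
    return K / (1.0 + A * np.exp(-alpha * i)) ** (1.0 / gamma)


def gompertz(intensity, b: float, c: float, K: float = 1.0) -> np.ndarray:
    """Gompertz curve K exp(-b exp(-c I)), the gamma -> 0 limit."""
    i = np.asarray(intensity, dtype=float)
    return K * np.exp(-b * np.exp(-c * i))


def _anchored_A(alpha: float, gamma: float, anchor: float) -> float:
    # F(anchor) = 0.01  =>  A = (0.01^-gamma - 1) e^(alpha * anchor)
    return float((_ANCHOR_LEVEL ** -gamma - 1.0) * np.exp(alpha * anchor))


@dataclass
class LogisticFit:
    """Fitted generalized-logistic parameters for one cumulative curve."""

    A: float
    alpha: float
    gamma: float
    rss: float
    anchor: float
    converged: bool
    message: str = ""
    K: float = 1.0

    def predict(self, intensity) -> np.ndarray:
        return generalized_logistic(intensity, self.A, self.alpha, self.gamma, self.K)


def fit_logistic(intensity, cumulative, anchor: float | None = None) -> LogisticFit:
    """Fit the anchored generalized-logistic curve to (I, F) pairs.

    ``anchor`` is the intensity at the first percentile of the underlying
    distribution; if omitted it is interpolated from the supplied curve at
    F = 0.01.  ``alpha`` and ``gamma`` are estimated by bounded nonlinear
    least squares (log-parameterised) from a small grid of restarts; ``A``
    follows from the anchor in closed form.  Non-convergence is reported in
    the returned object, not raised.
    """
    i = np.asarray(intensity, dtype=float)
    f = np.asarray(cumulative, dtype=float)
    if i.size != f.size or i.size < 5:
        raise ValueError("need at least 5 (intensity, cumulative) pairs of equal length")
    order = np.argsort(i)
    i, f = i[order], f[order]
    if np.any(np.diff(f) < -1e-9):
        raise ValueError("cumulative values must be nondecreasing in intensity")

    if anchor is None:
        anchor = float(np.interp(_ANCHOR_LEVEL, f, i))

    def residuals(theta: np.ndarray) -> np.ndarray:
        alpha, gamma = np.exp(theta)
        return generalized_logistic(i, _anchored_A(alpha, gamma, anchor), alpha, gamma) - f

    # starting alpha from the slope near the empirical median (logistic:
    # slope at midpoint = alpha / 4), gamma = 1
    mid = np.searchsorted(f, 0.5).clip(1, i.size - 1)
    di = i[mid] - i[mid - 1]
    slope = (f[mid] - f[mid - 1]) / di if di > 0 else 1.0
    alpha0 = max(4.0 * slope, 1e-2)

    best = None
    for fa in (0.3, 1.0, 3.0):
        for fg in (0.3, 1.0, 3.0):
            theta0 = np.log([alpha0 * fa, 1.0 * fg])
            try:
                sol = least_squares(residuals, theta0, bounds=(np.log([1e-4, 1e-3]),
                                                               np.log([1e4, 50.0])))
            except Exception:   # pragma: no cover - defensive
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return LogisticFit(A=np.nan, alpha=np.nan, gamma=np.nan, rss=np.inf,
                           anchor=anchor, converged=False,
                           message="all restarts failed")
    alpha, gamma = np.exp(best.x)
    return LogisticFit(A=_anchored_A(alpha, gamma, anchor), alpha=float(alpha),
                       gamma=float(gamma), rss=float(2 * best.cost), anchor=anchor,
                       converged=bool(best.success), message=str(best.message))


def summary_table(samples, include_fits: bool = False, grid=DEFAULT_GRID) -> pd.DataFrame:
    """Tidy per-(patient, marker) statistics table for class comparisons.

    One row per patient and marker with the median/mean/sd summaries and,
    when ``include_fits`` is set, the alpha/gamma parameters of the
    generalized-logistic fit to the percentile curve (intensity vs
    cumulative level).
    """
    rows = []
    for s in samples:
        summ = summaries(s.events, s.markers)
        for _, rec in summ.iterrows():
            row = {"patient_id": s.patient_id, "label": s.label,
                   "marker": rec["marker"], "median": rec["median"],
                   "mean": rec["mean"], "sd": rec["sd"]}
            if include_fits:
                vec = percentile_vector(s.marker_column(rec["marker"]), grid)
                fit = fit_logistic(vec, np.asarray(grid, dtype=float) / 100.0)
                row["alpha"] = fit.alpha if fit.converged else np.nan
                row["gamma"] = fit.gamma if fit.converged else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
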