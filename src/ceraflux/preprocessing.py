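"""Smoothing-spline interpolation of the sampled concentration series.

The raw data are duplicate measurements every 5 minutes over 0-30 min.
Assuming the stress response is a continuous phenomenon, each pool's
replicates are fit with a cubic smoothing spline and resampled on a
per-minute grid; the discrete first differences X(t) - X(t-1) serve as the
slope targets of the flux estimation stage (the spline's analytic
derivative is exposed for diagnostics only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

MINUTE_GRID = np.arange(31.0)


@dataclass
class SplineFit:
    """Smoothing-spline fit of one pool on [0, 30] minutes."""

    pool: int
    spline: object  # scipy BSpline
    smoothing: float | None  # None = chosen by generalized cross-validation
    values: np.ndarray  # X(t) at t = 0..30
    diffs: np.ndarray   # X(t) - X(t-1) for t = 1..30

    def __call__(self, t):
        return self.spline(t)

    def derivative(self, t):
        """Analytic spline derivative (diagnostics only; the estimators use
        the discrete first differences)."""
        return self.spline.derivative()(t)


def fit_smoothing_spline(
    times,
    replicate_values,
    smoothing: float | None = None,
    pool: int = 0,
    floor: float = 1e-9,
) -> SplineFit:
    """Fit a cubic smoothing spline to pooled replicate observations.

    ``times`` and ``replicate_values`` are flat, parallel arrays with one
    entry per observation (replicates appear as repeated times).  The fit
    minimizes the penalized least-squares criterion over all observations;
    replicates at a time point are equivalent to fitting their mean with
    weight equal to the replicate count, which is how the fit is computed.
    ``smoothing`` is the penalty parameter lambda (0 = interpolation limit);
    None selects it by generalized cross-validation.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(replicate_values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and values must have the same shape")
    if np.any(y <= 0):
        raise ValueError("concentration values must be positive")
    t_unique = np.unique(t)
    if t_unique.size < 4:
        raise ValueError("need at least 4 distinct time points for a cubic spline")

    y_mean = np.array([y[t == tu].mean() for tu in t_unique])
    w = np.array([(t == tu).sum() for tu in t_unique], dtype=float)
    spline = make_smoothing_spline(t_unique, y_mean, w=w, lam=smoothing)

    values = np.asarray(spline(MINUTE_GRID), dtype=float)
    if np.any(values <= 0):
        baseline = max(values.max(), y.max())
        warnings.warn(
            f"pool {pool}: spline non-positive at "
            f"{int((values <= 0).sum())} minute(s); flooring",
            stacklevel=2,
        )
        values = np.maximum(values, floor * baseline)
    return SplineFit(
        pool=pool,
        spline=spline,
        smoothing=smoothing,
        values=values,
        diffs=np.diff(values),
    )


def resample_per_minute(fit: SplineFit) -> tuple[np.ndarray, np.ndarray]:
    """Values at t = 0..30 (31 points) and first differences for t = 1..30."""
    return fit.values.copy(), fit.diffs.copy()


def preprocess_dataset(
    observations: pd.DataFrame,
    smoothing: float | None = None,
) -> tuple[pd.DataFrame, dict[int, SplineFit]]:
    """Fit every measured pool and assemble the per-minute table.

    ``observations`` is tidy (time_min, replicate, pool, value), as emitted
    by the synthetic-data generator or real data in the same schema.
    Returns the per-minute tidy table (time_min, pool, value, diff; diff is
    NaN at t=0) and the per-pool spline fits.
    """
    fits: dict[int, SplineFit] = {}
    rows = []
    for pool, grp in observations.groupby("pool"):
        fit = fit_smoothing_spline(
            grp["time_min"].to_numpy(),
            grp["value"].to_numpy(),
            smoothing=smoothing,
            pool=int(pool),
        )
        fits[int(pool)] = fit
        for i, t in enumerate(MINUTE_GRID):
            rows.append((int(t), int(pool), fit.values[i],
                         np.nan if i == 0 else fit.diffs[i - 1]))
    per_minute = pd.DataFrame(rows, columns=["time_min", "pool", "value", "diff"])
    return per_minute.sort_values(["pool", "time_min"]).reset_index(drop=True), fits
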