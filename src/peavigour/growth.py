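"""Two-phase ("broken-stick") growth modelling of seedling biomass series.

Shoot biomass of field pea seedlings, tracked as segmented plant pixels
(kilopixels, kPix) over days after sowing (DAS), shows a lag phase followed
by a linear growth phase.  The model here is a continuous piecewise-linear
regression with a single breakpoint::

    y(t) = Y + slope1 * (t - X)   for t <= X
    y(t) = Y + slope2 * (t - X)   for t >  X

where ``X`` is the breakpoint day, ``Y`` the biomass at the breakpoint and
``slope1``/``slope2`` the lag- and linear-phase accumulation rates.  The
fit minimises the residual sum of squares over all four parameters by
profiling ``X`` on a dense grid: at each candidate breakpoint the model is
linear in the basis ``{1, t - X, max(t - X, 0)}`` and is solved by ordinary
least squares; the grid optimum is then polished by bounded scalar
minimisation.

The module also provides the downstream scalar summaries used for vigour
ranking: relative growth rate (RGR, difference of mean log-biomass over a
day interval), the linear-phase onset rule (first integer day strictly
after the latest genotype breakpoint) and Tukey boxplot outlier screening.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger("peavigour.growth")

__all__ = [
    "GrowthSeries",
    "BrokenStickFit",
    "broken_stick_value",
    "fit_broken_stick",
    "rgr",
    "linear_phase_onset",
    "detect_outliers",
]

#: resolution (days) of the default breakpoint profiling grid
DEFAULT_GRID_STEP = 0.01

#: minimum number of observations accepted by the fitter
MIN_FIT_POINTS = 6


@dataclass
class GrowthSeries:
    """A biomass-vs-time series for one plant or one genotype.

    Parameters
    ----------
    genotype : str
        Genotype label.
    replicate : str | int | None
        Replicate identifier, or ``None`` for replicate-mean series.
    days : array-like of float
        Strictly increasing DAS values, at least 5 of them.
    values : array-like of float
        Positive biomass values (kPix), aligned with ``days``.
    """

    genotype: str
    replicate: str | int | None
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.ndim != 1 or self.days.shape != self.values.shape:
            raise ValueError("days and values must be 1-D arrays of equal length")
        if len(self.days) < 5:
            raise ValueError(f"growth series needs >= 5 observations, got {len(self.days)}")
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("biomass values must be finite")


@dataclass
class BrokenStickFit:
    """Fitted parameters of the continuous two-phase model.

    ``degenerate`` is set when the data are perfectly collinear, in which
    case the two slopes coincide and ``x_day`` is reported at the first
    grid point attaining the (flat) SSE minimum.
    """

    genotype: str
    x_day: float
    y_kpix: float
    slope1: float
    slope2: float
    adj_r2: float
    sse: float
    degenerate: bool = False
    n_obs: int = 0

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return broken_stick_value(t, self.x_day, self.y_kpix, self.slope1, self.slope2)


def broken_stick_value(
    t: np.ndarray | float, x: float, y: float, slope1: float, slope2: float
) -> np.ndarray | float:
    """Evaluate the continuous two-phase model at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    out = np.where(t <= x, y + slope1 * (t - x), y + slope2 * (t - x))
    return out if out.ndim else float(out)


def _profile_sse(t: np.ndarray, y: np.ndarray, candidates: np.ndarray):
    """Conditional least squares at each candidate breakpoint.

    For fixed X the model is linear in beta = (Y, slope1, d) with design
    columns (1, t - X, max(t - X, 0)) and slope2 = slope1 + d.  Normal
    equations are assembled for all candidates at once.
    """
    n = len(t)
    u = t[None, :] - candidates[:, None]            # (m, n)
    v = np.maximum(u, 0.0)
    ones = np.ones(n)

    def dot(a, b):
        return (a * b).sum(axis=1)

    m = len(candidates)
    G = np.empty((m, 3, 3))
    G[:, 0, 0] = n
    G[:, 0, 1] = G[:, 1, 0] = u.sum(axis=1)
    G[:, 0, 2] = G[:, 2, 0] = v.sum(axis=1)
    G[:, 1, 1] = dot(u, u)
    G[:, 1, 2] = G[:, 2, 1] = dot(u, v)
    G[:, 2, 2] = dot(v, v)
    B = np.empty((m, 3))
    B[:, 0] = ones @ y
    B[:, 1] = u @ y
    B[:, 2] = v @ y
    try:
        beta = np.linalg.solve(G, B[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.stack([np.linalg.lstsq(Gi, Bi, rcond=None)[0] for Gi, Bi in zip(G, B)])
    sse = np.maximum(float(y @ y) - (beta * B).sum(axis=1), 0.0)
    return beta, sse


def _sse_at(t: np.ndarray, y: np.ndarray, x: float) -> float:
    beta, sse = _profile_sse(t, y, np.asarray([x]))
    return float(sse[0])


def fit_broken_stick(
    series: GrowthSeries, grid_step: float = DEFAULT_GRID_STEP
) -> BrokenStickFit:
    """Fit the continuous two-phase model by breakpoint profiling.

    The breakpoint is profiled on a grid of resolution ``grid_step``
    between the 2nd and the (n-1)th observed day (so at least two
    observations lie strictly inside each phase at the grid limits), with
    ties broken toward the smallest candidate.  The grid optimum is then
    refined by bounded Brent minimisation within one grid cell.

    Raises
    ------
    ValueError
        If the series has fewer than 6 points.
    """
    t, y = series.days, series.values
    n = len(t)
    if n < MIN_FIT_POINTS:
        raise ValueError(f"broken-stick fit needs >= {MIN_FIT_POINTS} points, got {n}")

    lo, hi = t[1], t[-2]
    n_grid = int(round((hi - lo) / grid_step)) + 1
    grid = np.linspace(lo, hi, n_grid)
    beta, sse = _profile_sse(t, y, grid)
    i = int(np.argmin(sse))  # argmin returns the first minimum -> smallest X

    # nested single-line fit: detect perfectly collinear data
    coef = np.polyfit(t, y, 1)
    resid_line = y - np.polyval(coef, t)
    sse_line = float(resid_line @ resid_line)
    tss = float(((y - y.mean()) ** 2).sum())

    if sse_line <= sse[i] + 1e-10 * max(sse_line, 1.0):
        x_best = float(grid[int(np.argmin(sse))])
        slope = float(coef[0])
        logger.warning(
            "series %s/%s is collinear: single-line fit, breakpoint ill-defined",
            series.genotype, series.replicate,
        )
        r2 = 1.0 - sse_line / tss if tss > 0 else math.nan
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 5) if tss > 0 else math.nan
        return BrokenStickFit(
            genotype=series.genotype,
            x_day=x_best,
            y_kpix=float(np.polyval(coef, x_best)),
            slope1=slope,
            slope2=slope,
            adj_r2=adj,
            sse=sse_line,
            degenerate=True,
            n_obs=n,
        )

    # local refinement within the bracketing grid cell
    x_best, sse_best = float(grid[i]), float(sse[i])
    lo_b = float(grid[max(i - 1, 0)])
    hi_b = float(grid[min(i + 1, n_grid - 1)])
    if hi_b > lo_b:
        res = minimize_scalar(
            lambda x: _sse_at(t, y, x), bounds=(lo_b, hi_b), method="bounded",
            options={"xatol": 1e-8},
        )
        if res.fun < sse_best:
            x_best, sse_best = float(res.x), float(res.fun)

    beta_best, _ = _profile_sse(t, y, np.asarray([x_best]))
    y0, s1, d = beta_best[0]
    r2 = 1.0 - sse_best / tss if tss > 0 else math.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 5) if tss > 0 else math.nan
    return BrokenStickFit(
        genotype=series.genotype,
        x_day=x_best,
        y_kpix=float(y0),
        slope1=float(s1),
        slope2=float(s1 + d),
        adj_r2=adj,
        sse=sse_best,
        degenerate=False,
        n_obs=n,
    )


def rgr(
    series: GrowthSeries | Iterable[GrowthSeries], t1: float, t2: float
) -> float:
    """Relative growth rate between days ``t1`` and ``t2``.

    RGR = (mean ln W(t2) - mean ln W(t1)) / (t2 - t1), with the means of
    the log-transformed biomass taken across replicates (per-day mean of
    logs, not log of means).

    Raises
    ------
    ValueError
        If ``t1 >= t2``, either day is missing from a series, or a biomass
        value is non-positive.
    """
    if t1 >= t2:
        raise ValueError(f"t1 must precede t2, got {t1} >= {t2}")
    many = [series] if isinstance(series, GrowthSeries) else list(series)
    if not many:
        raise ValueError("no series supplied")

    def values_at(day: float) -> np.ndarray:
        out = []
        for s in many:
            hit = np.isclose(s.days, day)
            if not hit.any():
                raise ValueError(f"day {day} not present in series {s.genotype}/{s.replicate}")
            out.append(s.values[hit][0])
        return np.asarray(out)

    w1, w2 = values_at(t1), values_at(t2)
    if np.any(w1 <= 0) or np.any(w2 <= 0):
        raise ValueError("RGR requires positive biomass values")
    return float((np.log(w2).mean() - np.log(w1).mean()) / (t2 - t1))


def linear_phase_onset(fits: Iterable[BrokenStickFit | float]) -> int:
    """Smallest integer day strictly greater than the latest breakpoint.

    All genotypes are in their linear growth phase from this day onward,
    making it the earliest common day for cross-genotype vigour
    comparison.  An integer-valued maximum breakpoint maps to the *next*
    day (strictly greater).
    """
    xs = [f.x_day if isinstance(f, BrokenStickFit) else float(f) for f in fits]
    if not xs:
        raise ValueError("at least one fit is required")
    return int(math.floor(max(xs))) + 1


def detect_outliers(values: Sequence[float]) -> np.ndarray:
    """Tukey boxplot outlier flags.

    Values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] are flagged; quartiles use
    the linear-interpolation convention of :func:`numpy.percentile`.
    Requires at least 4 values.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValueError("outlier screening needs >= 4 values")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)
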