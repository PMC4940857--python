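"""Per-site temporal trend fitting, gained/lost/stable calls and selection.

Each site's normalized occupancy is regressed on time (hours) by ordinary
least squares across all replicate observations; the two-sided t-test on
the slope ranks sites, and sign + significance classify them as gained,
lost or stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PeakSet

P_FLOOR = 1e-300  # reported when the fit has zero residual variance


@dataclass(frozen=True)
class TrendResult:
    site_id: str
    slope: float  # RPM per hour
    p: float
    klass: str  # gained / lost / stable


def _ols_slope_p(y: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    n = t.size
    if n < 3 or np.unique(t).size < 2:
        raise ValueError("need >= 2 timepoints and >= 3 observations")
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ (y - y.mean())) / sxx
    resid = y - y.mean() - slope * tc
    s2 = float(resid @ resid) / (n - 2)
    if s2 <= 0:
        return slope, (P_FLOOR if slope != 0 else 1.0)
    se = math.sqrt(s2 / sxx)
    tstat = slope / se
    p = 2 * stats.t.sf(abs(tstat), df=n - 2)
    return slope, max(float(p), P_FLOOR)


def fit_site_trend(
    values: Sequence[float],
    times: Sequence[float],
    site_id: str = "",
    alpha: float = 0.05,
) -> TrendResult:
    """OLS of RPM on time for one site; replicates are independent points."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    slope, p = _ols_slope_p(y, t)
    return TrendResult(site_id, slope, p, classify_dynamics(slope, p, alpha))


def fit_trends(
    matrix: pd.DataFrame,
    times: Sequence[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Vectorized per-site OLS trend fit.

    ``matrix`` is sites x observation columns; ``times`` gives the hour of
    each column. Returns a DataFrame (site, slope, p, class) in input order.
    """
    t = np.asarray(times, dtype=float)
    y = matrix.to_numpy(dtype=float)
    n = t.size
    if y.shape[1] != n:
        raise ValueError("times length must match matrix columns")
    if n < 3 or np.unique(t).size < 2:
        raise ValueError("need >= 2 timepoints and >= 3 observations")
    tc = t - t.mean()
    sxx = float(tc @ tc)
    yc = y - y.mean(axis=1, keepdims=True)
    slope = (yc @ tc) / sxx
    resid = yc - slope[:, None] * tc[None, :]
    s2 = (resid ** 2).sum(axis=1) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slope / np.sqrt(s2 / sxx)
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(s2 <= 0, np.where(slope != 0, P_FLOOR, 1.0), np.maximum(p, P_FLOOR))
    klass = np.where(
        (p < alpha) & (slope > 0), "gained",
        np.where((p < alpha) & (slope < 0), "lost", "stable"),
    )
    return pd.DataFrame(
        {"site": matrix.index, "slope": slope, "p": p, "class": klass}
    ).set_index("site")


def classify_dynamics(slope: float, p: float, alpha: float = 0.05) -> str:
    """gained if slope > 0 and p < alpha; lost if slope < 0 and p < alpha; else stable."""
    if p < alpha and slope > 0:
        return "gained"
    if p < alpha and slope < 0:
        return "lost"
    return "stable"


def select_top_fraction(
    trends: pd.DataFrame,
    klass: str,
    fraction: float = 0.5,
) -> list[str]:
    """Best p-ranked ``fraction`` of sites in one dynamic class.

    Sites are ordered by ascending p, breaking ties by descending |slope|
    then site id; the first ceil(n * fraction) are returned.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    sub = trends[trends["class"] == klass].copy()
    if sub.empty:
        return []
    sub["absslope"] = sub["slope"].abs()
    sub = sub.sort_values(["p", "absslope"], ascending=[True, False], kind="mergesort")
    # stable sort on p/|slope|; final deterministic tie-break on site id
    order = sorted(
        range(len(sub)),
        key=lambda i: (sub["p"].iloc[i], -sub["absslope"].iloc[i], str(sub.index[i])),
    )
    k = math.ceil(len(sub) * fraction)
    return [str(sub.index[i]) for i in order[:k]]


def gained_lost_counts(control: PeakSet, treated: PeakSet, min_overlap_bp: int = 1) -> tuple[int, int]:
    """(gained, lost) site counts by presence/absence between conditions.

    Gained = treated peaks with no overlap in control; lost = control peaks
    with no overlap in treated.
    """
    gained = sum(1 for p in treated if control.max_overlap_bp(p.interval) < min_overlap_bp)
    lost = sum(1 for p in control if treated.max_overlap_bp(p.interval) < min_overlap_bp)
    return gained, lost


def percent_excess(a: int, b: int) -> int:
    """How much larger ``a`` is than ``b``, as a percent of ``a``.

    100 * (a - b) / a, rounded half away from zero to the nearest integer.
    """
    if not (a >= b >= 0):
        raise ValueError("need a >= b >= 0")
    if a == 0:
        raise ValueError("a must be positive")
    x = 100.0 * (a - b) / a
    return int(math.floor(x + 0.5))


__all__ = [
    "TrendResult",
    "fit_site_trend",
    "fit_trends",
    "classify_dynamics",
    "select_top_fraction",
    "gained_lost_counts",
    "percent_excess",
    "P_FLOOR",
]
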