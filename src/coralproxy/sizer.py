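"""SiZer: SIgnificant ZERo crossings of smoothed derivatives.

For every combination of time point t and smoothing bandwidth h, a
Gaussian-kernel-weighted local linear regression estimates the derivative
of the underlying trend, together with its standard error. Each (h, t) cell
is classified as significantly increasing, significantly decreasing, not
significant, or insufficient-data (effective sample size below a cutoff),
using pointwise two-sided Gaussian quantiles. Scanning a row of the
resulting map for transitions from significant increase to significant
decrease (or vice versa) localises trend-shift points such as the change
from a multidecadal rise to a decline in an annual proxy series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateDataError

__all__ = [
    "SiZerClass",
    "SiZerMap",
    "ShiftPoint",
    "local_linear_derivative",
    "sizer_map",
    "find_shift_points",
    "default_bandwidths",
]


class SiZerClass(IntEnum):
    INSUFFICIENT = 0
    DECREASING = 1
    NOT_SIGNIFICANT = 2
    INCREASING = 3


_CLASS_LABELS = {
    SiZerClass.INSUFFICIENT: "insufficient",
    SiZerClass.DECREASING: "decreasing",
    SiZerClass.NOT_SIGNIFICANT: "not_significant",
    SiZerClass.INCREASING: "increasing",
}


def default_bandwidths(low: float = 2.0, high: float = 25.0, num: int = 21) -> np.ndarray:
    """Log-spaced bandwidth grid in years (default 21 values, 2-25 yr)."""
    return np.geomspace(low, high, num)


@dataclass
class SiZerMap:
    grid: np.ndarray  # time grid (years)
    bandwidths: np.ndarray  # smoothing bandwidths (years)
    classes: np.ndarray  # (len(bandwidths), len(grid)) of SiZerClass
    slopes: np.ndarray
    ses: np.ndarray
    alpha: float

    def labels(self) -> np.ndarray:
        out = np.empty(self.classes.shape, dtype=object)
        for c, lab in _CLASS_LABELS.items():
            out[self.classes == c] = lab
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.labels(), columns=[f"{t:g}" for t in self.grid])
        df.insert(0, "bandwidth", self.bandwidths)
        return df


@dataclass(frozen=True)
class ShiftPoint:
    """A detected trend shift: the year interval over which the significant
    derivative changes sign, and the bandwidths supporting it."""

    interval: tuple[float, float]  # (last year of old trend, first year of new)
    direction: str  # "increase_to_decrease" or "decrease_to_increase"
    bandwidths: tuple[float, ...] = field(default=())
    ambiguous: bool = False


def local_linear_derivative(
    x: np.ndarray,
    y: np.ndarray,
    bandwidth: float,
    grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-weighted local linear slope, its SE, and the effective n.

    At each grid point t the model ``y ~ b0 + b1 (x - t)`` is fitted by
    weighted least squares with weights ``w_i = exp(-(x_i - t)^2 / (2 h^2))``.
    The slope variance uses the weighted sandwich form
    ``(X'WX)^-1 X'W^2X (X'WX)^-1 * sigma^2`` with the residual variance
    estimated from the weighted residual sum of squares; the effective
    sample size is ``(sum w)^2 / sum w^2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if x.size != y.size or x.size < 5:
        raise DegenerateDataError("local linear fit needs n >= 5 paired points")
    if bandwidth <= 0:
        raise ConfigError("bandwidth must be positive")
    slopes = np.full(grid.size, np.nan)
    ses = np.full(grid.size, np.nan)
    ess = np.zeros(grid.size)
    for j, t in enumerate(grid):
        w = np.exp(-((x - t) ** 2) / (2.0 * bandwidth**2))
        sw = w.sum()
        if sw <= 0 or not np.isfinite(sw):
            continue
        ess[j] = sw**2 / np.sum(w**2)
        X = np.column_stack([np.ones_like(x), x - t])
        XtW = X.T * w
        A = XtW @ X  # X'WX
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        beta = Ainv @ (XtW @ y)
        resid = y - X @ beta
        denom = max(ess[j] - 2.0, 1e-12)
        sigma2 = np.sum(w * resid**2) / sw * ess[j] / denom
        B = (X.T * w**2) @ X  # X'W^2X
        cov = Ainv @ B @ Ainv * sigma2
        slopes[j] = beta[1]
        ses[j] = np.sqrt(max(cov[1, 1], 0.0))
    return slopes, ses, ess


def sizer_map(
    series: pd.Series,
    bandwidths: np.ndarray | None = None,
    alpha: float = 0.05,
    ess_min: float = 5.0,
) -> SiZerMap:
    """Classify the sign of the smoothed derivative over (bandwidth, time).

    ``series`` is a year-indexed pandas Series (e.g. annual means of the
    low-pass proxy). Pointwise two-sided Gaussian quantiles at ``alpha``
    decide significance; cells with effective sample size below ``ess_min``
    are marked insufficient.
    """
    if bandwidths is None:
        bandwidths = default_bandwidths()
    bandwidths = np.asarray(bandwidths, dtype=float)
    if bandwidths.size == 0:
        raise ConfigError("empty bandwidth grid")
    x = np.asarray(series.index, dtype=float)
    y = series.to_numpy(dtype=float)
    if x.size < 10:
        raise DegenerateDataError("SiZer needs at least 10 time points")
    grid = x.copy()
    q = stats.norm.ppf(1.0 - alpha / 2.0)
    classes = np.full((bandwidths.size, grid.size), int(SiZerClass.NOT_SIGNIFICANT))
    all_slopes = np.full((bandwidths.size, grid.size), np.nan)
    all_ses = np.full((bandwidths.size, grid.size), np.nan)
    for i, h in enumerate(bandwidths):
        slopes, ses, ess = local_linear_derivative(x, y, h, grid)
        all_slopes[i] = slopes
        all_ses[i] = ses
        lo = slopes - q * ses
        hi = slopes + q * ses
        row = classes[i]
        row[ess < ess_min] = int(SiZerClass.INSUFFICIENT)
        ok = ess >= ess_min
        row[ok & (lo > 0)] = int(SiZerClass.INCREASING)
        row[ok & (hi < 0)] = int(SiZerClass.DECREASING)
        bad = ~np.isfinite(slopes) | ~np.isfinite(ses)
        row[bad] = int(SiZerClass.INSUFFICIENT)
    return SiZerMap(
        grid=grid, bandwidths=bandwidths, classes=classes,
        slopes=all_slopes, ses=all_ses, alpha=alpha,
    )


def _row_transitions(grid: np.ndarray, row: np.ndarray) -> list[tuple[tuple[float, float], str]]:
    """Sign transitions of the significant derivative along one bandwidth row.

    A transition is recorded when a significantly increasing cell is later
    followed by a significantly decreasing one (or vice versa) with only
    not-significant cells between; it is attributed to the interval between
    the last cell of the old trend and the first cell of the new."""
    out = []
    last_sig = None  # (class, year)
    for t, c in zip(grid, row):
        if c == SiZerClass.INSUFFICIENT:
            continue
        if c in (SiZerClass.INCREASING, SiZerClass.DECREASING):
            if last_sig is not None and last_sig[0] != c:
                direction = (
                    "increase_to_decrease"
                    if last_sig[0] == SiZerClass.INCREASING
                    else "decrease_to_increase"
                )
                out.append(((float(last_sig[1]), float(t)), direction))
            last_sig = (c, t)
    return out


def find_shift_points(
    smap: SiZerMap,
    bandwidth_range: tuple[float, float] | None = None,
    include_ambiguous: bool = False,
) -> list[ShiftPoint]:
    """Aggregate per-bandwidth derivative sign changes into shift points.

    Same-direction transitions whose year intervals overlap are taken to
    reflect one underlying shift: they are clustered across bandwidths, the
    cluster's interval is the intersection of its members (the years every
    supporting bandwidth brackets) and its bandwidths the union. A cluster
    that overlaps an opposite-direction cluster marks a stretch where the
    record cannot be split; both are flagged ambiguous and excluded unless
    ``include_ambiguous`` is set. Results are ordered by interval start.
    """
    if bandwidth_range is None:
        bandwidth_range = (float(smap.bandwidths.min()), float(smap.bandwidths.max()))
    lo, hi = bandwidth_range
    raw: dict[str, list[tuple[tuple[float, float], float]]] = {}
    for h, row in zip(smap.bandwidths, smap.classes):
        if not lo <= h <= hi:
            continue
        for interval, direction in _row_transitions(smap.grid, row):
            raw.setdefault(direction, []).append((interval, float(h)))

    def clusters(items: list[tuple[tuple[float, float], float]]):
        items = sorted(items)
        groups: list[list[tuple[tuple[float, float], float]]] = []
        for iv, h in items:
            if groups and iv[0] <= max(m[0][1] for m in groups[-1]):
                groups[-1].append((iv, h))
            else:
                groups.append([(iv, h)])
        return groups

    points: list[ShiftPoint] = []
    for direction, items in raw.items():
        for grp in clusters(items):
            start = max(iv[0] for iv, _ in grp)
            stop = min(iv[1] for iv, _ in grp)
            if start > stop:  # no common bracket; fall back to the envelope
                start = min(iv[0] for iv, _ in grp)
                stop = max(iv[1] for iv, _ in grp)
            points.append(
                ShiftPoint(
                    interval=(start, stop),
                    direction=direction,
                    bandwidths=tuple(sorted({h for _, h in grp})),
                )
            )
    # opposite-direction clusters that overlap mark an unsplittable stretch
    flagged: list[ShiftPoint] = []
    for p in points:
        clash = any(
            q.direction != p.direction
            and p.interval[0] <= q.interval[1]
            and q.interval[0] <= p.interval[1]
            for q in points
        )
        flagged.append(
            ShiftPoint(interval=p.interval, direction=p.direction,
                       bandwidths=p.bandwidths, ambiguous=clash)
        )
    if not include_ambiguous:
        flagged = [p for p in flagged if not p.ambiguous]
    flagged.sort(key=lambda p: p.interval)
    return flagged
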