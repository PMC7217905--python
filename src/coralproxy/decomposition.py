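"""Gaussian frequency-domain decomposition of monthly proxy series.

A monthly series is split into a **low-pass** component (multidecadal,
periods longer than ~2 years) and its exact complement, the **detrended**
(notch-filtered) component carrying seasonal and event-scale variability.

The filter is Gaussian in frequency, centred at zero, with half-amplitude
at the stated bandwidth: ``W(f) = exp(-ln2 * (f / bw)^2)``. Frequencies are
in cycles per day with a month of 365/12 days, so the default bandwidth of
0.00137 cpd corresponds to a two-year period (1/730.5 d). The series is
mean-removed, mirror-padded by one series length on each side to suppress
edge artifacts, transformed with the FFT, windowed, inverse-transformed,
trimmed and the mean restored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MonthlySeries
from .errors import ContiguityError, DegenerateDataError

logger = logging.getLogger(__name__)

__all__ = [
    "DAYS_PER_MONTH",
    "DEFAULT_BANDWIDTH_CPD",
    "Decomposition",
    "MSC",
    "gaussian_response",
    "exclude_core_top",
    "gaussian_lowpass",
    "gaussian_notch",
    "decompose",
    "mean_seasonal_cycle",
    "annual_means",
]

DAYS_PER_MONTH = 365.0 / 12.0
#: half-amplitude frequency separating >2-year from <2-year variability
DEFAULT_BANDWIDTH_CPD = 0.00137


def gaussian_response(freq_cpd, bandwidth_cpd: float = DEFAULT_BANDWIDTH_CPD):
    """Amplitude response W(f) of the low-pass filter; W(bandwidth) = 1/2."""
    f = np.asarray(freq_cpd, dtype=float)
    return np.exp(-np.log(2.0) * (f / bandwidth_cpd) ** 2)


@dataclass
class MSC:
    """Mean seasonal cycle: per-calendar-month climatology of a series."""

    mean: np.ndarray  # 12 values, January..December
    se: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        for arr in ("mean", "se", "n"):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=float))
        if self.mean.shape != (12,) or self.se.shape != (12,) or self.n.shape != (12,):
            raise DegenerateDataError("an MSC has exactly 12 monthly entries")

    @property
    def overall_mean(self) -> float:
        return float(self.mean.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": np.arange(1, 13), "mean": self.mean, "se": self.se,
             "n": self.n.astype(int)}
        )


@dataclass
class Decomposition:
    """Low-pass + detrended split of a monthly series (exact complement)."""

    lowpass: MonthlySeries
    detrended: MonthlySeries
    bandwidth_cpd: float
    excluded_months: int = 0


def exclude_core_top(series: MonthlySeries, n_months: int) -> MonthlySeries:
    """Drop the youngest ``n_months`` (e.g. the living-tissue layer, whose
    anomalously high trace-element values would bias the filtering)."""
    if n_months < 0:
        raise DegenerateDataError("n_months must be non-negative")
    if n_months == 0:
        return series
    if n_months >= len(series):
        raise DegenerateDataError(
            f"cannot exclude {n_months} months from a {len(series)}-month series"
        )
    return series.slice(series.start, series.end - n_months)


def tissue_layer_months(thickness_mm: float, mean_extension_mm_yr: float) -> int:
    """Number of whole months spanned by a core-top tissue layer.

    E.g. 4.1 mm at 9.6 mm/yr growth is 5.125 months, rounded to 5.
    """
    return int(round(thickness_mm / (mean_extension_mm_yr / 12.0)))


def _prepare(series: MonthlySeries) -> np.ndarray:
    x = series.values
    if len(x) < 24:
        raise DegenerateDataError("filtering requires at least 24 months")
    if not np.all(np.isfinite(x)):
        raise ContiguityError("filtering requires finite, gap-free values")
    return x


def gaussian_lowpass(
    series: MonthlySeries, bandwidth_cpd: float = DEFAULT_BANDWIDTH_CPD
) -> MonthlySeries:
    """Low-pass component: Gaussian frequency window applied via the FFT."""
    x = _prepare(series)
    n = x.size
    mean = x.mean()
    xc = x - mean
    # mirror-pad one series length on each side
    padded = np.concatenate([xc[::-1], xc, xc[::-1]])
    spec = np.fft.rfft(padded)
    freqs = np.fft.rfftfreq(padded.size, d=DAYS_PER_MONTH)  # cycles per day
    filtered = np.fft.irfft(spec * gaussian_response(freqs, bandwidth_cpd), n=padded.size)
    out = filtered[n: 2 * n] + mean
    return series.with_values(out)


def gaussian_notch(
    series: MonthlySeries, bandwidth_cpd: float = DEFAULT_BANDWIDTH_CPD
) -> MonthlySeries:
    """Detrended (notch) component: the exact complement of the low-pass."""
    lp = gaussian_lowpass(series, bandwidth_cpd)
    return series.with_values(series.values - lp.values)


def decompose(
    series: MonthlySeries,
    bandwidth_cpd: float = DEFAULT_BANDWIDTH_CPD,
    exclude_months: int = 0,
) -> Decomposition:
    """Tissue-layer exclusion followed by the low-pass/notch split."""
    trimmed = exclude_core_top(series, exclude_months)
    lp = gaussian_lowpass(trimmed, bandwidth_cpd)
    dt = trimmed.with_values(trimmed.values - lp.values)
    return Decomposition(lowpass=lp, detrended=dt, bandwidth_cpd=bandwidth_cpd,
                         excluded_months=exclude_months)


def mean_seasonal_cycle(detrended: MonthlySeries) -> MSC:
    """Climatological mean and standard error per calendar month."""
    if len(detrended) < 24:
        raise DegenerateDataError("an MSC needs at least 2 complete years")
    s = detrended.data
    grouped = s.groupby(s.index.month)
    mean = np.full(12, np.nan)
    se = np.zeros(12)
    n = np.zeros(12)
    for m, grp in grouped:
        mean[m - 1] = grp.mean()
        n[m - 1] = len(grp)
        if len(grp) > 1:
            se[m - 1] = grp.std(ddof=1) / np.sqrt(len(grp))
    if np.isnan(mean).any():
        raise DegenerateDataError("every calendar month needs at least one value")
    return MSC(mean=mean, se=se, n=n)


def annual_means(series: MonthlySeries, year_convention: str = "calendar") -> pd.Series:
    """Mean of the 12 monthly values of each complete calendar year.

    Incomplete first/last years are omitted (and logged). The result is a
    pandas Series indexed by integer year.
    """
    if year_convention != "calendar":
        raise DegenerateDataError(f"unknown year convention {year_convention!r}")
    s = series.data
    counts = s.groupby(s.index.year).size()
    complete = counts[counts == 12].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        logger.info("annual_means: omitting incomplete year(s) %s", dropped)
    if len(complete) == 0:
        raise DegenerateDataError("no complete calendar year in the series")
    out = s.groupby(s.index.year).mean().loc[complete]
    out.index.name = "year"
    return out
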