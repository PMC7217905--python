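"""High-peak detection on the detrended series and event lag matching.

A month is a *candidate* when the detrended value exceeds the overall mean
of the mean seasonal cycle by ``k_sigma`` standard deviations of the
residuals about the MSC (``k_sigma = 0`` is the literal exceed-the-MSC-mean
rule). Runs of consecutive candidate months collapse to the single highest
month — the *high-peak*. Peaks are then matched against a catalogue of
documented events (floods, typhoons, landslides, quarry collapses) allowing
a non-negative lag of up to ``max_lag_months``, reflecting the delayed
desorption of Ba from estuary-stored sediment and possible growth pauses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EventCatalog, EventRecord, MonthlySeries
from .decomposition import MSC
from .errors import DegenerateDataError

__all__ = [
    "PeakEvent",
    "MatchedEvent",
    "detect_high_peaks",
    "match_events",
    "count_peaks_by_period",
]


@dataclass(frozen=True)
class PeakEvent:
    month: pd.Period
    value: float
    exceedance: float  # value minus the detection threshold


@dataclass(frozen=True)
class MatchedEvent:
    peak: PeakEvent
    record: EventRecord
    lag_months: int


def detect_high_peaks(
    detrended: MonthlySeries, msc: MSC, k_sigma: float = 0.0
) -> list[PeakEvent]:
    """Detect run-collapsed high-peaks in the detrended series.

    Threshold = overall MSC mean + ``k_sigma`` * SD of (detrended minus the
    calendar-month MSC value). Within a run of consecutive candidates the
    highest value wins; ties break to the earlier month.
    """
    if len(detrended) == 0:
        raise DegenerateDataError("empty series")
    values = detrended.values
    months = detrended.index.month.to_numpy()
    residuals = values - msc.mean[months - 1]
    sd = float(np.std(residuals, ddof=1)) if len(values) > 1 else 0.0
    threshold = msc.overall_mean + k_sigma * sd
    candidate = values > threshold
    peaks: list[PeakEvent] = []
    i = 0
    n = len(values)
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and candidate[j + 1]:
            j += 1
        run = values[i: j + 1]
        best = i + int(np.argmax(run))  # argmax takes the first of tied maxima
        peaks.append(
            PeakEvent(
                month=detrended.index[best],
                value=float(values[best]),
                exceedance=float(values[best] - threshold),
            )
        )
        i = j + 1
    return peaks


def match_events(
    peaks: list[PeakEvent],
    catalog: EventCatalog,
    max_lag_months: int = 4,
) -> tuple[list[MatchedEvent], list[EventRecord], list[PeakEvent]]:
    """Greedily match catalogue events (by date) to peaks with 0 <= lag <= max.

    Each event takes the first unclaimed peak at or after its month within
    the lag window; a peak matches at most one event. Returns
    ``(matches, unmatched_events, unmatched_peaks)``.
    """
    free = sorted(peaks, key=lambda p: p.month.ordinal)
    matches: list[MatchedEvent] = []
    unmatched_events: list[EventRecord] = []
    for rec in catalog.sorted():
        hit = None
        for p in free:
            lag = p.month.ordinal - rec.date.ordinal
            if 0 <= lag <= max_lag_months:
                hit = (p, lag)
                break
        if hit is None:
            unmatched_events.append(rec)
        else:
            p, lag = hit
            free.remove(p)
            matches.append(MatchedEvent(peak=p, record=rec, lag_months=int(lag)))
    return matches, unmatched_events, free


def count_peaks_by_period(
    peaks: list[PeakEvent], boundary_year: int = 1996
) -> tuple[int, int]:
    """Peaks strictly before January of ``boundary_year`` vs from it onward."""
    boundary = pd.Period(year=boundary_year, month=1, freq="M")
    a = sum(1 for p in peaks if p.month < boundary)
    return a, len(peaks) - a
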