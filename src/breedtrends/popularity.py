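"""Per-breed popularity measures for boom-bust (fashion-cycle) analysis.

Four measures summarize each breed's registration time series N(t):

* total popularity P = sum of registrations over the observed span;
* volatility V = mean absolute year-to-year change |N(t+1) - N(t)|, with
  the consecutive-pair count as divisor (79 for a full 1926-2005 span);
* rate of increase before the highest popularity peak;
* rate of decrease after that peak.

The peak is the registration maximum; its beginning (end) is the year
nearest to and strictly before (after) the peak at which registrations
are at 10% or less of the peak value.  If either bound cannot be located
the breed has no peak.  Only the single highest peak is analyzed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import RegistrationMatrix

__all__ = [
    "PopularityProfile",
    "total_popularity",
    "volatility",
    "detect_peak",
    "peak_rates",
    "popularity_change",
    "profile_all",
]

#: Default relative threshold defining peak boundaries ("10% or less of
#: peak value"), inclusive.
PEAK_THRESHOLD = 0.10

#: Default window for the recent popularity-change measure.
CHANGE_WINDOW = (1996, 2005)


@dataclass
class PopularityProfile:
    breed: str
    total: float
    volatility: float
    n_changes: int
    has_peak: bool
    t_begin: int | None = None
    t_peak: int | None = None
    t_end: int | None = None
    rate_up: float | None = None
    rate_down: float | None = None
    change: float | None = None


def _as_arrays(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    s = series.dropna()
    if len(s) == 0:
        raise ValueError("empty series")
    return s.index.to_numpy(dtype=int), s.to_numpy(dtype=float)


def total_popularity(series: pd.Series) -> float:
    """Sum of registration counts over the breed's observed span."""
    _, counts = _as_arrays(series)
    return float(counts.sum())


def volatility(series: pd.Series) -> tuple[float, int]:
    """Mean absolute change between consecutive observed years.

    Returns ``(V, n_changes)`` where ``n_changes`` is the number of
    consecutive-year pairs averaged over.  Requires a span of at least two
    consecutive observed years.
    """
    years, counts = _as_arrays(series)
    consecutive = np.diff(years) == 1
    if not consecutive.any():
        raise ValueError("volatility undefined: no consecutive observed years")
    diffs = np.abs(np.diff(counts))[consecutive]
    return float(diffs.mean()), int(consecutive.sum())


def detect_peak(
    series: pd.Series,
    threshold: float = PEAK_THRESHOLD,
    scan: str = "nearest",
) -> tuple[bool, int | None, int | None, int | None]:
    """Locate the highest popularity peak and its boundaries.

    The peak year is the argmax of the series (earliest year on ties).
    Scanning backward (forward) from the peak, the beginning (end) is the
    first year with N <= threshold * N(peak); ``scan="outermost"`` instead
    takes the chronologically first (last) such year.  Returns
    ``(has_peak, t_begin, t_peak, t_end)`` with the years ``None`` when no
    peak qualifies (e.g. monotone, constant, or all-zero series).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if scan not in ("nearest", "outermost"):
        raise ValueError("scan must be 'nearest' or 'outermost'")
    years, counts = _as_arrays(series)
    i_peak = int(np.argmax(counts))
    peak_val = counts[i_peak]
    if peak_val <= 0:
        return False, None, None, None
    cut = threshold * peak_val
    before = np.flatnonzero(counts[:i_peak] <= cut)
    after = i_peak + 1 + np.flatnonzero(counts[i_peak + 1 :] <= cut)
    if len(before) == 0 or len(after) == 0:
        return False, None, None, None
    i_begin = before[-1] if scan == "nearest" else before[0]
    i_end = after[0] if scan == "nearest" else after[-1]
    return True, int(years[i_begin]), int(years[i_peak]), int(years[i_end])


def peak_rates(
    series: pd.Series,
    peak: tuple[int, int, int],
    normalized: bool = False,
) -> tuple[float, float]:
    """Rates of registration increase before and decrease after a peak.

    Net change divided by elapsed years on each flank, both reported as
    positive registrations/year.  With ``normalized=True`` both rates are
    divided by the peak count (fraction-of-peak per year).
    """
    t_begin, t_peak, t_end = peak
    if not t_begin < t_peak < t_end:
        raise ValueError(f"invalid peak triple {peak}")
    s = series.dropna()
    n_begin, n_peak, n_end = (float(s.loc[t]) for t in (t_begin, t_peak, t_end))
    r_up = (n_peak - n_begin) / (t_peak - t_begin)
    r_down = (n_peak - n_end) / (t_end - t_peak)
    if normalized:
        r_up /= n_peak
        r_down /= n_peak
    return r_up, r_down


def popularity_change(
    series: pd.Series,
    window: tuple[int, int] = CHANGE_WINDOW,
    relative: bool = False,
) -> float | None:
    """Signed registration change N(y_b) - N(y_a) over a year window.

    Returns ``None`` when either endpoint is unobserved for the breed (the
    breed is then excluded from change-based analyses, not an error).
    ``relative=True`` divides by N(y_a) when positive.
    """
    y_a, y_b = window
    s = series.dropna()
    if y_a not in s.index or y_b not in s.index:
        return None
    change = float(s.loc[y_b] - s.loc[y_a])
    if relative:
        base = float(s.loc[y_a])
        if base <= 0:
            return None
        change /= base
    return change


def profile_all(
    matrix: RegistrationMatrix,
    threshold: float = PEAK_THRESHOLD,
    scan: str = "nearest",
    rate_normalized: bool = False,
    change_window: tuple[int, int] = CHANGE_WINDOW,
    change_relative: bool = False,
) -> pd.DataFrame:
    """Compute the full popularity profile for every breed in a matrix.

    Returns a DataFrame indexed by breed with columns total, volatility,
    n_changes, has_peak, t_begin, t_peak, t_end, rate_up, rate_down and
    the windowed change; peakless breeds carry NaN in the peak and rate
    columns.  Deterministic given input and settings.
    """
    rows = []
    for breed in matrix.breeds:
        s = matrix.series(breed)
        vol, n_changes = volatility(s)
        has_peak, t_begin, t_peak, t_end = detect_peak(s, threshold, scan)
        if has_peak:
            r_up, r_down = peak_rates(
                s, (t_begin, t_peak, t_end), normalized=rate_normalized
            )
        else:
            r_up = r_down = None
        rows.append(
            {
                "breed": breed,
                "total": total_popularity(s),
                "volatility": vol,
                "n_changes": n_changes,
                "has_peak": has_peak,
                "t_begin": t_begin,
                "t_peak": t_peak,
                "t_end": t_end,
                "rate_up": r_up,
                "rate_down": r_down,
                "change": popularity_change(s, change_window, change_relative),
            }
        )
    return pd.DataFrame(rows).set_index("breed")
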