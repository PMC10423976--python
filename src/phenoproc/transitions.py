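"""Transition-date extraction from daily greenness series.

The green chromatic coordinate (Gcc) rises at spring green-up and falls at
autumn green-down.  Extraction composites the 90th percentile of Gcc over a
three-day moving window (after removing snow-contaminated days, whose
blue-white signal shifts Gcc downward), then finds where the composite
crosses 25% of the seasonal amplitude above the seasonal baseline: the
first upward crossing on the rising limb in spring, the last downward
crossing on the falling limb in autumn, linearly interpolated between
bracketing days.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .datatypes import GccSeries, SeasonalCurve, TransitionObservation

__all__ = [
    "exclude_snow_days",
    "composite_90th",
    "extract_transitions",
    "extract_both",
]

#: Fraction of the seasonal amplitude defining the transition threshold.
THRESHOLD_FRACTION = 0.25

#: Percentile used when compositing (linear-interpolation definition).
COMPOSITE_PERCENTILE = 90.0


class EmptySeriesError(ValueError):
    """No usable greenness observations remain."""


def exclude_snow_days(series: GccSeries, flags: Optional[Sequence[int]] = None) -> GccSeries:
    """Remove snow-contaminated days from a greenness series.

    ``flags`` lists day-of-year values to drop, in addition to any days
    already carrying the series' own snow flag.  Flags referencing days
    absent from the axis produce a warning, not an error.
    """
    drop = np.asarray(series.snow_flag, dtype=bool).copy()
    if flags is not None:
        flags = np.asarray(flags, dtype=int)
        present = np.isin(flags, series.doy)
        if not present.all():
            warnings.warn(
                f"{int((~present).sum())} snow flag(s) reference days absent from the series",
                stacklevel=2,
            )
        drop |= np.isin(series.doy, flags[present])
    keep = ~drop
    return GccSeries(
        enclosure_id=series.enclosure_id,
        roi_label=series.roi_label,
        doy=series.doy[keep],
        gcc=series.gcc[keep],
        snow_flag=np.zeros(int(keep.sum()), dtype=bool),
    )


def composite_90th(series: GccSeries, window: int = 3) -> SeasonalCurve:
    """Composite the 90th percentile of Gcc over a moving window.

    The composite is evaluated on a continuous daily axis spanning the
    series; window positions with no usable observation are filled by
    linear interpolation.
    """
    usable = ~series.snow_flag
    doy = series.doy[usable]
    gcc = series.gcc[usable]
    if doy.size == 0:
        raise EmptySeriesError("all days excluded from the greenness series")
    if doy.size < window:
        raise EmptySeriesError(f"fewer than {window} usable days")
    axis = np.arange(doy[0], doy[-1] + 1)
    half = window // 2
    out = np.full(axis.size, np.nan)
    for i, d in enumerate(axis):
        sel = (doy >= d - half) & (doy <= d + half)
        if sel.any():
            out[i] = np.percentile(gcc[sel], COMPOSITE_PERCENTILE)
    holes = np.isnan(out)
    if holes.any():
        out[holes] = np.interp(axis[holes], axis[~holes], out[~holes])
    baseline = float(np.min(out))
    amplitude = float(np.max(out) - baseline)
    return SeasonalCurve(
        doy=axis, gcc_90=out, baseline=baseline, amplitude=amplitude,
        threshold_fraction=THRESHOLD_FRACTION,
    )


def _interp_crossing(d0, d1, g0, g1, thr):
    return d0 + (thr - g0) / (g1 - g0) * (d1 - d0)


def _spring_crossing(curve: SeasonalCurve, shift: float = 0.0) -> Optional[float]:
    g = curve.gcc_90 + shift
    thr = curve.threshold_value
    peak = int(np.argmax(g))
    seg0 = int(np.argmin(g[: peak + 1]))
    for i in range(seg0, peak):
        if g[i] < thr <= g[i + 1]:
            return float(_interp_crossing(curve.doy[i], curve.doy[i + 1], g[i], g[i + 1], thr))
    return None


def _autumn_crossing(curve: SeasonalCurve, shift: float = 0.0) -> Optional[float]:
    g = curve.gcc_90 + shift
    thr = curve.threshold_value
    peak = int(np.argmax(g))
    tail_min = peak + int(np.argmin(g[peak:]))
    # last downward crossing before the late-season minimum
    for i in range(tail_min - 1, peak - 1, -1):
        if g[i] >= thr > g[i + 1]:
            return float(_interp_crossing(curve.doy[i], curve.doy[i + 1], g[i], g[i + 1], thr))
    return None


def extract_transitions(
    curve: SeasonalCurve,
    season: str,
    enclosure_id: str = "",
    year: int = 0,
    pft: str = "DN",
    residual_sd: float = 0.0,
) -> Optional[TransitionObservation]:
    """Transition date at the 25%-amplitude threshold crossing.

    Returns ``None`` when the curve never crosses the threshold in the
    requested direction (a distinguishable no-transition outcome, not an
    error).  Confidence bounds, when ``residual_sd`` > 0, are the crossing
    dates of the curve shifted by +/- one residual standard deviation — a
    heuristic interval, since greenness noise maps to date uncertainty
    through the local slope.
    """
    if curve.amplitude <= 0:
        raise ValueError("seasonal amplitude must be positive")
    crossing_fn = {"spring": _spring_crossing, "autumn": _autumn_crossing}[season]
    doy = crossing_fn(curve)
    if doy is None:
        return None
    lo = hi = doy
    if residual_sd > 0:
        for shift in (-residual_sd, residual_sd):
            c = crossing_fn(curve, shift)
            if c is not None:
                lo, hi = min(lo, c), max(hi, c)
    return TransitionObservation(
        enclosure_id=enclosure_id, year=year, pft=pft, season=season,
        doy=doy, ci_lower=lo, ci_upper=hi,
    )


def extract_both(
    series: GccSeries,
    enclosure_id: Optional[str] = None,
    year: int = 0,
    window: int = 3,
) -> dict[str, Optional[TransitionObservation]]:
    """Snow-exclude, composite and extract spring and autumn dates.

    The residual SD driving the heuristic confidence bounds is the standard
    deviation of usable daily Gcc about the composite curve.
    """
    clean = exclude_snow_days(series)
    curve = composite_90th(clean, window=window)
    on_curve = np.interp(clean.doy, curve.doy, curve.gcc_90)
    residual_sd = float(np.std(clean.gcc - on_curve))
    enc = enclosure_id if enclosure_id is not None else series.enclosure_id
    return {
        season: extract_transitions(
            curve, season, enclosure_id=enc, year=year,
            pft=series.roi_label, residual_sd=residual_sd,
        )
        for season in ("spring", "autumn")
    }
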