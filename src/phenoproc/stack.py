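"""Stacked driver arrays for fast model evaluation.

A :class:`DriverStack` flattens a collection of
:class:`~phenoproc.datatypes.DriverSeries` into 2-D arrays (series x day) on
a shared day-of-year axis, so every model evaluates all enclosure-years in
one vectorised pass.  This is what makes tens of thousands of annealing
iterations affordable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datatypes import DriverSeries

#: Growing-season window (day-of-year) over which the per-enclosure mean CO2
#: entering the CO2 model variants is taken.
GROWING_SEASON = (120, 280)


class DriverError(KeyError):
    """A model's required driver channel is absent from the data."""


@dataclass
class DriverStack:
    """Drivers for ``n`` enclosure-years on a common daily axis."""

    doy: np.ndarray            # (d,) shared day-of-year axis
    temperature: np.ndarray    # (n, d)
    daylength: Optional[np.ndarray] = None   # (n, d)
    vpd: Optional[np.ndarray] = None         # (n, d)
    water_table: Optional[np.ndarray] = None  # (n, d)
    co2_mean: Optional[np.ndarray] = None    # (n,) growing-season mean ppm
    keys: Optional[list[tuple[str, int]]] = None  # (enclosure_id, year)

    @property
    def n_series(self) -> int:
        return int(self.temperature.shape[0])

    @property
    def n_days(self) -> int:
        return int(self.doy.size)

    def index_of(self, doy_value: float) -> int:
        """Clipped array index of a (possibly negative) day-of-year value."""
        idx = int(round(doy_value)) - int(self.doy[0])
        return int(np.clip(idx, 0, self.n_days - 1))

    def require(self, *channels: str) -> None:
        missing = [
            ch
            for ch in channels
            if getattr(self, ch) is None
        ]
        if missing:
            raise DriverError(f"required driver channel(s) missing: {', '.join(missing)}")


def build_stack(
    series: Sequence[DriverSeries],
    temperature_channel: str | int = "air",
) -> DriverStack:
    """Stack driver series on the intersection of their daily axes.

    All series are aligned on the day-of-year values they share (leap-year
    series lose 29 Feb's extra slot at the end of the window, which no model
    threshold ever reaches).
    """
    if not series:
        raise ValueError("no driver series supplied")
    lo = max(int(s.doy[0]) for s in series)
    hi = min(int(s.doy[-1]) for s in series)
    if hi <= lo:
        raise ValueError("driver series have no overlapping daily window")
    doy = np.arange(lo, hi + 1)

    def _slice(s: DriverSeries, arr: np.ndarray) -> np.ndarray:
        i0 = int(lo - s.doy[0])
        return arr[i0 : i0 + doy.size]

    temp = np.vstack([_slice(s, s.temperature(temperature_channel)) for s in series])

    def _stack_opt(name: str) -> Optional[np.ndarray]:
        arrs = [getattr(s, name) for s in series]
        if any(a is None for a in arrs):
            return None
        return np.vstack([_slice(s, a) for s, a in zip(series, arrs)])

    daylength = _stack_opt("daylength")
    vpd = _stack_opt("vpd")
    water = _stack_opt("water_table")

    co2_mean = None
    if all(s.co2 is not None for s in series):
        gs = (doy >= GROWING_SEASON[0]) & (doy <= GROWING_SEASON[1])
        co2_mean = np.array(
            [float(np.mean(_slice(s, s.co2)[gs])) for s in series]
        )

    return DriverStack(
        doy=doy,
        temperature=temp,
        daylength=daylength,
        vpd=vpd,
        water_table=water,
        co2_mean=co2_mean,
        keys=[(s.enclosure_id, s.focal_year) for s in series],
    )
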