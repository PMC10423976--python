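"""Core data containers shared across the package.

The daily axis convention: day-of-year is 1-based in the focal calendar year
(1 Jan = 1); the driver window extends back through the previous autumn with
non-positive indices, so 31 Dec of the previous year is 0 and 1 Sep of the
previous year is -121. Chilling-accumulation start dates may therefore be
negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

#: Depths (cm) at which soil temperature is measured.
SOIL_DEPTHS_CM = (0, 5, 10, 20, 30, 40, 50, 100, 200)

#: Day-of-year index of 1 Sep of the previous year (window start).
WINDOW_START_DOY = -121

#: Returned when an accumulation model never reaches its threshold within
#: the evaluation window.  A value, not an error.
NO_TRANSITION = -9999

#: Plant functional types: deciduous needleleaf (Larix), evergreen
#: needleleaf (Picea), mixed shrub layer.
PFTS = ("DN", "EN", "SH")

SEASONS = ("spring", "autumn")


@dataclass
class EnclosureMetadata:
    """One experimental enclosure: warming level and CO2 treatment."""

    enclosure_id: str
    target_warming: float
    co2_treatment: str  # "ambient" | "elevated"
    measured_warming: float
    latitude: float = 47.5
    longitude: float = -93.45

    NOMINAL_WARMING_LEVELS = (0.0, 2.25, 4.5, 6.75, 9.0)

    def __post_init__(self) -> None:
        if not any(
            abs(self.target_warming - lv) < 1e-9 for lv in self.NOMINAL_WARMING_LEVELS
        ):
            raise ValueError(
                f"target_warming {self.target_warming} not one of the nominal "
                f"levels {self.NOMINAL_WARMING_LEVELS}"
            )
        if self.co2_treatment not in ("ambient", "elevated"):
            raise ValueError(f"co2_treatment must be ambient|elevated, got {self.co2_treatment!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of [-90, 90]")

    @property
    def elevated_co2(self) -> bool:
        return self.co2_treatment == "elevated"


@dataclass
class DriverSeries:
    """Aligned daily environmental drivers for one enclosure-year.

    All arrays share the ``doy`` axis, which runs from -121 (1 Sep of the
    previous calendar year) through 365 (366 in leap focal years) without
    gaps.
    """

    enclosure_id: str
    focal_year: int
    doy: np.ndarray
    t_air: np.ndarray
    t_soil: dict[int, np.ndarray] = field(default_factory=dict)
    water_table: Optional[np.ndarray] = None
    co2: Optional[np.ndarray] = None
    daylength: Optional[np.ndarray] = None
    vpd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        d = np.diff(self.doy)
        if self.doy.size and not np.all(d == 1):
            raise ValueError("doy axis must be strictly increasing with no gaps")
        n = self.doy.size
        for name in ("t_air", "water_table", "co2", "daylength", "vpd"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != n:
                    raise ValueError(f"{name} length {arr.size} != doy axis length {n}")
                setattr(self, name, arr)
        for depth, arr in self.t_soil.items():
            if depth not in SOIL_DEPTHS_CM:
                raise ValueError(f"unknown soil depth {depth} cm")
            arr = np.asarray(arr, dtype=float)
            if arr.size != n:
                raise ValueError(f"t_soil[{depth}] length mismatch")
            self.t_soil[depth] = arr
        if self.daylength is not None:
            dl = self.daylength
            if np.any((dl < 0) | (dl > 24)):
                raise ValueError("daylength outside [0, 24] h")

    @property
    def n_days(self) -> int:
        return int(self.doy.size)

    def index_of(self, doy: float) -> int:
        """Array index of a (possibly negative) day-of-year value."""
        return int(round(doy)) - int(self.doy[0])

    def temperature(self, channel: str | int = "air") -> np.ndarray:
        """Temperature array for a named channel: ``"air"`` or a depth in cm."""
        if channel == "air":
            return self.t_air
        depth = int(channel)
        if depth not in self.t_soil:
            raise KeyError(f"soil temperature at {depth} cm not available")
        return self.t_soil[depth]


@dataclass
class TransitionObservation:
    """One observed phenological transition date."""

    enclosure_id: str
    year: int
    pft: str
    season: str
    doy: float
    ci_lower: float = np.nan
    ci_upper: float = np.nan

    def __post_init__(self) -> None:
        if self.pft not in PFTS:
            raise ValueError(f"pft must be one of {PFTS}, got {self.pft!r}")
        if self.season not in SEASONS:
            raise ValueError(f"season must be spring|autumn, got {self.season!r}")
        if np.isfinite(self.ci_lower) and np.isfinite(self.ci_upper):
            if not (self.ci_lower <= self.doy <= self.ci_upper):
                raise ValueError("requires ci_lower <= doy <= ci_upper")


@dataclass
class GccSeries:
    """Daily greenness (green chromatic coordinate) for one camera ROI."""

    enclosure_id: str
    roi_label: str
    doy: np.ndarray
    gcc: np.ndarray
    snow_flag: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        self.gcc = np.asarray(self.gcc, dtype=float)
        if np.any(np.diff(self.doy) <= 0):
            raise ValueError("doy axis must be strictly increasing")
        if self.gcc.size != self.doy.size:
            raise ValueError("gcc length mismatch")
        if np.any((self.gcc <= 0) | (self.gcc >= 1)):
            raise ValueError("gcc must lie strictly in (0, 1)")
        if self.snow_flag is None:
            self.snow_flag = np.zeros(self.doy.size, dtype=bool)
        else:
            self.snow_flag = np.asarray(self.snow_flag, dtype=bool)
            if self.snow_flag.size != self.doy.size:
                raise ValueError("snow_flag length mismatch")


@dataclass
class SeasonalCurve:
    """Composited seasonal greenness curve with amplitude threshold."""

    doy: np.ndarray
    gcc_90: np.ndarray
    baseline: float
    amplitude: float
    threshold_fraction: float = 0.25

    @property
    def threshold_value(self) -> float:
        return self.baseline + self.threshold_fraction * self.amplitude


@dataclass
class ModelSpec:
    """A named phenology model: driver needs, parameters, evaluator.

    ``drivers`` uses the conventional letters: F forcing temperature,
    C chilling temperature, P photoperiod, V vapour pressure deficit,
    M moisture (water table), CO2 atmospheric CO2.
    """

    name: str
    season: str
    drivers: tuple[str, ...]
    parameter_names: tuple[str, ...]
    predict: Callable  # (params: ndarray, stack: DriverStack) -> ndarray of DOY
    description: str = ""

    @property
    def k_params(self) -> int:
        return len(self.parameter_names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ModelSpec({self.name}, {self.season}, drivers={'+'.join(self.drivers)}, "
            f"k={self.k_params})"
        )


@dataclass
class FitResult:
    """Outcome of calibrating one model against observations."""

    model: str
    season: str
    parameters: dict[str, float]
    predictions: np.ndarray
    observed: np.ndarray
    rmse: float
    aic: float
    n_obs: int
    k_params: int
    chain_costs: list[float] = field(default_factory=list)
    seed: Optional[int] = None
    temperature_channel: str = "air"
    observation_keys: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "season": self.season,
            "parameters": dict(self.parameters),
            "predictions": [float(p) for p in self.predictions],
            "observed": [float(o) for o in self.observed],
            "rmse": float(self.rmse),
            "aic": float(self.aic),
            "n_obs": int(self.n_obs),
            "k_params": int(self.k_params),
            "chain_costs": [float(c) for c in self.chain_costs],
            "seed": self.seed,
            "temperature_channel": str(self.temperature_channel),
            "observation_keys": [list(k) for k in self.observation_keys],
        }


#: ΔAIC support classes, boundaries at 2 and 10.
SUPPORT_EQUIVALENT = "equivalent"
SUPPORT_LITTLE = "little"
SUPPORT_NONE = "none"


def support_class(delta_aic: float) -> str:
    """Classify model support from ΔAIC (<2 equivalent, ≥2 little, ≥10 none)."""
    if delta_aic < 2.0:
        return SUPPORT_EQUIVALENT
    if delta_aic < 10.0:
        return SUPPORT_LITTLE
    return SUPPORT_NONE
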