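"""Autumn green-down (senescence) models.

Ten models built around cold-degree-day (CDD) accumulation: senescence is
predicted on the first day that accumulated cold forcing from a start date
``t0`` exceeds a requirement ``F_star``.  Variants weight the daily cold
increment by photoperiod (CDDP), by water-table depth (CDDM), replace
temperature entirely with a daylength deficit (PPM), or use a sigmoidal
rather than linear cold response (CDDs).  Each model also exists in a CO2
version in which elevated growing-season CO2 lowers the senescence
requirement, letting green-down occur with less cold forcing — warmer
enclosures senesce later, elevated-CO2 enclosures earlier.
"""

from __future__ import annotations

import numpy as np

from ._accum import first_crossing_doy, masked_cumsum
from .datatypes import ModelSpec
from .stack import DriverStack

__all__ = [
    "cold_rate",
    "co2_threshold_offset",
    "AUTUMN_MODELS",
    "get_autumn_model",
    "CO2_REFERENCE_PPM",
]

#: Reference (ambient-era) CO2 concentration; the CO2 offset acts on the
#: excess above this.
CO2_REFERENCE_PPM = 400.0

#: Floor on the effective requirement, as a fraction of F_star.
MIN_REQUIREMENT_FRACTION = 0.05


def cold_rate(t, form="linear", t_base=None, b_s=None, c_s=None):
    """Daily cold forcing increment.

    ``linear``: max(T_base - T, 0) cold degree days; ``sigmoid``:
    1/(1 + exp(b_s (T - c_s))), a saturating response decreasing in T.
    """
    t = np.asarray(t, dtype=float)
    if form == "linear":
        return np.maximum(t_base - t, 0.0)
    if form == "sigmoid":
        return 1.0 / (1.0 + np.exp(b_s * (t - c_s)))
    raise ValueError(f"unknown cold-response form {form!r}")


def co2_threshold_offset(f_star, c_co2, co2_mean, co2_ref=CO2_REFERENCE_PPM):
    """Effective senescence requirement under elevated CO2.

    F_eff = max(F_star - c_co2 * max(co2 - co2_ref, 0), 0.05 * F_star):
    a linear reduction per ppm above the reference, floored so the
    requirement stays positive.  At or below ambient, F_eff = F_star.
    """
    if c_co2 < 0:
        raise ValueError("c_co2 must be >= 0")
    excess = np.maximum(np.asarray(co2_mean, dtype=float) - co2_ref, 0.0)
    f_eff = np.maximum(f_star - c_co2 * excess, MIN_REQUIREMENT_FRACTION * f_star)
    return float(f_eff) if np.ndim(f_eff) == 0 else f_eff


def _water_weight(stack: DriverStack, m: float) -> np.ndarray:
    stack.require("water_table")
    return np.maximum(1.0 + m * stack.water_table, 0.0)


def _requirement(stack: DriverStack, f_star: float, c_co2: float | None) -> np.ndarray | float:
    if c_co2 is None:
        return f_star
    if stack.co2_mean is None:
        from .stack import DriverError

        raise DriverError("CO2 driver channel required for CO2 model variants")
    return co2_threshold_offset(f_star, c_co2, stack.co2_mean)


def _accumulate_to(stack, rate, t0, f_star, c_co2=None):
    acc = masked_cumsum(rate, stack.index_of(t0))
    return first_crossing_doy(stack, acc, _requirement(stack, f_star, c_co2))


def _predict_cdd(p, stack, c_co2=None):
    t0, t_base, f_star = p[:3]
    return _accumulate_to(stack, cold_rate(stack.temperature, "linear", t_base), t0, f_star, c_co2)


def _predict_cdds(p, stack, c_co2=None):
    t0, b_s, c_s, f_star = p[:4]
    return _accumulate_to(
        stack, cold_rate(stack.temperature, "sigmoid", b_s=b_s, c_s=c_s), t0, f_star, c_co2
    )


def _predict_cddp(p, stack, c_co2=None):
    t0, t_base, f_star = p[:3]
    stack.require("daylength")
    rate = cold_rate(stack.temperature, "linear", t_base) * (1.0 - stack.daylength / 24.0)
    return _accumulate_to(stack, rate, t0, f_star, c_co2)


def _predict_cddm(p, stack, c_co2=None):
    t0, t_base, m, f_star = p[:4]
    rate = cold_rate(stack.temperature, "linear", t_base) * _water_weight(stack, m)
    return _accumulate_to(stack, rate, t0, f_star, c_co2)


def _solstice_index(stack: DriverStack) -> int:
    """Index of the focal-year daylength maximum (summer solstice)."""
    stack.require("daylength")
    focal = stack.doy >= 1
    dl = np.where(focal, stack.daylength[0], -np.inf)
    return int(np.argmax(dl))


def _predict_ppm(p, stack, c_co2=None):
    l_crit, m, f_star = p[:3]
    stack.require("daylength")
    rate = np.maximum(l_crit - stack.daylength, 0.0) * _water_weight(stack, m)
    start = _solstice_index(stack)
    acc = masked_cumsum(rate, start)
    return first_crossing_doy(stack, acc, _requirement(stack, f_star, c_co2))


def _with_co2(base_fn):
    def fn(p, stack):
        return base_fn(p[:-1], stack, c_co2=p[-1])

    return fn


def _spec(name, drivers, params, fn, desc):
    return ModelSpec(
        name=name, season="autumn", drivers=tuple(drivers),
        parameter_names=tuple(params), predict=fn, description=desc,
    )


AUTUMN_MODELS: dict[str, ModelSpec] = {
    m.name: m
    for m in [
        _spec("CDD", "C", ("t0", "T_base", "F_star"), _predict_cdd,
              "Cold-degree-day accumulation to a senescence requirement"),
        _spec("CDDCO2", ("C", "CO2"), ("t0", "T_base", "F_star", "c_co2"),
              _with_co2(_predict_cdd),
              "CDD with a CO2 offset lowering the requirement"),
        _spec("CDDs", "C", ("t0", "b_s", "c_s", "F_star"), _predict_cdds,
              "CDD with sigmoidal cold response"),
        _spec("CDDsCO2", ("C", "CO2"), ("t0", "b_s", "c_s", "F_star", "c_co2"),
              _with_co2(_predict_cdds),
              "Sigmoidal CDD with a CO2 offset"),
        _spec("CDDP", "CP", ("t0", "T_base", "F_star"), _predict_cddp,
              "CDD weighted by night-fraction photoperiod (1 - L/24)"),
        _spec("CDDPCO2", ("C", "P", "CO2"), ("t0", "T_base", "F_star", "c_co2"),
              _with_co2(_predict_cddp),
              "Photoperiod-weighted CDD with a CO2 offset"),
        _spec("CDDM", "CM", ("t0", "T_base", "m", "F_star"), _predict_cddm,
              "CDD weighted by water-table depth (1 + m W)"),
        _spec("CDDMCO2", ("C", "M", "CO2"), ("t0", "T_base", "m", "F_star", "c_co2"),
              _with_co2(_predict_cddm),
              "Water-table-weighted CDD with a CO2 offset"),
        _spec("PPM", "PM", ("L_crit", "m", "F_star"), _predict_ppm,
              "Daylength-deficit accumulation from the solstice, water-table weighted"),
        _spec("PPMCO2", ("P", "M", "CO2"), ("L_crit", "m", "F_star", "c_co2"),
              _with_co2(_predict_ppm),
              "Photoperiod/water-table model with a CO2 offset"),
    ]
}


def get_autumn_model(name: str) -> ModelSpec:
    """Look up an autumn model by its abbreviation (case-insensitive)."""
    key = name.upper()
    aliases = {m.upper(): m for m in AUTUMN_MODELS}
    if key not in aliases:
        raise KeyError(f"unknown autumn model {name!r}; choose from {sorted(AUTUMN_MODELS)}")
    return AUTUMN_MODELS[aliases[key]]
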