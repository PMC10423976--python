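"""Spring green-up models.

Nineteen process-based models predicting the spring transition day of year
from daily drivers, spanning a complexity gradient from a two-parameter
linear regression on mean late-winter temperature to ten-parameter parallel
chilling-forcing models with a photoperiod term.

Families
--------
* Forcing-only (TT, TTs, PTT, PTTs, M1, M1s): growing-degree accumulation
  from a start date ``t0`` until a forcing requirement ``F_star`` is met,
  with an optional photoperiod multiplier (PTT: L/24; M1: (L/10)**k) and
  either a linear or sigmoidal temperature response.
* Alternating (AT): the forcing requirement declines exponentially with the
  number of chill days accumulated so far.
* Sequential (SQ, SQb, SM1, SM1b): a chilling requirement ``C_star`` must
  be met (triangular or bell-shaped chilling response) before forcing is
  allowed to accumulate.
* Parallel (PA, PAb, PM1, PM1b): chilling and forcing accumulate
  simultaneously; daily forcing is weighted by the fraction of the chilling
  requirement met so far.
* Unified (UM1): forcing requirement decays exponentially with accumulated
  bell-shaped chilling.
* Growing-season index (SGSI, AGSI): the product of clamped ramps in
  temperature, vapour pressure deficit and photoperiod, thresholded either
  on a 21-day moving average (SGSI) or on its accumulation (AGSI).

All predictors are pure functions of ``(parameter vector, DriverStack)``
returning one predicted day of year per enclosure-year, with a sentinel
(:data:`~phenoproc.datatypes.NO_TRANSITION`) when the threshold is never
reached within the evaluation window.
"""

from __future__ import annotations

import numpy as np

from ._accum import all_sentinel, first_crossing_doy, first_true_doy, masked_cumsum
from .datatypes import ModelSpec
from .stack import DriverStack

__all__ = [
    "forcing_rate_linear",
    "forcing_rate_sigmoid",
    "chilling_rate_triangular",
    "chilling_rate_bell",
    "photoperiod_multiplier",
    "SPRING_MODELS",
    "get_spring_model",
]

#: Day-of-year window over which the LIN model averages temperature.
LIN_WINDOW = (1, 120)

#: Moving-average window (days) for the SGSI threshold rule.
SGSI_SMOOTHING_DAYS = 21


# ---------------------------------------------------------------------------
# Rate functions
# ---------------------------------------------------------------------------

def forcing_rate_linear(t, t_base):
    """Growing-degree forcing: max(T - T_base, 0)."""
    return np.maximum(np.asarray(t, dtype=float) - t_base, 0.0)


def forcing_rate_sigmoid(t, b_f, c_f):
    """Sigmoidal forcing response 1/(1 + exp(-b_f (T - c_f))), in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-b_f * (np.asarray(t, dtype=float) - c_f)))


def chilling_rate_triangular(t, t_min, t_opt, t_max):
    """Triangular chilling effectiveness: 0 outside (T_min, T_max), 1 at T_opt.

    Raises ``ValueError`` unless T_min < T_opt < T_max; during optimisation
    that violation is converted to a sentinel-penalty, not an exception.
    """
    if not (t_min < t_opt < t_max):
        raise ValueError("requires T_min < T_opt < T_max")
    t = np.asarray(t, dtype=float)
    rising = (t - t_min) / (t_opt - t_min)
    falling = (t_max - t) / (t_max - t_opt)
    return np.clip(np.minimum(rising, falling), 0.0, 1.0)


def chilling_rate_bell(t, a_c, b_c, c_c):
    """Bell-shaped chilling response 1/(1 + exp(a_c dT^2 + b_c dT)), dT = T - c_c."""
    dt = np.asarray(t, dtype=float) - c_c
    return 1.0 / (1.0 + np.exp(a_c * dt * dt + b_c * dt))


def photoperiod_multiplier(daylength, variant="PTT", k=1.0):
    """Photoperiod weighting of the forcing rate.

    ``"PTT"``: L/24 (fraction of the day); ``"M1"``: (L/10)**k, unity at a
    10-hour day.
    """
    dl = np.asarray(daylength, dtype=float)
    if variant == "PTT":
        return dl / 24.0
    if variant == "M1":
        return (dl / 10.0) ** k
    raise ValueError(f"unknown photoperiod variant {variant!r}")


# ---------------------------------------------------------------------------
# Internal kernels
# ---------------------------------------------------------------------------

def _tri_rate_or_none(t, t_min, t_opt, t_max):
    try:
        return chilling_rate_triangular(t, t_min, t_opt, t_max)
    except ValueError:
        return None


def _forcing_threshold(stack, rate, t0, f_star):
    start = stack.index_of(t0)
    acc = masked_cumsum(rate, start)
    return first_crossing_doy(stack, acc, f_star)


def _predict_lin(p, stack: DriverStack):
    a, b = p
    lo, hi = LIN_WINDOW
    sel = (stack.doy >= lo) & (stack.doy <= hi)
    mean_t = stack.temperature[:, sel].mean(axis=1)
    return a + b * mean_t


def _predict_tt(p, stack):
    t0, t_base, f_star = p
    return _forcing_threshold(stack, forcing_rate_linear(stack.temperature, t_base), t0, f_star)


def _predict_tts(p, stack):
    t0, b_f, c_f, f_star = p
    return _forcing_threshold(stack, forcing_rate_sigmoid(stack.temperature, b_f, c_f), t0, f_star)


def _predict_ptt(p, stack):
    t0, t_base, f_star = p
    stack.require("daylength")
    rate = forcing_rate_linear(stack.temperature, t_base) * photoperiod_multiplier(stack.daylength)
    return _forcing_threshold(stack, rate, t0, f_star)


def _predict_ptts(p, stack):
    t0, b_f, c_f, f_star = p
    stack.require("daylength")
    rate = forcing_rate_sigmoid(stack.temperature, b_f, c_f) * photoperiod_multiplier(stack.daylength)
    return _forcing_threshold(stack, rate, t0, f_star)


def _predict_m1(p, stack):
    t0, t_base, k, f_star = p
    stack.require("daylength")
    rate = forcing_rate_linear(stack.temperature, t_base) * photoperiod_multiplier(
        stack.daylength, "M1", k
    )
    return _forcing_threshold(stack, rate, t0, f_star)


def _predict_m1s(p, stack):
    t0, b_f, c_f, k, f_star = p
    stack.require("daylength")
    rate = forcing_rate_sigmoid(stack.temperature, b_f, c_f) * photoperiod_multiplier(
        stack.daylength, "M1", k
    )
    return _forcing_threshold(stack, rate, t0, f_star)


def _predict_at(p, stack):
    t0, t_base, a, b, c = p
    start = stack.index_of(t0)
    chill_days = masked_cumsum((stack.temperature < t_base).astype(float), start)
    gdd = masked_cumsum(forcing_rate_linear(stack.temperature, t_base), start)
    requirement = a + b * np.exp(c * chill_days)
    return first_true_doy(stack, gdd >= requirement)


def _seq_predict(stack, chill_rate, forcing_rate, t0, t0_chill, c_star, f_star):
    """Sequential family: the chilling requirement gates forcing accumulation.

    Forcing starts the day the chilling requirement is met (inclusive) and not
    before t0; forcing accumulated before release is discarded."""
    if chill_rate is None:
        return all_sentinel(stack)
    chill_acc = masked_cumsum(chill_rate, stack.index_of(t0_chill))
    released = chill_acc >= c_star
    rel_idx = released.argmax(axis=1)
    ok = released[np.arange(stack.n_series), rel_idx]
    start = np.maximum(rel_idx, stack.index_of(t0))
    acc = masked_cumsum(forcing_rate, start)
    pred = first_crossing_doy(stack, acc, f_star)
    pred[~ok] = float(all_sentinel(stack)[0])
    return pred


def _predict_sq(p, stack):
    t0, t0_chill, t_base, t_min, t_opt, t_max, c_star, f_star = p
    chill = _tri_rate_or_none(stack.temperature, t_min, t_opt, t_max)
    forcing = forcing_rate_linear(stack.temperature, t_base)
    return _seq_predict(stack, chill, forcing, t0, t0_chill, c_star, f_star)


def _predict_sqb(p, stack):
    t0, t0_chill, t_base, a_c, b_c, c_c, c_star, f_star = p
    chill = chilling_rate_bell(stack.temperature, a_c, b_c, c_c)
    forcing = forcing_rate_linear(stack.temperature, t_base)
    return _seq_predict(stack, chill, forcing, t0, t0_chill, c_star, f_star)


def _predict_sm1(p, stack):
    t0, t0_chill, t_base, k, t_min, t_opt, t_max, c_star, f_star = p
    stack.require("daylength")
    chill = _tri_rate_or_none(stack.temperature, t_min, t_opt, t_max)
    forcing = forcing_rate_linear(stack.temperature, t_base) * photoperiod_multiplier(
        stack.daylength, "M1", k
    )
    return _seq_predict(stack, chill, forcing, t0, t0_chill, c_star, f_star)


def _predict_sm1b(p, stack):
    t0, t0_chill, t_base, k, a_c, b_c, c_c, c_star, f_star = p
    stack.require("daylength")
    chill = chilling_rate_bell(stack.temperature, a_c, b_c, c_c)
    forcing = forcing_rate_linear(stack.temperature, t_base) * photoperiod_multiplier(
        stack.daylength, "M1", k
    )
    return _seq_predict(stack, chill, forcing, t0, t0_chill, c_star, f_star)


def _parallel(stack, chill_rate, forcing_rate, t0, t0_chill, c_ini, c_star, f_star):
    """Chilling and forcing accumulate simultaneously; forcing is weighted by
    K(t) = min(1, (C_ini + C(t))/C_star)."""
    if chill_rate is None:
        return all_sentinel(stack)
    chill_acc = masked_cumsum(chill_rate, stack.index_of(t0_chill))
    if c_star <= 0:
        weight = np.ones_like(chill_acc)
    else:
        weight = np.minimum(1.0, (c_ini + chill_acc) / c_star)
    acc = masked_cumsum(weight * forcing_rate, stack.index_of(t0))
    return first_crossing_doy(stack, acc, f_star)


def _predict_pa(p, stack):
    t0, t0_chill, t_base, t_min, t_opt, t_max, c_ini, c_star, f_star = p
    chill = _tri_rate_or_none(stack.temperature, t_min, t_opt, t_max)
    forcing = forcing_rate_linear(stack.temperature, t_base)
    return _parallel(stack, chill, forcing, t0, t0_chill, c_ini, c_star, f_star)


def _predict_pab(p, stack):
    t0, t0_chill, t_base, a_c, b_c, c_c, c_ini, c_star, f_star = p
    chill = chilling_rate_bell(stack.temperature, a_c, b_c, c_c)
    forcing = forcing_rate_linear(stack.temperature, t_base)
    return _parallel(stack, chill, forcing, t0, t0_chill, c_ini, c_star, f_star)


def _predict_pm1(p, stack):
    t0, t0_chill, t_base, k, t_min, t_opt, t_max, c_ini, c_star, f_star = p
    stack.require("daylength")
    chill = _tri_rate_or_none(stack.temperature, t_min, t_opt, t_max)
    forcing = forcing_rate_linear(stack.temperature, t_base) * photoperiod_multiplier(
        stack.daylength, "M1", k
    )
    return _parallel(stack, chill, forcing, t0, t0_chill, c_ini, c_star, f_star)


def _predict_pm1b(p, stack):
    t0, t0_chill, t_base, k, a_c, b_c, c_c, c_ini, c_star, f_star = p
    stack.require("daylength")
    chill = chilling_rate_bell(stack.temperature, a_c, b_c, c_c)
    forcing = forcing_rate_linear(stack.temperature, t_base) * photoperiod_multiplier(
        stack.daylength, "M1", k
    )
    return _parallel(stack, chill, forcing, t0, t0_chill, c_ini, c_star, f_star)


def _predict_um1(p, stack):
    t0, a_c, b_c, c_c, b_f, c_f, k, w, z = p
    stack.require("daylength")
    if z < 0:
        return all_sentinel(stack)
    start = stack.index_of(t0)
    chill_acc = masked_cumsum(chilling_rate_bell(stack.temperature, a_c, b_c, c_c), start)
    forcing = forcing_rate_sigmoid(stack.temperature, b_f, c_f) * photoperiod_multiplier(
        stack.daylength, "M1", k
    )
    acc = masked_cumsum(forcing, start)
    requirement = w * np.exp(-z * chill_acc)
    return first_true_doy(stack, acc >= requirement)


def _ramp(x, x_min, x_max):
    return np.clip((x - x_min) / (x_max - x_min), 0.0, 1.0)


def _gsi_index(p, stack):
    t0, t_mn, t_mx, v_mn, v_mx, l_mn, l_mx, k, thresh = p
    stack.require("daylength", "vpd")
    if t_mx <= t_mn or v_mx <= v_mn or l_mx <= l_mn:
        return None
    # VPD suppresses the index: high deficit -> stomatal closure
    idx = (
        _ramp(stack.temperature, t_mn, t_mx)
        * (1.0 - _ramp(stack.vpd, v_mn, v_mx))
        * _ramp(stack.daylength, l_mn, l_mx) ** k
    )
    return idx


def _predict_sgsi(p, stack):
    idx = _gsi_index(p, stack)
    if idx is None:
        return all_sentinel(stack)
    t0, thresh = p[0], p[-1]
    w = SGSI_SMOOTHING_DAYS
    kernel = np.ones(w) / w
    sm = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, idx)
    cols = np.arange(stack.n_days)
    hit = (sm >= thresh) & (cols[None, :] >= stack.index_of(t0))
    return first_true_doy(stack, hit)


def _predict_agsi(p, stack):
    idx = _gsi_index(p, stack)
    if idx is None:
        return all_sentinel(stack)
    t0, f_star = p[0], p[-1]
    acc = masked_cumsum(idx, stack.index_of(t0))
    return first_crossing_doy(stack, acc, f_star)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def _spec(name, drivers, params, fn, desc):
    return ModelSpec(
        name=name, season="spring", drivers=tuple(drivers),
        parameter_names=tuple(params), predict=fn, description=desc,
    )


SPRING_MODELS: dict[str, ModelSpec] = {
    m.name: m
    for m in [
        _spec("LIN", "F", ("a", "b"), _predict_lin,
              "Linear regression of transition DOY on mean late-winter temperature"),
        _spec("TT", "F", ("t0", "T_base", "F_star"), _predict_tt,
              "Thermal time: GDD accumulation to a forcing requirement"),
        _spec("TTs", "F", ("t0", "b_f", "c_f", "F_star"), _predict_tts,
              "Thermal time with sigmoidal temperature response"),
        _spec("PTT", "PF", ("t0", "T_base", "F_star"), _predict_ptt,
              "Photo-thermal time: GDD weighted by L/24"),
        _spec("PTTs", "PF", ("t0", "b_f", "c_f", "F_star"), _predict_ptts,
              "Photo-thermal time, sigmoidal response"),
        _spec("M1", "PF", ("t0", "T_base", "k", "F_star"), _predict_m1,
              "Thermal time with exponential photoperiod multiplier (L/10)^k"),
        _spec("M1s", "PF", ("t0", "b_f", "c_f", "k", "F_star"), _predict_m1s,
              "M1 with sigmoidal temperature response"),
        _spec("AT", "CF", ("t0", "T_base", "a", "b", "c"), _predict_at,
              "Alternating: forcing requirement declines with chill-day count"),
        _spec("SQ", "CF", ("t0", "t0_chill", "T_base", "T_min", "T_opt", "T_max",
                           "C_star", "F_star"), _predict_sq,
              "Sequential: triangular chilling must complete before forcing"),
        _spec("SQb", "CF", ("t0", "t0_chill", "T_base", "a_c", "b_c", "c_c",
                            "C_star", "F_star"), _predict_sqb,
              "Sequential with bell-shaped chilling"),
        _spec("SM1", "CPF", ("t0", "t0_chill", "T_base", "k", "T_min", "T_opt",
                             "T_max", "C_star", "F_star"), _predict_sm1,
              "Sequential M1: chilling gate plus photoperiod-weighted forcing"),
        _spec("SM1b", "CPF", ("t0", "t0_chill", "T_base", "k", "a_c", "b_c", "c_c",
                              "C_star", "F_star"), _predict_sm1b,
              "Sequential M1 with bell-shaped chilling"),
        _spec("PA", "CPF", ("t0", "t0_chill", "T_base", "T_min", "T_opt", "T_max",
                            "C_ini", "C_star", "F_star"), _predict_pa,
              "Parallel: simultaneous chilling and chill-weighted forcing"),
        _spec("PAb", "CPF", ("t0", "t0_chill", "T_base", "a_c", "b_c", "c_c",
                             "C_ini", "C_star", "F_star"), _predict_pab,
              "Parallel with bell-shaped chilling"),
        _spec("PM1", "CPF", ("t0", "t0_chill", "T_base", "k", "T_min", "T_opt",
                             "T_max", "C_ini", "C_star", "F_star"), _predict_pm1,
              "Parallel M1: parallel model with photoperiod-weighted forcing"),
        _spec("PM1b", "CPF", ("t0", "t0_chill", "T_base", "k", "a_c", "b_c", "c_c",
                              "C_ini", "C_star", "F_star"), _predict_pm1b,
              "Parallel M1 with bell-shaped chilling"),
        _spec("UM1", "CPF", ("t0", "a_c", "b_c", "c_c", "b_f", "c_f", "k", "w", "z"),
              _predict_um1,
              "Unified M1: forcing requirement decays with accumulated chilling"),
        _spec("SGSI", "FPV", ("t0", "T_min", "T_max", "V_min", "V_max", "L_min",
                              "L_max", "k", "threshold"), _predict_sgsi,
              "Smoothed growing-season index crossing a threshold"),
        _spec("AGSI", "FPV", ("t0", "T_min", "T_max", "V_min", "V_max", "L_min",
                              "L_max", "k", "F_star"), _predict_agsi,
              "Accumulated growing-season index crossing a requirement"),
    ]
}


def get_spring_model(name: str) -> ModelSpec:
    """Look up a spring model by its abbreviation (case-insensitive)."""
    key = name.upper()
    aliases = {m.upper(): m for m in SPRING_MODELS}
    if key not in aliases:
        raise KeyError(f"unknown spring model {name!r}; choose from {sorted(SPRING_MODELS)}")
    return SPRING_MODELS[aliases[key]]
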