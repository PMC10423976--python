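"""Independent day-by-day accumulation oracles for every model.

Each oracle below re-implements one model's documented accumulation rule as
an explicit per-day scalar loop over a single driver trace, sharing no code
with the vectorised kernels.  On random traces every model's prediction
must equal its oracle exactly (integer day of year, or the no-transition
sentinel).
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import phenoproc as pp
from phenoproc.datatypes import NO_TRANSITION

SENT = float(NO_TRANSITION)


# ---------------------------------------------------------------------------
# oracle helpers (plain Python, day-by-day)
# ---------------------------------------------------------------------------

def _idx(doy, t0):
    i = int(round(t0)) - int(doy[0])
    return min(max(i, 0), doy.size - 1)


def _lin_force(t, t_base):
    return max(t - t_base, 0.0)


def _sig_force(t, b_f, c_f):
    return 1.0 / (1.0 + math.exp(-b_f * (t - c_f)))


def _tri_chill(t, t_min, t_opt, t_max):
    if t <= t_min or t >= t_max:
        return 0.0
    if t <= t_opt:
        return (t - t_min) / (t_opt - t_min)
    return (t_max - t) / (t_max - t_opt)


def _bell_chill(t, a_c, b_c, c_c):
    dt = t - c_c
    return 1.0 / (1.0 + math.exp(a_c * dt * dt + b_c * dt))


def _photo(daylen, variant, k=1.0):
    if variant == "PTT":
        return daylen / 24.0
    return (daylen / 10.0) ** k


def _first_crossing(trace, rate, t0, f_star):
    doy = trace.doy
    acc = 0.0
    for i in range(doy.size):
        if i >= _idx(doy, t0):
            acc += rate[i]
        if acc >= f_star:
            return float(doy[i])
    return SENT


def _ramp(x, lo, hi):
    return min(max((x - lo) / (hi - lo), 0.0), 1.0)


def _gsi_daily(trace, p):
    out = []
    for i in range(trace.doy.size):
        out.append(
            _ramp(trace.t_air[i], p["T_min"], p["T_max"])
            * (1.0 - _ramp(trace.vpd[i], p["V_min"], p["V_max"]))
            * _ramp(trace.daylength[i], p["L_min"], p["L_max"]) ** p["k"]
        )
    return out


def _gs_mean_co2(trace):
    vals = [c for d, c in zip(trace.doy, trace.co2) if 120 <= d <= 280]
    return sum(vals) / len(vals)


def _co2_requirement(trace, f_star, c_co2):
    if c_co2 is None:
        return f_star
    excess = max(_gs_mean_co2(trace) - 400.0, 0.0)
    return max(f_star - c_co2 * excess, 0.05 * f_star)


# ---------------------------------------------------------------------------
# spring oracles
# ---------------------------------------------------------------------------

def oracle_lin(p, trace):
    vals = [t for d, t in zip(trace.doy, trace.t_air) if 1 <= d <= 120]
    return p["a"] + p["b"] * (sum(vals) / len(vals))


def oracle_tt(p, trace):
    rate = [_lin_force(t, p["T_base"]) for t in trace.t_air]
    return _first_crossing(trace, rate, p["t0"], p["F_star"])


def oracle_tts(p, trace):
    rate = [_sig_force(t, p["b_f"], p["c_f"]) for t in trace.t_air]
    return _first_crossing(trace, rate, p["t0"], p["F_star"])


def oracle_ptt(p, trace):
    rate = [_lin_force(t, p["T_base"]) * _photo(dl, "PTT")
            for t, dl in zip(trace.t_air, trace.daylength)]
    return _first_crossing(trace, rate, p["t0"], p["F_star"])


def oracle_ptts(p, trace):
    rate = [_sig_force(t, p["b_f"], p["c_f"]) * _photo(dl, "PTT")
            for t, dl in zip(trace.t_air, trace.daylength)]
    return _first_crossing(trace, rate, p["t0"], p["F_star"])


def oracle_m1(p, trace):
    rate = [_lin_force(t, p["T_base"]) * _photo(dl, "M1", p["k"])
            for t, dl in zip(trace.t_air, trace.daylength)]
    return _first_crossing(trace, rate, p["t0"], p["F_star"])


def oracle_m1s(p, trace):
    rate = [_sig_force(t, p["b_f"], p["c_f"]) * _photo(dl, "M1", p["k"])
            for t, dl in zip(trace.t_air, trace.daylength)]
    return _first_crossing(trace, rate, p["t0"], p["F_star"])


def oracle_at(p, trace):
    doy = trace.doy
    start = _idx(doy, p["t0"])
    chill_days = 0.0
    gdd = 0.0
    for i in range(doy.size):
        if i >= start:
            chill_days += 1.0 if trace.t_air[i] < p["T_base"] else 0.0
            gdd += _lin_force(trace.t_air[i], p["T_base"])
        if gdd >= p["a"] + p["b"] * math.exp(p["c"] * chill_days):
            return float(doy[i])
    return SENT


def _oracle_sequential(p, trace, chill_fn, photo_k=None):
    doy = trace.doy
    chill_start = _idx(doy, p["t0_chill"])
    chill = 0.0
    release = None
    for i in range(doy.size):
        if i >= chill_start:
            chill += chill_fn(trace.t_air[i])
        if chill >= p["C_star"]:
            release = i
            break
    if release is None:
        return SENT
    start = max(release, _idx(doy, p["t0"]))
    acc = 0.0
    for i in range(doy.size):
        if i >= start:
            f = _lin_force(trace.t_air[i], p["T_base"])
            if photo_k is not None:
                f *= _photo(trace.daylength[i], "M1", photo_k)
            acc += f
        if acc >= p["F_star"]:
            return float(doy[i])
    return SENT


def oracle_sq(p, trace):
    return _oracle_sequential(
        p, trace, lambda t: _tri_chill(t, p["T_min"], p["T_opt"], p["T_max"])
    )


def oracle_sqb(p, trace):
    return _oracle_sequential(
        p, trace, lambda t: _bell_chill(t, p["a_c"], p["b_c"], p["c_c"])
    )


def oracle_sm1(p, trace):
    return _oracle_sequential(
        p, trace, lambda t: _tri_chill(t, p["T_min"], p["T_opt"], p["T_max"]),
        photo_k=p["k"],
    )


def oracle_sm1b(p, trace):
    return _oracle_sequential(
        p, trace, lambda t: _bell_chill(t, p["a_c"], p["b_c"], p["c_c"]),
        photo_k=p["k"],
    )


def _oracle_parallel(p, trace, chill_fn, photo_k=None):
    doy = trace.doy
    chill_start = _idx(doy, p["t0_chill"])
    force_start = _idx(doy, p["t0"])
    chill = 0.0
    acc = 0.0
    for i in range(doy.size):
        if i >= chill_start:
            chill += chill_fn(trace.t_air[i])
        if p["C_star"] <= 0:
            weight = 1.0
        else:
            weight = min(1.0, (p["C_ini"] + chill) / p["C_star"])
        if i >= force_start:
            f = _lin_force(trace.t_air[i], p["T_base"])
            if photo_k is not None:
                f *= _photo(trace.daylength[i], "M1", photo_k)
            acc += weight * f
        if acc >= p["F_star"]:
            return float(doy[i])
    return SENT


def oracle_pa(p, trace):
    return _oracle_parallel(
        p, trace, lambda t: _tri_chill(t, p["T_min"], p["T_opt"], p["T_max"])
    )


def oracle_pab(p, trace):
    return _oracle_parallel(
        p, trace, lambda t: _bell_chill(t, p["a_c"], p["b_c"], p["c_c"])
    )


def oracle_pm1(p, trace):
    return _oracle_parallel(
        p, trace, lambda t: _tri_chill(t, p["T_min"], p["T_opt"], p["T_max"]),
        photo_k=p["k"],
    )


def oracle_pm1b(p, trace):
    return _oracle_parallel(
        p, trace, lambda t: _bell_chill(t, p["a_c"], p["b_c"], p["c_c"]),
        photo_k=p["k"],
    )


def oracle_um1(p, trace):
    doy = trace.doy
    start = _idx(doy, p["t0"])
    chill = 0.0
    acc = 0.0
    for i in range(doy.size):
        if i >= start:
            chill += _bell_chill(trace.t_air[i], p["a_c"], p["b_c"], p["c_c"])
            acc += (
                _sig_force(trace.t_air[i], p["b_f"], p["c_f"])
                * _photo(trace.daylength[i], "M1", p["k"])
            )
        if acc >= p["w"] * math.exp(-p["z"] * chill):
            return float(doy[i])
    return SENT


def oracle_sgsi(p, trace):
    doy = trace.doy
    idx = _gsi_daily(trace, p)
    n = doy.size
    start = _idx(doy, p["t0"])
    for i in range(n):
        # zero-padded centred 21-day mean (divide by 21 even at the edges)
        lo, hi = max(0, i - 10), min(n, i + 11)
        sm = sum(idx[lo:hi]) / 21.0
        if i >= start and sm >= p["threshold"]:
            return float(doy[i])
    return SENT


def oracle_agsi(p, trace):
    idx = _gsi_daily(trace, p)
    return _first_crossing(trace, idx, p["t0"], p["F_star"])


# ---------------------------------------------------------------------------
# autumn oracles
# ---------------------------------------------------------------------------

def _cold_lin(t, t_base):
    return max(t_base - t, 0.0)


def _cold_sig(t, b_s, c_s):
    return 1.0 / (1.0 + math.exp(b_s * (t - c_s)))


def _oracle_autumn(trace, rate, t0, f_star, c_co2):
    req = _co2_requirement(trace, f_star, c_co2)
    doy = trace.doy
    acc = 0.0
    for i in range(doy.size):
        if i >= _idx(doy, t0):
            acc += rate[i]
        if acc >= req:
            return float(doy[i])
    return SENT


def oracle_cdd(p, trace, c_co2=None):
    rate = [_cold_lin(t, p["T_base"]) for t in trace.t_air]
    return _oracle_autumn(trace, rate, p["t0"], p["F_star"], c_co2)


def oracle_cdds(p, trace, c_co2=None):
    rate = [_cold_sig(t, p["b_s"], p["c_s"]) for t in trace.t_air]
    return _oracle_autumn(trace, rate, p["t0"], p["F_star"], c_co2)


def oracle_cddp(p, trace, c_co2=None):
    rate = [_cold_lin(t, p["T_base"]) * (1.0 - dl / 24.0)
            for t, dl in zip(trace.t_air, trace.daylength)]
    return _oracle_autumn(trace, rate, p["t0"], p["F_star"], c_co2)


def oracle_cddm(p, trace, c_co2=None):
    rate = [_cold_lin(t, p["T_base"]) * max(1.0 + p["m"] * w, 0.0)
            for t, w in zip(trace.t_air, trace.water_table)]
    return _oracle_autumn(trace, rate, p["t0"], p["F_star"], c_co2)


def oracle_ppm(p, trace, c_co2=None):
    doy = trace.doy
    # accumulation starts at the focal-year daylength maximum (solstice)
    best, solstice = -1.0, 0
    for i in range(doy.size):
        if doy[i] >= 1 and trace.daylength[i] > best:
            best, solstice = trace.daylength[i], i
    req = _co2_requirement(trace, p["F_star"], c_co2)
    acc = 0.0
    for i in range(doy.size):
        if i >= solstice:
            acc += max(p["L_crit"] - trace.daylength[i], 0.0) * max(
                1.0 + p["m"] * trace.water_table[i], 0.0
            )
        if acc >= req:
            return float(doy[i])
    return SENT


# ---------------------------------------------------------------------------
# parameter sets and the exactness test
# ---------------------------------------------------------------------------

SPRING_CASES = {
    "LIN": ({"a": 60.0, "b": -2.0}, oracle_lin),
    "TT": ({"t0": 1, "T_base": 0.0, "F_star": 150.0}, oracle_tt),
    "TTs": ({"t0": 1, "b_f": 0.5, "c_f": 5.0, "F_star": 40.0}, oracle_tts),
    "PTT": ({"t0": 1, "T_base": 0.0, "F_star": 80.0}, oracle_ptt),
    "PTTs": ({"t0": 1, "b_f": 0.5, "c_f": 5.0, "F_star": 25.0}, oracle_ptts),
    "M1": ({"t0": 1, "T_base": 0.0, "k": 1.5, "F_star": 120.0}, oracle_m1),
    "M1s": ({"t0": 1, "b_f": 0.5, "c_f": 5.0, "k": 1.5, "F_star": 40.0}, oracle_m1s),
    "AT": ({"t0": 1, "T_base": 5.0, "a": 50.0, "b": 300.0, "c": -0.05}, oracle_at),
    "SQ": ({"t0": 30, "t0_chill": -121, "T_base": 2.0, "T_min": -10.0, "T_opt": 0.0,
            "T_max": 8.0, "C_star": 40.0, "F_star": 60.0}, oracle_sq),
    "SQb": ({"t0": 30, "t0_chill": -121, "T_base": 2.0, "a_c": 0.05, "b_c": 0.1,
             "c_c": 0.0, "C_star": 30.0, "F_star": 60.0}, oracle_sqb),
    "SM1": ({"t0": 30, "t0_chill": -121, "T_base": 2.0, "k": 1.2, "T_min": -10.0,
             "T_opt": 0.0, "T_max": 8.0, "C_star": 40.0, "F_star": 60.0}, oracle_sm1),
    "SM1b": ({"t0": 30, "t0_chill": -121, "T_base": 2.0, "k": 1.2, "a_c": 0.05,
              "b_c": 0.1, "c_c": 0.0, "C_star": 30.0, "F_star": 60.0}, oracle_sm1b),
    "PA": ({"t0": 1, "t0_chill": -121, "T_base": 2.0, "T_min": -10.0, "T_opt": 0.0,
            "T_max": 8.0, "C_ini": 0.0, "C_star": 60.0, "F_star": 70.0}, oracle_pa),
    "PAb": ({"t0": 1, "t0_chill": -121, "T_base": 2.0, "a_c": 0.05, "b_c": 0.1,
             "c_c": 0.0, "C_ini": 5.0, "C_star": 60.0, "F_star": 70.0}, oracle_pab),
    "PM1": ({"t0": 1, "t0_chill": -121, "T_base": 2.0, "k": 1.2, "T_min": -10.0,
             "T_opt": 0.0, "T_max": 8.0, "C_ini": 0.0, "C_star": 60.0,
             "F_star": 70.0}, oracle_pm1),
    "PM1b": ({"t0": 1, "t0_chill": -121, "T_base": 2.0, "k": 1.2, "a_c": 0.05,
              "b_c": 0.1, "c_c": 0.0, "C_ini": 5.0, "C_star": 60.0,
              "F_star": 70.0}, oracle_pm1b),
    "UM1": ({"t0": 1, "a_c": 0.05, "b_c": 0.1, "c_c": 0.0, "b_f": 0.5, "c_f": 5.0,
             "k": 1.2, "w": 200.0, "z": 0.02}, oracle_um1),
    "SGSI": ({"t0": 1, "T_min": 0.0, "T_max": 10.0, "V_min": 0.5, "V_max": 3.0,
              "L_min": 8.0, "L_max": 14.0, "k": 1.0, "threshold": 0.3}, oracle_sgsi),
    "AGSI": ({"t0": 1, "T_min": 0.0, "T_max": 10.0, "V_min": 0.5, "V_max": 3.0,
              "L_min": 8.0, "L_max": 14.0, "k": 1.0, "F_star": 15.0}, oracle_agsi),
}

AUTUMN_CASES = {
    "CDD": ({"t0": 200, "T_base": 15.0, "F_star": 200.0}, oracle_cdd),
    "CDDs": ({"t0": 200, "b_s": 0.3, "c_s": 10.0, "F_star": 40.0}, oracle_cdds),
    "CDDP": ({"t0": 200, "T_base": 15.0, "F_star": 120.0}, oracle_cddp),
    "CDDM": ({"t0": 200, "T_base": 15.0, "m": 0.02, "F_star": 150.0}, oracle_cddm),
    "PPM": ({"L_crit": 14.0, "m": 0.01, "F_star": 300.0}, oracle_ppm),
}


def _predict_single(model, params, trace):
    stack = pp.build_stack([trace])
    x = np.array([params[n] for n in model.parameter_names], dtype=float)
    return float(model.predict(x, stack)[0])


@pytest.mark.parametrize("name", sorted(SPRING_CASES))
def test_spring_models_match_oracle(name, random_traces):
    params, oracle = SPRING_CASES[name]
    model = pp.get_spring_model(name)
    for trace in random_traces:
        got, want = _predict_single(model, params, trace), oracle(params, trace)
        if name == "LIN":
            # LIN is a continuous regression, not an integer-DOY accumulator;
            # only float summation order can differ from the oracle
            assert got == pytest.approx(want, rel=1e-12)
        else:
            assert got == want


@pytest.mark.parametrize("name", sorted(AUTUMN_CASES))
def test_autumn_models_match_oracle(name, random_traces):
    params, oracle = AUTUMN_CASES[name]
    model = pp.get_autumn_model(name)
    for trace in random_traces:
        assert _predict_single(model, params, trace) == oracle(params, trace)


@pytest.mark.parametrize("name", sorted(AUTUMN_CASES))
def test_autumn_co2_variants_match_oracle(name, random_traces):
    base_params, oracle = AUTUMN_CASES[name]
    c_co2 = 0.1
    model = pp.get_autumn_model(name + "CO2")
    params = dict(base_params, c_co2=c_co2)
    for trace in random_traces:
        assert _predict_single(model, params, trace) == oracle(base_params, trace, c_co2)


def test_some_predictions_are_finite_and_some_sentinel_coverage(random_traces):
    """The trace set must actually exercise both crossing and non-crossing
    branches somewhere across the model matrix, or the oracle comparison
    would be vacuous."""
    finite = sentinel = 0
    for name, (params, _) in {**SPRING_CASES, **AUTUMN_CASES}.items():
        model = (pp.get_spring_model(name) if name in SPRING_CASES
                 else pp.get_autumn_model(name))
        for trace in random_traces:
            v = _predict_single(model, params, trace)
            if v == SENT:
                sentinel += 1
            else:
                finite += 1
    assert finite > 0
    assert finite + sentinel == 24 * len(random_traces)
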