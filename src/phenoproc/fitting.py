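"""Parameter estimation and model selection.

Calibration minimises the root-mean-square error between observed and
predicted transition dates by generalized simulated annealing
(:func:`scipy.optimize.dual_annealing`) within uniform parameter bounds,
run as independent parallel chains; the reported fit is the chain with the
lowest AIC.  Model comparison uses a sum-of-squares AIC,
``AIC = 2k + n ln(SSE/n)``, with ΔAIC support classes bounded at 2
(essentially equivalent) and 10 (no support).
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import dual_annealing

from .datatypes import (
    NO_TRANSITION,
    DriverSeries,
    FitResult,
    ModelSpec,
    TransitionObservation,
    support_class,
)
from .stack import DriverError, DriverStack, build_stack

__all__ = [
    "FitConfig",
    "ComparisonTable",
    "cost_rmse",
    "compute_aic",
    "fit_model",
    "rank_models",
    "compare_driver_depths",
    "apply_fitted",
    "default_bounds",
]

#: Epsilon floor for a zero sum of squared errors in the AIC.
SSE_EPSILON = 1e-8


@dataclass
class FitConfig:
    """Controls for simulated-annealing calibration.

    ``n_iterations`` is the objective-evaluation budget per chain.  Chains
    draw independent sub-seeds from the master ``seed`` so results are
    reproducible and independent of execution order.
    """

    n_chains: int = 25
    n_iterations: int = 40_000
    seed: int = 0
    penalty: float = 9999.0
    bounds: Optional[dict[str, tuple[float, float]]] = None
    initial_temp: float = 5230.0
    visit: float = 2.62
    accept: float = -5.0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@functools.lru_cache(maxsize=1)
def _bounds_table() -> dict:
    text = resources.files("phenoproc").joinpath("data/parameter_bounds.yaml").read_text()
    return yaml.safe_load(text)


def default_bounds(model: ModelSpec) -> dict[str, tuple[float, float]]:
    """Packaged default bounds for a model, keyed by parameter name."""
    table = _bounds_table().get(model.season, {})
    if model.name not in table:
        raise KeyError(f"no default bounds for model {model.name}")
    raw = table[model.name]
    out = {}
    for name in model.parameter_names:
        if name not in raw:
            raise KeyError(f"bounds for {model.name} missing parameter {name}")
        lo, hi = float(raw[name][0]), float(raw[name][1])
        if not lo < hi:
            raise ValueError(f"bounds for {model.name}.{name} must have lower < upper")
        out[name] = (lo, hi)
    return out


def cost_rmse(observed, predicted, penalty: float = 9999.0) -> float:
    """RMSE in days; sentinel (no-transition) predictions are replaced by
    the penalty value before squaring so failed parameter vectors are
    dominated."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0:
        raise ValueError("empty observation list")
    if obs.size != pred.size:
        raise ValueError("observed and predicted lengths differ")
    pred = np.where(pred == NO_TRANSITION, penalty, pred)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def compute_aic(observed, predicted, k: int) -> float:
    """Sum-of-squares AIC: ``2k + n ln(SSE/n)`` with natural log."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = obs.size
    if n < 1:
        raise ValueError("need at least one observation")
    sse = float(np.sum((obs - pred) ** 2))
    if sse <= 0.0:
        warnings.warn("SSE is zero; flooring at epsilon for the AIC", stacklevel=2)
        sse = SSE_EPSILON
    return 2.0 * k + n * np.log(sse / n)


def _pair_observations(
    observations: Sequence[TransitionObservation],
    drivers: Sequence[DriverSeries],
) -> tuple[list[TransitionObservation], list[DriverSeries]]:
    by_key = {(d.enclosure_id, d.focal_year): d for d in drivers}
    matched_obs, matched_drv = [], []
    for o in observations:
        key = (o.enclosure_id, o.year)
        if key not in by_key:
            raise ValueError(f"no driver series for observation {key}")
        matched_obs.append(o)
        matched_drv.append(by_key[key])
    return matched_obs, matched_drv


def _make_cost(model: ModelSpec, stack: DriverStack, observed: np.ndarray, penalty: float):
    def cost(x: np.ndarray) -> float:
        pred = model.predict(x, stack)
        return cost_rmse(observed, pred, penalty)

    return cost


def fit_model(
    model: ModelSpec,
    observations: Sequence[TransitionObservation],
    drivers: Sequence[DriverSeries],
    config: Optional[FitConfig] = None,
    temperature_channel: str | int = "air",
) -> FitResult:
    """Calibrate one model against observed transition dates.

    Runs ``config.n_chains`` independent simulated-annealing chains (uniform
    random start inside the bounds, independent sub-seeds) and returns the
    chain with the lowest AIC.  Deterministic given ``config.seed``.
    """
    config = config or FitConfig()
    obs_list, drv_list = _pair_observations(observations, drivers)
    stack = build_stack(drv_list, temperature_channel)
    observed = np.array([o.doy for o in obs_list], dtype=float)

    bounds_map = default_bounds(model)
    if config.bounds:
        bounds_map.update(config.bounds)
    bounds = [bounds_map[name] for name in model.parameter_names]
    cost = _make_cost(model, stack, observed, config.penalty)

    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    best = None
    chain_costs: list[float] = []
    for ss in children:
        rng = np.random.default_rng(ss)
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = dual_annealing(
            cost,
            bounds=bounds,
            maxiter=10_000_000,
            maxfun=config.n_iterations,
            rng=np.random.default_rng(ss.spawn(1)[0]),
            no_local_search=True,
            initial_temp=config.initial_temp,
            visit=config.visit,
            accept=config.accept,
            x0=x0,
        )
        pred = model.predict(res.x, stack)
        aic = compute_aic(observed, np.where(pred == NO_TRANSITION, config.penalty, pred),
                          model.k_params)
        chain_costs.append(float(res.fun))
        if best is None or aic < best[0]:
            best = (aic, res.x, pred)

    aic, x, pred = best
    pred_eff = np.where(pred == NO_TRANSITION, config.penalty, pred)
    return FitResult(
        model=model.name,
        season=model.season,
        parameters={n: float(v) for n, v in zip(model.parameter_names, x)},
        predictions=np.asarray(pred, dtype=float),
        observed=observed,
        rmse=cost_rmse(observed, pred, config.penalty),
        aic=float(compute_aic(observed, pred_eff, model.k_params)),
        n_obs=observed.size,
        k_params=model.k_params,
        chain_costs=chain_costs,
        seed=config.seed,
        temperature_channel=str(temperature_channel),
        observation_keys=[(o.enclosure_id, o.year) for o in obs_list],
    )


@dataclass
class ComparisonTable:
    """Models ranked by AIC with ΔAIC support classes."""

    models: list[str]
    aic: list[float]
    rmse: list[float]
    delta_aic: list[float]
    support: list[str]
    k_params: list[int] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model": self.models,
                "k_params": self.k_params,
                "rmse": self.rmse,
                "aic": self.aic,
                "delta_aic": self.delta_aic,
                "support": self.support,
            }
        )

    @property
    def best(self) -> str:
        return self.models[0]


def rank_models(fits: Sequence[FitResult]) -> ComparisonTable:
    """Rank fitted models by AIC (ascending) and classify ΔAIC support.

    All fits must be against the same observation set, otherwise AICs are
    not comparable.
    """
    if not fits:
        raise ValueError("no fits to rank")
    ref = fits[0]
    for f in fits[1:]:
        if f.observation_keys != ref.observation_keys or not np.array_equal(
            f.observed, ref.observed
        ):
            raise ValueError(
                f"fits for {f.model} and {ref.model} are on different observation sets"
            )
    order = sorted(fits, key=lambda f: f.aic)
    amin = order[0].aic
    deltas = [f.aic - amin for f in order]
    return ComparisonTable(
        models=[f.model for f in order],
        aic=[float(f.aic) for f in order],
        rmse=[float(f.rmse) for f in order],
        delta_aic=[float(d) for d in deltas],
        support=[support_class(d) for d in deltas],
        k_params=[f.k_params for f in order],
    )


def compare_driver_depths(
    model: ModelSpec,
    observations: Sequence[TransitionObservation],
    drivers: Sequence[DriverSeries],
    channels: Sequence[str | int] = ("air", 0, 5, 10, 20, 30, 40, 50, 100, 200),
    config: Optional[FitConfig] = None,
):
    """Fit one model per temperature channel (air, soil depths) with
    identical configuration and seeds; channels absent from the data are
    reported as such rather than failing the scan.

    Returns a DataFrame with columns channel, available, aic, rmse.
    """
    import pandas as pd

    config = config or FitConfig()
    rows = []
    for ch in channels:
        try:
            fit = fit_model(model, observations, drivers, config, temperature_channel=ch)
            rows.append(
                {"channel": str(ch), "available": True, "aic": fit.aic, "rmse": fit.rmse}
            )
        except (KeyError, DriverError):
            rows.append(
                {"channel": str(ch), "available": False, "aic": np.nan, "rmse": np.nan}
            )
    return pd.DataFrame(rows)


def apply_fitted(
    model: ModelSpec,
    parameters: dict[str, float],
    observations: Sequence[TransitionObservation],
    drivers: Sequence[DriverSeries],
    temperature_channel: str | int = "air",
    penalty: float = 9999.0,
) -> tuple[float, np.ndarray]:
    """Forward-apply fitted parameters to (possibly external) data.

    Pure evaluation, no refitting.  Raises
    :class:`~phenoproc.stack.DriverError` when a required channel (e.g.
    water table) is absent, so callers can skip the model with a notice.

    Returns (rmse, predictions).
    """
    obs_list, drv_list = _pair_observations(observations, drivers)
    stack = build_stack(drv_list, temperature_channel)
    x = np.array([parameters[n] for n in model.parameter_names], dtype=float)
    pred = model.predict(x, stack)
    observed = np.array([o.doy for o in obs_list], dtype=float)
    return cost_rmse(observed, pred, penalty), pred
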