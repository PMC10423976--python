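"""Shared accumulation helpers for the phenology model kernels."""

from __future__ import annotations

import numpy as np

from .datatypes import NO_TRANSITION
from .stack import DriverStack


def masked_cumsum(rate: np.ndarray, start_idx: np.ndarray | int) -> np.ndarray:
    """Cumulative sum of ``rate`` (n, d) with per-row accumulation start.

    Days before ``start_idx`` contribute zero."""
    n, d = rate.shape
    cols = np.arange(d)
    start = np.broadcast_to(np.atleast_1d(start_idx), (n,)) if np.ndim(start_idx) else np.full(n, start_idx)
    mask = cols[None, :] >= start[:, None]
    return np.cumsum(rate * mask, axis=1)


def first_true_doy(stack: DriverStack, hit: np.ndarray) -> np.ndarray:
    """Day-of-year of the first True per row of ``hit`` (n, d); sentinel if none."""
    idx = hit.argmax(axis=1)
    ok = hit[np.arange(hit.shape[0]), idx]
    doy = stack.doy[idx].astype(float)
    doy[~ok] = NO_TRANSITION
    return doy


def first_crossing_doy(
    stack: DriverStack,
    accumulated: np.ndarray,
    threshold: np.ndarray | float,
    not_before_idx: np.ndarray | int | None = None,
) -> np.ndarray:
    """First day the (non-decreasing) accumulation reaches a threshold."""
    thr = np.atleast_1d(np.asarray(threshold, dtype=float))
    if thr.size == 1:
        thr = np.full(accumulated.shape[0], thr[0])
    hit = accumulated >= thr[:, None]
    if not_before_idx is not None:
        cols = np.arange(accumulated.shape[1])
        nb = np.broadcast_to(np.atleast_1d(not_before_idx), (accumulated.shape[0],))
        hit = hit & (cols[None, :] >= nb[:, None])
    return first_true_doy(stack, hit)


def all_sentinel(stack: DriverStack) -> np.ndarray:
    """Sentinel prediction for every series (parameter-domain violations)."""
    return np.full(stack.n_series, float(NO_TRANSITION))
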