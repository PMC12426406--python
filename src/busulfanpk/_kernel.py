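"""Fixed-step RK4 integration of the busulfan/GSH system on event-aligned grids.

The structural ODE is mildly nonlinear (elimination is proportional to the
normalized glutathione pool, which is itself depleted by elimination), so
profiles are integrated numerically.  All dosing starts/stops, observation
times and occasion boundaries are knots of the grid, so the forcing function
and the occasion-wise clearance multiplier are exactly piecewise constant on
every step and classical RK4 retains its full order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

__all__ = ["Grid", "build_grid", "integrate_grid"]


@njit(cache=True)
def _rhs(a1, a2, g, r, k10, k12, k21, dep, k_gsh, inv_vc):
    da1 = r - k10 * g * a1 - k12 * a1 + k21 * a2
    da2 = k12 * a1 - k21 * a2
    dg = k_gsh * (1.0 - g) - dep * g * k10 * a1
    dau = a1 * inv_vc
    return da1, da2, dg, dau


@njit(cache=True)
def integrate_grid(times, rates, clmult, cl, vc, q, vp, s_gsh, k_gsh):
    """RK4 over a prebuilt grid.

    times : (n,) grid nodes, strictly increasing, starting at the first dose.
    rates : (n-1,) infusion rate (mg/h) on each interval.
    clmult : (n-1,) multiplicative clearance factor (exp of occasion kappa).
    Returns (conc, gsh, auc) at the grid nodes; conc in mg/L.
    """
    n = times.shape[0]
    conc = np.empty(n)
    gsh = np.empty(n)
    auc = np.empty(n)
    inv_vc = 1.0 / vc
    k12 = q / vc
    k21 = q / vp
    dep = s_gsh * inv_vc
    a1 = 0.0
    a2 = 0.0
    g = 1.0
    au = 0.0
    conc[0] = 0.0
    gsh[0] = 1.0
    auc[0] = 0.0
    for i in range(n - 1):
        h = times[i + 1] - times[i]
        r = rates[i]
        k10 = cl * clmult[i] * inv_vc
        d1 = _rhs(a1, a2, g, r, k10, k12, k21, dep, k_gsh, inv_vc)
        d2 = _rhs(a1 + 0.5 * h * d1[0], a2 + 0.5 * h * d1[1],
                  g + 0.5 * h * d1[2], r, k10, k12, k21, dep, k_gsh, inv_vc)
        d3 = _rhs(a1 + 0.5 * h * d2[0], a2 + 0.5 * h * d2[1],
                  g + 0.5 * h * d2[2], r, k10, k12, k21, dep, k_gsh, inv_vc)
        d4 = _rhs(a1 + h * d3[0], a2 + h * d3[1],
                  g + h * d3[2], r, k10, k12, k21, dep, k_gsh, inv_vc)
        a1 += h * (d1[0] + 2.0 * d2[0] + 2.0 * d3[0] + d4[0]) / 6.0
        a2 += h * (d1[1] + 2.0 * d2[1] + 2.0 * d3[1] + d4[1]) / 6.0
        g += h * (d1[2] + 2.0 * d2[2] + 2.0 * d3[2] + d4[2]) / 6.0
        au += h * (d1[3] + 2.0 * d2[3] + 2.0 * d3[3] + d4[3]) / 6.0
        if a1 < 0.0:
            a1 = 0.0
        conc[i + 1] = a1 * inv_vc
        gsh[i + 1] = g
        auc[i + 1] = au
    return conc, gsh, auc


@dataclass
class Grid:
    """Event-aligned integration grid for one subject/regimen."""

    times: np.ndarray
    rates: np.ndarray            # per interval, mg/h
    occ: np.ndarray              # per interval, occasion index (int)
    obs_idx: np.ndarray          # node indices of requested observation times
    n_occasions: int = 1
    _ones: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def clmult(self, kappa: np.ndarray | None) -> np.ndarray:
        if kappa is None or len(kappa) == 0:
            if self._ones is None:
                self._ones = np.ones(len(self.rates))
            return self._ones
        return np.exp(np.asarray(kappa))[self.occ]


def build_grid(
    doses: Sequence,
    obs_times: Sequence[float] | np.ndarray = (),
    horizon: float | None = None,
    dt: float = 0.05,
    occasion_bounds: Sequence[float] = (),
) -> Grid:
    """Build an integration grid whose knots include every dosing start/stop,
    observation time and occasion boundary, subdivided to steps <= ``dt``.

    ``doses`` is a sequence of objects with ``start_time``, ``amount`` and
    ``infusion_duration`` attributes (or (start, amount, duration) triples).
    """
    starts, amts, durs = [], [], []
    for d in doses:
        try:
            s, a, u = d.start_time, d.amount, d.infusion_duration
        except AttributeError:
            s, a, u = d
        starts.append(float(s))
        amts.append(float(a))
        durs.append(float(u))
    starts_a = np.asarray(starts)
    amts_a = np.asarray(amts)
    durs_a = np.asarray(durs)
    obs = np.asarray(obs_times, dtype=float)
    if horizon is None:
        cand = [0.0]
        if len(starts_a):
            cand.append(float(np.max(starts_a + durs_a)))
        if obs.size:
            cand.append(float(np.max(obs)))
        horizon = max(cand)
    knots = [0.0, float(horizon)]
    knots.extend(starts_a.tolist())
    knots.extend((starts_a + durs_a).tolist())
    knots.extend(obs.tolist())
    knots.extend(float(b) for b in occasion_bounds)
    k = np.unique(np.round(np.asarray(knots, dtype=float), 9))
    k = k[(k >= 0.0) & (k <= horizon + 1e-12)]
    pieces = [np.array([0.0])]
    for lo, hi in zip(k[:-1], k[1:]):
        nstep = max(1, int(np.ceil((hi - lo) / dt - 1e-9)))
        pieces.append(np.linspace(lo, hi, nstep + 1)[1:])
    times = np.concatenate(pieces)
    mids = 0.5 * (times[:-1] + times[1:])
    rates = np.zeros(len(mids))
    for s, a, u in zip(starts_a, amts_a, durs_a):
        active = (mids > s) & (mids < s + u)
        rates[active] += a / u
    bounds = np.asarray(occasion_bounds, dtype=float)
    occ = np.searchsorted(bounds, mids, side="right").astype(np.int64)
    obs_idx = np.searchsorted(times, np.round(obs, 9))
    if obs.size and not np.allclose(times[obs_idx], obs, atol=1e-6):
        raise ValueError("observation times are not grid knots")
    return Grid(times=times, rates=rates, occ=occ, obs_idx=obs_idx,
                n_occasions=len(bounds) + 1)
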