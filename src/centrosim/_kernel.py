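"""Numba kernels for the direct-method stochastic simulation algorithm.

Propensities are restricted to the "bilinear mass-action" form

    a_j(x) = rate_j · (Σ_k co1[j,k]·x[i1[j,k]] + c1_j) · (Σ_k co2[j,k]·x[i2[j,k]] + c2_j)

which covers every reaction in this package (zeroth order, first order,
bimolecular, and size-modulated variants).  Factors are stored sparsely;
an empty factor is the constant 1.

Status codes returned by the kernels:
    0  reached t_max
    1  absorbed (all propensities zero before t_max)
   -1  negative propensity (offending reaction index in the second slot)
   -2  NaN propensity
   -3  a state component went negative after applying a stoichiometry
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ssa_grid", "ssa_events"]


@njit(cache=True)
def _propensities(x, rates, i1, co1, c1, n1, i2, co2, c2, n2, props):
    total = 0.0
    bad = -1
    for j in range(rates.shape[0]):
        f1 = c1[j]
        for k in range(n1[j]):
            f1 += co1[j, k] * x[i1[j, k]]
        f2 = c2[j]
        for k in range(n2[j]):
            f2 += co2[j, k] * x[i2[j, k]]
        a = rates[j] * f1 * f2
        if a < 0.0:
            return -1.0, j
        if np.isnan(a):
            return -2.0, j
        props[j] = a
        total += a
    return total, bad


@njit(cache=True)
def ssa_grid(x0, rates, i1, co1, c1, n1, i2, co2, c2, n2,
             d_idx, d_val, d_n, t_grid, rng):
    """Direct-method SSA recording the state on a fixed time grid.

    Returns (states, status, info) where ``states[k]`` is the state at
    ``t_grid[k]`` and info is the offending reaction index on error.
    """
    nspecies = x0.shape[0]
    ngrid = t_grid.shape[0]
    x = x0.copy()
    out = np.empty((ngrid, nspecies), dtype=np.int64)
    props = np.empty(rates.shape[0], dtype=np.float64)
    t = 0.0
    rec = 0
    # record t=0 (t_grid[0] is required to be 0)
    out[rec] = x
    rec += 1
    t_max = t_grid[ngrid - 1]
    while True:
        total, bad = _propensities(x, rates, i1, co1, c1, n1, i2, co2, c2, n2, props)
        if total < 0.0:
            return out, int(total), bad
        if total == 0.0:
            while rec < ngrid:
                out[rec] = x
                rec += 1
            return out, 1, -1
        r1 = rng.random()
        tau = np.log(1.0 / r1) / total
        t_next = t + tau
        while rec < ngrid and t_grid[rec] < t_next:
            out[rec] = x
            rec += 1
        if t_next > t_max or rec >= ngrid:
            while rec < ngrid:
                out[rec] = x
                rec += 1
            return out, 0, -1
        r2 = rng.random()
        target = r2 * total
        cum = 0.0
        j = rates.shape[0] - 1
        for jj in range(rates.shape[0]):
            cum += props[jj]
            if target < cum:
                j = jj
                break
        for k in range(d_n[j]):
            idx = d_idx[j, k]
            x[idx] += d_val[j, k]
            if x[idx] < 0:
                return out, -3, j
        t = t_next
    return out, 0, -1


@njit(cache=True)
def ssa_events(x0, rates, i1, co1, c1, n1, i2, co2, c2, n2,
               d_idx, d_val, d_n, t_max, max_events, rng):
    """Direct-method SSA recording every reaction event.

    Returns (times, states, n_records, status, info).  The first record is
    the initial state at t = 0.
    """
    nspecies = x0.shape[0]
    x = x0.copy()
    times = np.empty(max_events + 1, dtype=np.float64)
    out = np.empty((max_events + 1, nspecies), dtype=np.int64)
    props = np.empty(rates.shape[0], dtype=np.float64)
    t = 0.0
    times[0] = 0.0
    out[0] = x
    nrec = 1
    while nrec <= max_events:
        total, bad = _propensities(x, rates, i1, co1, c1, n1, i2, co2, c2, n2, props)
        if total < 0.0:
            return times, out, nrec, int(total), bad
        if total == 0.0:
            return times, out, nrec, 1, -1
        r1 = rng.random()
        tau = np.log(1.0 / r1) / total
        t_next = t + tau
        if t_next > t_max:
            return times, out, nrec, 0, -1
        r2 = rng.random()
        target = r2 * total
        cum = 0.0
        j = rates.shape[0] - 1
        for jj in range(rates.shape[0]):
            cum += props[jj]
            if target < cum:
                j = jj
                break
        for k in range(d_n[j]):
            idx = d_idx[j, k]
            x[idx] += d_val[j, k]
            if x[idx] < 0:
                return times, out, nrec, -3, j
        t = t_next
        times[nrec] = t
        out[nrec] = x
        nrec += 1
    return times, out, nrec, 2, -1  # 2: hit max_events
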