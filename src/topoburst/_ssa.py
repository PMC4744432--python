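"""Numba-compiled Gillespie direct-method kernels.

All kernels operate on a generic mass-action network: ``rates[j]`` times the
product of the copy numbers of at most two reactant species (``reactants[j]``,
-1 padded; catalysts appear as reactants with zero net stoichiometry).
Randomness is numba's internal per-thread stream, reseeded at the top of every
kernel call, so a (network, seed) pair maps to one exact trajectory.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _propensities(x, rates, reactants, a):
    a0 = 0.0
    for j in range(rates.shape[0]):
        aj = rates[j]
        r0 = reactants[j, 0]
        if r0 >= 0:
            aj *= x[r0]
        r1 = reactants[j, 1]
        if r1 >= 0:
            aj *= x[r1]
        a[j] = aj
        a0 += aj
    return a0


@njit(cache=False)
def _select(a, a0):
    r = np.random.random() * a0
    c = 0.0
    j_sel = a.shape[0] - 1
    for j in range(a.shape[0]):
        c += a[j]
        if r < c:
            j_sel = j
            break
    return j_sel


@njit(cache=False)
def ssa_record(x0, rates, stoich, reactants, record_times, seed):
    """Run one trajectory, sampling the state at each of ``record_times``."""
    np.random.seed(seed)
    n_sp = x0.shape[0]
    n_rec = record_times.shape[0]
    x = x0.copy()
    out = np.empty((n_rec, n_sp), np.int64)
    a = np.empty(rates.shape[0])
    t = 0.0
    i_rec = 0
    while i_rec < n_rec:
        a0 = _propensities(x, rates, reactants, a)
        if a0 <= 0.0:  # absorbing state: the state holds forever
            while i_rec < n_rec:
                out[i_rec] = x
                i_rec += 1
            break
        tau = -np.log(1.0 - np.random.random()) / a0
        t_next = t + tau
        while i_rec < n_rec and record_times[i_rec] < t_next:
            out[i_rec] = x
            i_rec += 1
        if i_rec >= n_rec:
            break
        j = _select(a, a0)
        for s in range(n_sp):
            x[s] += stoich[j, s]
        t = t_next
    return out


@njit(cache=False)
def ssa_final(x0, rates, stoich, reactants, t_end, seed):
    """Run one trajectory and return only the state at t_end."""
    np.random.seed(seed)
    n_sp = x0.shape[0]
    x = x0.copy()
    a = np.empty(rates.shape[0])
    t = 0.0
    while True:
        a0 = _propensities(x, rates, reactants, a)
        if a0 <= 0.0:
            break
        t += -np.log(1.0 - np.random.random()) / a0
        if t > t_end:
            break
        j = _select(a, a0)
        for s in range(n_sp):
            x[s] += stoich[j, s]
    return x


@njit(cache=False)
def ssa_final_many(x0, rates, stoich, reactants, t_end, seeds):
    """Independent replicates: one end-state row per seed."""
    out = np.empty((seeds.shape[0], x0.shape[0]), np.int64)
    for c in range(seeds.shape[0]):
        out[c] = ssa_final(x0, rates, stoich, reactants, t_end, seeds[c])
    return out


@njit(cache=False)
def ssa_events(x0, rates, stoich, reactants, t_end, max_events, seed):
    """Run one trajectory logging (time, reaction index) for every firing.

    Returns (times, reaction_ids, n_events, overflowed, final_state).
    """
    np.random.seed(seed)
    n_sp = x0.shape[0]
    x = x0.copy()
    a = np.empty(rates.shape[0])
    times = np.empty(max_events)
    rxn = np.empty(max_events, np.int64)
    t = 0.0
    n = 0
    overflowed = False
    while True:
        a0 = _propensities(x, rates, reactants, a)
        if a0 <= 0.0:
            break
        t += -np.log(1.0 - np.random.random()) / a0
        if t > t_end:
            break
        if n >= max_events:
            overflowed = True
            break
        j = _select(a, a0)
        for s in range(n_sp):
            x[s] += stoich[j, s]
        times[n] = t
        rxn[n] = j
        n += 1
    return times[:n], rxn[:n], n, overflowed, x
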