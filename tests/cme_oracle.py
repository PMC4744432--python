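"""Chemical-master-equation oracle for small networks.

Independent of the simulation engine: states are enumerated by breadth-first
reachability within per-species caps, the generator matrix is assembled from
mass-action propensities written out here from scratch, and the stationary
law is obtained with the scipy matrix exponential.
"""

import numpy as np
from scipy.linalg import expm


def _propensity(state, rate, reactants):
    a = rate
    for r in reactants:
        if r >= 0:
            a *= state[r]
    return a


def enumerate_states(x0, stoich, caps):
    start = tuple(int(v) for v in x0)
    seen = {start}
    stack = [start]
    while stack:
        s = stack.pop()
        for row in stoich:
            t = tuple(a + b for a, b in zip(s, row))
            if any(v < 0 for v in t) or any(v > c for v, c in zip(t, caps)):
                continue
            if t not in seen:
                seen.add(t)
                stack.append(t)
    states = sorted(seen)
    return states, {s: i for i, s in enumerate(states)}


def stationary_distribution(x0, rates, stoich, reactants, caps, t_relax=200.0):
    """P(state) at time t_relax (>> all relaxation times) from the CME.

    Transitions that would leave the capped box are dropped (reflecting
    truncation); choose caps far in the tail so this is negligible.
    """
    states, index = enumerate_states(x0, stoich, caps)
    n = len(states)
    Q = np.zeros((n, n))
    for i, s in enumerate(states):
        for j in range(len(rates)):
            a = _propensity(s, rates[j], reactants[j])
            if a <= 0.0:
                continue
            t = tuple(x + d for x, d in zip(s, stoich[j]))
            if any(v < 0 for v in t) or any(v > c for v, c in zip(t, caps)):
                continue
            k = index[t]
            Q[i, k] += a
            Q[i, i] -= a
    p0 = np.zeros(n)
    p0[index[tuple(int(v) for v in x0)]] = 1.0
    p = p0 @ expm(Q * t_relax)
    p = np.clip(p, 0.0, None)
    return states, p / p.sum()


def empirical_state_distribution(samples, states):
    """Empirical probability of each oracle state in an (n_cells, n_species) array."""
    index = {s: i for i, s in enumerate(states)}
    p = np.zeros(len(states))
    extra = 0
    for row in np.asarray(samples):
        key = tuple(int(v) for v in row)
        if key in index:
            p[index[key]] += 1
        else:
            extra += 1
    return p / len(samples), extra / len(samples)
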