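"""Jit-compiled inner loops for the Metropolis chain and the coupled HREM sweep.

All kernels draw randomness from numba's internal Mersenne-Twister state, seeded
explicitly at entry, so a given (arguments, seed) pair reproduces bit-identical
output.  Potentials are passed in a flat encoding so a single kernel serves both
coordinate families:

``kind == KIND_TORSION``
    U(x) = sum_j a[j]/2 * (1 - cos(b[j]*x - c[j])), x periodic on [-pi, pi)
``kind == KIND_POLY``
    U(x) = sum_j a[j] * x**j on [lo, hi]; proposals outside the domain are
    rejected (hard confining wall, symmetric proposal => detailed balance holds)
"""

import numpy as np
from numba import njit

KIND_TORSION = 0
KIND_POLY = 1

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _energy(kind, a, b, c, x):
    e = 0.0
    if kind == KIND_TORSION:
        for j in range(a.shape[0]):
            e += 0.5 * a[j] * (1.0 - np.cos(b[j] * x - c[j]))
    else:
        p = 1.0
        for j in range(a.shape[0]):
            e += a[j] * p
            p *= x
    return e


@njit(cache=True)
def run_chain(kind, a, b, c, lo, hi, beta_s, x0, n_steps, step, record_interval, seed):
    """Metropolis random walk targeting exp(-beta_s * U); returns recorded coords."""
    np.random.seed(seed)
    n_rec = n_steps // record_interval
    out = np.empty(n_rec)
    x = x0
    u = _energy(kind, a, b, c, x)
    r = 0
    for t in range(n_steps):
        xp = x + step * (2.0 * np.random.random() - 1.0)
        inside = True
        if kind == KIND_TORSION:
            if xp >= np.pi:
                xp -= TWO_PI
            elif xp < -np.pi:
                xp += TWO_PI
        else:
            if xp < lo or xp > hi:
                inside = False
        if inside:
            up = _energy(kind, a, b, c, xp)
            if up <= u or np.random.random() < np.exp(-beta_s * (up - u)):
                x = xp
                u = up
        if (t + 1) % record_interval == 0:
            out[r] = x
            r += 1
    return out


@njit(cache=True)
def run_hrem_block(kind, a, b, c, lo, hi,
                   beta, s, x, u, walker,
                   bath_var, sweep_offset, n_sweeps, attempt_interval, step, seed,
                   walker_rec, coord_rec,
                   ex_sweep, ex_pair, ex_delta, ex_acc,
                   attempts, accepts):
    """Advance all n node-chains for n_sweeps exchange sweeps (state mutated in place).

    Chain i targets exp(-beta*s[i]*U).  Each sweep: attempt_interval Metropolis
    steps per chain, then one exchange pass over alternating even/odd contiguous
    node pairs.  An accepted exchange swaps configurations (and walker ids)
    between the two node slots, which is identical to swapping the scaling
    factors between the two walkers.  ``bath_var`` > 0 adds, per attempt, a
    fresh Gaussian bath energy drawn from its exact conditional at each node's
    scaling (mean -beta*s*var, variance var); the constant bath mean cancels in
    the energy difference and is omitted.

    Returns the number of exchange-log entries written.
    """
    np.random.seed(seed)
    n = s.shape[0]
    m = 0
    for sw in range(n_sweeps):
        for i in range(n):
            bs = beta * s[i]
            xi = x[i]
            ui = u[i]
            for t in range(attempt_interval):
                xp = xi + step * (2.0 * np.random.random() - 1.0)
                inside = True
                if kind == KIND_TORSION:
                    if xp >= np.pi:
                        xp -= TWO_PI
                    elif xp < -np.pi:
                        xp += TWO_PI
                else:
                    if xp < lo or xp > hi:
                        inside = False
                if inside:
                    up = _energy(kind, a, b, c, xp)
                    if up <= ui or np.random.random() < np.exp(-bs * (up - ui)):
                        xi = xp
                        ui = up
            x[i] = xi
            u[i] = ui
        parity = (sweep_offset + sw) % 2
        for k in range(parity, n - 1, 2):
            ua = u[k]
            ub = u[k + 1]
            if bath_var > 0.0:
                sd = np.sqrt(bath_var)
                ua += -beta * s[k] * bath_var + sd * np.random.normal()
                ub += -beta * s[k + 1] * bath_var + sd * np.random.normal()
            d = beta * (s[k] - s[k + 1]) * (ub - ua)
            acc = 0
            if d <= 0.0 or np.random.random() < np.exp(-d):
                acc = 1
                tmp = x[k]
                x[k] = x[k + 1]
                x[k + 1] = tmp
                tmp = u[k]
                u[k] = u[k + 1]
                u[k + 1] = tmp
                tw = walker[k]
                walker[k] = walker[k + 1]
                walker[k + 1] = tw
            ex_sweep[m] = sweep_offset + sw
            ex_pair[m] = k
            ex_delta[m] = d
            ex_acc[m] = acc
            attempts[k] += 1
            accepts[k] += acc
            m += 1
        for i in range(n):
            walker_rec[sw, i] = walker[i]
            coord_rec[sw, i] = x[i]
    return m


@njit(cache=True)
def run_discrete_pair(energies, beta, s0, s1, n_sweeps, seed):
    """Two-replica HREM on a discrete state space; returns the joint visit counts.

    Each sweep: one Metropolis move per chain (uniform proposal over the other
    states) followed by one exchange attempt.  counts[i, j] accumulates visits
    to (state at node 0, state at node 1) after each sweep.
    """
    np.random.seed(seed)
    ns = energies.shape[0]
    counts = np.zeros((ns, ns), dtype=np.int64)
    st0 = 0
    st1 = 0
    for sw in range(n_sweeps):
        p = int(np.random.random() * (ns - 1))
        prop = p if p < st0 else p + 1
        du = energies[prop] - energies[st0]
        if du <= 0.0 or np.random.random() < np.exp(-beta * s0 * du):
            st0 = prop
        p = int(np.random.random() * (ns - 1))
        prop = p if p < st1 else p + 1
        du = energies[prop] - energies[st1]
        if du <= 0.0 or np.random.random() < np.exp(-beta * s1 * du):
            st1 = prop
        d = beta * (s0 - s1) * (energies[st1] - energies[st0])
        if d <= 0.0 or np.random.random() < np.exp(-d):
            tmp = st0
            st0 = st1
            st1 = tmp
        counts[st0, st1] += 1
    return counts


@njit(cache=True)
def birth_death_walk(n_nodes, p_up, p_down, n_steps, x0, seed):
    """Lazy nearest-neighbour walk on nodes 0..n_nodes-1 with reflecting ends."""
    np.random.seed(seed)
    out = np.empty(n_steps, dtype=np.int64)
    x = x0
    for t in range(n_steps):
        r = np.random.random()
        if r < p_up:
            if x < n_nodes - 1:
                x += 1
        elif r < p_up + p_down:
            if x > 0:
                x -= 1
        out[t] = x
    return out
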