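"""Numba-compiled inner loop of the exact stochastic simulation.

The kernel is the direct-method Gillespie algorithm specialised to the
birth-death-migration loop: per node i the enabled events are forward
migration at rate r*n_i*(1+rho)/2, backward migration at rate
r*n_i*(1-rho)/2, birth at rate mu*n_i, and death at rate mu*n_tot/Z at each
populated node (Z = number of populated nodes). The kernel seeds numba's
own MT19937 stream, so a run is bit-reproducible given (state, params, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event-kind codes shared with gillespie.py
FORWARD, BACKWARD, BIRTH, DEATH = 0, 1, 2, 3


@njit(cache=True, inline="always")
def _event_rate(kind, i, n, r, rho, mu, ntot, z):
    if kind == FORWARD:
        return r * n[i] * (1.0 + rho) / 2.0
    if kind == BACKWARD:
        return r * n[i] * (1.0 - rho) / 2.0
    if kind == BIRTH:
        return mu * n[i]
    if n[i] > 0:  # DEATH only at populated nodes
        return mu * ntot / z
    return 0.0


@njit(cache=True, inline="always")
def _apply_event(kind, i, n, n_nodes, counts):
    if kind == FORWARD:
        n[i] -= 1
        n[(i + 1) % n_nodes] += 1
    elif kind == BACKWARD:
        n[i] -= 1
        n[(i - 1) % n_nodes] += 1
    elif kind == BIRTH:
        n[i] += 1
    else:
        n[i] -= 1
    counts[kind] += 1


@njit(cache=True)
def simulate_core(n0, r, rho, mu, sample_times, seed):
    """Run one realization, sampling on a fixed time grid.

    Sampling is piecewise-constant: the state recorded at a grid time is the
    state immediately before it. On extinction the trajectory is truncated at
    the last grid point reached.

    Returns (samples, n_valid, event_counts, t_final, n_final) where
    ``samples[:n_valid]`` are the recorded grid states and ``event_counts``
    holds totals per event kind.
    """
    np.random.seed(seed)
    n_nodes = n0.shape[0]
    n_grid = sample_times.shape[0]
    out = np.zeros((n_grid, n_nodes), dtype=np.int64)
    counts = np.zeros(4, dtype=np.int64)
    n = n0.copy()
    t = 0.0
    gi = 0

    while True:
        ntot = 0
        z = 0
        for i in range(n_nodes):
            ntot += n[i]
            if n[i] > 0:
                z += 1
        if ntot == 0:
            break  # extinct: no event can fire again
        total = ntot * (r + 2.0 * mu)
        dt = np.random.exponential(1.0) / total
        t_next = t + dt
        while gi < n_grid and sample_times[gi] <= t_next:
            for i in range(n_nodes):
                out[gi, i] = n[i]
            gi += 1
        if gi >= n_grid:
            t = t_next
            break
        # pick the event proportionally to its propensity
        u = np.random.random() * total
        acc = 0.0
        done = False
        last_kind = -1
        last_node = -1
        for kind in range(4):
            for i in range(n_nodes):
                rate = _event_rate(kind, i, n, r, rho, mu, ntot, z)
                if rate > 0.0:
                    last_kind = kind
                    last_node = i
                    acc += rate
                    if u < acc:
                        _apply_event(kind, i, n, n_nodes, counts)
                        done = True
                        break
            if done:
                break
        if not done:
            # floating-point slack at u ~ total: take the last enabled event
            _apply_event(last_kind, last_node, n, n_nodes, counts)
        t = t_next

    return out, gi, counts, t, n
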