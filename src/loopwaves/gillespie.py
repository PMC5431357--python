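"""Exact continuous-time stochastic simulation of the loop process.

Two engines share the same event semantics:

* a pure-Python reference path built from :func:`propensities` and
  :func:`gillespie_step` (numpy ``Generator`` RNG), used whenever an event
  log is requested, and
* a numba-compiled kernel (:mod:`loopwaves._kernels`) for long runs.

Each engine is bit-reproducible given ``(params, initial, seed)``; the two
engines consume different RNG streams, so they agree in distribution, not
path-by-path. Extinction (an empty system) is an absorbing state, not an
error: the trajectory is truncated there and flagged ``"extinct"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import ModelParams, SystemState

__all__ = [
    "EVENT_KINDS",
    "EventRecord",
    "Propensities",
    "Trajectory",
    "EnsembleResult",
    "Extinct",
    "propensities",
    "gillespie_step",
    "simulate",
    "ensemble",
]

EVENT_KINDS = ("migrate_forward", "migrate_backward", "birth", "death")


class Extinct(Exception):
    """The system is empty: total propensity is zero and no event can fire."""


@dataclass(frozen=True)
class EventRecord:
    kind: str
    node: int
    t: float


@dataclass(frozen=True)
class Propensities:
    """Per-node event rates for one configuration (all non-negative)."""

    forward: np.ndarray
    backward: np.ndarray
    birth: np.ndarray
    death: np.ndarray

    @property
    def total(self) -> float:
        return float(
            self.forward.sum() + self.backward.sum() + self.birth.sum() + self.death.sum()
        )

    def flat(self) -> np.ndarray:
        """Rates concatenated in kernel order: forward, backward, birth, death."""
        return np.concatenate([self.forward, self.backward, self.birth, self.death])


def propensities(state: SystemState, params: ModelParams) -> Propensities:
    """Event rates at a configuration.

    Node ``i`` emits forward migrations at ``r*n_i*(1+rho)/2``, backward at
    ``r*n_i*(1-rho)/2`` and births at ``mu*n_i``. Deaths fire at rate
    ``mu*n_tot/Z`` at every *populated* node (never at an empty one), so the
    total death rate equals the total birth rate ``mu*n_tot`` and the total
    population follows a critical birth-death process.
    """
    n = state.n.astype(float)
    ntot = n.sum()
    z = state.z
    forward = params.r * n * (1.0 + params.rho) / 2.0
    backward = params.r * n * (1.0 - params.rho) / 2.0
    birth = params.mu * n
    death = np.zeros_like(n)
    if z > 0 and params.mu > 0:
        death[state.n > 0] = params.mu * ntot / z
    return Propensities(forward, backward, birth, death)


def gillespie_step(
    state: SystemState, params: ModelParams, rng: np.random.Generator
) -> tuple[EventRecord, SystemState]:
    """One exact jump of the chain: exponential waiting time, categorical event.

    Raises :class:`Extinct` when the system is empty (absorbed).
    """
    props = propensities(state, params)
    total = props.total
    if total <= 0.0:
        raise Extinct("empty system: total propensity is zero")
    dt = rng.exponential(1.0 / total)
    flat = props.flat()
    u = rng.random() * total
    idx = int(np.searchsorted(np.cumsum(flat), u, side="right"))
    idx = min(idx, len(flat) - 1)
    # guard against landing on a zero-rate slot through floating-point slack
    if flat[idx] == 0.0:
        idx = int(np.flatnonzero(flat)[-1])
    n_nodes = params.n_nodes
    kind_code, node = divmod(idx, n_nodes)
    new = state.copy()
    new.t = state.t + dt
    if kind_code == _kernels.FORWARD:
        new.n[node] -= 1
        new.n[(node + 1) % n_nodes] += 1
    elif kind_code == _kernels.BACKWARD:
        new.n[node] -= 1
        new.n[(node - 1) % n_nodes] += 1
    elif kind_code == _kernels.BIRTH:
        new.n[node] += 1
    else:
        new.n[node] -= 1
    return EventRecord(EVENT_KINDS[kind_code], node, new.t), new


@dataclass
class Trajectory:
    """One realization sampled on a regular time grid.

    ``states[k]`` is the configuration immediately before ``sample_times[k]``
    (piecewise-constant interpolation). ``status`` is ``"ok"`` or
    ``"extinct"``; an extinct trajectory is truncated at the last grid point
    reached before absorption.
    """

    sample_times: np.ndarray
    states: np.ndarray
    params: ModelParams
    seed: int
    status: str = "ok"
    events: list | None = None
    event_counts: dict = field(default_factory=dict)
    final_time: float = 0.0
    final_state: np.ndarray | None = None

    @property
    def totals(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return len(self.sample_times)


def _sample_grid(t_max: float, sample_dt: float) -> np.ndarray:
    if not t_max > 0:
        raise ValueError(f"t_max must be > 0, got {t_max}")
    if not sample_dt > 0:
        raise ValueError(f"sample_dt must be > 0, got {sample_dt}")
    n_grid = int(np.floor(t_max / sample_dt + 1e-9)) + 1
    return np.arange(n_grid) * sample_dt


def simulate(
    params: ModelParams,
    initial,
    t_max: float,
    seed: int,
    sample_dt: float = 0.1,
    record_events: bool = False,
) -> Trajectory:
    """Simulate one exact realization.

    Parameters
    ----------
    initial : array-like of int
        Per-node initial populations (length ``params.n_nodes``).
    record_events : bool
        Keep the full event log (uses the Python reference engine; slower).
    """
    n0 = np.asarray(initial, dtype=np.int64)
    if n0.shape != (params.n_nodes,):
        raise ValueError(
            f"initial must have length {params.n_nodes}, got shape {n0.shape}"
        )
    if np.any(n0 < 0):
        raise ValueError("initial populations must be non-negative")
    grid = _sample_grid(t_max, sample_dt)
    if record_events:
        return _simulate_python(params, n0, grid, seed)

    samples, n_valid, counts, t_final, n_final = _kernels.simulate_core(
        n0, params.r, params.rho, params.mu, grid, int(seed) % (2**32)
    )
    status = "ok" if n_valid == len(grid) else "extinct"
    return Trajectory(
        sample_times=grid[:n_valid],
        states=samples[:n_valid],
        params=params,
        seed=int(seed),
        status=status,
        events=None,
        event_counts={k: int(c) for k, c in zip(EVENT_KINDS, counts)},
        final_time=float(t_final),
        final_state=n_final,
    )


def _simulate_python(
    params: ModelParams, n0: np.ndarray, grid: np.ndarray, seed: int
) -> Trajectory:
    rng = np.random.default_rng(seed)
    state = SystemState(n0.copy(), 0.0)
    events: list[EventRecord] = []
    counts = dict.fromkeys(EVENT_KINDS, 0)
    samples = np.zeros((len(grid), params.n_nodes), dtype=np.int64)
    gi = 0
    status = "ok"
    while gi < len(grid):
        try:
            ev, new = gillespie_step(state, params, rng)
        except Extinct:
            status = "extinct"
            break
        while gi < len(grid) and grid[gi] <= new.t:
            samples[gi] = state.n
            gi += 1
        events.append(ev)
        counts[ev.kind] += 1
        state = new
    return Trajectory(
        sample_times=grid[:gi],
        states=samples[:gi],
        params=params,
        seed=int(seed),
        status=status,
        events=events,
        event_counts=counts,
        final_time=state.t,
        final_state=state.n.copy(),
    )


@dataclass
class EnsembleResult:
    """Replicate trajectories plus per-time cross-replicate moments.

    Extinct replicates contribute their true post-extinction state (all
    zeros) to the moments, so the conserved-mean-total property holds across
    the full ensemble.
    """

    sample_times: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    trajectories: list
    statuses: list

    @property
    def mean_total(self) -> np.ndarray:
        return self.mean.sum(axis=1)


def ensemble(
    params: ModelParams,
    initial,
    n_reps: int,
    seed_base: int,
    t_max: float,
    sample_dt: float = 0.1,
) -> EnsembleResult:
    """Run ``n_reps`` independent realizations; replicate k uses seed_base + k."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    grid = _sample_grid(t_max, sample_dt)
    stack = np.zeros((n_reps, len(grid), params.n_nodes), dtype=np.int64)
    trajs = []
    statuses = []
    for k in range(n_reps):
        traj = simulate(params, initial, t_max, seed=seed_base + k, sample_dt=sample_dt)
        stack[k, : traj.n_samples] = traj.states  # zeros beyond extinction
        trajs.append(traj)
        statuses.append(traj.status)
    mean = stack.mean(axis=0)
    var = stack.var(axis=0, ddof=0)
    return EnsembleResult(grid, mean, var, trajs, statuses)
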