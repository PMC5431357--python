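"""Exact transient solution of the master equation on a truncated lattice.

The probability vector over all configurations with total population at most
``n_max`` evolves as ``dP/dt = G P``, where the off-diagonal entries of the
generator ``G`` are exactly the per-event propensities of the stochastic
simulator and the diagonal is minus the total out-rate. Births that would
push the total above ``n_max`` keep their rate on the diagonal but have no
destination inside the lattice, so the generator is sub-stochastic: the row
sums (in the out-rate sense) equal minus the leak rate of the state, and the
mass that escapes is tracked explicitly as ``leaked``. This makes the
truncation honest — probability plus leaked mass is conserved to solver
tolerance.

At desk scale this module is the ground-truth oracle against which the
Gillespie engine is validated.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .gillespie import propensities
from .model import ModelParams, SystemState

__all__ = [
    "StateSpace",
    "LatticeDistribution",
    "Marginals",
    "enumerate_states",
    "build_generator",
    "evolve",
    "marginals",
]

#: dense linear algebra below this state count, sparse above (results agree)
DENSE_STATE_LIMIT = 2000


@dataclass(frozen=True)
class StateSpace:
    """Bijection between lattice states (sum <= n_max) and 0..K-1.

    K = C(n_max + N, N) states, enumerated in lexicographic order.
    """

    n_nodes: int
    n_max: int
    states: np.ndarray  # (K, N) int array
    _index: dict

    @property
    def size(self) -> int:
        return len(self.states)

    def index(self, state) -> int:
        return self._index[tuple(int(x) for x in state)]


def enumerate_states(n_nodes: int, n_max: int) -> StateSpace:
    """All non-negative N-vectors with total <= n_max, with an index map."""
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    states = [
        s
        for s in itertools.product(range(n_max + 1), repeat=n_nodes)
        if sum(s) <= n_max
    ]
    arr = np.array(states, dtype=np.int64)
    index = {s: k for k, s in enumerate(states)}
    assert len(states) == math.comb(n_max + n_nodes, n_nodes)
    return StateSpace(n_nodes, n_max, arr, index)


def build_generator(
    params: ModelParams, n_max: int, space: StateSpace | None = None
) -> tuple[scipy.sparse.csr_matrix, StateSpace]:
    """Sub-stochastic generator G with dP/dt = G P on the truncated lattice.

    ``G[target, source]`` is the propensity of the source->target event;
    ``G[s, s]`` is minus the total out-rate of ``s`` including births whose
    target lies outside the lattice (the leak channel).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if space is None:
        space = enumerate_states(params.n_nodes, n_max)
    n_nodes = params.n_nodes
    rows, cols, vals = [], [], []
    for k, s in enumerate(space.states):
        props = propensities(SystemState(s.copy()), params)
        out_rate = 0.0
        total = int(s.sum())
        for i in range(n_nodes):
            moves = (
                (props.forward[i], (i + 1) % n_nodes, -1, +1),
                (props.backward[i], (i - 1) % n_nodes, -1, +1),
            )
            for rate, j, di, dj in moves:
                if rate > 0.0:
                    t = s.copy()
                    t[i] += di
                    t[j] += dj
                    rows.append(space.index(t))
                    cols.append(k)
                    vals.append(rate)
                    out_rate += rate
            if props.birth[i] > 0.0:
                out_rate += props.birth[i]
                if total + 1 <= n_max:  # else: leak channel, no destination
                    t = s.copy()
                    t[i] += 1
                    rows.append(space.index(t))
                    cols.append(k)
                    vals.append(props.birth[i])
            if props.death[i] > 0.0:
                t = s.copy()
                t[i] -= 1
                rows.append(space.index(t))
                cols.append(k)
                vals.append(props.death[i])
                out_rate += props.death[i]
        if out_rate > 0.0:
            rows.append(k)
            cols.append(k)
            vals.append(-out_rate)
    gen = scipy.sparse.csr_matrix(
        (vals, (rows, cols)), shape=(space.size, space.size)
    )
    return gen, space


@dataclass
class LatticeDistribution:
    """Probability distribution over the truncated configuration lattice."""

    space: StateSpace
    p: np.ndarray
    t: float = 0.0
    leaked: float = 0.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.space.size,):
            raise ValueError("probability vector does not match the state space")

    @classmethod
    def point_mass(cls, space: StateSpace, state) -> "LatticeDistribution":
        p = np.zeros(space.size)
        p[space.index(state)] = 1.0
        return cls(space, p)

    def probability(self, state) -> float:
        return float(self.p[self.space.index(state)])


def evolve(
    dist: LatticeDistribution,
    params: ModelParams,
    t: float,
    generator: scipy.sparse.csr_matrix | None = None,
    leak_tol: float | None = 1e-6,
) -> LatticeDistribution:
    """Propagate the distribution forward by time ``t`` (matrix exponential).

    Dense ``expm`` is used for small lattices, Krylov ``expm_multiply`` above
    :data:`DENSE_STATE_LIMIT`; the two agree to solver tolerance. Warns if
    the accumulated leaked mass exceeds ``leak_tol`` (truncation too small).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return LatticeDistribution(dist.space, dist.p.copy(), dist.t, dist.leaked)
    if generator is None:
        generator, _ = build_generator(params, dist.space.n_max, dist.space)
    if dist.space.size <= DENSE_STATE_LIMIT:
        p_new = scipy.linalg.expm(generator.toarray() * t) @ dist.p
    else:
        p_new = scipy.sparse.linalg.expm_multiply(generator * t, dist.p)
    p_new = np.where(np.abs(p_new) < 1e-300, 0.0, p_new)
    leaked = dist.leaked + float(dist.p.sum() - p_new.sum())
    if leak_tol is not None and leaked > leak_tol:
        warnings.warn(
            f"leaked probability mass {leaked:.3e} exceeds tolerance "
            f"{leak_tol:.1e}; increase n_max",
            stacklevel=2,
        )
    return LatticeDistribution(dist.space, p_new, dist.t + t, leaked)


@dataclass(frozen=True)
class Marginals:
    """Per-node population distributions and their means."""

    pmfs: tuple  # one array of length n_max+1 per node
    means: np.ndarray

    @property
    def mean_total(self) -> float:
        return float(self.means.sum())


def marginals(dist: LatticeDistribution) -> Marginals:
    """Exact per-node marginal pmfs over 0..n_max, and per-node means."""
    space = dist.space
    pmfs = []
    means = np.zeros(space.n_nodes)
    for i in range(space.n_nodes):
        pmf = np.zeros(space.n_max + 1)
        np.add.at(pmf, space.states[:, i], dist.p)
        pmfs.append(pmf)
        means[i] = float(np.arange(space.n_max + 1) @ pmf)
    return Marginals(tuple(pmfs), means)
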