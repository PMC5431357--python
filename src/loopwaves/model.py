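"""Parameters, states, and the linear algebra of the birth-death-migration loop.

The model: particles sit on the nodes of a directed loop of ``N`` nodes. Each
particle migrates to an adjacent node at rate ``r``, choosing the forward
direction (node ``i`` to ``i+1 mod N``) with probability ``(1 + rho)/2`` and the
backward direction with probability ``(1 - rho)/2``. Each particle gives birth
at rate ``mu``; deaths remove particles from the whole system at the matching
total rate ``mu * n_tot``, drawn with equal probability from each *populated*
node, so the total population is a critical birth-death process whose mean is
conserved.

Conventions
-----------
All matrices in this module act on **row vectors**: the mean populations evolve
as ``d<n>/dt = <n> @ B``. Row ``i`` of the migration matrix therefore carries
the rates *out of* node ``i``, and every row of every generator sums to zero
(conservation of the mean total). Nodes are indexed ``0..N-1`` and "forward"
is ``i -> i+1 (mod N)``, so ``rho = 1`` is a pure forward cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "SystemState",
    "RateMatrixSet",
    "SpectralSummary",
    "BoundaryAnalysisError",
    "migration_matrix",
    "interior_generator",
    "boundary_generator",
    "control_parameter",
    "params_for_theta",
    "hopf_threshold",
    "interior_eigenvalues",
    "kappa_b",
    "kappa_e",
]


class BoundaryAnalysisError(ValueError):
    """Raised when boundary (sliding-mode) analysis is requested for N != 3.

    The mean-field boundary dynamics are derived only for the three-node
    loop; for larger loops the boundary equations are not available and we
    refuse rather than guess.
    """


@dataclass(frozen=True)
class ModelParams:
    """Dynamical parameters of the birth-death-migration process.

    Parameters
    ----------
    r : float
        Migration rate per particle per unit time (> 0).
    rho : float
        Directional bias, dimensionless, in [-1, 1]. ``rho = 0`` means
        unbiased migration; ``rho = 1`` a pure forward cycle.
    mu : float
        Birth rate per particle, which equals the total death rate per
        particle (>= 0).
    n_nodes : int
        Number of nodes in the loop (>= 2; wave analysis needs >= 3).
    """

    r: float
    rho: float
    mu: float
    n_nodes: int = 3

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"migration rate r must be > 0, got {self.r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"bias rho must be in [-1, 1], got {self.rho}")
        if not self.mu >= 0:
            raise ValueError(f"birth-death rate mu must be >= 0, got {self.mu}")
        if not (isinstance(self.n_nodes, (int, np.integer)) and self.n_nodes >= 2):
            raise ValueError(f"n_nodes must be an integer >= 2, got {self.n_nodes}")

    @property
    def theta(self) -> float:
        """Control parameter theta = (2*mu - 3*r) / (r*rho); needs rho != 0."""
        return control_parameter(self)


@dataclass
class SystemState:
    """Integer population configuration of the network at a time.

    ``z`` (number of populated nodes) is always recomputed from ``n``; it is
    never cached, so it can never go stale.
    """

    n: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.n.ndim != 1 or self.n.size < 2:
            raise ValueError("state vector must be 1-D with at least 2 nodes")
        if np.any(self.n < 0):
            raise ValueError("populations must be non-negative")

    @property
    def z(self) -> int:
        """Number of populated nodes (recomputed on every access)."""
        return int(np.count_nonzero(self.n))

    @property
    def total(self) -> int:
        return int(self.n.sum())

    def copy(self) -> "SystemState":
        return SystemState(self.n.copy(), self.t)


def migration_matrix(params: ModelParams) -> np.ndarray:
    """N x N migration generator M (row convention).

    Row ``i``: ``-r`` on the diagonal, ``r*(1+rho)/2`` in column ``i+1 mod N``
    and ``r*(1-rho)/2`` in column ``i-1 mod N``. Rows sum to zero. For N = 2
    both off-diagonal contributions land in the same column.
    """
    n = params.n_nodes
    m = np.zeros((n, n))
    fwd = params.r * (1.0 + params.rho) / 2.0
    bwd = params.r * (1.0 - params.rho) / 2.0
    for i in range(n):
        m[i, i] -= params.r
        m[i, (i + 1) % n] += fwd
        m[i, (i - 1) % n] += bwd
    return m


def interior_generator(params: ModelParams) -> np.ndarray:
    """Mean-field generator when every node is populated.

    ``B = M + mu*I - (mu/N)*U`` where ``U`` is the all-ones matrix: births act
    locally (the identity), deaths uniformly across all N populated nodes.
    The uniform row vector is a left eigenvector with eigenvalue 0.
    """
    n = params.n_nodes
    return (
        migration_matrix(params)
        + params.mu * np.eye(n)
        - (params.mu / n) * np.ones((n, n))
    )


def boundary_generator(params: ModelParams, empty_node: int) -> np.ndarray:
    """Mean-field generator on the simplex boundary where one node is empty.

    ``B = M + mu*I - (mu/2)*U2`` where ``U2`` is the all-ones matrix with the
    column of the empty node zeroed: deaths are shared by the two remaining
    populated nodes only. Defined for the three-node loop.
    """
    if params.n_nodes != 3:
        raise BoundaryAnalysisError(
            "boundary analysis unsupported for N != 3 "
            f"(got N = {params.n_nodes}); the boundary mean-field equations "
            "are only derived for the three-node loop"
        )
    if not 0 <= empty_node < 3:
        raise ValueError(f"empty_node must be in 0..2, got {empty_node}")
    u2 = np.ones((3, 3))
    u2[:, empty_node] = 0.0
    return migration_matrix(params) + params.mu * np.eye(3) - (params.mu / 2.0) * u2


def control_parameter(params: ModelParams) -> float:
    """theta = (2*mu - 3*r) / (r*rho), the single knob of the 3-node analysis.

    theta < 0: amorphous; 0 < theta < theta_c: waves; theta > theta_c:
    collapse (waves and collapse coexist for 1 < theta < theta_c). With
    rho < 0 the loop runs backwards and the regime structure applies to
    |theta|. Undefined at rho = 0, where no oscillatory regime exists.
    """
    if params.rho == 0:
        raise ValueError(
            "control parameter undefined for rho = 0 (no directional bias, "
            "no oscillatory regime)"
        )
    return (2.0 * params.mu - 3.0 * params.r) / (params.r * params.rho)


def params_for_theta(
    theta: float, r: float = 1.0, rho: float = 1.0, n_nodes: int = 3
) -> ModelParams:
    """Parameters with the requested control parameter: mu = (theta*r*rho + 3r)/2."""
    if rho == 0:
        raise ValueError("cannot target a control parameter with rho = 0")
    mu = (theta * r * rho + 3.0 * r) / 2.0
    if mu < 0:
        raise ValueError(f"theta = {theta} would need a negative mu = {mu}")
    return ModelParams(r=r, rho=rho, mu=mu, n_nodes=n_nodes)


def hopf_threshold(params: ModelParams) -> float:
    """Birth-death rate at which the uniform state loses stability.

    ``mu* = r * (1 - cos(2*pi/N))`` from the leading eigenvalue pair crossing
    the imaginary axis; independent of rho. Equals (3/2) r at N = 3 and
    decreases monotonically to 0 as N grows.
    """
    if params.n_nodes < 3:
        raise ValueError("Hopf threshold requires a loop of at least 3 nodes")
    return params.r * (1.0 - math.cos(2.0 * math.pi / params.n_nodes))


@dataclass(frozen=True)
class SpectralSummary:
    """Eigenvalues of the interior mean-field generator plus derived flags."""

    eigenvalues: tuple
    hopf_threshold: float
    is_oscillatory: bool

    def to_dict(self) -> dict:
        return {
            "eigenvalues": [
                {"re": float(s.real), "im": float(s.imag)} for s in self.eigenvalues
            ],
            "hopf_threshold": float(self.hopf_threshold),
            "is_oscillatory": bool(self.is_oscillatory),
        }


def interior_eigenvalues(params: ModelParams) -> SpectralSummary:
    """Closed-form spectrum of the interior generator.

    sigma_0 = 0 (the conserved mean total) plus, for k = 1..N-1,

        sigma_k = mu - r + r*cos(2*pi*k/N) + i * r*rho*sin(2*pi*k/N),

    which come in complex-conjugate pairs. At N = 3 the nonzero pair is
    ``mu - (3/2) r +/- i (sqrt(3)/2) r rho``.
    """
    n = params.n_nodes
    sigmas = [complex(0.0, 0.0)]
    for k in range(1, n):
        ang = 2.0 * math.pi * k / n
        sigmas.append(
            complex(
                params.mu - params.r + params.r * math.cos(ang),
                params.r * params.rho * math.sin(ang),
            )
        )
    osc = any(abs(s.imag) > 0 for s in sigmas)
    hopf = hopf_threshold(params) if n >= 3 else float("nan")
    return SpectralSummary(tuple(sigmas), hopf, osc)


def kappa_b(theta: float) -> float:
    """Boundary-exit threshold: sliding requires lead fraction <= kappa_b.

    kappa_b = (1/2) * (1 + theta/3); the Filippov weight w equals exactly 1
    when the lead-node fraction sits at kappa_b.
    """
    return 0.5 * (1.0 + theta / 3.0)


def kappa_e(theta: float) -> float:
    """Unstable equilibrium position on the boundary: (1/2) * (1 - 1/theta).

    Arrivals below kappa_e slide into the collapsed vertex; above it they
    slide outward to kappa_b and re-enter the interior. Undefined at
    theta = 0.
    """
    if theta == 0:
        raise ValueError("kappa_e undefined at theta = 0")
    return 0.5 * (1.0 - 1.0 / theta)


@dataclass(frozen=True)
class RateMatrixSet:
    """The migration matrix plus interior and boundary mean-field generators."""

    M: np.ndarray
    B_interior: np.ndarray
    B_boundary: tuple = field(default=())

    @classmethod
    def from_params(cls, params: ModelParams) -> "RateMatrixSet":
        boundary: tuple = ()
        if params.n_nodes == 3:
            boundary = tuple(boundary_generator(params, j) for j in range(3))
        return cls(
            M=migration_matrix(params),
            B_interior=interior_generator(params),
            B_boundary=boundary,
        )
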