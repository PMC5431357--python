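"""Deterministic (macroscopic) dynamics of the three-node loop.

In the large-population limit the mean populations live on the simplex
``m_0 + m_1 + m_2 = n_bar`` and obey a piecewise-smooth system:

* **interior** (all nodes populated): the linear flow ``dm/dt = m B_interior``
  whose nonzero eigenvalues ``mu - (3/2) r +/- i (sqrt(3)/2) r rho`` make
  trajectories exponential spirals around the uniform point;
* **boundary** (one node empty): a Filippov sliding mode in which the interior
  and boundary generators are blended with weight ``w = Pr{n_empty > 0}``
  chosen to pin the empty component at zero. The sliding flow reduces to the
  scalar equation ``dx/dt = (r rho theta / 2) (x - kappa_e)`` for the lead
  fraction ``x = m_lead / n_bar``, where the lead node is the populated node
  feeding the empty one. Sliding is admissible while ``x <= kappa_b``; below
  ``kappa_e`` (possible only for theta > 1) the state slides into a vertex and
  collapses.

The control parameter ``theta = (2 mu - 3 r) / (r rho)`` organises everything:
theta < 0 amorphous, 0 < theta < theta_c rotating limit cycle (the wave),
theta > theta_c forced collapse, with coexistence for 1 < theta < theta_c.
``theta_c ~= 1.2037`` solves ``l(theta_c/sqrt(3)) + pi/6 = 0`` with
``l(x) = log(x)/x``.

Interior segments use the exact closed-form spiral (the Fourier mode of the
circulant generator); boundary-hit times are located by dense scanning plus
bracketed root-finding, and the limit cycle by iterating the boundary-to-
boundary Poincare map, which the sliding exit at ``kappa_b`` makes strongly
contracting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import (
    ModelParams,
    control_parameter,
    interior_generator,
    boundary_generator,
    kappa_b,
    kappa_e,
    params_for_theta,
)

__all__ = [
    "MeanState",
    "WaveCharacteristics",
    "HybridTrajectory",
    "interior_flow",
    "boundary_weight",
    "boundary_flow",
    "integrate",
    "limit_cycle",
    "theta_critical",
    "grazing_theta",
    "wave_characteristics_curve",
]

#: a simplex component at or below snap * n_bar is treated as exactly zero
BOUNDARY_SNAP = 1e-9

_MIRROR = np.array([0, 2, 1])  # node relabelling that reverses the loop


@dataclass
class MeanState:
    """Mean populations on the simplex, with the active region label."""

    m: np.ndarray
    t: float = 0.0
    region: str = "interior"

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (3,):
            raise ValueError("mean state must have 3 components")
        if np.any(self.m < -1e-12):
            raise ValueError("mean populations must be non-negative")

    @property
    def nbar(self) -> float:
        return float(self.m.sum())


def theta_critical() -> float:
    """Critical control parameter above which the deterministic wave cannot exist.

    Root of ``l(theta/sqrt(3)) + pi/6 = 0`` with ``l(x) = log(x)/x``,
    bracketed in (1, sqrt(3)); approximately 1.2037.
    """

    def resid(theta: float) -> float:
        x = theta / math.sqrt(3.0)
        return math.log(x) / x + math.pi / 6.0

    return brentq(resid, 1.0 + 1e-12, math.sqrt(3.0) - 1e-12, xtol=1e-12)


def _require_three_nodes(params: ModelParams) -> None:
    if params.n_nodes != 3:
        # boundary/limit-cycle analysis is derived for the 3-node loop only
        from .model import BoundaryAnalysisError

        raise BoundaryAnalysisError(
            f"mean-field boundary analysis unsupported for N = {params.n_nodes}"
        )


def interior_flow(m, params: ModelParams) -> np.ndarray:
    """Rate of change of the mean populations when all nodes are populated.

    Row convention: returns ``m @ B_interior``; components sum to zero.
    """
    m = np.asarray(m, dtype=float)
    return m @ interior_generator(params)


def _lead_other(empty_node: int) -> tuple[int, int]:
    """On boundary ``m[empty] = 0``: lead node feeds the empty one."""
    return (empty_node - 1) % 3, (empty_node + 1) % 3


def boundary_weight(m, params: ModelParams, empty_node: int) -> float:
    """Filippov weight ``w = Pr{n_empty > 0}`` that pins the empty component.

    ``w = (3r / 2mu) * (2 rho x + 1 - rho)`` with ``x`` the lead-node
    fraction. Sliding is admissible iff ``0 <= w <= 1``, i.e. ``x <= kappa_b``.
    """
    _require_three_nodes(params)
    if params.mu == 0:
        raise ValueError("boundary weight undefined for mu = 0 (no death process)")
    m = np.asarray(m, dtype=float)
    nbar = m.sum()
    lead, _ = _lead_other(empty_node)
    x = m[lead] / nbar
    return (3.0 * params.r / (2.0 * params.mu)) * (
        2.0 * params.rho * x + 1.0 - params.rho
    )


def _slide_coeffs(params: ModelParams) -> tuple[float, float]:
    """Sliding flow dx/dt = a*x + b for the lead fraction x.

    ``a = mu - (3/2) r = r*rho*theta/2`` and ``b = -a*kappa_e`` expressed
    without theta so the formula stays finite at theta = 0.
    """
    a = params.mu - 1.5 * params.r
    b = 0.75 * params.r - 0.5 * params.mu + 0.25 * params.r * params.rho
    return a, b


class SlidingExit(RuntimeError):
    """Sliding condition w in [0, 1] violated: the state leaves the boundary."""


def boundary_flow(m, params: ModelParams, empty_node: int) -> np.ndarray:
    """Sliding vector field on the boundary with ``m[empty_node] = 0``.

    The empty component is held at exactly zero; the lead fraction obeys
    ``dx/dt = (r rho theta / 2)(x - kappa_e)`` and the other populated node
    changes oppositely, conserving the total. Raises :class:`SlidingExit`
    when the admissibility condition fails (caller switches to the interior
    flow).
    """
    _require_three_nodes(params)
    m = np.asarray(m, dtype=float)
    w = boundary_weight(m, params, empty_node)
    if not 0.0 <= w <= 1.0 + 1e-12:
        raise SlidingExit(
            f"sliding inadmissible: w = {w:.6g} outside [0, 1]; "
            "the trajectory leaves the boundary"
        )
    nbar = m.sum()
    lead, other = _lead_other(empty_node)
    a, b = _slide_coeffs(params)
    dx = (a * (m[lead] / nbar) + b) * nbar
    out = np.zeros(3)
    out[lead] = dx
    out[other] = -dx
    return out


# ---------------------------------------------------------------------------
# interior closed-form spiral


def _spiral_mode(m, params: ModelParams):
    """Decompose a simplex state into centre + rotating Fourier mode.

    m_j(t) = nbar/3 + 2 Re( c1 * exp((lam - i om) t) * exp(2 pi i j / 3) )
    with lam = mu - 3r/2 (radial growth rate) and om = (sqrt(3)/2) r rho
    (angular frequency; positive rho rotates the disturbance forward).
    """
    m = np.asarray(m, dtype=float)
    nbar = m.sum()
    d = m - nbar / 3.0
    j = np.arange(3)
    c1 = complex((d * np.exp(-2j * np.pi * j / 3)).sum() / 3.0)
    lam = params.mu - 1.5 * params.r
    om = (math.sqrt(3.0) / 2.0) * params.r * params.rho
    return nbar, c1, lam, om


def _spiral_states(m, params: ModelParams, t) -> np.ndarray:
    """Exact interior solution at times ``t`` (array) from state ``m``."""
    nbar, c1, lam, om = _spiral_mode(m, params)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ph = c1 * np.exp(2j * np.pi * np.arange(3) / 3)
    return nbar / 3.0 + 2.0 * np.real(
        np.exp((lam - 1j * om) * t)[:, None] * ph[None, :]
    )


def _first_boundary_hit(m, params: ModelParams, t_limit: float):
    """First time > 0 at which an interior spiral component reaches zero.

    Returns ``(t_hit, node)`` or ``None`` when no component can reach zero
    within ``t_limit`` (decaying spiral, or stationary at the centre).
    Dense scanning at ~2000 points per rotation plus bracketed root-finding;
    robust to the tangential start of a boundary departure (the scan begins
    one step after t = 0).
    """
    nbar, c1, lam, om = _spiral_mode(m, params)
    amp = 2.0 * abs(c1)
    thresh = nbar / 3.0
    if amp < 1e-14 * nbar:
        return None  # at the equilibrium point
    t_rot = 2.0 * math.pi / abs(om) if om != 0 else 4.0 / params.r
    dt = t_rot / 2048.0

    if lam < 0:
        if amp <= thresh:
            return None  # envelope already inside the simplex, shrinking
        horizon = min(t_limit, math.log(thresh / amp) / lam + 2 * dt)
    elif lam == 0:
        if amp < thresh * (1.0 - 1e-12):
            return None
        horizon = min(t_limit, 2.0 * t_rot)
    else:
        t_reach = max(0.0, math.log(thresh / amp) / lam)
        horizon = min(t_limit, t_reach + 3.0 * t_rot)

    t_lo = dt
    while t_lo < t_limit:
        ts = np.arange(t_lo, horizon + dt, dt)
        if len(ts) == 0:
            break
        vals = _spiral_states(m, params, ts)
        neg = np.min(vals, axis=1) < 0.0
        if np.any(neg):
            k = int(np.argmax(neg))
            lo = ts[k] - dt
            best = None
            for comp in range(3):

                def f(tt, comp=comp):
                    return _spiral_states(m, params, [tt])[0, comp]

                if f(ts[k]) < 0.0 and f(lo) > 0.0:
                    root = brentq(f, lo, ts[k], xtol=1e-13, rtol=8.9e-16)
                    if best is None or root < best[0]:
                        best = (root, comp)
            if best is not None:
                return best
            t_lo = ts[k] + dt  # degenerate bracket; continue past it
            continue
        if lam > 0 and horizon < t_limit:
            t_lo = horizon
            horizon = min(t_limit, horizon + 2.0 * t_rot)
            continue
        return None
    return None


# ---------------------------------------------------------------------------
# hybrid (event-driven) integration


@dataclass
class HybridTrajectory:
    """Piecewise trajectory of the mean state with its terminal classification.

    ``label`` is one of ``amorphous`` (converged to the uniform centre),
    ``limit_cycle`` (settled on the rotating wave), ``collapsed`` (reached a
    vertex), or ``undetermined``.
    """

    times: np.ndarray
    m: np.ndarray
    region: list
    label: str
    nbar: float
    arrivals: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def _mirror_params(params: ModelParams) -> ModelParams:
    return ModelParams(params.r, -params.rho, params.mu, params.n_nodes)


def integrate(
    params: ModelParams,
    m0,
    t_max: float,
    *,
    snap: float = BOUNDARY_SNAP,
    cycle_tol: float = 1e-9,
    center_tol: float = 1e-6,
    samples_per_rotation: int = 256,
    max_phases: int = 2000,
) -> HybridTrajectory:
    """Event-driven integration of the hybrid mean-field system.

    Alternates exact interior spirals with analytic boundary slides until the
    trajectory converges to the centre (``amorphous``), closes on the rotating
    cycle (``limit_cycle``; successive boundary arrivals within
    ``cycle_tol * n_bar``), or reaches a vertex (``collapsed``). Negative
    ``rho`` is handled by the mirror symmetry (node order reversal).
    """
    _require_three_nodes(params)
    if params.rho == 0:
        raise ValueError("hybrid integration requires a directional bias (rho != 0)")
    if params.rho < 0:
        inner = integrate(
            _mirror_params(params),
            np.asarray(m0, dtype=float)[_MIRROR],
            t_max,
            snap=snap,
            cycle_tol=cycle_tol,
            center_tol=center_tol,
            samples_per_rotation=samples_per_rotation,
            max_phases=max_phases,
        )
        return HybridTrajectory(
            inner.times,
            inner.m[:, _MIRROR],
            inner.region,
            inner.label,
            inner.nbar,
            [((-e) % 3, x) for e, x in inner.arrivals],
            inner.diagnostics,
        )

    m = np.asarray(m0, dtype=float).copy()
    if np.any(m < 0) or m.sum() <= 0:
        raise ValueError("initial mean state must be non-negative with positive total")
    nbar = float(m.sum())
    theta = control_parameter(params)
    kb = kappa_b(theta)
    a, b = _slide_coeffs(params)
    _, _, lam, om = _spiral_mode(m, params)
    t_rot = 2.0 * math.pi / abs(om)
    dt_sample = t_rot / samples_per_rotation

    times = [0.0]
    path = [m.copy()]
    region: list[str] = ["interior"]
    arrivals: list[tuple[int, float]] = []
    label = "undetermined"
    diagnostics: dict = {}
    t = 0.0

    def record(ts, ms, reg):
        for tt, mm in zip(ts, ms):
            times.append(float(tt))
            path.append(np.asarray(mm, dtype=float))
            region.append(reg)

    for _phase in range(max_phases):
        if t >= t_max:
            break
        zero = np.flatnonzero(m <= snap * nbar)
        if len(zero) >= 2:
            label = "collapsed"
            region[-1] = "vertex"
            break
        if len(zero) == 1:
            e = int(zero[0])
            m[e] = 0.0
            lead, other = _lead_other(e)
            x0 = m[lead] / nbar
            g0 = a * x0 + b
            if x0 >= kb - 1e-14 or g0 == 0.0 and x0 >= kb:
                # inadmissible sliding: leave the boundary immediately
                region[-1] = "interior"
            elif abs(g0) < 1e-15 * max(abs(a), 1.0):
                label = "undetermined"
                diagnostics["note"] = "stalled at the unstable boundary equilibrium"
                break
            elif g0 > 0.0:
                # slide outward to the exit point kappa_b, then depart
                if a != 0.0:
                    t_slide = math.log((a * kb + b) / g0) / a
                else:
                    t_slide = (kb - x0) / b
                t_end = min(t_slide, t_max - t)
                ts = np.arange(dt_sample, t_end, dt_sample)
                ts = np.append(ts, t_end)
                if a != 0.0:
                    xs = -b / a + (x0 + b / a) * np.exp(a * ts)
                else:
                    xs = x0 + b * ts
                ms = np.zeros((len(ts), 3))
                ms[:, lead] = xs * nbar
                ms[:, other] = (1.0 - xs) * nbar
                record(t + ts, ms, f"boundary{e}")
                t += t_end
                if t_end < t_slide:
                    break  # ran out of time mid-slide
                m = np.zeros(3)
                m[lead] = kb * nbar
                m[other] = (1.0 - kb) * nbar
                continue
            else:
                # slide inward to the vertex: collapse
                t_slide = math.log(b / g0) / a
                t_end = min(t_slide, t_max - t)
                ts = np.arange(dt_sample, t_end, dt_sample)
                ts = np.append(ts, t_end)
                xs = -b / a + (x0 + b / a) * np.exp(a * ts)
                ms = np.zeros((len(ts), 3))
                ms[:, lead] = np.maximum(xs, 0.0) * nbar
                ms[:, other] = (1.0 - np.maximum(xs, 0.0)) * nbar
                record(t + ts, ms, f"boundary{e}")
                t += t_end
                if t_end < t_slide:
                    break
                m = np.zeros(3)
                m[other] = nbar
                record([t], [m.copy()], "vertex")
                label = "collapsed"
                break

        hit = _first_boundary_hit(m, params, t_max - t)
        if hit is None:
            nb, c1, lam_, _ = _spiral_mode(m, params)
            amp = 2.0 * abs(c1)
            if lam_ < 0 or amp < 1e-12 * nbar:
                if lam_ < 0 and amp > 0:
                    t_conv = min(
                        t_max - t, math.log(center_tol * nbar / (3 * amp)) / lam_
                    )
                    t_conv = max(t_conv, dt_sample)
                    ts = np.arange(dt_sample, t_conv, dt_sample)
                    ts = np.append(ts, t_conv)
                    record(t + ts, _spiral_states(m, params, ts), "interior")
                    t += t_conv
                label = "amorphous" if lam_ < 0 else "undetermined"
                if lam_ >= 0 and amp < 1e-12 * nbar:
                    diagnostics["note"] = "started at the unstable centre"
            else:
                ts = np.arange(dt_sample, t_max - t, dt_sample)
                if len(ts):
                    record(t + ts, _spiral_states(m, params, ts), "interior")
                t = t_max
                label = "undetermined"
                diagnostics["note"] = "no boundary reached within t_max"
            break

        t_hit, node = hit
        ts = np.arange(dt_sample, t_hit, dt_sample)
        ts = np.append(ts, t_hit)
        ms = _spiral_states(m, params, ts)
        ms[-1, node] = 0.0
        ms[-1] = np.maximum(ms[-1], 0.0)
        ms[-1] *= nbar / ms[-1].sum()
        record(t + ts, ms, "interior")
        region[-1] = f"boundary{node}"
        t += t_hit
        m = ms[-1].copy()
        lead, _ = _lead_other(node)
        x_arr = m[lead] / nbar
        arrivals.append((node, x_arr))
        if len(arrivals) >= 2 and abs(arrivals[-1][1] - arrivals[-2][1]) <= cycle_tol:
            label = "limit_cycle"
            break
    else:
        diagnostics["note"] = "phase budget exhausted"

    return HybridTrajectory(
        np.asarray(times),
        np.vstack(path),
        region,
        label,
        nbar,
        arrivals,
        diagnostics,
    )


# ---------------------------------------------------------------------------
# limit cycle and wave characteristics


@dataclass(frozen=True)
class WaveCharacteristics:
    """Frequency and amplitude of the deterministic rotating wave.

    ``frequency`` counts full revolutions of the disturbance per unit time
    (one revolution = three boundary-to-boundary segments);
    ``fhat = frequency / (r * |rho|)`` is the universal scaling function of
    theta. ``amplitude`` is the cycle maximum of one node's population
    divided by the mean per-node population ``n_bar / 3`` (so 1 at the
    uniform state, 3 at full collapse). ``marginal`` flags the
    non-hyperbolic endpoints theta = 0 and theta = theta_c.
    """

    theta: float
    frequency: float
    fhat: float
    amplitude: float
    period: float
    exists: bool
    marginal: bool = False
    diagnostics: dict = field(default_factory=dict, compare=False)


def _flight(x_dep: float, params: ModelParams):
    """Interior flight from a boundary departure, in the rotating frame.

    Departure state (lead, empty, other) = (x_dep, 0, 1 - x_dep) on the
    boundary with node 1 empty. Returns (t_flight, arrival state, arrival
    node); for the wave the arrival node is 2 and the new lead is node 1.
    """
    m0 = np.array([x_dep, 0.0, 1.0 - x_dep])
    hit = _first_boundary_hit(m0, params, t_limit=1e6)
    if hit is None:
        return None
    t_hit, node = hit
    m_arr = _spiral_states(m0, params, [t_hit])[0]
    m_arr[node] = 0.0
    m_arr = np.maximum(m_arr, 0.0)
    m_arr /= m_arr.sum()
    return t_hit, m_arr, node


def limit_cycle(
    params: ModelParams, *, cycle_tol: float = 1e-9, max_iter: int = 200
) -> WaveCharacteristics:
    """Locate the attracting rotating wave and measure its characteristics.

    Iterates the boundary-to-boundary Poincare map (departure coordinate on
    one boundary, by the cyclic symmetry) until successive departures agree
    to ``cycle_tol``; the sliding exit pins departures at ``kappa_b`` so
    convergence is immediate whenever the arrival slides. No cycle exists
    for theta outside (0, theta_c).
    """
    _require_three_nodes(params)
    work = params if params.rho > 0 else _mirror_params(params)
    if params.rho == 0:
        raise ValueError("wave analysis requires a directional bias (rho != 0)")
    theta = control_parameter(work)
    tc = theta_critical()
    if theta <= 1e-12 or theta >= tc - 1e-12:
        return WaveCharacteristics(
            theta=theta,
            frequency=float("nan"),
            fhat=float("nan"),
            amplitude=float("nan"),
            period=float("nan"),
            exists=False,
            marginal=(abs(theta) <= 1e-12 or abs(theta - tc) <= 1e-12),
        )

    kb = kappa_b(theta)
    ke = kappa_e(theta) if theta != 0 else -math.inf
    a, b = _slide_coeffs(work)
    x_dep = kb
    t_flight = t_slide = 0.0
    x_arr = math.nan
    converged = False
    for _ in range(max_iter):
        res = _flight(x_dep, work)
        if res is None:
            return WaveCharacteristics(
                theta, math.nan, math.nan, math.nan, math.nan, False,
                diagnostics={"note": "no boundary reached from departure"},
            )
        t_flight, m_arr, node = res
        if node != 2:
            return WaveCharacteristics(
                theta, math.nan, math.nan, math.nan, math.nan, False,
                diagnostics={"note": f"unexpected arrival boundary {node}"},
            )
        x_arr = float(m_arr[1])  # new lead fraction on the next boundary
        if theta > 1.0 and x_arr <= ke:
            return WaveCharacteristics(
                theta, math.nan, math.nan, math.nan, math.nan, False,
                diagnostics={"note": "arrival below kappa_e: collapse branch"},
            )
        if x_arr >= kb:
            t_slide = 0.0
            x_new = x_arr
        else:
            t_slide = math.log((a * kb + b) / (a * x_arr + b)) / a
            x_new = kb
        if abs(x_new - x_dep) <= cycle_tol:
            x_dep = x_new
            converged = True
            break
        x_dep = x_new
    if not converged:
        warnings.warn("Poincare iteration did not converge", stacklevel=2)

    period = 3.0 * (t_flight + t_slide)
    freq = 1.0 / period
    fhat = freq / (work.r * work.rho)

    # cycle maximum of a single node's fraction (times 3 by the convention)
    ts = np.linspace(0.0, t_flight, 4097)
    m0 = np.array([x_dep, 0.0, 1.0 - x_dep])
    vals = _spiral_states(m0, work, ts)
    k = int(np.argmax(vals))
    peak = float(vals.flat[k])
    row, col = divmod(k, 3)
    if 0 < row < len(ts) - 1:  # parabolic refinement of the sampled peak
        y0, y1, y2 = vals[row - 1, col], vals[row, col], vals[row + 1, col]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            peak = float(y1 - (y0 - y2) ** 2 / (8 * denom))
    peak = max(peak, kb, 1.0 - x_arr)
    amplitude = 3.0 * peak

    return WaveCharacteristics(
        theta=theta,
        frequency=freq,
        fhat=fhat,
        amplitude=amplitude,
        period=period,
        exists=True,
        diagnostics={
            "t_flight": t_flight,
            "t_slide": t_slide,
            "x_departure": x_dep,
            "x_arrival": x_arr,
        },
    )


def grazing_theta(r: float = 1.0, rho: float = 1.0) -> float:
    """Control parameter at which the cycle grazes the boundary equilibrium.

    Root of ``x_arrival(theta) - kappa_e(theta)`` continued from the wave
    side; coincides with ``theta_critical()`` (the wave ceases to exist when
    the cycle's boundary arrival reaches the unstable boundary point).
    """

    def gap(theta: float) -> float:
        work = params_for_theta(theta, r=r, rho=rho)
        res = _flight(kappa_b(theta), work)
        if res is None:
            return -1.0
        _, m_arr, _ = res
        return float(m_arr[1]) - kappa_e(theta)

    return brentq(gap, 1.05, 1.35, xtol=1e-10)


def wave_characteristics_curve(
    thetas, r: float = 1.0, rho: float = 1.0
):
    """Limit-cycle frequency/amplitude over a theta grid, as a DataFrame."""
    import pandas as pd

    rows = []
    for theta in np.asarray(thetas, dtype=float):
        wc = limit_cycle(params_for_theta(theta, r=r, rho=rho))
        rows.append(
            {
                "theta": theta,
                "fhat": wc.fhat,
                "frequency": wc.frequency,
                "amplitude": wc.amplitude,
                "period": wc.period,
                "exists": wc.exists,
            }
        )
    return pd.DataFrame(rows)
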