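"""Observables of stochastic trajectories: regimes, frequency, amplitude.

The regimes of the loop process are qualitative phases of the occupancy
pattern: *amorphous* (fractions hover around 1/3), *wave* (a coherent
disturbance rotates, each node periodically emptying and refilling),
*intermittent* (wave epochs alternate with epochs of lodging at a single
node), and *collapsed* (the bulk sits at one node). The classifier and the
estimators work only on occupancy fractions, so they are invariant under
cyclic relabelling of the nodes and under rescaling all populations.

The wave frequency is measured by the net winding of the leading-node label:
each forward hand-over of the maximum-occupancy node counts +1, each backward
hand-over -1, and three net forward steps make one full revolution. This is
robust to amplitude noise and matches the full-revolution period convention
of the mean-field limit cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gillespie import Trajectory
from .model import ModelParams

__all__ = [
    "RegimeLabel",
    "occupancy_fractions",
    "classify",
    "window_frequencies",
    "cycle_amplitudes",
    "estimate_frequency",
    "estimate_amplitude",
]

#: a node whose time-averaged occupancy exceeds this is "holding the bulk"
COLLAPSE_THRESHOLD = 0.9
#: a node whose occupancy drops below this has "emptied"
EMPTY_THRESHOLD = 0.05


@dataclass(frozen=True)
class RegimeLabel:
    """Classification of one trajectory plus the diagnostic scores used."""

    label: str  # amorphous | wave | intermittent | collapsed | extinct | undetermined
    evidence: dict = field(default_factory=dict)


def occupancy_fractions(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample fractions n_i / n_tot; the extinct tail (if any) is dropped.

    Returns (times, fractions) with fractions summing to 1 at every sample.
    Raises if the trajectory never has a populated sample.
    """
    totals = traj.totals
    alive = totals > 0
    if not np.any(alive):
        raise ValueError("no occupancy defined: trajectory has no populated samples")
    times = traj.sample_times[alive]
    frac = traj.states[alive].astype(float) / totals[alive, None]
    return times, frac


def _winding(frac: np.ndarray) -> np.ndarray:
    """Cumulative net forward hand-overs of the leading-node label.

    A transition of the argmax from node i to i+1 (mod 3) counts +1, to
    i-1 counts -1; flicker between neighbours cancels, so the winding is a
    robust phase for the rotating disturbance.
    """
    lead = np.argmax(frac, axis=1)
    step = np.diff(lead) % frac.shape[1]
    inc = np.where(step == 1, 1, np.where(step == frac.shape[1] - 1, -1, 0))
    return np.concatenate([[0], np.cumsum(inc)])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [start, stop) of the maximal True runs of a boolean mask."""
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[~mask[edges]] + 1)
    stops = list(edges[mask[edges]] + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        stops = stops + [len(mask)]
    return list(zip(starts, stops))


def _dwell_time(params: ModelParams) -> float:
    """Minimum duration for a single-node epoch to count as a collapse epoch.

    One mean-field wave period when the deterministic cycle exists, else the
    linear rotation period 2*pi / ((sqrt(3)/2) r |rho|); an unbiased loop
    (rho = 0) has no rotation and falls back to the migration time scale.
    """
    if params.rho == 0:
        return 4.0 / params.r
    from .meanfield import limit_cycle

    try:
        wc = limit_cycle(params)
        if wc.exists:
            return wc.period
    except ValueError:
        pass
    return 2.0 * math.pi / ((math.sqrt(3.0) / 2.0) * params.r * abs(params.rho))


def classify(
    traj: Trajectory,
    params: ModelParams | None = None,
    window: float = 10.0,
    collapse_threshold: float = COLLAPSE_THRESHOLD,
    empty_threshold: float = EMPTY_THRESHOLD,
) -> RegimeLabel:
    """Assign a regime label to one trajectory.

    Decision rule: find *collapse epochs* — maximal stretches with the
    leading occupancy above ``collapse_threshold`` lasting at least one wave
    period. If such epochs exist, the trajectory is ``collapsed`` when no
    wave epoch (a full revolution of the leading node) occurs after the
    first of them and fewer than two full revolutions precede it, otherwise
    ``intermittent``. Without collapse epochs it is ``wave`` when the
    disturbance completes at least two net revolutions and nodes empty
    recurrently, else ``amorphous``. Deterministic given the trajectory.
    """
    if params is None:
        params = traj.params
    if traj.status == "extinct":
        return RegimeLabel("extinct", {"final_time": traj.final_time})
    times, frac = occupancy_fractions(traj)
    span = float(times[-1] - times[0])
    if span < window:
        return RegimeLabel("undetermined", {"span": span, "window": window})

    maxfrac = frac.max(axis=1)
    wind = _winding(frac)
    rotations_total = abs(wind[-1]) / 3.0
    dwell = _dwell_time(params)

    runs = [
        (i, j)
        for i, j in _runs(maxfrac > collapse_threshold)
        if times[j - 1] - times[i] >= dwell
    ]
    empty_events = len(_runs(frac.min(axis=1) < empty_threshold))

    tail = times >= times[-1] - window
    evidence = {
        "m_star": float(maxfrac[tail].mean()),
        "rotations_total": rotations_total,
        "n_collapse_epochs": len(runs),
        "n_empty_events": empty_events,
        "dwell": dwell,
        "collapse_threshold": collapse_threshold,
        "empty_threshold": empty_threshold,
    }

    if runs:
        first_stop = runs[0][1]
        rot_after = abs(wind[-1] - wind[min(first_stop, len(wind) - 1)]) / 3.0
        rot_before = abs(wind[runs[0][0]]) / 3.0
        evidence["rotations_after_first_collapse"] = rot_after
        evidence["rotations_before_first_collapse"] = rot_before
        # a completed revolution after (or two before) a collapse epoch means
        # the trajectory switched between wave- and collapse-behaviour
        if rot_after >= 1.0 or rot_before >= 2.0:
            return RegimeLabel("intermittent", evidence)
        return RegimeLabel("collapsed", evidence)

    if rotations_total >= 2.0 and empty_events >= 2:
        return RegimeLabel("wave", evidence)
    return RegimeLabel("amorphous", evidence)


#: minimum fraction of leading-node hand-overs that must share one direction
COHERENCE_THRESHOLD = 0.5


def _require_rotations(frac: np.ndarray, min_rotations: float) -> np.ndarray:
    """Winding of a coherently rotating disturbance, or an "undefined" signal.

    Requires both enough net revolutions and directional coherence: a
    disturbance that rotates has nearly all leading-node hand-overs in one
    direction, whereas an amorphous argmax random-walks (net winding grows
    only diffusively, coherence ~ 1/sqrt(steps)).
    """
    wind = _winding(frac)
    total = abs(wind[-1]) / 3.0
    steps = int(np.abs(np.diff(wind)).sum())
    coherence = abs(wind[-1]) / max(steps, 1)
    if total < min_rotations or coherence < COHERENCE_THRESHOLD:
        raise ValueError(
            f"no coherent oscillation: {total:.2f} net revolutions at "
            f"directional coherence {coherence:.2f} "
            f"(need >= {min_rotations} and >= {COHERENCE_THRESHOLD})"
        )
    return wind


def window_frequencies(
    traj: Trajectory, n_windows: int = 5, min_rotations: float = 1.5
) -> np.ndarray:
    """Per-window revolution rates of the travelling disturbance.

    The trajectory is split into ``n_windows`` equal time windows; within
    each, the winding increment between the first and last hand-over is
    divided by the time between them (so window edges falling between
    hand-overs do not truncate fractional rotations). Raises when the whole
    trajectory shows no coherent oscillation.
    """
    times, frac = occupancy_fractions(traj)
    wind = _require_rotations(frac, min_rotations)
    step_idx = np.flatnonzero(np.diff(wind)) + 1  # samples where the lead hands over
    edges = np.linspace(times[0], times[-1], n_windows + 1)
    rates = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        inside = step_idx[(times[step_idx] >= lo) & (times[step_idx] <= hi)]
        if len(inside) >= 2:
            first, last = inside[0], inside[-1]
            span = times[last] - times[first]
            if span > 0:
                rates.append(abs(wind[last] - wind[first]) / 3.0 / span)
    return np.asarray(rates)


def cycle_amplitudes(
    traj: Trajectory, node: int = 0, min_rotations: float = 1.5
) -> np.ndarray:
    """Per-cycle amplitudes ``3 * max n_node / n_tot`` of one node.

    Cycles are delimited by successive full revolutions of the leading-node
    winding, so each contains one peak of the tracked node. The amplitude
    convention gives 1 at the uniform state and 3 at full collapse. Raises
    when no coherent oscillation is present.
    """
    _, frac = occupancy_fractions(traj)
    wind = _require_rotations(frac, min_rotations)
    sign = 1 if wind[-1] >= 0 else -1
    targets = 3 * sign * np.arange(1, int(abs(wind[-1]) / 3.0) + 1)
    bounds = [0] + [int(np.argmax(sign * wind >= sign * tgt)) for tgt in targets]
    amps = []
    for i, j in zip(bounds[:-1], bounds[1:]):
        if j > i:
            amps.append(3.0 * float(frac[i : j + 1, node].max()))
    return np.asarray(amps)


def estimate_frequency(
    traj: Trajectory, n_windows: int = 5, min_rotations: float = 1.5
) -> tuple[float, float]:
    """Wave frequency (full revolutions per unit time) with its spread.

    Mean and standard deviation of the :func:`window_frequencies` estimates.
    """
    rates = window_frequencies(traj, n_windows, min_rotations)
    return float(rates.mean()), float(rates.std(ddof=1) if len(rates) > 1 else 0.0)


def estimate_amplitude(
    traj: Trajectory, node: int = 0, min_rotations: float = 1.5
) -> tuple[float, float]:
    """Wave amplitude with its spread across cycles.

    Mean and standard deviation of the :func:`cycle_amplitudes` estimates.
    """
    amps = cycle_amplitudes(traj, node, min_rotations)
    return float(amps.mean()), float(amps.std(ddof=1) if len(amps) > 1 else 0.0)
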