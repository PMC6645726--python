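"""Dynamical-regime classification and phase diagrams.

A frozen (autonomous) circuit is assigned one of five regimes from its
attractor census: monostable or multistable, each with or without damped
oscillations (a spiral sink among the attractors), or a sustained limit
cycle.  Phase diagrams sweep maternal input levels, regulatory weights,
or the two composite control parameters of a simplified AC/DC model, and
record the regime per grid cell.  All sweeps freeze the non-varied
maternal inputs to their values at time class T1, following the
convention used for the circuit's bifurcation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .circuit import GeneCircuit
from .phase_space import (FrozenField, InstantaneousPortrait, SPIRAL_SINK,
                          UNSTABLE_FOCUS, find_steady_states)

__all__ = [
    "RegimeLabel",
    "PhaseDiagram",
    "classify_regime",
    "detect_limit_cycle",
    "maternal_phase_diagram",
    "weight_phase_diagram",
    "simplified_acdc",
    "control_parameter_map",
    "boundary_position",
    "MONOSTABLE",
    "MONOSTABLE_OSC",
    "MULTISTABLE",
    "MULTISTABLE_OSC",
    "LIMIT_CYCLE",
]

MONOSTABLE = "monostable"
MONOSTABLE_OSC = "monostable-damped-oscillatory"
MULTISTABLE = "multistable"
MULTISTABLE_OSC = "multistable-damped-oscillatory"
LIMIT_CYCLE = "limit-cycle"

BASE_LABELS = (MONOSTABLE, MONOSTABLE_OSC, MULTISTABLE, MULTISTABLE_OSC,
               LIMIT_CYCLE)


@dataclass(frozen=True)
class RegimeLabel:
    """One of the five dynamical regimes, plus a near-bifurcation flag."""

    base: str
    near_bifurcation: bool = False

    def __post_init__(self):
        if self.base not in BASE_LABELS:
            raise ValueError(f"unknown regime label {self.base!r}")

    @property
    def multistable(self) -> bool:
        return self.base in (MULTISTABLE, MULTISTABLE_OSC)

    def __str__(self):
        return self.base + ("*" if self.near_bifurcation else "")


def detect_limit_cycle(field: FrozenField, initial_conditions=None,
                       horizon: float | None = None,
                       transient_fraction: float = 0.5,
                       amplitude_rel: float = 0.01,
                       stationarity_rel: float = 0.05,
                       n_samples: int = 4000):
    """Test for sustained oscillations by long simulation.

    Integrates the frozen field from each initial condition over
    ``horizon`` (default ``50 / min(lambda)``, well past the slowest
    decay timescale), discards the leading ``transient_fraction``, and
    reports a limit cycle iff, for some trajectory, (a) the peak-to-peak
    amplitude of at least one gene exceeds ``amplitude_rel`` of its
    saturation R/lambda, and (b) the amplitudes of successive oscillation
    periods agree to within ``stationarity_rel`` (stationarity, as
    opposed to slow damped spirals).  Returns ``(bool, amplitudes)``
    where ``amplitudes`` is the per-gene peak-to-peak amplitude of the
    retained window of the qualifying (or first) trajectory.
    """
    c = field.circuit
    upper = c.saturation()
    if horizon is None:
        horizon = 50.0 / float(c.decay.min())
    if initial_conditions is None:
        initial_conditions = [0.05 * upper, 0.5 * upper,
                              upper * np.linspace(0.2, 0.9, c.n_genes)]
    best_amp = np.zeros(c.n_genes)
    for x0 in initial_conditions:
        t_eval = np.linspace(0.0, horizon, n_samples)
        sol = solve_ivp(lambda t, y: field(y), (0.0, horizon),
                        np.asarray(x0, dtype=float), t_eval=t_eval,
                        method="LSODA", rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise RuntimeError(f"limit-cycle probe failed: {sol.message}")
        keep = sol.t >= transient_fraction * horizon
        y = sol.y[:, keep]
        amp = y.max(axis=1) - y.min(axis=1)
        if amp.max() > best_amp.max():
            best_amp = amp
        if np.all(amp < amplitude_rel * upper):
            continue  # converged to a fixed point from this start
        g = int(np.argmax(amp / upper))
        series = y[g]
        prominence = 0.1 * amp[g]
        peaks, _ = find_peaks(series, prominence=prominence)
        troughs, _ = find_peaks(-series, prominence=prominence)
        if peaks.size < 3 or troughs.size < 2:
            continue
        cycle_amps = []
        for k in range(peaks.size - 1):
            lo = series[troughs[(troughs > peaks[k]) & (troughs < peaks[k + 1])]]
            if lo.size == 0:
                continue
            cycle_amps.append(series[peaks[k]] - lo.min())
        cycle_amps = np.asarray(cycle_amps)
        if cycle_amps.size < 2:
            continue
        rel = np.abs(np.diff(cycle_amps)) / np.maximum(cycle_amps[:-1], 1e-300)
        if np.all(rel < stationarity_rel):
            return True, amp
    return False, best_amp


def classify_regime(field: FrozenField,
                    portrait: InstantaneousPortrait | None = None,
                    cycle_check: bool = False,
                    grid_points: int = 5) -> RegimeLabel:
    """Regime of a frozen circuit from its attractor census.

    One attractor: monostable; two or more: multistable; the damped-
    oscillatory variants apply when any attractor is a spiral sink.  With
    ``cycle_check`` on, an empty attractor set, or an unstable focus
    coexisting with the (always bounded) sigmoidal flow, triggers the
    limit-cycle detector, which takes precedence.  An empty portrait with
    the check off is unclassifiable and raises.
    """
    if portrait is None:
        states = find_steady_states(field, grid_points=grid_points)
        portrait = InstantaneousPortrait(time=np.nan,
                                         maternal_values=field.maternal_values,
                                         steady_states=states,
                                         bounds=np.stack(
                                             [np.zeros(field.circuit.n_genes),
                                              field.circuit.saturation()],
                                             axis=1),
                                         converged=bool(states))
    attractors = portrait.attractors
    near = any(s.near_bifurcation for s in portrait.steady_states)
    has_unstable_focus = any(s.label == UNSTABLE_FOCUS
                             for s in portrait.steady_states)
    if cycle_check and (not attractors or has_unstable_focus):
        cyc, _ = detect_limit_cycle(field)
        if cyc:
            return RegimeLabel(LIMIT_CYCLE, near)
    if not attractors:
        if not cycle_check:
            raise ValueError("portrait has no attractor; enable cycle_check "
                             "to classify")
        # bounded flow with neither attractor nor sustained cycle: treat as
        # monostable around the slowest transient (degenerate but possible
        # near criticality)
        return RegimeLabel(MONOSTABLE, True)
    damped = any(s.label == SPIRAL_SINK for s in attractors)
    if len(attractors) == 1:
        return RegimeLabel(MONOSTABLE_OSC if damped else MONOSTABLE, near)
    return RegimeLabel(MULTISTABLE_OSC if damped else MULTISTABLE, near)


@dataclass
class PhaseDiagram:
    """Grid of regime labels over one or two control axes."""

    axis_names: tuple
    axis_grids: tuple
    labels: np.ndarray  # object array of RegimeLabel, shape (n1,) or (n1, n2)
    context: dict = field(default_factory=dict)

    def __post_init__(self):
        grids = tuple(np.asarray(g, dtype=float) for g in self.axis_grids)
        for g in grids:
            if g.size > 1 and np.any(np.diff(g) <= 0):
                raise ValueError("axis grids must be strictly monotone")
        self.axis_grids = grids
        self.labels = np.asarray(self.labels, dtype=object)
        expected = tuple(g.size for g in grids)
        if self.labels.shape != expected:
            raise ValueError(f"labels shape {self.labels.shape} does not "
                             f"match axis grids {expected}")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        if self.labels.ndim == 1:
            for i, v in enumerate(self.axis_grids[0]):
                lab = self.labels[i]
                recs.append((v, lab.base, lab.near_bifurcation))
            return pd.DataFrame(recs, columns=[self.axis_names[0], "label",
                                               "near_bifurcation"])
        for i, v1 in enumerate(self.axis_grids[0]):
            for j, v2 in enumerate(self.axis_grids[1]):
                lab = self.labels[i, j]
                recs.append((v1, v2, lab.base, lab.near_bifurcation))
        return pd.DataFrame(recs, columns=[*self.axis_names, "label",
                                           "near_bifurcation"])


def _value_grid(value_range, step) -> np.ndarray:
    lo, hi = float(value_range[0]), float(value_range[1])
    step = abs(float(step))
    if step == 0:
        raise ValueError("step must be non-zero")
    if hi < lo:
        raise ValueError(f"empty sweep range {value_range}; pass (lo, hi) "
                         "with lo <= hi")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def maternal_phase_diagram(sub: GeneCircuit, maternal, positions,
                           varied: str = "Bcd",
                           value_range=(0.0, 30.0), step: float = 0.01,
                           t1_time: float | None = None,
                           grid_points: int = 5,
                           cycle_check: bool = False) -> PhaseDiagram:
    """Regime map over (position, level of one maternal input).

    For each cell, the non-varied maternal input is frozen at its T1
    value for that position, the varied one is set to the cell value, and
    the instantaneous portrait of the subcircuit is censused and
    classified.  Default sweep mirrors the published convention: Bcd from
    0 to 30 in steps of 0.01 (Cad sweeps use 60 to 120 in steps of 0.1).
    """
    k = sub.maternal_index(varied)
    if t1_time is None:
        from .circuit import StageSchedule
        t1_time = float(StageSchedule.c14a_only().class_times("midpoint")[0])
    positions = np.asarray(positions, dtype=float)
    grid = _value_grid(value_range, step)
    labels = np.empty((positions.size, grid.size), dtype=object)
    for i, pos in enumerate(positions):
        base_mv = maternal.evaluate(pos, t1_time)
        for j, v in enumerate(grid):
            mv = base_mv.copy()
            mv[k] = v
            field_ = FrozenField(sub, mv)
            labels[i, j] = classify_regime(field_, cycle_check=cycle_check,
                                           grid_points=grid_points)
    return PhaseDiagram(("position", varied), (positions, grid), labels,
                        context={"circuit": sub.name, "varied": varied,
                                 "t1_time": t1_time})


def weight_phase_diagram(sub: GeneCircuit, maternal, weights, ranges, steps,
                         positions=None, position: float | None = None,
                         t1_time: float | None = None, grid_points: int = 5,
                         cycle_check: bool = False) -> PhaseDiagram:
    """Regime map over one or two gap-gap regulatory weights.

    ``weights`` is a list of one or two (regulator, target) pairs; each
    grid cell overwrites those entries of W and classifies the frozen
    portrait with maternal inputs fixed at their T1 values.  One-weight
    sweeps may use position as the second axis (pass ``positions``);
    two-weight sweeps fix a single nucleus (pass ``position``).
    """
    weights = list(weights)
    for reg, tgt in weights:
        sub.gene_index(reg), sub.gene_index(tgt)
    if t1_time is None:
        from .circuit import StageSchedule
        t1_time = float(StageSchedule.c14a_only().class_times("midpoint")[0])
    if len(weights) == 1 and positions is not None:
        positions = np.asarray(positions, dtype=float)
        grid = _value_grid(ranges[0], steps[0])
        labels = np.empty((positions.size, grid.size), dtype=object)
        for i, pos in enumerate(positions):
            mv = maternal.evaluate(pos, t1_time)
            for j, v in enumerate(grid):
                circ = sub.with_weight(weights[0][0], weights[0][1], v)
                labels[i, j] = classify_regime(FrozenField(circ, mv),
                                               cycle_check=cycle_check,
                                               grid_points=grid_points)
        name = f"w({weights[0][0]}->{weights[0][1]})"
        return PhaseDiagram(("position", name), (positions, grid), labels,
                            context={"circuit": sub.name, "t1_time": t1_time})
    if position is None:
        raise ValueError("two-weight sweeps require a fixed nucleus position")
    mv = maternal.evaluate(float(position), t1_time)
    grids = [_value_grid(r, s) for r, s in zip(ranges, steps)]
    if len(weights) == 1:
        grid = grids[0]
        labels = np.empty(grid.size, dtype=object)
        for j, v in enumerate(grid):
            circ = sub.with_weight(weights[0][0], weights[0][1], v)
            labels[j] = classify_regime(FrozenField(circ, mv),
                                        cycle_check=cycle_check,
                                        grid_points=grid_points)
        name = f"w({weights[0][0]}->{weights[0][1]})"
        return PhaseDiagram((name,), (grid,), labels,
                            context={"circuit": sub.name, "position": position,
                                     "t1_time": t1_time})
    labels = np.empty((grids[0].size, grids[1].size), dtype=object)
    for i, v1 in enumerate(grids[0]):
        for j, v2 in enumerate(grids[1]):
            circ = sub.with_weight(weights[0][0], weights[0][1], v1)
            circ = circ.with_weight(weights[1][0], weights[1][1], v2)
            labels[i, j] = classify_regime(FrozenField(circ, mv),
                                           cycle_check=cycle_check,
                                           grid_points=grid_points)
    names = tuple(f"w({r}->{t})" for r, t in weights)
    return PhaseDiagram(names, tuple(grids), labels,
                        context={"circuit": sub.name, "position": position,
                                 "t1_time": t1_time})


def boundary_position(diagram: PhaseDiagram, axis: int = 0):
    """Bifurcation boundary along one axis of a two-regime diagram.

    Scans the axis for the single transition between multistable and
    monostable labels and reports the midpoint between the last cell of
    one regime and the first of the other; ``None`` if the axis is
    uniform.  For 2-D diagrams the other axis must be of length 1.
    """
    labels = diagram.labels
    if labels.ndim == 2:
        if labels.shape[1 - axis] != 1:
            raise ValueError("boundary_position needs a single row/column")
        labels = labels[:, 0] if axis == 0 else labels[0, :]
    grid = diagram.axis_grids[axis]
    multi = np.array([lab.multistable for lab in labels])
    if multi.all() or not multi.any():
        return None
    flips = np.flatnonzero(np.diff(multi.astype(int)) != 0)
    i = flips[0]
    return 0.5 * (grid[i] + grid[i + 1])


def simplified_acdc(positive_feedback_strength: float,
                    negative_feedback_strength: float,
                    production: float = 10.0, decay: float = 0.1,
                    basal: float = 2.5) -> GeneCircuit:
    """Minimal three-gene AC/DC circuit driven by two control parameters.

    All genes share one production rate, one decay rate and one constant
    basal activation; there is no auto-activation and no maternal input.
    The negative-feedback control ``n`` sets the three repressions of the
    cycle g1 -| g2 -| g3 -| g1; the positive-feedback control ``p`` adds
    mutual repression between g1 and g2 (the double-negative pair), so
    the shared g1 -| g2 edge carries ``-(n + p)``.  With ``p = 0`` and
    large ``n`` the circuit is a repressilator; with ``n = 0`` and large
    ``p`` it is a toggle switch.
    """
    p = float(positive_feedback_strength)
    n = float(negative_feedback_strength)
    if p < 0 or n < 0:
        raise ValueError("control parameters must be >= 0")
    W = np.zeros((3, 3))
    W[0, 1] = -(n + p)
    W[1, 0] = -p
    W[1, 2] = -n
    W[2, 0] = -n
    return GeneCircuit(
        genes=("g1", "g2", "g3"), maternal=(),
        production=np.full(3, production), decay=np.full(3, decay),
        gap_weights=W, maternal_weights=np.zeros((0, 3)),
        basal=np.full(3, basal),
        name=f"acdc-simplified(p={p:g},n={n:g})",
    )


def control_parameter_map(positive_grid, negative_grid, production: float = 10.0,
                          decay: float = 0.1, basal: float = 2.5,
                          grid_points: int = 5) -> PhaseDiagram:
    """Regime map over the two composite AC/DC control parameters.

    Each cell builds the simplified circuit for (p, n) and classifies it
    with the limit-cycle check enabled, so all five regimes can appear.
    """
    pg = np.asarray(positive_grid, dtype=float)
    ng = np.asarray(negative_grid, dtype=float)
    labels = np.empty((pg.size, ng.size), dtype=object)
    for i, p in enumerate(pg):
        for j, n in enumerate(ng):
            circ = simplified_acdc(p, n, production, decay, basal)
            field_ = FrozenField(circ, np.zeros(0))
            labels[i, j] = classify_regime(field_, cycle_check=True,
                                           grid_points=grid_points)
    return PhaseDiagram(("positive_feedback", "negative_feedback"),
                        (pg, ng), labels,
                        context={"production": production, "decay": decay,
                                 "basal": basal})
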