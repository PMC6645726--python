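"""Connectionist gene-circuit model of the gap gene network.

A circuit describes a set of zygotic gap genes (hb, Kr, kni, gt in the
*Drosophila* trunk) regulated by each other and by external maternal
gradients (Bcd, Cad).  Protein concentration ``g_a`` in a nucleus evolves
as

    dg_a/dt = R_a * phi(u_a) - lambda_a * g_a
    u_a     = sum_b w_ba g_b + sum_m e_ma g_m + h_a

with the sigmoid regulation-expression function
``phi(u) = (u / sqrt(u^2 + 1) + 1) / 2``.  During mitosis production is
switched off (``R_a = 0``) while decay continues; nuclear divisions are
discrete, instantaneous events at the end of mitosis.  Diffusion is
omitted, so each nucleus is an independent low-dimensional dynamical
system driven by its local, time-varying maternal inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GeneCircuit",
    "StageSchedule",
    "Trajectory",
    "regulation_expression",
    "regulation_expression_prime",
    "total_input",
    "total_input_vector",
    "derivatives",
    "simulate_nucleus",
    "simulate_row",
]

INTERPHASE = "interphase"
MITOSIS = "mitosis"


def regulation_expression(u):
    """Sigmoid regulation-expression function ``phi``.

    Maps total regulatory input ``u`` (dimensionless) to fractional
    promoter activity in the open interval (0, 1):
    ``phi(u) = (u / sqrt(u**2 + 1) + 1) / 2``.

    Accepts scalars or arrays; raises ``ValueError`` on non-finite input.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("regulation_expression: input u must be finite")
    out = 0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)
    return out if out.ndim else float(out)


def regulation_expression_prime(u):
    """Derivative ``phi'(u) = 1 / (2 (u**2 + 1)**(3/2))``; ``phi'(0) = 0.5``."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("regulation_expression_prime: input u must be finite")
    out = 0.5 / np.power(u * u + 1.0, 1.5)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GeneCircuit:
    """Full parameterisation of a connectionist gene circuit.

    Parameters
    ----------
    genes
        Ordered gap-gene identifiers (the set G).
    maternal
        Ordered maternal regulator identifiers (the set M).
    production
        Per-gene maximum production rate ``R_a`` (concentration/min, >= 0).
    decay
        Per-gene decay rate ``lambda_a`` (1/min, > 0).
    gap_weights
        Matrix ``W`` of shape (len(G), len(G)); entry ``W[b, a]`` is the
        regulatory effect of gap regulator *b* on target *a*
        (regulator-by-target orientation).
    maternal_weights
        Matrix ``E`` of shape (len(M), len(G)); entry ``E[m, a]`` is the
        effect of maternal regulator *m* on target *a*.
    basal
        Per-gene threshold ``h_a`` (dimensionless input units).
    """

    genes: tuple
    maternal: tuple
    production: np.ndarray
    decay: np.ndarray
    gap_weights: np.ndarray
    maternal_weights: np.ndarray
    basal: np.ndarray
    name: str = "circuit"

    def __post_init__(self):
        genes = tuple(self.genes)
        mats = tuple(self.maternal)
        if len(set(genes)) != len(genes):
            raise ValueError("gene identifiers must be unique")
        if len(set(mats)) != len(mats):
            raise ValueError("maternal identifiers must be unique")
        n, m = len(genes), len(mats)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "maternal", mats)
        for attr, shape in (
            ("production", (n,)),
            ("decay", (n,)),
            ("basal", (n,)),
            ("gap_weights", (n, n)),
            ("maternal_weights", (m, n)),
        ):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"{attr} has shape {arr.shape}, expected {shape} for "
                    f"{n} genes / {m} maternal regulators"
                )
            object.__setattr__(self, attr, arr)
        if np.any(self.production < 0):
            raise ValueError("production rates must be >= 0")
        if np.any(self.decay <= 0):
            raise ValueError("decay rates must be strictly positive")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}; circuit genes: {self.genes}")

    def maternal_index(self, m: str) -> int:
        try:
            return self.maternal.index(m)
        except ValueError:
            raise KeyError(f"unknown maternal regulator {m!r}")

    def saturation(self) -> np.ndarray:
        """Per-gene saturation level ``R_a / lambda_a`` (upper bound on
        equilibrium concentration since ``phi < 1``)."""
        return self.production / self.decay

    def with_weight(self, regulator: str, target: str, value: float) -> "GeneCircuit":
        """Return a copy with one gap-gap weight ``w_{regulator,target}``
        overwritten."""
        W = self.gap_weights.copy()
        W[self.gene_index(regulator), self.gene_index(target)] = value
        return replace(self, gap_weights=W)


@dataclass(frozen=True)
class StageSchedule:
    """Timing of the hybrid cleavage-cycle scheme.

    Time is measured in minutes with ``t0`` at the onset of the first
    simulated phase.  The default schedule covers C13 interphase, C13
    mitosis (production off), an instantaneous nuclear division at the end
    of mitosis, and the C14A interphase, which is subdivided into eight
    time classes T1-T8 of equal duration.  A C14A-only schedule (used for
    subcircuit analysis, which involves no mitosis or division) is
    obtained with :meth:`c14a_only`.
    """

    t0: float = 0.0
    c13_interphase: float = 16.0
    c13_mitosis: float = 5.0
    c14a_duration: float = 50.0
    n_classes: int = 8

    def __post_init__(self):
        if self.c13_interphase < 0 or self.c13_mitosis < 0:
            raise ValueError("phase durations must be >= 0")
        if self.c14a_duration <= 0:
            raise ValueError("C14A duration must be positive")
        if self.n_classes < 1:
            raise ValueError("need at least one C14A time class")

    @classmethod
    def c14a_only(cls, t_start: float = 21.0, duration: float = 50.0,
                  n_classes: int = 8) -> "StageSchedule":
        """Schedule covering only the C14A interphase (no mitosis/division)."""
        return cls(t0=t_start, c13_interphase=0.0, c13_mitosis=0.0,
                   c14a_duration=duration, n_classes=n_classes)

    @property
    def mitosis_start(self) -> float:
        return self.t0 + self.c13_interphase

    @property
    def division_time(self) -> float:
        """Instantaneous division at the end of C13 mitosis (equals the
        C14A onset)."""
        return self.t0 + self.c13_interphase + self.c13_mitosis

    @property
    def c14a_start(self) -> float:
        return self.division_time

    @property
    def t_end(self) -> float:
        return self.c14a_start + self.c14a_duration

    @property
    def has_division(self) -> bool:
        return self.c13_interphase > 0 or self.c13_mitosis > 0

    @property
    def class_duration(self) -> float:
        return self.c14a_duration / self.n_classes

    def phases(self):
        """Contiguous (start, end, phase) segments covering the span."""
        segs = []
        if self.c13_interphase > 0:
            segs.append((self.t0, self.mitosis_start, INTERPHASE))
        if self.c13_mitosis > 0:
            segs.append((self.mitosis_start, self.division_time, MITOSIS))
        segs.append((self.c14a_start, self.t_end, INTERPHASE))
        return segs

    def class_bounds(self) -> np.ndarray:
        """Boundaries of the T1..Tn time classes (n_classes + 1 values)."""
        return self.c14a_start + self.class_duration * np.arange(self.n_classes + 1)

    def class_times(self, anchor: str = "midpoint") -> np.ndarray:
        """Representative time of each class: 'start', 'midpoint' or 'end'."""
        b = self.class_bounds()
        if anchor == "start":
            return b[:-1]
        if anchor == "end":
            return b[1:]
        if anchor == "midpoint":
            return 0.5 * (b[:-1] + b[1:])
        raise ValueError(f"unknown anchor {anchor!r}")

    def class_labels(self):
        return tuple(f"T{i + 1}" for i in range(self.n_classes))

    def phase_at(self, t: float) -> str:
        if self.c13_interphase > 0 and self.t0 <= t < self.mitosis_start:
            return INTERPHASE
        if self.c13_mitosis > 0 and self.mitosis_start <= t < self.division_time:
            return MITOSIS
        return INTERPHASE


@dataclass
class Trajectory:
    """Time-indexed gap-protein state of one nucleus.

    ``states`` has one row per sample time and one column per gene in
    ``genes``; ``position`` is the nucleus location in % A-P (anterior at
    0%).
    """

    position: float
    times: np.ndarray
    states: np.ndarray
    genes: tuple

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(self.genes)):
            raise ValueError("states shape must be (n_times, n_genes)")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def gene_series(self, gene: str) -> np.ndarray:
        return self.states[:, self.genes.index(gene)]

    def at_times(self, times) -> np.ndarray:
        """States at the requested subset of sample times (exact match)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.times, times)
        idx = np.clip(idx, 0, self.times.size - 1)
        if not np.allclose(self.times[idx], times, rtol=0, atol=1e-9):
            raise ValueError("requested times are not sample times of this trajectory")
        return self.states[idx]


def total_input_vector(state, maternal_values, circuit: GeneCircuit) -> np.ndarray:
    """Total regulatory input ``u_a`` for every target gene.

    ``u = state @ W + maternal_values @ E + h`` with the regulator-by-
    target weight orientation.
    """
    state = np.asarray(state, dtype=float)
    mat = np.asarray(maternal_values, dtype=float)
    if state.shape[-1] != circuit.n_genes:
        raise ValueError(
            f"gap state vector has length {state.shape[-1]}, expected "
            f"{circuit.n_genes} (genes {circuit.genes})"
        )
    if mat.shape[-1] != len(circuit.maternal):
        raise ValueError(
            f"maternal vector has length {mat.shape[-1]}, expected "
            f"{len(circuit.maternal)} (maternal {circuit.maternal})"
        )
    return state @ circuit.gap_weights + mat @ circuit.maternal_weights + circuit.basal


def total_input(state, maternal_values, circuit: GeneCircuit, target: str) -> float:
    """Total regulatory input ``u_a`` for a single target gene."""
    u = total_input_vector(state, maternal_values, circuit)
    return float(u[circuit.gene_index(target)])


def derivatives(t, state, circuit: GeneCircuit, maternal, position: float,
                phase: str = INTERPHASE) -> np.ndarray:
    """Right-hand side of the circuit ODE at time ``t``.

    During interphase: ``R_a phi(u_a) - lambda_a g_a``; during mitosis the
    production term is dropped (``R_a`` set to zero) and only decay acts.
    ``maternal`` is a :class:`~gapdyn.profiles.MaternalProfiles` evaluator.
    """
    if phase not in (INTERPHASE, MITOSIS):
        raise ValueError(f"unknown phase {phase!r}")
    state = np.asarray(state, dtype=float)
    if phase == MITOSIS:
        return -circuit.decay * state
    mat = maternal.evaluate(position, t)
    u = total_input_vector(state, mat, circuit)
    return circuit.production * regulation_expression(u) - circuit.decay * state


_SOLVER_OPTS = dict(method="LSODA", rtol=1e-8, atol=1e-10)


def _integrate_segment(circuit, maternal, position, y0, t_start, t_end, phase,
                       t_eval, solver_opts):
    def rhs(t, y):
        return derivatives(t, y, circuit, maternal, position, phase)

    sol = solve_ivp(rhs, (t_start, t_end), y0, t_eval=t_eval,
                    dense_output=False, **solver_opts)
    if not sol.success:
        last = sol.t[-1] if sol.t.size else t_start
        raise RuntimeError(
            f"ODE solver failed in {phase} segment at t={last:.4f} min "
            f"(position {position}%): {sol.message}"
        )
    return sol


def simulate_nucleus(circuit: GeneCircuit, maternal, position: float,
                     initial_state, schedule: StageSchedule,
                     output_times=None, solver_opts=None) -> Trajectory:
    """Integrate the hybrid model for a single nucleus.

    The ODE is integrated phase by phase with exact stops at phase
    boundaries, so the mitotic production switch is never smeared by the
    adaptive step controller.  The instantaneous division event leaves the
    state of the nucleus unchanged (daughters inherit the mother's
    concentrations; see :func:`simulate_row` for the spatial bookkeeping).
    """
    opts = dict(_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    if output_times is None:
        output_times = schedule.class_times("midpoint")
    output_times = np.asarray(output_times, dtype=float)
    if output_times.size and (output_times[0] < schedule.t0 - 1e-9
                              or output_times[-1] > schedule.t_end + 1e-9):
        raise ValueError("output_times must lie within the schedule span")

    y = np.asarray(initial_state, dtype=float).copy()
    if y.shape != (circuit.n_genes,):
        raise ValueError("initial_state length must match circuit gene count")
    samples_t, samples_y = [], []
    if output_times.size and np.isclose(output_times[0], schedule.t0):
        samples_t.append(float(schedule.t0))
        samples_y.append(y.copy())
    for seg_start, seg_end, phase in schedule.phases():
        mask = (output_times > seg_start + 1e-12) & (output_times <= seg_end + 1e-12)
        t_eval = np.clip(output_times[mask], seg_start, seg_end)
        want_end = not (t_eval.size and np.isclose(t_eval[-1], seg_end))
        eval_pts = np.concatenate([t_eval, [seg_end]]) if want_end else t_eval
        sol = _integrate_segment(circuit, maternal, position, y, seg_start,
                                 seg_end, phase, eval_pts, opts)
        y = sol.y[:, -1].copy()
        n_out = t_eval.size
        for k in range(n_out):
            samples_t.append(float(sol.t[k]))
            samples_y.append(sol.y[:, k].copy())
    times = np.array(samples_t)
    states = np.array(samples_y) if samples_y else np.empty((0, circuit.n_genes))
    return Trajectory(position=position, times=times, states=states,
                      genes=circuit.genes)


def daughter_positions(mother_position: float) -> tuple:
    """Positions of the two daughter nuclei after division.

    Daughters sit at +/- 0.5% of the mother on the 2%-spaced C13 lattice
    and are rounded (half up) to the 1% C14A lattice: a mother at an odd
    percent p yields daughters at p and p + 1.
    """
    lo = float(np.floor(mother_position - 0.5 + 0.5))
    hi = float(np.floor(mother_position + 0.5 + 0.5))
    return (lo, hi)


def simulate_row(circuit: GeneCircuit, maternal, positions,
                 initial_states, schedule: StageSchedule,
                 output_times=None, solver_opts=None):
    """Simulate a one-dimensional row of independent nuclei.

    Without diffusion every nucleus is independent; this is a literal loop
    over :func:`simulate_nucleus`, so the result is identical to
    per-nucleus simulation.  If the schedule includes the C13 division,
    ``positions`` are the C13 mother nuclei (2% spacing); each mother is
    replaced at the division event by two daughters on the 1% C14A lattice
    that inherit her concentrations.  Daughters falling outside the
    maternal profiles' position support are dropped (their inputs are
    undefined there).

    Returns one :class:`Trajectory` per (final) nucleus, sorted by
    position; pre-division samples of a daughter repeat the mother's
    trajectory.
    """
    positions = [float(p) for p in positions]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate nucleus positions")
    initial_states = np.asarray(initial_states, dtype=float)
    if initial_states.ndim == 1:
        initial_states = np.tile(initial_states, (len(positions), 1))
    if initial_states.shape != (len(positions), circuit.n_genes):
        raise ValueError("need one initial state per nucleus")
    if output_times is None:
        output_times = schedule.class_times("midpoint")
    output_times = np.asarray(output_times, dtype=float)

    if not schedule.has_division:
        trajs = [
            simulate_nucleus(circuit, maternal, p, s, schedule, output_times,
                             solver_opts)
            for p, s in zip(positions, initial_states)
        ]
        return sorted(trajs, key=lambda tr: tr.position)

    t_div = schedule.division_time
    pre_times = output_times[output_times <= t_div + 1e-12]
    post_times = output_times[output_times > t_div + 1e-12]
    pre_schedule = StageSchedule(t0=schedule.t0,
                                 c13_interphase=schedule.c13_interphase,
                                 c13_mitosis=schedule.c13_mitosis,
                                 c14a_duration=1e-9,
                                 n_classes=1)
    c14a_schedule = StageSchedule.c14a_only(t_start=t_div,
                                            duration=schedule.c14a_duration,
                                            n_classes=schedule.n_classes)
    pos_lo, pos_hi = maternal.position_range()
    trajs = []
    for p, s in zip(positions, initial_states):
        req = np.unique(np.concatenate([pre_times, [t_div]]))
        mother = simulate_nucleus(circuit, maternal, p, s, pre_schedule, req,
                                  solver_opts)
        state_at_div = mother.states[-1]
        div_sampled = pre_times.size and np.isclose(pre_times[-1], t_div)
        mother_samples_t = mother.times if div_sampled else mother.times[:-1]
        mother_samples_y = mother.states[: mother_samples_t.size]
        for dpos in daughter_positions(p):
            if dpos < pos_lo - 1e-9 or dpos > pos_hi + 1e-9:
                continue
            post = simulate_nucleus(circuit, maternal, dpos, state_at_div,
                                    c14a_schedule, post_times, solver_opts)
            times = np.concatenate([mother_samples_t, post.times])
            states = np.vstack([mother_samples_y, post.states]) \
                if mother_samples_t.size else post.states
            trajs.append(Trajectory(position=dpos, times=times, states=states,
                                    genes=circuit.genes))
    trajs.sort(key=lambda tr: tr.position)
    return trajs
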