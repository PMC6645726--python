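"""Instantaneous (frozen-time) phase-space analysis.

The gap circuit is non-autonomous: its maternal inputs vary in time.  An
instantaneous phase portrait freezes the maternal concentrations at one
time point, making the system autonomous, and records all steady states
of the frozen vector field together with their Jacobian eigenvalues and
a stability class (point attractor, spiral sink, saddle, unstable
node/focus).  Steady states are found by Newton-Raphson iteration from a
regular grid of seed points spanning each gene's attainable range
[0, R_a/lambda_a] (phi < 1 bounds every equilibrium), plus optional
user-supplied seeds such as trajectory endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import (GeneCircuit, regulation_expression,
                      regulation_expression_prime, total_input_vector)

__all__ = [
    "SteadyState",
    "InstantaneousPortrait",
    "FrozenField",
    "frozen_field",
    "jacobian",
    "find_steady_states",
    "classify_steady_state",
    "portrait_series",
    "POINT_ATTRACTOR",
    "SPIRAL_SINK",
    "SADDLE",
    "UNSTABLE_NODE",
    "UNSTABLE_FOCUS",
]

POINT_ATTRACTOR = "point attractor"
SPIRAL_SINK = "spiral sink"
SADDLE = "saddle"
UNSTABLE_NODE = "unstable node"
UNSTABLE_FOCUS = "unstable focus"

ATTRACTOR_LABELS = (POINT_ATTRACTOR, SPIRAL_SINK)

REAL_TOL = 1e-6
IMAG_TOL = 1e-9
ROOT_TOL = 1e-9
DEDUP_REL = 1e-4


class FrozenField:
    """Autonomous vector field of a circuit with maternal inputs frozen."""

    def __init__(self, circuit: GeneCircuit, maternal_values):
        maternal_values = np.asarray(maternal_values, dtype=float)
        if maternal_values.shape != (len(circuit.maternal),):
            raise ValueError("maternal_values length must match circuit "
                             "maternal regulators")
        if not np.all(np.isfinite(maternal_values)) or np.any(maternal_values < 0):
            raise ValueError("frozen maternal values must be finite and >= 0")
        self.circuit = circuit
        self.maternal_values = maternal_values

    def __call__(self, g) -> np.ndarray:
        """dg/dt at state g (supports a trailing gene axis for batches)."""
        g = np.asarray(g, dtype=float)
        c = self.circuit
        u = total_input_vector(g, np.broadcast_to(self.maternal_values,
                                                  g.shape[:-1] + (len(c.maternal),)),
                               c)
        return c.production * regulation_expression(u) - c.decay * g

    def jacobian(self, g) -> np.ndarray:
        """J_ab = d(dg_a/dt)/dg_b = R_a phi'(u_a) w_ba - lambda_a delta_ab.

        Accepts a single point (n,) or a batch (..., n); the Jacobian is
        returned with matching leading axes.
        """
        g = np.asarray(g, dtype=float)
        c = self.circuit
        u = total_input_vector(
            g, np.broadcast_to(self.maternal_values,
                               g.shape[:-1] + (len(c.maternal),)), c)
        dphi = regulation_expression_prime(u)
        # row a (equation), column b (state): R_a phi'(u_a) W[b, a]
        J = (c.production * np.atleast_1d(dphi))[..., :, None] * c.gap_weights.T
        J = J - np.diag(c.decay)
        return J if g.ndim > 1 else J.reshape(c.n_genes, c.n_genes)


def frozen_field(circuit: GeneCircuit, maternal_values) -> FrozenField:
    """Autonomous vector field with maternal concentrations held constant."""
    return FrozenField(circuit, maternal_values)


def jacobian(circuit: GeneCircuit, maternal_values, point) -> np.ndarray:
    """Jacobian of the frozen field at a point (analytic closed form)."""
    return FrozenField(circuit, maternal_values).jacobian(point)


def classify_steady_state(eigenvalues, real_tol: float = REAL_TOL,
                          imag_tol: float = IMAG_TOL):
    """Stability class from Jacobian eigenvalues.

    Returns ``(label, near_bifurcation)``.  All real parts negative:
    point attractor, or spiral sink if any eigenvalue has a non-trivial
    imaginary part.  Mixed signs: saddle.  All positive: unstable
    node/focus by the same imaginary criterion.  Any real part within
    ``real_tol`` of zero sets the near-bifurcation flag (the state sits
    close to criticality and its class is not trustworthy).
    """
    ev = np.asarray(eigenvalues, dtype=complex)
    if ev.size == 0:
        raise ValueError("eigenvalue list must be non-empty")
    re, im = ev.real, np.abs(ev.imag)
    near = bool(np.any(np.abs(re) <= real_tol))
    oscillatory = bool(np.any(im > imag_tol))
    if np.all(re < -real_tol):
        label = SPIRAL_SINK if oscillatory else POINT_ATTRACTOR
    elif np.all(re > real_tol):
        label = UNSTABLE_FOCUS if oscillatory else UNSTABLE_NODE
    else:
        label = SADDLE
    return label, near


@dataclass
class SteadyState:
    """A root of the frozen field with its linear stability analysis."""

    location: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    label: str
    near_bifurcation: bool = False

    @property
    def is_attractor(self) -> bool:
        return self.label in ATTRACTOR_LABELS


@dataclass
class InstantaneousPortrait:
    """All steady states of the frozen system at one time point."""

    time: float
    maternal_values: np.ndarray
    steady_states: list
    bounds: np.ndarray
    converged: bool = True

    @property
    def attractors(self):
        return [s for s in self.steady_states if s.is_attractor]

    @property
    def saddles(self):
        return [s for s in self.steady_states if s.label == SADDLE]

    def n_attractors(self) -> int:
        return len(self.attractors)


def _newton_batch(field: FrozenField, seeds: np.ndarray, upper: np.ndarray,
                  max_iter: int = 100, tol: float = 1e-12) -> np.ndarray:
    """Run Newton-Raphson from every seed simultaneously.

    Returns the (n_seeds, n) array of final iterates; non-convergent or
    diverged seeds end as NaN rows.  Vectorising over seeds keeps large
    phase-diagram sweeps tractable.
    """
    x = np.array(seeds, dtype=float)
    active = np.ones(x.shape[0], dtype=bool)
    blow_up = 100.0 * upper.max() + 1e3
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        f = field(x[idx])
        done = np.max(np.abs(f), axis=-1) < tol
        active[idx[done]] = False
        idx = idx[~done]
        if idx.size == 0:
            continue
        f = f[~done]
        J = field.jacobian(x[idx])
        step = np.full_like(f, np.nan)
        ok = np.abs(np.linalg.det(J)) > 1e-300
        if ok.any():
            step[ok] = np.linalg.solve(J[ok], f[ok][..., None])[..., 0]
        xa = x[idx] - step
        bad = (~np.all(np.isfinite(xa), axis=-1)
               | (np.max(np.abs(xa), axis=-1) > blow_up))
        xa[bad] = np.nan
        x[idx] = xa
        active[idx[bad]] = False
    return x


def find_steady_states(field: FrozenField, bounds=None, extra_seeds=None,
                       grid_points: int = 5, root_tol: float = ROOT_TOL,
                       dedup_rel: float = DEDUP_REL):
    """Newton-Raphson census of the frozen field's steady states.

    Seeds a regular ``grid_points``-per-dimension grid over
    ``[0, R_a/lambda_a]`` (plus any ``extra_seeds``), iterates Newton's
    method with the analytic Jacobian, keeps converged roots with
    residual max-norm below ``root_tol``, discards roots outside the
    physically meaningful box (any coordinate < -1e-6 or
    > 1.5 R_a/lambda_a), and deduplicates at a per-axis tolerance of
    ``dedup_rel * R_a/lambda_a``.  Returns classified
    :class:`SteadyState` objects sorted by location; the list is empty
    (and flagged by the caller) if no seed converges.
    """
    c = field.circuit
    upper = c.saturation()
    if bounds is None:
        bounds = np.stack([np.zeros(c.n_genes), upper], axis=1)
    bounds = np.asarray(bounds, dtype=float)
    axes = [np.linspace(bounds[i, 0], bounds[i, 1], grid_points)
            for i in range(c.n_genes)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, c.n_genes)
    seeds = mesh
    if extra_seeds is not None:
        extra = np.atleast_2d(np.asarray(extra_seeds, dtype=float))
        seeds = np.vstack([mesh, extra])

    dedup = dedup_rel * upper
    finals = _newton_batch(field, seeds, upper)
    roots = []
    for x in finals:
        if not np.all(np.isfinite(x)):
            continue
        if np.max(np.abs(field(x))) >= root_tol:
            continue
        if np.any(x < -1e-6) or np.any(x > 1.5 * upper):
            continue
        if any(np.all(np.abs(x - r) <= dedup) for r in roots):
            continue
        roots.append(x)

    states = []
    for x in sorted(roots, key=lambda r: tuple(r)):
        ev = np.linalg.eigvals(field.jacobian(x))
        label, near = classify_steady_state(ev)
        states.append(SteadyState(location=x,
                                  residual=float(np.max(np.abs(field(x)))),
                                  eigenvalues=ev, label=label,
                                  near_bifurcation=near))
    return states


def basin_census(field: FrozenField, grid_per_dim: int = 20,
                 horizon: float | None = None, dedup_rel: float = 1e-3,
                 rtol: float = 1e-8, atol: float = 1e-10):
    """Brute-force attractor census by dense forward simulation.

    Starts one trajectory from every point of a ``grid_per_dim``-per-axis
    grid over [0, R_a/lambda_a], integrates all of them as one stacked
    (non-stiff) system over ``horizon`` (default ``60 / min(lambda)``),
    and clusters the endpoints at a per-axis tolerance of
    ``dedup_rel * R_a/lambda_a``.  Returns the list of distinct
    convergence limits (attractor locations).  Entirely independent of
    the Newton-Raphson census, so it can serve as its oracle.
    """
    from scipy.integrate import solve_ivp

    c = field.circuit
    upper = c.saturation()
    if horizon is None:
        horizon = 60.0 / float(c.decay.min())
    axes = [np.linspace(0.0, u, grid_per_dim) for u in upper]
    X0 = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, c.n_genes)

    def rhs(t, y):
        return field(y.reshape(-1, c.n_genes)).ravel()

    sol = solve_ivp(rhs, (0.0, horizon), X0.ravel(), method="RK45",
                    t_eval=[horizon], rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"basin census integration failed: {sol.message}")
    ends = sol.y[:, -1].reshape(-1, c.n_genes)
    tol = dedup_rel * upper
    clusters = []
    counts = []
    for x in ends:
        for i, r in enumerate(clusters):
            if np.all(np.abs(x - r) <= 10 * tol):
                clusters[i] = (counts[i] * r + x) / (counts[i] + 1)
                counts[i] += 1
                break
        else:
            clusters.append(x.copy())
            counts.append(1)
    return [np.asarray(r) for r in clusters]


def portrait_series(circuit: GeneCircuit, maternal, position: float,
                    times=None, schedule=None, extra_seeds=None,
                    grid_points: int = 5):
    """Instantaneous phase portraits at a sequence of time points.

    Maternal inputs are frozen at each requested time (default: the
    T1-T8 class midpoints of the standard C14A window) and the steady
    states of the resulting autonomous system are censused and
    classified independently per time point.
    """
    if times is None:
        from .circuit import StageSchedule
        schedule = schedule or StageSchedule.c14a_only()
        times = schedule.class_times("midpoint")
    portraits = []
    for t in np.asarray(times, dtype=float):
        mv = maternal.evaluate(position, t)
        field = FrozenField(circuit, mv)
        states = find_steady_states(field, extra_seeds=extra_seeds,
                                    grid_points=grid_points)
        portraits.append(InstantaneousPortrait(
            time=float(t), maternal_values=mv, steady_states=states,
            bounds=np.stack([np.zeros(circuit.n_genes), circuit.saturation()],
                            axis=1),
            converged=bool(states)))
    return portraits
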