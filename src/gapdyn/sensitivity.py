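"""Node-removal sensitivity screen.

A gap gene is dispensable in a nucleus if erasing its node (the gene and
every interaction it participates in) from the circuit at the onset of
C14A leaves the developmental trajectory essentially unchanged.  The
screen quantifies this with a scaled Euclidean distance between the full
and the node-removed trajectory, sampled at the eight C14A time classes;
contiguous runs of near-zero distance delimit each gene's region of
dispensability, which in turn reveal the network's dynamical modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import GeneCircuit, StageSchedule, Trajectory, simulate_nucleus

__all__ = [
    "SensitivityProfile",
    "remove_node",
    "node_sensitivity",
    "sensitivity_scan",
    "insensitive_regions",
]


def remove_node(circuit: GeneCircuit, gene: str) -> GeneCircuit:
    """Circuit with one gap gene and all its interactions erased.

    Removes the gene's row and column of W, its maternal-weight column,
    and its entries of R, lambda and h; everything else is untouched.
    """
    k = circuit.gene_index(gene)
    keep = [i for i in range(circuit.n_genes) if i != k]
    return GeneCircuit(
        genes=tuple(g for g in circuit.genes if g != gene),
        maternal=circuit.maternal,
        production=circuit.production[keep],
        decay=circuit.decay[keep],
        gap_weights=circuit.gap_weights[np.ix_(keep, keep)],
        maternal_weights=circuit.maternal_weights[:, keep],
        basal=circuit.basal[keep],
        name=f"{circuit.name}-minus-{gene}",
    )


def _expand_reduced(reduced: Trajectory, genes: tuple) -> np.ndarray:
    """States of the reduced trajectory on the full gene panel, with the
    removed gene's concentration entered as zero."""
    out = np.zeros((reduced.times.size, len(genes)))
    for j, g in enumerate(genes):
        if g in reduced.genes:
            out[:, j] = reduced.gene_series(g)
    return out


def node_sensitivity(full_traj: Trajectory, reduced_traj: Trajectory) -> float:
    """Distance d between a full and a node-removed trajectory.

    ``d = sqrt( sum_i sum_a (g_a^full(T_i) - g_a^reduced(T_i))^2 / n )``
    where i runs over the n compared time classes and a over the full
    gene panel; the removed gene contributes its full-model concentration
    (its reduced-trajectory value is zero by convention).  With this
    normalisation a constant offset delta in one gene gives d = delta.
    """
    if full_traj.times.size != reduced_traj.times.size or not np.allclose(
            full_traj.times, reduced_traj.times, rtol=0, atol=1e-9):
        raise ValueError("trajectories must be sampled at the same time classes")
    a = full_traj.states
    b = _expand_reduced(reduced_traj, full_traj.genes) \
        if reduced_traj.genes != full_traj.genes else reduced_traj.states
    n = full_traj.times.size
    return float(np.sqrt(np.sum((a - b) ** 2) / n))


@dataclass
class SensitivityProfile:
    """Grid of node-sensitivity values d over (position, removed gene)."""

    positions: np.ndarray
    genes: tuple
    d: np.ndarray  # shape (n_positions, n_genes)
    circuit_name: str = ""
    threshold: float | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (self.positions.size, len(self.genes)):
            raise ValueError("d must have shape (n_positions, n_genes)")
        if np.any(self.d < 0):
            raise ValueError("node sensitivity d must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        recs = [
            (p, g, self.d[i, j])
            for i, p in enumerate(self.positions)
            for j, g in enumerate(self.genes)
        ]
        return pd.DataFrame(recs, columns=["position", "removed_gene", "d"])


def sensitivity_scan(circuit: GeneCircuit, maternal, initial_states,
                     positions, schedule: StageSchedule | None = None,
                     solver_opts=None) -> SensitivityProfile:
    """Node-removal screen over C14A for every position and gene.

    ``initial_states`` are the full-model gap concentrations at C14A
    onset (time class T1), one row per position.  For each nucleus the
    full circuit and every single-gene-removed circuit are integrated
    over C14A only (no mitosis or division) and compared at the T1-T8
    class midpoints.
    """
    schedule = schedule or StageSchedule.c14a_only()
    if schedule.has_division:
        raise ValueError("sensitivity_scan runs over C14A only; use a "
                         "division-free schedule")
    positions = np.asarray(positions, dtype=float)
    initial_states = np.asarray(initial_states, dtype=float)
    if initial_states.shape != (positions.size, circuit.n_genes):
        raise ValueError("need one T1 initial state per position")
    times = schedule.class_times("midpoint")
    reduced_circuits = {g: remove_node(circuit, g) for g in circuit.genes}
    d = np.zeros((positions.size, circuit.n_genes))
    for i, pos in enumerate(positions):
        full = simulate_nucleus(circuit, maternal, pos, initial_states[i],
                                schedule, times, solver_opts)
        for j, gene in enumerate(circuit.genes):
            sub = reduced_circuits[gene]
            keep = [circuit.genes.index(g) for g in sub.genes]
            try:
                red = simulate_nucleus(sub, maternal, pos,
                                       initial_states[i][keep], schedule,
                                       times, solver_opts)
                d[i, j] = node_sensitivity(full, red)
            except Exception as exc:
                raise RuntimeError(
                    f"sensitivity scan failed at position {pos}%, removed "
                    f"gene {gene!r}"
                ) from exc
    return SensitivityProfile(positions, circuit.genes, d,
                              circuit_name=circuit.name)


def insensitive_regions(profile: SensitivityProfile, threshold: float | None = None):
    """Maximal contiguous position runs with d(gene) below threshold.

    The default threshold is 5% of the maximum d observed in the scan.
    Returns a list of (gene, (position_lo, position_hi)) with intervals
    closed on the nucleus lattice; an empty list is possible.
    """
    if threshold is None:
        threshold = 0.05 * float(profile.d.max()) if profile.d.size else 0.0
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    regions = []
    for j, gene in enumerate(profile.genes):
        below = profile.d[:, j] < threshold
        i = 0
        while i < below.size:
            if below[i]:
                k = i
                while k + 1 < below.size and below[k + 1]:
                    k += 1
                regions.append((gene, (float(profile.positions[i]),
                                       float(profile.positions[k]))))
                i = k + 1
            else:
                i += 1
    return regions
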