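"""AC/DC subcircuit extraction, simulation and comparison.

An AC/DC subcircuit is the restriction of the full gap circuit to three
member genes, keeping their mutual (and auto-) regulatory weights, their
maternal input rows, and their production/decay/threshold parameters
unchanged.  Subcircuits are simulated over C14A only (no mitosis or
division) from the full model's state at time class T1, and compared to
the full model within their regions of influence with a dynamic-range
normalised trajectory distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import GeneCircuit, StageSchedule, Trajectory, simulate_nucleus

__all__ = [
    "SubcircuitAssignment",
    "DEFAULT_ASSIGNMENT",
    "extract_subcircuit",
    "simulate_subcircuit",
    "compare_trajectories",
]


@dataclass(frozen=True)
class SubcircuitAssignment:
    """Named 3-gene subcircuits with their regions of influence.

    ``modules`` maps name -> (member genes, (lo, hi) position interval in
    % A-P, closed on the nucleus lattice).  Regions may not overlap.
    """

    modules: tuple  # of (name, genes, (lo, hi))

    def __post_init__(self):
        seen = set()
        for name, genes, (lo, hi) in self.modules:
            if len(genes) != 3:
                raise ValueError(f"module {name}: member set must have size 3")
            if hi < lo:
                raise ValueError(f"module {name}: empty region")
            for other in seen:
                olo, ohi = other
                if lo <= ohi and olo <= hi:
                    raise ValueError(f"module {name}: regions overlap")
            seen.add((lo, hi))

    def __iter__(self):
        return iter(self.modules)

    def module(self, name: str):
        for n, genes, region in self.modules:
            if n == name:
                return genes, region
        raise KeyError(f"unknown module {name!r}")


# The three trunk modules: member genes and regions of influence.  The
# nuclei at 48% and 60% fall in the one-nucleus gaps between regions and
# belong to neither module.
DEFAULT_ASSIGNMENT = SubcircuitAssignment((
    ("acdc1", ("hb", "Kr", "gt"), (35.0, 47.0)),
    ("acdc2", ("hb", "Kr", "kni"), (49.0, 59.0)),
    ("acdc3", ("Kr", "kni", "gt"), (61.0, 75.0)),
))


def extract_subcircuit(circuit: GeneCircuit, genes) -> GeneCircuit:
    """Restriction of the circuit to the given member genes.

    Keeps the submatrix of W (auto-activation included), the full
    maternal columns, and unchanged R, lambda and h for the members.
    """
    genes = tuple(genes)
    idx = [circuit.gene_index(g) for g in genes]
    return GeneCircuit(
        genes=genes,
        maternal=circuit.maternal,
        production=circuit.production[idx],
        decay=circuit.decay[idx],
        gap_weights=circuit.gap_weights[np.ix_(idx, idx)],
        maternal_weights=circuit.maternal_weights[:, idx],
        basal=circuit.basal[idx],
        name=f"{circuit.name}-sub-" + "-".join(genes),
    )


def simulate_subcircuit(sub: GeneCircuit, maternal, position: float,
                        initial_state, schedule: StageSchedule | None = None,
                        output_times=None, solver_opts=None) -> Trajectory:
    """Simulate a subcircuit over C14A only.

    ``initial_state`` is the full model's member-gene concentration
    vector at time class T1.  The schedule must contain no mitosis or
    division (default: the standard C14A window).
    """
    schedule = schedule or StageSchedule.c14a_only()
    if schedule.has_division:
        raise ValueError("subcircuit simulations cover C14A only; the "
                         "schedule may not contain mitosis or division")
    return simulate_nucleus(sub, maternal, position, initial_state, schedule,
                            output_times, solver_opts)


def compare_trajectories(sub_traj: Trajectory, full_traj: Trajectory,
                         shared_genes=None):
    """Dynamic-range normalised distance between two trajectories.

    For each shared gene the per-class differences are normalised by the
    gene's dynamic range in the full trajectory (max - min; falls back to
    the max, then to 1, for flat series), then combined with the same
    time-class-mean Euclidean form as the node-sensitivity metric.
    Returns ``(overall, per_gene)`` where ``per_gene`` maps gene name to
    its own normalised distance; a gene offset by exactly its dynamic
    range at every class scores 1.
    """
    if shared_genes is None:
        shared_genes = tuple(g for g in sub_traj.genes if g in full_traj.genes)
    shared_genes = tuple(shared_genes)
    if not shared_genes:
        raise ValueError("no shared genes to compare")
    if sub_traj.times.size != full_traj.times.size or not np.allclose(
            sub_traj.times, full_traj.times, rtol=0, atol=1e-9):
        raise ValueError("trajectories must share their sampling times")
    n = full_traj.times.size
    per_gene = {}
    sq = 0.0
    for g in shared_genes:
        a = full_traj.gene_series(g)
        b = sub_traj.gene_series(g)
        rng = float(a.max() - a.min())
        if rng <= 0:
            rng = float(a.max()) if a.max() > 0 else 1.0
        r = (a - b) / rng
        per_gene[g] = float(np.sqrt(np.sum(r ** 2) / n))
        sq += np.sum(r ** 2)
    overall = float(np.sqrt(sq / n))
    return overall, per_gene
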