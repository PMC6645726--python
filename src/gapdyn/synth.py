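"""Synthetic inputs: maternal gradients, ground-truth circuits, datasets.

The generators emulate the qualitative features of the blastoderm trunk:
an anterior-decaying, Bcd-like exponential gradient; a posterior-rising,
Cad-like sigmoid gradient; and gap-gene expression produced by a known
ground-truth circuit built from the alternating-cushions architecture
(strong mutual repression between non-adjacent genes, weak asymmetric
repression between neighbours, auto-activation, maternal activation).
Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import GeneCircuit, StageSchedule, simulate_row
from .profiles import MaternalProfiles

__all__ = [
    "ExpressionDataset",
    "generate_synthetic_gradients",
    "generate_ground_truth_circuit",
    "generate_synthetic_dataset",
    "C14A_POSITIONS",
    "C13_POSITIONS",
]

# Nuclear lattices of the trunk domain: 41 C14A nuclei at integer percent
# positions 35..75; their 21 C13 mothers on a 2% lattice.
C14A_POSITIONS = np.arange(35.0, 76.0, 1.0)
C13_POSITIONS = np.arange(35.0, 76.0, 2.0)

GAP_GENES = ("hb", "Kr", "kni", "gt")
MATERNAL_GENES = ("Bcd", "Cad")


@dataclass
class ExpressionDataset:
    """Gap-gene expression records keyed by (position, time class, gene).

    ``data`` columns: position (% A-P), time_class (e.g. "T1".."T8" or
    "C13"), gene, concentration (a.u.), and optionally weight (used by the
    weighted-RMS objective; defaults to 1).
    """

    data: pd.DataFrame
    provenance: str = "synthetic"
    seed: int | None = None

    def __post_init__(self):
        required = {"position", "time_class", "gene", "concentration"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"expression table missing columns: {sorted(missing)}")
        if self.provenance not in ("measured", "synthetic"):
            raise ValueError("provenance must be 'measured' or 'synthetic'")
        if (self.data["concentration"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        keys = self.data[["position", "time_class", "gene"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate record for key {tuple(dup)}")
        if "weight" not in self.data.columns:
            self.data = self.data.assign(weight=1.0)
        self.data = self.data.reset_index(drop=True)

    def __len__(self):
        return len(self.data)

    def pivot(self) -> pd.DataFrame:
        """Wide table indexed by (position, time_class) with gene columns."""
        return self.data.pivot(index=["position", "time_class"],
                               columns="gene", values="concentration")


def generate_synthetic_gradients(anterior_peak: float = 65.0,
                                 length_scale: float = 11.5,
                                 posterior_plateau: float = 115.0,
                                 time_modulation: float = 0.02,
                                 seed: int = 0,
                                 positions=None,
                                 schedule: StageSchedule | None = None
                                 ) -> MaternalProfiles:
    """Smooth Bcd-like and Cad-like maternal gradients over the trunk.

    The Bcd-like profile is ``A exp(-(x - x_min) / l)``, strictly
    decreasing towards the posterior; the Cad-like profile is a logistic
    rise towards a posterior plateau.  With the defaults the Bcd-like
    gradient spans roughly 23 -> 7 a.u. between 47 and 61% A-P and the
    Cad-like gradient roughly 70 -> 108 a.u. over the same region, the
    concentration ranges the circuit's regime analyses probe.  Both
    profiles decline mildly and linearly in time (``time_modulation``
    fraction per C14A time class); a small seeded per-gene amplitude
    jitter (<= 1%) makes distinct seeds produce distinct tables without
    breaking monotonicity.
    """
    if anterior_peak <= 0 or posterior_plateau <= 0:
        raise ValueError("gradient amplitudes must be positive")
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    schedule = schedule or StageSchedule()
    if positions is None:
        positions = C14A_POSITIONS
    positions = np.asarray(positions, dtype=float)
    times = np.unique(np.concatenate([
        [schedule.t0, schedule.mitosis_start],
        schedule.class_bounds(),
        schedule.class_times("midpoint"),
    ]))
    span_classes = (times - schedule.t0) / schedule.class_duration
    if time_modulation < 0 or time_modulation * span_classes[-1] >= 1:
        raise ValueError("time_modulation per class must be >= 0 and small "
                         "enough to keep concentrations positive")
    rng = np.random.default_rng(seed)
    jitter = 1.0 + 0.01 * rng.uniform(-1.0, 1.0, size=2)

    x = positions[:, None]
    tmod_bcd = 1.0 - time_modulation * span_classes[None, :]
    tmod_cad = 1.0 - 0.5 * time_modulation * span_classes[None, :]
    bcd = (anterior_peak * jitter[0]
           * np.exp(-(x - positions[0]) / length_scale) * tmod_bcd)
    sigmoid = 1.0 / (1.0 + np.exp(-(x - 53.0) / 6.0))
    cad = posterior_plateau * jitter[1] * (0.52 + 0.48 * sigmoid) * tmod_cad
    values = np.stack([bcd, cad])
    return MaternalProfiles(MATERNAL_GENES, positions, times, values)


def _full_archetype(rng: np.random.Generator) -> GeneCircuit:
    """Four-gene trunk circuit with alternating-cushions architecture.

    Strong double-negative feedback couples the non-adjacent pairs
    (hb, kni) and (Kr, gt); weak asymmetric repression acts between
    overlapping neighbours (posterior gene represses the anterior one);
    every gene weakly auto-activates.  Maternal activation positions the
    domains: Bcd drives hb and Kr in the anterior, Cad drives kni and gt
    towards the posterior.
    """
    genes = GAP_GENES
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    R = rng.uniform(12.0, 18.0, n)
    lam = rng.uniform(0.09, 0.11, n)
    W = np.zeros((n, n))
    # auto-activation
    for g in genes:
        W[idx[g], idx[g]] = rng.uniform(0.004, 0.007)
    # strong double-negative pairs
    for a, b in (("hb", "kni"), ("Kr", "gt")):
        W[idx[a], idx[b]] = rng.uniform(-0.048, -0.038)
        W[idx[b], idx[a]] = rng.uniform(-0.048, -0.038)
    # weak asymmetric repression of the anterior neighbour
    for reg, tgt in (("Kr", "hb"), ("kni", "Kr"), ("gt", "kni")):
        W[idx[reg], idx[tgt]] = rng.uniform(-0.0035, -0.0015)
    E = np.zeros((2, n))
    E[0, idx["hb"]] = rng.uniform(0.11, 0.13)    # Bcd -> hb
    E[0, idx["Kr"]] = rng.uniform(0.055, 0.065)  # Bcd -> Kr
    E[1, idx["Kr"]] = rng.uniform(0.009, 0.011)  # Cad -> Kr (general activator)
    E[1, idx["kni"]] = rng.uniform(0.085, 0.095)  # Cad -> kni
    E[1, idx["gt"]] = rng.uniform(0.058, 0.062)  # Cad -> gt
    # Thresholds position the two pair races at different A-P positions:
    # hb/kni tips near 48%, Kr/gt near 57%, yielding staggered domains.
    h = np.array([
        rng.uniform(-2.4, -2.0),    # hb
        rng.uniform(-2.6, -2.2),    # Kr
        rng.uniform(-6.7, -6.4),    # kni
        rng.uniform(-6.8, -6.5),    # gt
    ])
    return GeneCircuit(genes, MATERNAL_GENES, R, lam, W, E, h,
                       name="synthetic-full")


def _acdc_archetype(rng: np.random.Generator) -> GeneCircuit:
    """Three-gene AC/DC motif: a strong double-negative pair (g1, g3)
    combined with a weak three-gene negative cycle g1 -| g2 -| g3 -| g1."""
    genes = ("g1", "g2", "g3")
    n = 3
    R = rng.uniform(12.0, 18.0, n)
    lam = rng.uniform(0.09, 0.11, n)
    W = np.zeros((n, n))
    for i in range(n):
        W[i, i] = rng.uniform(0.004, 0.007)
    # strong pair between the non-adjacent genes
    W[0, 2] = rng.uniform(-0.048, -0.038)
    W[2, 0] = rng.uniform(-0.048, -0.038)
    # weak negative cycle (the g1 -| g3 edge of the cycle is carried by the
    # strong pair edge already present)
    W[0, 1] += rng.uniform(-0.0035, -0.0015)
    W[1, 2] += rng.uniform(-0.0035, -0.0015)
    E = np.zeros((2, n))
    E[0, 0] = rng.uniform(0.08, 0.12)
    E[0, 1] = rng.uniform(0.03, 0.05)
    E[1, 1] = rng.uniform(0.01, 0.02)
    E[1, 2] = rng.uniform(0.03, 0.05)
    h = rng.uniform(-3.0, -2.0, n)
    return GeneCircuit(genes, MATERNAL_GENES, R, lam, W, E, h,
                       name="synthetic-acdc")


def generate_ground_truth_circuit(archetype: str = "full",
                                  seed: int = 0) -> GeneCircuit:
    """Seeded ground-truth circuit of a given archetype ('full' or 'acdc').

    Magnitudes are drawn from fixed ranges chosen so that strong-pair
    weights always exceed weak-cycle weights in magnitude.
    """
    rng = np.random.default_rng(seed)
    if archetype == "full":
        return _full_archetype(rng)
    if archetype == "acdc":
        return _acdc_archetype(rng)
    raise ValueError(f"unknown archetype {archetype!r}; use 'full' or 'acdc'")


def generate_synthetic_dataset(circuit: GeneCircuit,
                               gradients: MaternalProfiles,
                               noise_sd: float = 0.0,
                               seed: int = 0,
                               schedule: StageSchedule | None = None,
                               initial_states=None,
                               solver_opts=None) -> ExpressionDataset:
    """Simulate the circuit over the full schedule and sample noisy data.

    The circuit is run for every C13 mother nucleus from the given initial
    state (default: all zero, letting maternal inputs establish the
    domains), daughters are sampled at the T1-T8 class midpoints, and
    independent zero-mean Gaussian noise (sd ``noise_sd``, truncated at 0)
    is added.  The generating seed is recorded on the dataset.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    schedule = schedule or StageSchedule()
    positions = C13_POSITIONS if schedule.has_division else C14A_POSITIONS
    lo, hi = gradients.position_range()
    positions = positions[(positions >= lo) & (positions <= hi)]
    if initial_states is None:
        initial_states = np.zeros((positions.size, circuit.n_genes))
    sample_times = schedule.class_times("midpoint")
    trajs = simulate_row(circuit, gradients, positions, initial_states,
                         schedule, sample_times, solver_opts)
    rng = np.random.default_rng(seed)
    labels = schedule.class_labels()
    recs = []
    for tr in trajs:
        clean = tr.at_times(sample_times)
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) \
            if noise_sd > 0 else clean
        noisy = np.maximum(noisy, 0.0)
        for j, lab in enumerate(labels):
            for a, gene in enumerate(circuit.genes):
                recs.append((tr.position, lab, gene, noisy[j, a], 1.0))
    df = pd.DataFrame(recs, columns=["position", "time_class", "gene",
                                     "concentration", "weight"])
    return ExpressionDataset(df, provenance="synthetic", seed=seed)
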