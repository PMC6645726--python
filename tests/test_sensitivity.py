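import numpy as np
import pytest
from dataclasses import replace

from gapdyn.circuit import Trajectory, simulate_nucleus
from gapdyn.sensitivity import (SensitivityProfile, insensitive_regions,
                                node_sensitivity, remove_node,
                                sensitivity_scan)


def _toy_traj(states, genes=("hb", "Kr", "kni", "gt"), position=50.0):
    states = np.asarray(states, dtype=float)
    times = 21.0 + 6.25 * (np.arange(states.shape[0]) + 0.5)
    return Trajectory(position=position, times=times, states=states,
                      genes=tuple(genes))


class TestRemoveNode:
    def test_shapes_after_removal(self, full_circuit):
        sub = remove_node(full_circuit, "kni")
        assert sub.genes == ("hb", "Kr", "gt")
        assert sub.gap_weights.shape == (3, 3)
        assert sub.maternal_weights.shape == (2, 3)
        # remaining parameters untouched
        for g in sub.genes:
            i, j = full_circuit.gene_index(g), sub.gene_index(g)
            assert sub.production[j] == full_circuit.production[i]
            assert sub.basal[j] == full_circuit.basal[i]
        for ga in sub.genes:
            for gb in sub.genes:
                assert (sub.gap_weights[sub.gene_index(ga), sub.gene_index(gb)]
                        == full_circuit.gap_weights[
                            full_circuit.gene_index(ga),
                            full_circuit.gene_index(gb)])

    def test_unknown_gene(self, full_circuit):
        with pytest.raises(KeyError):
            remove_node(full_circuit, "eve")

    def test_removing_uncoupled_gene_leaves_dynamics_identical(
            self, full_circuit, gradients, c14a):
        # zero out every interaction of gt, and start it at zero: the other
        # genes' trajectories must be bit-identical with and without it
        k = full_circuit.gene_index("gt")
        W = full_circuit.gap_weights.copy()
        W[k, :] = 0.0
        W[:, k] = 0.0
        E = full_circuit.maternal_weights.copy()
        E[:, k] = 0.0
        circ = replace(full_circuit, gap_weights=W, maternal_weights=E)
        sub = remove_node(circ, "gt")
        g0 = np.array([20.0, 40.0, 5.0, 0.0])
        times = c14a.class_times("midpoint")
        full = simulate_nucleus(circ, gradients, 49.0, g0, c14a, times)
        red = simulate_nucleus(sub, gradients, 49.0, g0[[0, 1, 2]], c14a,
                               times)
        # the extra (decoupled) dimension still influences the adaptive
        # step controller, so agreement is to solver accuracy, not bitwise
        for g in sub.genes:
            assert np.allclose(full.gene_series(g), red.gene_series(g),
                               rtol=0, atol=1e-6)


class TestNodeSensitivityMetric:
    def test_identical_trajectories_give_zero(self):
        a = _toy_traj(np.random.default_rng(0).uniform(0, 50, (8, 4)))
        assert node_sensitivity(a, a) == 0.0

    def test_constant_offset_in_one_gene_gives_delta(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 50, (8, 4))
        delta = 3.7
        shifted = base.copy()
        shifted[:, 2] += delta
        d = node_sensitivity(_toy_traj(base), _toy_traj(shifted))
        assert d == pytest.approx(delta, rel=1e-12)

    def test_two_class_toy_hand_sum(self):
        a = _toy_traj([[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]])
        b = _toy_traj([[0.0, 2.0, 3.0, 4.0], [5.0, 4.0, 7.0, 5.0]])
        # squared differences: class 1: 1; class 2: 4 + 9 = 13; mean over 2
        expected = np.sqrt((1 + 13) / 2)
        assert node_sensitivity(a, b) == pytest.approx(expected, rel=1e-12)

    def test_removed_gene_counts_as_zero(self):
        full = _toy_traj(np.full((8, 4), 5.0))
        reduced = Trajectory(position=50.0, times=full.times,
                             states=np.full((8, 3), 5.0),
                             genes=("hb", "Kr", "gt"))
        # kni contributes its full-model value 5 at every class
        assert node_sensitivity(full, reduced) == pytest.approx(5.0)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            A, B, C = (_toy_traj(rng.uniform(0, 100, (8, 4)))
                       for _ in range(3))
            dab = node_sensitivity(A, B)
            dba = node_sensitivity(B, A)
            dac = node_sensitivity(A, C)
            dcb = node_sensitivity(C, B)
            assert dab >= 0
            assert dab == pytest.approx(dba, rel=1e-12)
            assert dab <= dac + dcb + 1e-9

    def test_mismatched_sampling_rejected(self):
        a = _toy_traj(np.zeros((8, 4)))
        b = _toy_traj(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="time classes"):
            node_sensitivity(a, b)


class TestInsensitiveRegions:
    def _profile(self, d):
        d = np.asarray(d, dtype=float)
        return SensitivityProfile(np.arange(35.0, 35.0 + d.shape[0]),
                                  ("hb",) if d.ndim == 1 else
                                  tuple(f"g{j}" for j in range(d.shape[1])),
                                  d.reshape(d.shape[0], -1))

    def test_identically_zero_gene_spans_whole_domain(self):
        prof = self._profile(np.zeros(10))
        regions = insensitive_regions(prof, threshold=0.5)
        assert regions == [("hb", (35.0, 44.0))]

    def test_zero_threshold_on_positive_profile_is_empty(self):
        prof = self._profile(np.ones(5))
        assert insensitive_regions(prof, threshold=0.0) == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        prof = self._profile(rng.uniform(0, 10, 30))

        def cells(tau):
            out = set()
            for gene, (lo, hi) in insensitive_regions(prof, tau):
                out.update(np.arange(lo, hi + 1))
            return out

        assert cells(2.0) <= cells(5.0) <= cells(9.0)


class TestSensitivityScan:
    def test_recovers_constructed_regions(self, full_circuit, gradients,
                                          t1_states):
        """The seeded ground-truth circuit is built so that kni/gt are
        silent and dispensable in the anterior and hb in the posterior;
        the screen must recover those regions of insensitivity."""
        positions, states = t1_states
        prof = sensitivity_scan(full_circuit, gradients, states, positions)
        regions = dict()
        for gene, (lo, hi) in insensitive_regions(prof):
            regions.setdefault(gene, []).append((lo, hi))

        def covered(gene, lo, hi):
            return any(rlo <= lo and hi <= rhi
                       for rlo, rhi in regions.get(gene, []))

        assert covered("kni", 35.0, 45.0)
        assert covered("gt", 35.0, 45.0)
        assert covered("hb", 55.0, 75.0)
        # the screen must NOT call the essential anterior genes dispensable
        assert not covered("hb", 35.0, 45.0)
        assert not covered("Kr", 35.0, 45.0)

    def test_d_nonnegative_and_zero_iff_identical(self, full_circuit,
                                                  gradients, t1_states):
        positions, states = t1_states
        prof = sensitivity_scan(full_circuit, gradients, states[:3],
                                positions[:3])
        assert np.all(prof.d >= 0)
        assert np.all(prof.d > 0)  # every gene interacts in this circuit
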