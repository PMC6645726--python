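import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapdyn.circuit import (GeneCircuit, StageSchedule, daughter_positions,
                            derivatives, regulation_expression,
                            regulation_expression_prime, simulate_nucleus,
                            simulate_row, total_input, total_input_vector)
from gapdyn.synth import C13_POSITIONS

from conftest import autonomous_circuit


class TestRegulationExpression:
    def test_closed_form_values(self):
        assert regulation_expression(0.0) == pytest.approx(0.5)
        assert regulation_expression(1.0) == pytest.approx(
            0.5 * (1 / np.sqrt(2) + 1))

    @given(st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_odd_symmetry_about_half(self, u):
        assert regulation_expression(-u) == pytest.approx(
            1.0 - regulation_expression(u), abs=1e-12)

    @given(st.floats(-30, 30), st.floats(1e-6, 5))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_bounded(self, u, du):
        lo, hi = regulation_expression(u), regulation_expression(u + du)
        assert lo < hi
        assert 0.0 < lo < 1.0 and 0.0 < hi < 1.0

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            regulation_expression(np.nan)
        with pytest.raises(ValueError):
            regulation_expression(np.inf)

    def test_derivative_closed_form_matches_finite_differences(self):
        assert regulation_expression_prime(0.0) == pytest.approx(0.5)
        for u in (-3.0, -0.7, 0.0, 1.3, 8.0):
            eps = 1e-6
            fd = (regulation_expression(u + eps)
                  - regulation_expression(u - eps)) / (2 * eps)
            assert regulation_expression_prime(u) == pytest.approx(fd, abs=1e-8)


class TestTotalInput:
    def _circuit(self, n=3, m=2, seed=0):
        rng = np.random.default_rng(seed)
        return GeneCircuit(tuple("abc"[:n]), tuple("MN"[:m]),
                           rng.uniform(5, 20, n), rng.uniform(0.05, 0.2, n),
                           rng.normal(0, 0.02, (n, n)),
                           rng.normal(0, 0.02, (m, n)), rng.normal(0, 2, n))

    def test_basal_only(self):
        c = GeneCircuit(("a",), (), [1.0], [0.1], [[0.0]],
                        np.zeros((0, 1)), [-2.5])
        assert total_input([0.0], [], c, "a") == pytest.approx(-2.5)

    def test_single_regulator_product(self):
        c = GeneCircuit(("a", "b"), (), [1, 1], [0.1, 0.1],
                        [[0.0, 0.0], [-0.001, 0.0]], np.zeros((0, 2)), [0, 0])
        assert total_input([0.0, 100.0], [], c, "a") == pytest.approx(-0.1)

    def test_matches_scalar_loop_oracle(self):
        c = self._circuit(seed=42)
        rng = np.random.default_rng(7)
        g = rng.uniform(0, 100, 3)
        m = rng.uniform(0, 50, 2)
        u = total_input_vector(g, m, c)
        for a in range(3):
            expected = sum(c.gap_weights[b, a] * g[b] for b in range(3))
            expected += sum(c.maternal_weights[k, a] * m[k] for k in range(2))
            expected += c.basal[a]
            assert u[a] == pytest.approx(expected, rel=1e-12)
            assert total_input(g, m, c, c.genes[a]) == pytest.approx(expected)

    def test_dimension_mismatch_names_vector(self):
        c = self._circuit()
        with pytest.raises(ValueError, match="gap state"):
            total_input_vector([1.0], [0.0, 0.0], c)
        with pytest.raises(ValueError, match="maternal"):
            total_input_vector([1.0, 1.0, 1.0], [0.0], c)


class _ConstantMaternal:
    """Minimal profile stub with constant concentrations everywhere."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def evaluate(self, position, time):
        return self.values.copy()

    def evaluate_gene(self, gene, position, time):
        idx = {"Bcd": 0, "Cad": 1}[gene]
        return np.broadcast_to(self.values[idx], np.shape(position)).copy()

    def position_range(self):
        return (0.0, 100.0)


class TestDerivatives:
    def test_mitosis_is_pure_decay(self, full_circuit, gradients):
        g = np.array([10.0, 20.0, 5.0, 1.0])
        rate = derivatives(17.0, g, full_circuit, gradients, 50.0, "mitosis")
        assert np.allclose(rate, -full_circuit.decay * g, rtol=0, atol=1e-14)

    def test_fixed_point_has_zero_rate(self, full_circuit, gradients):
        t, pos = 30.0, 50.0
        mat = gradients.evaluate(pos, t)
        g = np.zeros(4)
        u = total_input_vector(g, mat, full_circuit)
        g_star = (full_circuit.production * regulation_expression(u)
                  / full_circuit.decay)
        # re-evaluate u at g_star and iterate to an actual fixed point
        for _ in range(200):
            u = total_input_vector(g_star, mat, full_circuit)
            g_star = (full_circuit.production * regulation_expression(u)
                      / full_circuit.decay)
        rate = derivatives(t, g_star, full_circuit, gradients, pos)
        assert np.max(np.abs(rate)) < 1e-8

    def test_zero_production_is_decay_field(self, gradients, full_circuit):
        from dataclasses import replace
        c0 = replace(full_circuit, production=np.zeros(4))
        g = np.array([3.0, 1.0, 4.0, 1.5])
        rate = derivatives(30.0, g, c0, gradients, 50.0)
        assert np.allclose(rate, -c0.decay * g)


class TestSimulateNucleus:
    def test_zero_production_matches_exponential_decay(self, gradients, c14a):
        from dataclasses import replace
        circ = replace(autonomous_circuit(0), production=np.zeros(3),
                       maternal=("Bcd", "Cad"),
                       maternal_weights=np.zeros((2, 3)))
        g0 = np.array([50.0, 10.0, 80.0])
        times = c14a.class_times("end")
        tr = simulate_nucleus(circ, _ConstantMaternal([5.0, 50.0]), 50.0, g0,
                              c14a, times)
        for k, t in enumerate(times):
            expected = g0 * np.exp(-circ.decay * (t - c14a.t0))
            assert np.allclose(tr.states[k], expected, rtol=1e-6)

    def test_constant_inputs_converge_to_frozen_root(self, acdc_circuit):
        from gapdyn.phase_space import FrozenField
        mat = np.array([10.0, 80.0])
        sched = StageSchedule.c14a_only(t_start=0.0, duration=600.0)
        tr = simulate_nucleus(acdc_circuit, _ConstantMaternal(mat), 50.0,
                              np.zeros(3), sched, [600.0])
        field = FrozenField(acdc_circuit, mat)
        assert np.max(np.abs(field(tr.states[-1]))) < 1e-6

    def test_concentrations_non_increasing_during_mitosis(self, full_circuit,
                                                          gradients, schedule):
        times = np.linspace(schedule.mitosis_start, schedule.division_time, 6)
        tr = simulate_nucleus(full_circuit, gradients, 45.0,
                              np.full(4, 30.0), schedule, times)
        assert np.all(np.diff(tr.states, axis=0) <= 1e-10)

    def test_boundedness_and_positivity(self, gradients, schedule):
        for seed in range(3):
            circ = autonomous_circuit(seed, n=4)
            from dataclasses import replace
            circ = replace(circ, maternal=("Bcd", "Cad"),
                           maternal_weights=np.abs(
                               np.random.default_rng(seed).normal(
                                   0, 0.01, (2, 4))))
            g0 = np.full(4, 10.0)
            tr = simulate_nucleus(circ, gradients, 55.0, g0, schedule,
                                  schedule.class_times("midpoint"))
            cap = np.maximum(g0, circ.saturation()) * (1 + 1e-6)
            assert np.all(tr.states <= cap)
            assert np.all(tr.states >= -1e-8)


class TestSimulateRow:
    def test_division_yields_41_daughters(self, full_circuit, gradients,
                                          schedule):
        trajs = simulate_row(full_circuit, gradients, C13_POSITIONS,
                             np.zeros((21, 4)), schedule,
                             schedule.class_times("midpoint"))
        positions = [tr.position for tr in trajs]
        assert positions == list(np.arange(35.0, 76.0))
        assert len(trajs) == 41

    def test_daughter_positions_rounding(self):
        assert daughter_positions(35.0) == (35.0, 36.0)
        assert daughter_positions(75.0) == (75.0, 76.0)

    def test_single_nucleus_row_reduces_to_simulate_nucleus(
            self, full_circuit, gradients, c14a):
        g0 = np.array([5.0, 40.0, 1.0, 0.5])
        times = c14a.class_times("midpoint")
        row = simulate_row(full_circuit, gradients, [49.0], [g0], c14a, times)
        single = simulate_nucleus(full_circuit, gradients, 49.0, g0, c14a,
                                  times)
        assert np.array_equal(row[0].states, single.states)

    def test_row_matches_per_nucleus_and_is_order_invariant(
            self, full_circuit, gradients, c14a, t1_states):
        positions, states = t1_states
        pick = [0, 10, 25, 40]
        times = c14a.class_times("midpoint")
        row = simulate_row(full_circuit, gradients, positions[pick],
                           states[pick], c14a, times)
        perm = [2, 0, 3, 1]
        row_perm = simulate_row(full_circuit, gradients,
                                positions[pick][perm], states[pick][perm],
                                c14a, times)
        for tr, trp, i in zip(row, row_perm, pick):
            single = simulate_nucleus(full_circuit, gradients, positions[i],
                                      states[i], c14a, times)
            assert np.max(np.abs(tr.states - single.states)) < 1e-8
            assert np.array_equal(tr.states, trp.states)

    def test_duplicate_positions_rejected(self, full_circuit, gradients, c14a):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_row(full_circuit, gradients, [49.0, 49.0],
                         np.zeros((2, 4)), c14a)


class TestStageSchedule:
    def test_default_phase_structure(self, schedule):
        phases = schedule.phases()
        assert [p[2] for p in phases] == ["interphase", "mitosis",
                                          "interphase"]
        starts = [p[0] for p in phases]
        ends = [p[1] for p in phases]
        assert ends[0] == starts[1] and ends[1] == starts[2]
        assert schedule.division_time == schedule.c14a_start == 21.0

    def test_eight_equal_time_classes(self, schedule):
        bounds = schedule.class_bounds()
        assert bounds.size == 9
        assert np.allclose(np.diff(bounds), 6.25)
        assert schedule.class_labels() == tuple(f"T{i}" for i in range(1, 9))

    def test_c14a_only_has_no_division(self, c14a):
        assert not c14a.has_division
        assert [p[2] for p in c14a.phases()] == ["interphase"]
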