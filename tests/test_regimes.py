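import numpy as np
import pytest
from dataclasses import replace

from gapdyn.circuit import GeneCircuit
from gapdyn.phase_space import FrozenField, basin_census, find_steady_states
from gapdyn.regimes import (LIMIT_CYCLE, MONOSTABLE, MONOSTABLE_OSC,
                            MULTISTABLE, RegimeLabel, boundary_position,
                            classify_regime, control_parameter_map,
                            detect_limit_cycle, maternal_phase_diagram,
                            simplified_acdc, weight_phase_diagram)
from gapdyn.subcircuits import extract_subcircuit


def _field(circ):
    return FrozenField(circ, np.zeros(len(circ.maternal)))


class TestClassifyRegime:
    def test_toggle_is_multistable(self):
        W = np.array([[0.008, -0.05], [-0.05, 0.008]])
        circ = GeneCircuit(("a", "b"), (), [15.0, 15.0], [0.1, 0.1], W,
                           np.zeros((0, 2)), [1.5, 1.5])
        lab = classify_regime(_field(circ))
        assert lab.base == MULTISTABLE

    def test_single_spiral_sink_is_monostable_damped(self):
        circ = simplified_acdc(0.0, 0.03)
        field = _field(circ)
        states = find_steady_states(field)
        assert len(states) == 1 and states[0].label == "spiral sink"
        assert classify_regime(field).base == MONOSTABLE_OSC

    def test_steep_repression_cycle_is_limit_cycle(self):
        lab = classify_regime(_field(simplified_acdc(0.0, 0.06)),
                              cycle_check=True)
        assert lab.base == LIMIT_CYCLE


class TestDetectLimitCycle:
    def test_decay_only_field_is_not_oscillatory(self):
        circ = GeneCircuit(("a", "b", "c"), (), [0.001] * 3, [0.1] * 3,
                           np.zeros((3, 3)), np.zeros((0, 3)), [-50.0] * 3)
        ok, amp = detect_limit_cycle(_field(circ))
        assert not ok
        assert np.all(amp < 1e-3 * circ.saturation())

    def test_repressilator_sustains_ten_stationary_cycles(self):
        field = _field(simplified_acdc(0.0, 0.06))
        # period is ~37 min; a 1200 min horizon keeps > 10 cycles after the
        # 50% transient cut
        ok, amp = detect_limit_cycle(field, horizon=1200.0, n_samples=8000)
        assert ok
        assert amp.max() > 10.0

    def test_globally_attracting_fixed_point_from_random_starts(self):
        circ = simplified_acdc(0.0, 0.0)
        field = _field(circ)
        rng = np.random.default_rng(0)
        ics = [rng.uniform(0, circ.saturation()) for _ in range(10)]
        ok, _ = detect_limit_cycle(field, initial_conditions=ics)
        assert not ok


class TestSimplifiedAcdc:
    def test_zero_controls_uncoupled_and_monostable(self):
        circ = simplified_acdc(0.0, 0.0)
        assert np.array_equal(circ.gap_weights, np.zeros((3, 3)))
        assert classify_regime(_field(circ)).base == MONOSTABLE

    def test_pure_positive_feedback_is_multistable_with_basin_oracle(self):
        circ = simplified_acdc(0.06, 0.0)
        field = _field(circ)
        assert classify_regime(field).base == MULTISTABLE
        assert len(basin_census(field, grid_per_dim=12)) >= 2

    def test_negative_controls_rejected(self):
        with pytest.raises(ValueError):
            simplified_acdc(-0.1, 0.0)


class TestControlParameterMap:
    def test_no_cycles_without_negative_feedback_and_consistency(self):
        pg = np.linspace(0.0, 0.08, 4)
        diagram = control_parameter_map(pg, [0.0])
        bases = {diagram.labels[i, 0].base for i in range(4)}
        assert LIMIT_CYCLE not in bases
        # any single cell equals a standalone classification
        lab = classify_regime(_field(simplified_acdc(pg[2], 0.0)),
                              cycle_check=True)
        assert diagram.labels[2, 0] == lab

    def test_wide_map_contains_the_three_main_regimes(self):
        diagram = control_parameter_map(np.linspace(0, 0.08, 5),
                                        np.linspace(0, 0.08, 5))
        bases = {lab.base for lab in diagram.labels.ravel()}
        assert {MONOSTABLE, MULTISTABLE, LIMIT_CYCLE} <= bases


class TestPhaseDiagrams:
    def test_zero_maternal_weights_make_label_constant_along_axis(
            self, acdc_circuit, gradients):
        circ = replace(acdc_circuit, maternal_weights=np.zeros((2, 3)))
        d = maternal_phase_diagram(circ, gradients, [50.0], "Bcd",
                                   (0.0, 20.0), 5.0)
        labels = d.labels[0]
        assert all(lab == labels[0] for lab in labels)

    def test_bcd_threshold_is_single_and_monotone(self, full_circuit,
                                                  gradients):
        """The hb/Kr/kni subcircuit of the ground-truth circuit behaves as
        an activator-controlled switch: monostable at low Bcd, multistable
        above a single threshold."""
        sub = extract_subcircuit(full_circuit, ("hb", "Kr", "kni"))
        d = maternal_phase_diagram(sub, gradients, [53.0], "Bcd",
                                   (0.0, 30.0), 0.5)
        multi = np.array([lab.multistable for lab in d.labels[0]])
        flips = np.flatnonzero(np.diff(multi.astype(int)))
        assert flips.size == 1
        assert not multi[0] and multi[-1]
        thr = boundary_position(
            type(d)(("Bcd",), (d.axis_grids[1],), d.labels[0]))
        assert 10.0 < thr < 25.0

    def test_refining_the_sweep_preserves_labels(self, full_circuit,
                                                 gradients):
        sub = extract_subcircuit(full_circuit, ("hb", "Kr", "kni"))
        coarse = maternal_phase_diagram(sub, gradients, [53.0], "Bcd",
                                        (10.0, 26.0), 4.0)
        fine = maternal_phase_diagram(sub, gradients, [53.0], "Bcd",
                                      (10.0, 26.0), 2.0)
        for j, v in enumerate(coarse.axis_grids[1]):
            j_fine = int(np.flatnonzero(
                np.isclose(fine.axis_grids[1], v))[0])
            assert coarse.labels[0, j] == fine.labels[0, j_fine]

    def test_weight_sweep_moves_the_bifurcation(self, full_circuit,
                                                gradients):
        """Strengthening the repression of hb by Kr shrinks the multistable
        (anterior-type) range of the hb/Kr/kni subcircuit, mirroring the
        criticality of that interaction."""
        sub = extract_subcircuit(full_circuit, ("hb", "Kr", "kni"))
        positions = np.arange(47.0, 56.0)
        d = weight_phase_diagram(sub, gradients, [("Kr", "hb")],
                                 [(-0.004, 0.0)], [0.001],
                                 positions=positions)
        grid = d.axis_grids[1]
        n_multi = {grid[j]: sum(d.labels[i, j].multistable
                                for i in range(positions.size))
                   for j in range(grid.size)}
        assert n_multi[grid[-1]] >= n_multi[grid[0]]
        assert n_multi[grid[-1]] > 0

    def test_empty_range_rejected(self, acdc_circuit, gradients):
        with pytest.raises(ValueError, match="empty"):
            maternal_phase_diagram(acdc_circuit, gradients, [50.0], "Bcd",
                                   (5.0, 1.0), 0.1)

    def test_unknown_weight_rejected(self, acdc_circuit, gradients):
        with pytest.raises(KeyError):
            weight_phase_diagram(acdc_circuit, gradients, [("hb", "g1")],
                                 [(-0.01, 0.0)], [0.005], position=50.0)


class TestRegimeLabel:
    def test_only_known_bases_allowed(self):
        with pytest.raises(ValueError):
            RegimeLabel("chaotic")

    def test_multistable_flag(self):
        assert RegimeLabel(MULTISTABLE).multistable
        assert not RegimeLabel(MONOSTABLE).multistable
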