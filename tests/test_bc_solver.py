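"""Fixed-point boundary-condition solver vs the exact linear oracle."""

import numpy as np
import pytest

from conftest import vessel_with_resistance
from ffrnet import (CoronaryTree, SolverSettings, Stenosis,
                    calibrate_microcirculation, direct_solve_linear,
                    distribute_flow, identify_hyperemic_flows,
                    network_pressures, solve_hyperemic)
from ffrnet.synthetic_cohort import CohortSpec, generate_tree, _place_stenosis
from ffrnet.units import MLS_TO_M3S, MMHG_S_ML_TO_SI


def single_vessel_re(r_e: float) -> CoronaryTree:
    return CoronaryTree(segments={"root": vessel_with_resistance(r_e)})


class TestNetworkPressures:
    def test_zero_resistance_keeps_inlet_pressure(self):
        tree = single_vessel_re(1e-9)
        field = network_pressures(tree, {"root": 4 * MLS_TO_M3S}, p0=88.0)
        assert field.p_dist["root"] / 133.322 == pytest.approx(88.0, abs=1e-6)

    def test_single_segment_drop(self):
        # R_e = 4 mmHg·s/mL at Q = 4 mL/s from P0 = 88 → outlet at 72 mmHg
        tree = single_vessel_re(4.0)
        field = network_pressures(tree, {"root": 4 * MLS_TO_M3S}, p0=88.0)
        assert field.p_dist["root"] / 133.322 == pytest.approx(72.0, rel=1e-9)

    def test_pressure_non_increasing_root_to_leaf(self, asymmetric_tree):
        flows = distribute_flow(asymmetric_tree, 2.8e-6)
        field = network_pressures(asymmetric_tree, flows.outlet_flows, p0=90.0)
        for sid, seg in asymmetric_tree.segments.items():
            assert field.p_dist[sid] <= field.p_prox[sid]
            if seg.parent:
                assert field.p_prox[sid] == field.p_dist[seg.parent]


class TestFixedPoint:
    def test_single_outlet_closed_form(self):
        # Q* = P0/(R_e + R_j) = 88/22 = 4 mL/s; outlet pressure 72 mmHg
        tree = single_vessel_re(4.0)
        r_j = {"root": 18.0 * MMHG_S_ML_TO_SI}
        flows, report = identify_hyperemic_flows(tree, 88.0, r_j,
                                                 SolverSettings(tolerance=1e-8))
        assert report.converged
        assert flows.outlet_flows["root"] / MLS_TO_M3S == pytest.approx(4.0, rel=1e-6)
        field = network_pressures(tree, flows.outlet_flows, 88.0)
        assert field.p_dist["root"] / 133.322 == pytest.approx(72.0, rel=1e-5)

    def test_no_epicardial_coupling_converges_in_one_full_step(self):
        tree = single_vessel_re(1e-12)
        r_j = {"root": 20.0 * MMHG_S_ML_TO_SI}
        flows, report = identify_hyperemic_flows(
            tree, 88.0, r_j, SolverSettings(alpha=1.0, init="uniform"))
        assert report.iterations == 1 and report.converged
        assert flows.outlet_flows["root"] == pytest.approx(
            88.0 * 133.322 / r_j["root"], rel=1e-9)

    def test_symmetric_bifurcation_equal_flows(self, symmetric_bifurcation, blood):
        resting = distribute_flow(symmetric_bifurcation, 2.8e-6)
        rmap = calibrate_microcirculation(symmetric_bifurcation, 93.3, resting, blood)
        flows, report = identify_hyperemic_flows(
            symmetric_bifurcation, 82.1, rmap.micro_hyperemic, resting=resting)
        assert report.converged
        assert flows.outlet_flows["L"] == pytest.approx(flows.outlet_flows["R"], rel=1e-9)

    def test_certificate_at_convergence(self, asymmetric_tree, blood):
        """At convergence the matching condition holds: per-outlet
        |P0 − (Σ path drops + Q_j R_j)| / P0 ≤ tolerance."""
        resting = distribute_flow(asymmetric_tree, 2.8e-6)
        rmap = calibrate_microcirculation(asymmetric_tree, 93.3, resting, blood)
        settings = SolverSettings()
        flows, report = identify_hyperemic_flows(
            asymmetric_tree, 82.1, rmap.micro_hyperemic, settings, blood, resting)
        assert report.converged
        field = network_pressures(asymmetric_tree, flows.outlet_flows, 82.1, blood)
        p0_pa = 82.1 * 133.322
        for o in asymmetric_tree.outlets:
            drops = p0_pa - field.p_dist[o]
            mismatch = abs(p0_pa - (drops + flows.outlet_flows[o]
                                    * rmap.micro_hyperemic[o])) / p0_pa
            assert mismatch <= settings.tolerance

    def test_monotone_residual_decay_alpha_03(self, asymmetric_tree, blood):
        resting = distribute_flow(asymmetric_tree, 2.8e-6)
        rmap = calibrate_microcirculation(asymmetric_tree, 93.3, resting, blood)
        _, report = identify_hyperemic_flows(
            asymmetric_tree, 82.1, rmap.micro_hyperemic,
            SolverSettings(alpha=0.3, tolerance=1e-10), blood, resting)
        hist = report.residual_history[3:]  # after burn-in
        assert all(b < a for a, b in zip(hist, hist[1:]))

    def test_eq10_literal_has_no_fixed_point(self):
        """The literal damped pressure update is inconsistent with the
        matching condition; it must not be reported as converged."""
        tree = single_vessel_re(4.0)
        r_j = {"root": 18.0 * MMHG_S_ML_TO_SI}
        flows, report = identify_hyperemic_flows(
            tree, 88.0, r_j,
            SolverSettings(eq10_literal=True, max_iter=300, adaptive_alpha=False))
        assert not report.converged
        assert report.final_residual > 1e-4

    def test_severe_stenosis_still_converges(self, asymmetric_tree, physiology):
        tree = asymmetric_tree.with_stenoses([
            Stenosis(segment="lad", start=0.01, length=0.005, severity=0.9,
                     ref_diameter=0.003)])
        field, flows, report, p0 = solve_hyperemic(tree, physiology)
        assert report.converged
        assert all(q > 0 for q in flows.outlet_flows.values())


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_fixed_point_matches_direct_solve(self, seed, blood):
        """Linear-model fixed point equals the exact solve (rel. tol 1e-6)
        on randomized stenosed trees with up to 32 outlets."""
        spec = CohortSpec(seed=seed, depth_range=(2, 5))
        rng = np.random.default_rng(seed)
        tree = generate_tree(seed, spec)
        tree = tree.with_stenoses([_place_stenosis(rng, tree, spec)])
        assert len(tree.outlets) <= 32
        resting = distribute_flow(tree, 2.8e-6)
        rmap = calibrate_microcirculation(tree, 93.3, resting, blood)
        exact = direct_solve_linear(tree, 82.1, rmap.micro_hyperemic, blood)
        flows, report = identify_hyperemic_flows(
            tree, 82.1, rmap.micro_hyperemic,
            SolverSettings(tolerance=1e-9, max_iter=50000), blood, resting)
        assert report.converged
        for o in tree.outlets:
            assert flows.outlet_flows[o] == pytest.approx(
                exact.outlet_flows[o], rel=1e-6)

    def test_direct_solve_single_outlet_closed_form(self):
        tree = single_vessel_re(4.0)
        flows = direct_solve_linear(tree, 88.0, {"root": 18.0 * MMHG_S_ML_TO_SI})
        assert flows.q_total / MLS_TO_M3S == pytest.approx(4.0, rel=1e-12)

    def test_near_zero_junction_decouples_branches(self):
        # a zero-resistance root makes the two daughters independent circuits
        root = vessel_with_resistance(1e-12, sid="root")
        a = vessel_with_resistance(4.0, sid="a", parent="root")
        b = vessel_with_resistance(8.0, sid="b", parent="root")
        tree = CoronaryTree(segments={"root": root, "a": a, "b": b})
        r_j = {"a": 18.0 * MMHG_S_ML_TO_SI, "b": 36.0 * MMHG_S_ML_TO_SI}
        flows = direct_solve_linear(tree, 88.0, r_j)
        assert flows.outlet_flows["a"] / MLS_TO_M3S == pytest.approx(4.0, rel=1e-6)
        assert flows.outlet_flows["b"] / MLS_TO_M3S == pytest.approx(2.0, rel=1e-6)


class TestHyperemiaPhysiology:
    def test_flow_ratio_limits_to_088_over_023(self, blood, physiology):
        """With epicardial resistance ≪ microcirculation resistance the
        hyperemic/resting total-flow ratio approaches 0.88/0.23."""
        tree = CoronaryTree(segments={"root": vessel_with_resistance(1e-6)})
        resting = distribute_flow(tree, 2.8e-6)
        _, flows, report, _ = solve_hyperemic(tree, physiology)
        ratio = flows.q_total / resting.q_total
        assert ratio == pytest.approx(0.88 / 0.23, rel=1e-3)

    def test_stenosis_strictly_reduces_hyperemic_flow(self, asymmetric_tree, physiology):
        _, healthy, _, _ = solve_hyperemic(asymmetric_tree, physiology)
        stenosed = asymmetric_tree.with_stenoses([
            Stenosis(segment="lad", start=0.01, length=0.005, severity=0.5,
                     ref_diameter=0.003)])
        _, sten, _, _ = solve_hyperemic(stenosed, physiology)
        assert sten.q_total < healthy.q_total
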