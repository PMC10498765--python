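"""FFR extraction for both methods, measurement convention, profiles."""

import numpy as np
import pytest

from conftest import vessel_with_resistance
from ffrnet import (CoronaryTree, InputError, PatientPhysiology, Segment,
                    SolverSettings, Stenosis, ffr_d, ffr_u, network_pressures,
                    pressure_profile, solve_hyperemic)
from ffrnet.ffr import ffrd_total_flow
from ffrnet.tree_model import scale_stenosis
from ffrnet.units import MLS_TO_M3S, MMHG_S_ML_TO_SI


def long_stenosed_vessel(severity=0.5):
    """12 cm uniform vessel, lesion ending 4 cm in: room for the 3 cm offset."""
    seg = Segment(id="root", length=0.12, d_prox=0.003, d_dist=0.003)
    st = Stenosis(segment="root", start=0.035, length=0.005, severity=severity,
                  ref_diameter=0.003)
    return CoronaryTree(segments={"root": seg}, stenoses=[st])


class TestFFRU:
    def test_healthy_zero_resistance_gives_unity(self, physiology):
        tree = CoronaryTree(
            segments={"root": vessel_with_resistance(1e-9)},
            stenoses=[Stenosis(segment="root", start=0.0, length=1e-6,
                               severity=1e-9, ref_diameter=0.003)])
        res = ffr_u(tree, physiology)
        assert res[0].ffr == pytest.approx(1.0, abs=1e-9)

    def test_no_stenosis_returns_empty(self, asymmetric_tree, physiology):
        assert ffr_u(asymmetric_tree, physiology) == []

    def test_single_outlet_closed_form(self):
        """P0=88, R_e=4, R_j=18 mmHg·s/mL → Q*=4 mL/s, FFR at outlet 72/88."""
        seg = vessel_with_resistance(4.0)
        # lesion spanning nearly the whole vessel so the measurement point
        # clips to the outlet (fallback)
        st = Stenosis(segment="root", start=0.0, length=seg.length * 0.99,
                      severity=1e-12, ref_diameter=0.003)
        tree = CoronaryTree(segments={"root": seg}, stenoses=[st])
        from ffrnet import identify_hyperemic_flows
        flows, rep = identify_hyperemic_flows(tree, 88.0,
                                              {"root": 18.0 * MMHG_S_ML_TO_SI},
                                              SolverSettings(tolerance=1e-9))
        field = network_pressures(tree, flows.outlet_flows, 88.0)
        assert field.p_dist["root"] / field.p0_pa == pytest.approx(72.0 / 88.0, rel=1e-6)

    def test_measurement_point_3cm_past_lesion(self, physiology):
        tree = long_stenosed_vessel()
        res = ffr_u(tree, physiology)[0]
        assert res.position == pytest.approx(0.04 + 0.03)
        assert not res.fallback
        assert 0 < res.ffr <= 1

    def test_short_vessel_fallback_flagged(self, physiology):
        seg = Segment(id="root", length=0.05, d_prox=0.003, d_dist=0.003)
        st = Stenosis(segment="root", start=0.03, length=0.01, severity=0.5,
                      ref_diameter=0.003)
        tree = CoronaryTree(segments={"root": seg}, stenoses=[st])
        res = ffr_u(tree, physiology)[0]
        assert res.fallback
        assert res.position == pytest.approx(0.05)

    def test_severity_sweep_strictly_decreasing(self, physiology):
        base = long_stenosed_vessel().stenoses[0]
        tree = long_stenosed_vessel()
        ffrs = []
        for sev in np.linspace(0.05, 0.9, 8):
            t = tree.with_stenoses([scale_stenosis(base, float(sev))])
            ffrs.append(ffr_u(t, physiology, flow_solver="direct")[0].ffr)
        assert all(b < a for a, b in zip(ffrs, ffrs[1:]))

    def test_increasing_severity_never_raises_downstream_pressure(
            self, asymmetric_tree, physiology):
        mk = lambda sev: asymmetric_tree.with_stenoses([
            Stenosis(segment="lad", start=0.01, length=0.005, severity=sev,
                     ref_diameter=0.003)])
        f1, _, _, _ = solve_hyperemic(mk(0.3), physiology)
        f2, _, _, _ = solve_hyperemic(mk(0.6), physiology)
        for sid in ("lad", "d1", "lad2"):
            assert f2.p_dist[sid] <= f1.p_dist[sid]

    def test_fixed_point_and_direct_agree(self, physiology):
        tree = long_stenosed_vessel(0.6)
        a = ffr_u(tree, physiology, settings=SolverSettings(tolerance=1e-9))[0].ffr
        b = ffr_u(tree, physiology, flow_solver="direct")[0].ffr
        assert a == pytest.approx(b, rel=1e-6)

    def test_unconverged_result_is_flagged(self, physiology):
        tree = long_stenosed_vessel(0.8)
        res = ffr_u(tree, physiology,
                    settings=SolverSettings(max_iter=2, adaptive_alpha=False))[0]
        assert not res.converged


class TestFFRD:
    def test_requires_mass_and_heart_rate(self, physiology):
        incomplete = PatientPhysiology(p_systolic=120, p_diastolic=80,
                                       cardiac_output=4.2)
        with pytest.raises(InputError, match="myocardial_mass"):
            ffr_d(long_stenosed_vessel(), incomplete)

    def test_healthy_zero_resistance_gives_unity(self, physiology):
        tree = CoronaryTree(
            segments={"root": vessel_with_resistance(1e-9)},
            stenoses=[Stenosis(segment="root", start=0.0, length=1e-6,
                               severity=1e-9, ref_diameter=0.003)])
        assert ffr_d(tree, physiology)[0].ffr == pytest.approx(1.0, abs=1e-9)

    def test_fixed_flow_reproduces_network_arithmetic(self, physiology):
        """With the flow pinned at 4 mL/s on R_e = 4 mmHg·s/mL and the inlet
        at 88 mmHg, FFR at the outlet is 72/88 — the same arithmetic as the
        coupled method's closed form."""
        seg = vessel_with_resistance(4.0)
        st = Stenosis(segment="root", start=0.0, length=seg.length * 0.99,
                      severity=1e-12, ref_diameter=0.003)
        tree = CoronaryTree(segments={"root": seg}, stenoses=[st])
        phys = PatientPhysiology(p_systolic=88, p_diastolic=88 - 1e-9,
                                 cardiac_output=4.2, heart_rate=68,
                                 myocardial_mass=142.5)
        res = ffr_d(tree, phys, q_total=4.0 * MLS_TO_M3S)[0]
        assert res.ffr == pytest.approx(72.0 / 88.0, rel=1e-9)

    def test_underestimates_ffr_on_severe_stenosis(self, physiology):
        """Without stenosis–flow coupling the comparator pushes the healthy
        flow through the lesion, so FFR_D < FFR_U for a severe stenosis."""
        tree = long_stenosed_vessel(0.8)
        fu = ffr_u(tree, physiology, settings=SolverSettings(tolerance=1e-8))[0].ffr
        fd = ffr_d(tree, physiology)[0].ffr
        assert fd < fu

    def test_total_flow_formula_scales_with_mass(self):
        assert ffrd_total_flow(200.0) > ffrd_total_flow(100.0)
        # hyperemia scaling is the 0.88/0.23 clinical ratio by default
        assert ffrd_total_flow(142.5, hyperemia_factor=1.0) * (0.88 / 0.23) == \
            pytest.approx(ffrd_total_flow(142.5))

    def test_diastolic_inlet_option(self, physiology):
        tree = long_stenosed_vessel(0.5)
        mean_res = ffr_d(tree, physiology)[0]
        dia_res = ffr_d(tree, physiology, inlet_pressure="diastolic")[0]
        assert mean_res.p_a == pytest.approx(93.3333, abs=1e-3)
        assert dia_res.p_a == pytest.approx(80.0)


class TestPressureProfile:
    def test_constant_profile_zero_resistance(self, physiology):
        tree = CoronaryTree(segments={"root": vessel_with_resistance(1e-9)})
        field, _, _, _ = solve_hyperemic(tree, physiology)
        prof = pressure_profile(field, ["root"])
        assert prof["ffr"].min() == pytest.approx(1.0, abs=1e-9)

    def test_linear_decline_uniform_vessel(self, physiology):
        tree = CoronaryTree(segments={
            "root": Segment(id="root", length=0.1, d_prox=0.003, d_dist=0.003)})
        field, _, _, _ = solve_hyperemic(tree, physiology)
        prof = pressure_profile(field, ["root"])
        # pressure linear in arc length: residual of a linear fit ~ 0
        coeffs = np.polyfit(prof["arc_position"], prof["pressure_mmhg"], 1)
        fit = np.polyval(coeffs, prof["arc_position"])
        assert np.abs(prof["pressure_mmhg"] - fit).max() < 1e-9
        assert coeffs[0] < 0

    def test_profile_endpoint_matches_nodal_pressure(self, physiology):
        tree = long_stenosed_vessel()
        field, _, _, _ = solve_hyperemic(tree, physiology)
        prof = pressure_profile(field, ["root"])
        assert prof["pressure_mmhg"].iloc[-1] * 133.322 == pytest.approx(
            field.p_dist["root"], rel=1e-12)
        assert prof["arc_position"].is_monotonic_increasing

    def test_ffr_monotone_decreasing_along_path(self, physiology):
        tree = long_stenosed_vessel(0.7)
        field, _, _, _ = solve_hyperemic(tree, physiology)
        prof = pressure_profile(field, ["root"])
        diffs = np.diff(prof["ffr"].to_numpy())
        assert (diffs <= 1e-15).all()
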