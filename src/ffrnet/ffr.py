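"""FFR extraction: the coupled-boundary-condition estimate and the
diameter-flow comparator.

FFR_U pipeline (per patient): mean aortic pressure → resting coronary flow
(4% of cardiac output) → allometric distribution over the outlets →
resting microcirculation calibration → hyperemia transforms (inlet pressure
×0.88, microcirculation ×0.23) → under-relaxed fixed-point identification
of hyperemic outlet flows with stenotic resistance included → pressure
field → FFR = P_d / P_a, with P_d sampled 3 cm downstream of each lesion's
distal shoulder (staying on the same branch; clipped and flagged at branch
ends) and P_a the hyperemic inlet pressure.

FFR_D comparator: total hyperemic flow from an empirical allometric
myocardial-mass formula, distributed over the HEALTHY tree by the same
power law, with NO stenosis–flow coupling — one forward pressure pass.
The total-flow formula shipped here (Q_rest = k·M^0.75, k configurable) is
a documented stand-in for the method's unpublished empirical constant, and
is recorded in each result's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bc_solver import (ConvergenceReport, PressureField, SolverSettings,
                        direct_solve_linear, identify_hyperemic_flows,
                        network_pressures)
from .errors import InputError
from .physiology import (FlowAssignment, distribute_flow, pressures_for,
                         total_coronary_flow,
                         HYPEREMIA_PRESSURE_DROP, HYPEREMIA_RESISTANCE_FACTOR)
from .resistance import BloodProperties, calibrate_microcirculation
from .tree_model import CoronaryTree, PatientPhysiology, Stenosis
from .units import PA_TO_MMHG

#: Distance downstream of the lesion's distal shoulder where FFR is read, m.
MEASUREMENT_OFFSET = 0.03

#: Stand-in constant of the diameter-flow method's empirical total-flow
#: formula: resting coronary flow in mL/min = FFRD_K * mass_g**0.75.
FFRD_K = 4.0
FFRD_MASS_EXPONENT = 0.75


@dataclass(frozen=True)
class FFRResult:
    """One lesion's FFR estimate with its measurement context."""

    lesion_id: str
    method: str                  # "FFR_U" or "FFR_D"
    ffr: float
    p_d: float                   # mmHg, at measurement point
    p_a: float                   # mmHg, inlet reference
    segment: str                 # segment carrying the measurement point
    position: float              # arc position of the measurement, m
    fallback: bool = False       # True if < 3 cm of vessel remained distal
    converged: bool = True
    report: ConvergenceReport | None = field(default=None, compare=False)
    metadata: dict = field(default_factory=dict, compare=False)


def _measurement_point(tree: CoronaryTree, lesion: Stenosis) -> tuple[str, float, bool]:
    """3 cm past the lesion's distal shoulder on the same branch, clipped."""
    seg = tree.segments[lesion.segment]
    s = lesion.end + MEASUREMENT_OFFSET
    if s > seg.length:
        return seg.id, seg.length, True
    return seg.id, s, False


def _extract(tree: CoronaryTree, field_: PressureField, p_a_pa: float, method: str,
             converged: bool, report: ConvergenceReport | None,
             metadata: dict) -> list[FFRResult]:
    results = []
    for idx, lesion in enumerate(tree.stenoses):
        sid, s, fb = _measurement_point(tree, lesion)
        p_d_pa = field_.pressure_at(sid, s)
        results.append(FFRResult(
            lesion_id=f"{lesion.segment}:{idx}", method=method,
            ffr=p_d_pa / p_a_pa, p_d=p_d_pa * PA_TO_MMHG, p_a=p_a_pa * PA_TO_MMHG,
            segment=sid, position=s, fallback=fb, converged=converged,
            report=report, metadata=metadata))
    return results


def solve_hyperemic(
    tree: CoronaryTree,
    physiology: PatientPhysiology,
    blood: BloodProperties | None = None,
    settings: SolverSettings | None = None,
    flow_solver: str = "fixed_point",
) -> tuple[PressureField, FlowAssignment, ConvergenceReport | None, float]:
    """Run the full boundary-condition chain; returns (field, flows, report, P0 mmHg).

    ``flow_solver`` may be "fixed_point" (the coupled iteration) or "direct"
    (the exact linear solve; linear stenosis model only).
    """
    blood = blood or BloodProperties()
    settings = settings or SolverSettings()
    pset = pressures_for(physiology)
    q_total = total_coronary_flow(physiology.cardiac_output)
    resting = distribute_flow(tree, q_total)
    rmap = calibrate_microcirculation(tree, pset.p_mbp, resting, blood)
    if flow_solver == "direct":
        if settings.stenosis_model != "linear":
            raise InputError("direct solver requires the linear stenosis model")
        flows = direct_solve_linear(tree, pset.p0, rmap.micro_hyperemic, blood)
        report = None
        converged = True
    elif flow_solver == "fixed_point":
        flows, report = identify_hyperemic_flows(
            tree, pset.p0, rmap.micro_hyperemic, settings, blood, resting)
        converged = report.converged
    else:
        raise InputError(f"unknown flow_solver {flow_solver!r}")
    field_ = network_pressures(tree, flows.outlet_flows, pset.p0, blood,
                               settings.stenosis_model)
    field_.converged = converged  # type: ignore[attr-defined]
    return field_, flows, report, pset.p0


def ffr_u(
    tree: CoronaryTree,
    physiology: PatientPhysiology,
    blood: BloodProperties | None = None,
    settings: SolverSettings | None = None,
    flow_solver: str = "fixed_point",
) -> list[FFRResult]:
    """FFR via coupled boundary-condition identification, one result per lesion.

    An unconverged solve is returned flagged (``converged=False``), never
    silently; a tree without stenoses yields an empty list.
    """
    field_, flows, report, p0 = solve_hyperemic(
        tree, physiology, blood, settings, flow_solver)
    converged = report.converged if report is not None else True
    meta = {"flow_solver": flow_solver,
            "hyperemia": {"pressure_drop": HYPEREMIA_PRESSURE_DROP,
                          "resistance_factor": HYPEREMIA_RESISTANCE_FACTOR}}
    return _extract(tree, field_, field_.p0_pa, "FFR_U", converged, report, meta)


def ffrd_total_flow(myocardial_mass: float, k: float = FFRD_K,
                    exponent: float = FFRD_MASS_EXPONENT,
                    hyperemia_factor: float | None = None) -> float:
    """Hyperemic total coronary flow (m³/s) of the diameter-flow comparator.

    Resting flow k·M^exponent mL/min scaled to hyperemia by
    (1 − 0.12)/0.23 by default.
    """
    if hyperemia_factor is None:
        hyperemia_factor = (1.0 - HYPEREMIA_PRESSURE_DROP) / HYPEREMIA_RESISTANCE_FACTOR
    q_rest_ml_min = k * myocardial_mass ** exponent
    return q_rest_ml_min * 1e-6 / 60.0 * hyperemia_factor


def ffr_d(
    tree: CoronaryTree,
    physiology: PatientPhysiology,
    blood: BloodProperties | None = None,
    settings: SolverSettings | None = None,
    q_total: float | None = None,
    inlet_pressure: str = "mean",
) -> list[FFRResult]:
    """Diameter-flow comparator: fixed outlet flows, one pressure pass.

    Requires myocardial mass and heart rate in the physiology record.
    ``q_total`` (m³/s) overrides the empirical formula when given.
    ``inlet_pressure`` is "mean" (default) or "diastolic".
    """
    settings = settings or SolverSettings()
    blood = blood or BloodProperties()
    if physiology.myocardial_mass is None or physiology.heart_rate is None:
        raise InputError("FFR_D requires myocardial_mass and heart_rate")
    if q_total is None:
        q_total = ffrd_total_flow(physiology.myocardial_mass)
    if inlet_pressure == "mean":
        p_a = pressures_for(physiology).p_mbp
    elif inlet_pressure == "diastolic":
        p_a = physiology.p_diastolic
    else:
        raise InputError(f"unknown inlet_pressure {inlet_pressure!r}")
    # distribution ignores stenoses by construction (healthy diameters)
    flows = distribute_flow(tree, q_total, state="hyperemic")
    field_ = network_pressures(tree, flows.outlet_flows, p_a, blood,
                               settings.stenosis_model)
    meta = {"q_total_m3s": q_total, "inlet_pressure": inlet_pressure,
            "flow_formula": f"{FFRD_K}*M^{FFRD_MASS_EXPONENT} mL/min (stand-in)"}
    return _extract(tree, field_, field_.p0_pa, "FFR_D", True, None, meta)


def pressure_profile(field_: PressureField, path: list[str],
                     samples_per_segment: int = 25):
    """Sampled (arc position from root, pressure, FFR) along a root path.

    Returns a pandas DataFrame; the FFR column is pressure / inlet pressure.
    Lesion edges are included as sample points so focal drops are sharp.
    """
    import pandas as pd
    from .tree_model import effective_intervals

    rows = []
    offset = 0.0
    for sid in path:
        seg = field_.tree.segments[sid]
        breaks = {0.0, seg.length}
        for s0, s1, _, _ in effective_intervals(seg, field_.tree.stenoses_on(sid)):
            breaks.update((s0, s1))
        breaks.update(i * seg.length / samples_per_segment
                      for i in range(samples_per_segment + 1))
        for s in sorted(breaks):
            p = field_.pressure_at(sid, s)
            rows.append({"arc_position": offset + s, "segment": sid,
                         "pressure_mmhg": p * PA_TO_MMHG,
                         "ffr": p / field_.p0_pa})
        offset += seg.length
    return pd.DataFrame(rows)
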