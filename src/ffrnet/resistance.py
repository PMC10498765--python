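"""Epicardial Poiseuille resistances and resting microcirculation calibration.

A branch's baseline resistance is the Ohm-analogy Poiseuille form

    R = 8 π μ L / A²,   A = (A_inlet + A_outlet) / 2,

which for a uniform tube equals the textbook 128 μ L / (π d⁴). When a
diameter profile or stenosis annotations are present the same form is
applied piecewise over the profile intervals, so a focal lesion produces a
localized resistance and a flat profile reduces to the closed form exactly.

Microcirculation resistances are calibrated at rest: walking each
root→outlet path stepwise proximal→distal, the drop across a segment is
ΔP = R·Q with Q the conserved through-flow, the microcirculation inlet
pressure at outlet i is P_i = P_MBP − Σ ΔP, and R_i = P_i / Q_i (venous
pressure taken as zero). Calibration uses the healthy geometry: epicardial
stenosis severity does not affect minimal microvascular resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import CalibrationError, SingularGeometryError
from .physiology import FlowAssignment, hyperemia_resistance
from .tree_model import (CoronaryTree, Segment, Stenosis, effective_intervals,
                         path_to_root, segment_mean_area)
from .units import MMHG_TO_PA

#: Young–Tsai-style sudden-expansion loss coefficient for the optional
#: nonlinear stenosis term.
K_T_DEFAULT = 1.52


@dataclass(frozen=True)
class BloodProperties:
    """Newtonian blood: dynamic viscosity (Pa·s) and density (kg/m³)."""

    viscosity: float = 0.0035
    density: float = 1050.0

    def __post_init__(self) -> None:
        if not (self.viscosity > 0 and self.density > 0):
            raise SingularGeometryError("blood properties must be positive")


@dataclass
class ResistanceMap:
    """Per-segment epicardial and per-outlet microcirculation resistances (SI)."""

    segment: dict[str, float] = field(default_factory=dict)
    micro_resting: dict[str, float] = field(default_factory=dict)
    micro_hyperemic: dict[str, float] = field(default_factory=dict)
    micro_inlet_pressure: dict[str, float] = field(default_factory=dict)  # Pa, resting


def _poiseuille_interval(mu: float, length: float, d0: float, d1: float) -> float:
    """8πμΔL/A² with the two-point mean area of the interval."""
    if d0 <= 0 or d1 <= 0:
        raise SingularGeometryError(f"non-positive lumen diameter ({d0}, {d1})")
    area = 0.5 * (math.pi * d0 * d0 / 4.0 + math.pi * d1 * d1 / 4.0)
    return 8.0 * math.pi * mu * length / (area * area)


def segment_resistance(segment: Segment, blood: BloodProperties) -> float:
    """Baseline (healthy) resistance of a segment in Pa·s/m³.

    Without a profile this is the closed form on the two-point mean area;
    with a profile it is the piecewise sum over profile intervals.
    """
    if segment.diameter_profile is None:
        area = segment_mean_area(segment)
        if area <= 0:
            raise SingularGeometryError(f"zero mean area on segment {segment.id!r}")
        return 8.0 * math.pi * blood.viscosity * segment.length / (area * area)
    return sum(
        _poiseuille_interval(blood.viscosity, s1 - s0, d0, d1)
        for s0, s1, d0, d1 in effective_intervals(segment)
    )


def partial_resistance(segment: Segment, stenoses: Sequence[Stenosis],
                       blood: BloodProperties, s_end: float) -> float:
    """Resistance of the stenosis-modified lumen from arc 0 up to ``s_end``."""
    total = 0.0
    for s0, s1, d0, d1 in effective_intervals(segment, stenoses):
        if s0 >= s_end:
            break
        hi = min(s1, s_end)
        if hi <= s0:
            continue
        t = (hi - s0) / (s1 - s0)
        d_hi = (1.0 - t) * d0 + t * d1
        total += _poiseuille_interval(blood.viscosity, hi - s0, d0, d_hi)
    return total


def stenosis_effective_resistance(
    segment: Segment,
    stenoses: Sequence[Stenosis],
    blood: BloodProperties,
    q: float | None = None,
    k_t: float = K_T_DEFAULT,
) -> float:
    """Resistance of a segment with its lesions applied, in Pa·s/m³.

    Linear mode (``q is None``): piecewise Poiseuille over the
    stenosis-modified diameter profile; with no lesions this equals
    :func:`segment_resistance`. Nonlinear mode adds, per lesion, a
    sudden-expansion loss ΔP = k_t · ρ/(2 A₀²) · (A₀/A_s − 1)² · Q²
    (A₀ reference lumen, A_s lesion lumen) folded in as ΔP/Q, so it
    vanishes as Q → 0.
    """
    stenoses = [st for st in stenoses if st.segment == segment.id]
    if not stenoses:
        return segment_resistance(segment, blood)
    r = sum(_poiseuille_interval(blood.viscosity, s1 - s0, d0, d1)
            for s0, s1, d0, d1 in effective_intervals(segment, stenoses))
    if q is not None and q > 0:
        for st in stenoses:
            a0 = math.pi * st.ref_diameter ** 2 / 4.0
            a_s = math.pi * st.lesion_diameter ** 2 / 4.0
            if a_s <= 0:
                raise SingularGeometryError(
                    f"stenosis on {segment.id!r} closes the lumen")
            dp = k_t * blood.density / (2.0 * a0 * a0) * (a0 / a_s - 1.0) ** 2 * q * q
            r += dp / q
    return r


def through_flows(tree: CoronaryTree, outlet_flows: dict[str, float]) -> dict[str, float]:
    """Conserved through-flow per segment: sum of its descendant outlet flows."""
    flows: dict[str, float] = {}
    def visit(sid: str) -> float:
        kids = tree.children(sid)
        q = outlet_flows[sid] if not kids else sum(visit(k) for k in kids)
        flows[sid] = q
        return q
    visit(tree.root)
    return flows


def calibrate_microcirculation(
    tree: CoronaryTree,
    p_mbp: float,
    resting: FlowAssignment,
    blood: BloodProperties,
    hyperemia_factor: float | None = None,
) -> ResistanceMap:
    """Resting microcirculation resistance per outlet (and hyperemic, scaled).

    ``p_mbp`` is in mmHg. Epicardial drops use the HEALTHY geometry. Raises
    :class:`CalibrationError` naming the outlet if any microcirculation
    inlet pressure comes out non-positive.
    """
    p_mbp_pa = p_mbp * MMHG_TO_PA
    rmap = ResistanceMap()
    for seg in tree.segments.values():
        rmap.segment[seg.id] = segment_resistance(seg, blood)
    q_through = through_flows(tree, resting.outlet_flows)

    for outlet in tree.outlets:
        drop = sum(rmap.segment[sid] * q_through[sid] for sid in path_to_root(tree, outlet))
        p_i = p_mbp_pa - drop
        if p_i <= 0:
            raise CalibrationError(
                f"outlet {outlet!r}: microcirculation inlet pressure "
                f"{p_i / MMHG_TO_PA:.2f} mmHg is non-positive")
        q_s = resting.outlet_flows[outlet]
        rmap.micro_inlet_pressure[outlet] = p_i
        rmap.micro_resting[outlet] = p_i / q_s
    if hyperemia_factor is None:
        rmap.micro_hyperemic = {o: hyperemia_resistance(r)
                                for o, r in rmap.micro_resting.items()}
    else:
        rmap.micro_hyperemic = {o: hyperemia_resistance(r, hyperemia_factor)
                                for o, r in rmap.micro_resting.items()}
    return rmap
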