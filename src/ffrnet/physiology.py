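"""Patient physiology → coronary flow, its distribution, hyperemia transforms.

Resting total coronary flow is taken as a fixed fraction (default 4%) of
cardiac output. The flow is pushed down the tree with an allometric
power-law split: at each junction a daughter of effective diameter D takes a
share proportional to D**exponent, with exponent 7/3 by default (the
form-follows-function scaling between branch flow and branch diameter).
The raw daughter/parent power-law ratios need not sum to one, so shares are
normalized at each junction — flow is conserved exactly.

Hyperemia (adenosine) is modelled by two clinical statistics: mean aortic
pressure drops by 12% and microcirculatory resistance falls to 0.23 of its
resting value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError
from .tree_model import CoronaryTree, Segment
from .units import LMIN_TO_M3S

#: Default configuration, overridable per call.
FLOW_FRACTION = 0.04            # resting coronary flow as fraction of cardiac output
FLOW_EXPONENT = 7.0 / 3.0       # allometric flow–diameter exponent
HYPEREMIA_PRESSURE_DROP = 0.12  # fractional fall of mean pressure at hyperemia
HYPEREMIA_RESISTANCE_FACTOR = 0.23  # hyperemic / resting microcirculation resistance


@dataclass(frozen=True)
class FlowAssignment:
    """Inlet flow and its per-outlet split, all in m³/s."""

    q_total: float
    outlet_flows: dict[str, float]
    state: str = "resting"  # or "hyperemic"

    def __post_init__(self) -> None:
        if self.q_total <= 0 or any(q <= 0 for q in self.outlet_flows.values()):
            raise DomainError("all flows must be positive")


@dataclass(frozen=True)
class PressureSet:
    """Resting mean and hyperemic inlet pressures, mmHg."""

    p_mbp: float
    p0: float
    source: object = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.p0 < self.p_mbp:
            raise DomainError(f"require 0 < P0 < P_MBP, got ({self.p0}, {self.p_mbp})")


def mean_blood_pressure(p_systolic: float, p_diastolic: float) -> float:
    """Mean aortic pressure (P_sys + 2 P_dia)/3, mmHg in → mmHg out."""
    if not p_systolic >= p_diastolic or not p_diastolic > 0:
        raise DomainError(
            f"require systolic >= diastolic > 0, got ({p_systolic}, {p_diastolic})")
    return (p_systolic + 2.0 * p_diastolic) / 3.0


def total_coronary_flow(cardiac_output: float, fraction: float = FLOW_FRACTION) -> float:
    """Resting coronary flow in m³/s from cardiac output in L/min."""
    if not cardiac_output > 0:
        raise DomainError(f"cardiac output must be > 0, got {cardiac_output}")
    return fraction * cardiac_output * LMIN_TO_M3S


def _effective_diameter(seg: Segment, convention: str) -> float:
    if convention == "proximal":
        return seg.d_prox
    if convention == "mean":
        return 0.5 * (seg.d_prox + seg.d_dist)
    raise DomainError(f"unknown effective-diameter convention {convention!r}")


def distribute_flow(
    tree: CoronaryTree,
    q_total: float,
    exponent: float = FLOW_EXPONENT,
    effective_diameter: str = "proximal",
    state: str = "resting",
) -> FlowAssignment:
    """Split ``q_total`` over the outlets by the allometric power law.

    At each junction daughter k receives ``Q_parent * D_k**exponent /
    sum_m D_m**exponent``. Diameters are read from the healthy geometry —
    stenosis annotations do not redistribute resting flow (epicardial
    severity does not alter minimal microvascular resistance). Flow is
    conserved exactly at every junction; a single child passes all flow
    through.
    """
    if not q_total > 0:
        raise DomainError(f"q_total must be > 0, got {q_total}")
    through: dict[str, float] = {tree.root: q_total}
    stack = [tree.root]
    while stack:
        sid = stack.pop()
        kids = tree.children(sid)
        if not kids:
            continue
        q_parent = through[sid]
        if len(kids) == 1:
            through[kids[0]] = q_parent
        else:
            diams = [_effective_diameter(tree.segments[k], effective_diameter)
                     for k in kids]
            d_ref = max(diams)  # normalize before powering: huge exponents stay finite
            weights = [(d / d_ref) ** exponent for d in diams]
            total = sum(weights)
            qs = [q_parent * w / total for w in weights]
            # absorb the rounding remainder into the largest share so the
            # split sums exactly to the parent flow and no share hits zero
            imax = max(range(len(qs)), key=qs.__getitem__)
            qs[imax] = q_parent - sum(q for i, q in enumerate(qs) if i != imax)
            for k, q in zip(kids, qs):
                through[k] = q
        stack.extend(kids)
    return FlowAssignment(q_total=q_total,
                          outlet_flows={o: through[o] for o in tree.outlets},
                          state=state)


def hyperemia_pressure(p_mbp: float, drop: float = HYPEREMIA_PRESSURE_DROP) -> float:
    """Hyperemic inlet pressure: mean pressure reduced by ``drop`` (default 12%)."""
    if p_mbp < 0:
        raise DomainError(f"pressure must be >= 0, got {p_mbp}")
    return (1.0 - drop) * p_mbp


def hyperemia_resistance(r_resting: float,
                         factor: float = HYPEREMIA_RESISTANCE_FACTOR) -> float:
    """Hyperemic microcirculation resistance, ``factor`` × resting (default 0.23)."""
    if r_resting < 0:
        raise DomainError(f"resistance must be >= 0, got {r_resting}")
    return factor * r_resting


def pressures_for(physiology, drop: float = HYPEREMIA_PRESSURE_DROP) -> PressureSet:
    """Resting mean and hyperemic inlet pressure for a patient."""
    p_mbp = mean_blood_pressure(physiology.p_systolic, physiology.p_diastolic)
    return PressureSet(p_mbp=p_mbp, p0=hyperemia_pressure(p_mbp, drop), source=physiology)
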