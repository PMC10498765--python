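"""Hyperemic outlet-flow identification by under-relaxed fixed-point coupling.

The unknowns are the hyperemic outlet flows Q_j. Stenotic epicardial
resistance, microcirculation resistance R_j and the hyperemic inlet
pressure P0 are coupled: each outlet pressure P_j follows from the network
pressure solve at the current flows, and the flows are updated with the
damped scheme

    Q_j ← (1 − α) Q_j + α P_j / R_j,

iterated until the per-outlet matching condition — epicardial pressure
drops plus the microcirculatory drop Q_j R_j balance the inlet pressure —
holds to a dimensionless residual max_j |P_j − Q_j R_j| / P0 ≤ tol
(default 1e-4). Because P_j = P0 − Σ path drops, this residual is exactly
|P0 − (Σ drops + Q_j R_j)| / P0.

For the linear (flow-independent) stenosis model the same fixed point is
also available as one exact linear solve (:func:`direct_solve_linear`),
which serves as the solver's oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, SingularGeometryError
from .physiology import FlowAssignment
from .resistance import (BloodProperties, partial_resistance,
                         stenosis_effective_resistance, through_flows)
from .tree_model import CoronaryTree, path_to_root
from .units import MMHG_TO_PA

logger = logging.getLogger(__name__)

_FLOW_EPS = 1e-12  # m³/s; clip for transiently negative iterates


@dataclass(frozen=True)
class SolverSettings:
    """Under-relaxation and stopping controls for the fixed-point solver."""

    alpha: float = 0.3
    tolerance: float = 1e-4
    max_iter: int = 10000
    init: str = "resting"        # or "uniform"
    stenosis_model: str = "linear"   # or "nonlinear"
    eq10_literal: bool = False   # keep the literal printed pressure update
    adaptive_alpha: bool = True  # halve alpha after sustained residual growth

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise DomainError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.tolerance > 0:
            raise DomainError(f"tolerance must be > 0, got {self.tolerance}")


@dataclass
class ConvergenceReport:
    iterations: int = 0
    final_residual: float = float("nan")
    residual_history: list[float] = field(default_factory=list)
    converged: bool = False
    alpha_final: float = float("nan")


class PressureField:
    """Nodal pressures of one network solve; supports arc-position queries."""

    def __init__(self, tree: CoronaryTree, outlet_flows: dict[str, float],
                 p0_pa: float, blood: BloodProperties, stenosis_model: str):
        self.tree = tree
        self.blood = blood
        self.p0_pa = p0_pa
        self.stenosis_model = stenosis_model
        self.q_through = through_flows(tree, outlet_flows)
        self.r_eff: dict[str, float] = {}
        for sid, seg in tree.segments.items():
            q = self.q_through[sid] if stenosis_model == "nonlinear" else None
            self.r_eff[sid] = stenosis_effective_resistance(
                seg, tree.stenoses_on(sid), blood, q=q)
        self.p_prox: dict[str, float] = {}
        self.p_dist: dict[str, float] = {}
        stack = [tree.root]
        while stack:
            sid = stack.pop()
            seg = tree.segments[sid]
            p_in = p0_pa if seg.parent is None else self.p_dist[seg.parent]
            self.p_prox[sid] = p_in
            self.p_dist[sid] = p_in - self.r_eff[sid] * self.q_through[sid]
            stack.extend(tree.children(sid))

    def outlet_pressures(self) -> dict[str, float]:
        return {o: self.p_dist[o] for o in self.tree.outlets}

    def pressure_at(self, segment_id: str, s: float) -> float:
        """Pressure (Pa) at arc position ``s`` along a segment.

        The nonlinear expansion loss, when active, is lumped at the lesion
        and accrues with the Poiseuille fraction of the segment drop.
        """
        seg = self.tree.segments[segment_id]
        stenoses = self.tree.stenoses_on(segment_id)
        r_part = partial_resistance(seg, stenoses, self.blood, s)
        r_lin = partial_resistance(seg, stenoses, self.blood, seg.length)
        r_total = self.r_eff[segment_id]
        frac = r_part / r_lin if r_lin > 0 else 0.0
        return self.p_prox[segment_id] - frac * r_total * self.q_through[segment_id]


def network_pressures(tree: CoronaryTree, outlet_flows: dict[str, float],
                      p0: float, blood: BloodProperties | None = None,
                      stenosis_model: str = "linear") -> PressureField:
    """Forward 0D pressure solve: ``p0`` in mmHg, given outlet flows in m³/s.

    Segment through-flows follow from conservation; each node pressure is
    the inlet pressure minus the accumulated R_eff·Q drops along its root
    path, stenosis overrides included.
    """
    if p0 <= 0:
        raise DomainError(f"inlet pressure must be > 0, got {p0}")
    blood = blood or BloodProperties()
    return PressureField(tree, outlet_flows, p0 * MMHG_TO_PA, blood, stenosis_model)


def _initial_flows(tree: CoronaryTree, settings: SolverSettings,
                   resting: FlowAssignment | None, p0_pa: float,
                   r_micro: dict[str, float]) -> dict[str, float]:
    outlets = tree.outlets
    if settings.init == "resting" and resting is not None:
        return dict(resting.outlet_flows)
    # uniform start: each outlet as if alone against its microcirculation
    return {o: p0_pa / r_micro[o] / len(outlets) for o in outlets}


def identify_hyperemic_flows(
    tree: CoronaryTree,
    p0: float,
    r_micro: dict[str, float],
    settings: SolverSettings | None = None,
    blood: BloodProperties | None = None,
    resting: FlowAssignment | None = None,
) -> tuple[FlowAssignment, ConvergenceReport]:
    """Identify hyperemic outlet flows by the under-relaxed fixed point.

    ``p0`` is the hyperemic inlet pressure (mmHg), ``r_micro`` the hyperemic
    microcirculation resistance per outlet (Pa·s/m³). Returns the flow
    assignment and a convergence report; non-convergence is reported, not
    raised. Iteration order over outlets is sorted ids, so runs are
    bit-reproducible.
    """
    settings = settings or SolverSettings()
    blood = blood or BloodProperties()
    p0_pa = p0 * MMHG_TO_PA
    outlets = tree.outlets
    missing = [o for o in outlets if o not in r_micro]
    if missing:
        raise DomainError(f"no microcirculation resistance for outlets {missing}")

    q = _initial_flows(tree, settings, resting, p0_pa, r_micro)
    alpha = settings.alpha
    report = ConvergenceReport(alpha_final=alpha)
    field_ = network_pressures(tree, q, p0, blood, settings.stenosis_model)
    p = field_.outlet_pressures()
    stall_window = 10
    last_adjust = 0
    warned_negative: set[str] = set()

    for it in range(1, settings.max_iter + 1):
        q_new = {}
        for o in outlets:
            val = (1.0 - alpha) * q[o] + alpha * p[o] / r_micro[o]
            if val <= 0:
                if o not in warned_negative:
                    logger.warning("outlet %s: negative flow iterate clipped", o)
                    warned_negative.add(o)
                val = _FLOW_EPS
            q_new[o] = val
        q = q_new
        field_ = network_pressures(tree, q, p0, blood, settings.stenosis_model)
        p_net = field_.outlet_pressures()
        if settings.eq10_literal:
            # the literal damped pressure update, kept for comparison only
            p = {o: p[o] + alpha * (p0_pa - p[o] + q[o] * r_micro[o]) for o in outlets}
        else:
            p = p_net
        residual = max(abs(p_net[o] - q[o] * r_micro[o]) for o in outlets) / p0_pa
        report.residual_history.append(residual)
        report.iterations = it
        if residual <= settings.tolerance:
            report.converged = True
            break
        # no net progress over a window ⇒ diverging or oscillating: damp harder
        if (settings.adaptive_alpha and it - last_adjust > stall_window
                and residual >= report.residual_history[-1 - stall_window]):
            alpha = max(alpha / 2.0, 1e-4)
            last_adjust = it
            logger.debug("residual stalled/diverging; alpha halved to %g", alpha)

    report.final_residual = report.residual_history[-1] if report.residual_history else float("nan")
    report.alpha_final = alpha
    flows = FlowAssignment(q_total=sum(q[o] for o in outlets),
                           outlet_flows=dict(q), state="hyperemic")
    return flows, report


def direct_solve_linear(
    tree: CoronaryTree,
    p0: float,
    r_micro: dict[str, float],
    blood: BloodProperties | None = None,
) -> FlowAssignment:
    """Exact hyperemic flows for the linear stenosis model (solver oracle).

    Assembles M Q = P0·1 with M[j,k] = Σ_{s ∈ path(j) ∩ path(k)} R_s + δ_jk R_j
    — each shared epicardial segment contributes its resistance to the pair —
    and solves it directly.
    """
    blood = blood or BloodProperties()
    p0_pa = p0 * MMHG_TO_PA
    outlets = tree.outlets
    n = len(outlets)
    r_eff = {sid: stenosis_effective_resistance(seg, tree.stenoses_on(sid), blood)
             for sid, seg in tree.segments.items()}
    paths = {o: set(path_to_root(tree, o)) for o in outlets}
    m = np.zeros((n, n))
    for j, oj in enumerate(outlets):
        for k, ok in enumerate(outlets):
            m[j, k] = sum(r_eff[s] for s in paths[oj] & paths[ok])
        m[j, j] += r_micro[oj]
    try:
        qvec = np.linalg.solve(m, np.full(n, p0_pa))
    except np.linalg.LinAlgError as exc:
        raise SingularGeometryError(f"singular network system: {exc}") from exc
    return FlowAssignment(q_total=float(qvec.sum()),
                          outlet_flows={o: float(qv) for o, qv in zip(outlets, qvec)},
                          state="hyperemic")
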