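"""Steady lumped-parameter blood flow on a vascular network.

The incompressible laminar model is reduced to its fully developed limit:
every segment is a Hagen-Poiseuille conductor, mass conservation holds at
every junction, and the boundary conditions mirror the imaging protocol —
measured mean velocities at the four afferent inlets, and outlet
volumetric flows split in proportion to outlet cross-section area.

The nodal pressures then satisfy a weighted graph-Laplacian system with
Neumann data given by the boundary flows; one reference node (the first
outlet) is grounded at 0 mmHg, so only pressure differences are physical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .network import NetworkStructureError, VascularNetwork, VesselSegment, equivalent_radius
from .units import PA_PER_MMHG, cm_s_to_mm_s


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties.

    density: g/mm^3 (default 1.05e-3, i.e. 1.05 g/cm^3)
    kinematic_viscosity: mm^2/s (default 3.33, i.e. 3.5 mPa*s dynamic)
    """

    density: float = 1.05e-3
    kinematic_viscosity: float = 3.33

    def __post_init__(self):
        if self.density <= 0 or self.kinematic_viscosity <= 0:
            raise ValueError("blood properties must be strictly positive")

    @property
    def dynamic_viscosity(self) -> float:
        """mu = rho * nu, in g/(mm*s) == Pa*s."""
        return self.density * self.kinematic_viscosity


@dataclass
class PressureFlowState:
    """Solved nodal pressures (mmHg) and segment flows (mm^3/s).

    Flows are signed by segment orientation (positive from ``from_node``
    to ``to_node``).  ``boundary`` holds the prescribed terminal flows,
    positive into the network.
    """

    pressures: dict[str, float]
    flows: dict[str, float]
    boundary: dict[str, float] = field(default_factory=dict)

    def interior_residuals(self, net: VascularNetwork) -> dict[str, float]:
        """Net signed flow at each interior (junction) node."""
        res = {nid: 0.0 for nid, n in net.nodes.items() if n.kind == "junction"}
        for seg in net.segments.values():
            q = self.flows[seg.id]
            if seg.from_node in res:
                res[seg.from_node] -= q
            if seg.to_node in res:
                res[seg.to_node] += q
        return res


InletConditions = Mapping[str, float]  # inlet node id -> mean velocity, cm/s


def segment_conductance(seg: VesselSegment, blood: BloodProperties) -> float:
    """Poiseuille conductance G = pi r^4 / (8 mu L), in (mm^3/s) per mmHg."""
    r = equivalent_radius(seg.area)
    g_pa = math.pi * r ** 4 / (8.0 * blood.dynamic_viscosity * seg.length)
    return g_pa * PA_PER_MMHG


def boundary_flows(net: VascularNetwork, inlets: InletConditions) -> dict[str, float]:
    """Terminal volumetric flows (mm^3/s), positive into the network.

    Inlet k carries v_k * A_k from its prescribed mean velocity (cm/s) and
    the area of its single incident segment.  The total inflow is split
    over the outlets in proportion to outlet cross-section area, so the
    balance holds exactly by construction.
    """
    missing = [nid for nid in net.inlets if nid not in inlets]
    if missing:
        raise ValueError(f"no inlet velocity given for {missing}")

    flows: dict[str, float] = {}
    total_in = 0.0
    for nid in net.inlets:
        area = net.terminal_segment(nid).area
        q = cm_s_to_mm_s(float(inlets[nid])) * area
        flows[nid] = q
        total_in += q

    outlet_areas = {nid: net.terminal_segment(nid).area for nid in net.outlets}
    total_area = sum(outlet_areas.values())
    if total_area <= 0:
        raise NetworkStructureError("total outlet area is zero; cannot split outflow")
    for nid, area in outlet_areas.items():
        flows[nid] = -total_in * area / total_area
    return flows


def lengthen_outlets(net: VascularNetwork, terminal_ids, extra_length: float) -> VascularNetwork:
    """Return a copy with each named outlet's terminal segment extended.

    Mirrors the simulation protocol of adding 1 mm extension sections to
    outlets that sit close to a bifurcation, so the outlet boundary
    condition acts on a developed profile.  Area is unchanged.
    """
    out = net.copy()
    for nid in terminal_ids:
        if nid not in out.outlets:
            raise NetworkStructureError(f"{nid!r} is not an outlet terminal")
        seg = out.segments[out.terminal_segment(nid).id]
        seg.length += float(extra_length)
    return out


def assemble_laplacian(net: VascularNetwork,
                       edge_weight: Mapping[str, complex]) -> tuple[list[str], np.ndarray]:
    """Weighted graph Laplacian over the network's nodes.

    ``edge_weight`` maps segment id to its (possibly complex) admittance.
    """
    order = list(net.nodes)
    pos = {nid: i for i, nid in enumerate(order)}
    dtype = complex if any(isinstance(w, complex) for w in edge_weight.values()) else float
    lap = np.zeros((len(order), len(order)), dtype=dtype)
    for seg in net.segments.values():
        w = edge_weight[seg.id]
        i, j = pos[seg.from_node], pos[seg.to_node]
        lap[i, i] += w
        lap[j, j] += w
        lap[i, j] -= w
        lap[j, i] -= w
    return order, lap


def solve_network(net: VascularNetwork,
                  edge_admittance: Mapping[str, complex],
                  boundary: Mapping[str, complex],
                  reference_node: str | None = None) -> PressureFlowState:
    """Solve L p = b with one grounded reference node.

    Shared by the steady solver (real admittances) and the per-harmonic
    pulsatile solver (complex admittances).
    """
    order, lap = assemble_laplacian(net, edge_admittance)
    pos = {nid: i for i, nid in enumerate(order)}
    b = np.zeros(len(order), dtype=lap.dtype)
    for nid, q in boundary.items():
        b[pos[nid]] += q

    ref = reference_node if reference_node is not None else net.outlets[0]
    k = pos[ref]
    keep = [i for i in range(len(order)) if i != k]
    try:
        p_red = np.linalg.solve(lap[np.ix_(keep, keep)], b[keep])
    except np.linalg.LinAlgError as exc:
        raise NetworkStructureError(
            "pressure system is singular (disconnected component?)") from exc

    p = np.zeros(len(order), dtype=lap.dtype)
    p[keep] = p_red

    pressures = {nid: p[pos[nid]] for nid in order}
    flows = {
        seg.id: edge_admittance[seg.id]
        * (pressures[seg.from_node] - pressures[seg.to_node])
        for seg in net.segments.values()
    }
    if lap.dtype != complex:
        pressures = {k2: float(np.real(v)) for k2, v in pressures.items()}
        flows = {k2: float(np.real(v)) for k2, v in flows.items()}
    return PressureFlowState(pressures=pressures, flows=flows, boundary=dict(boundary))


def solve_steady(net: VascularNetwork, inlets: InletConditions,
                 blood: BloodProperties) -> PressureFlowState:
    """Steady pressure/flow solution for prescribed inlet mean velocities."""
    cond = {seg.id: segment_conductance(seg, blood) for seg in net.segments.values()}
    bnd = boundary_flows(net, inlets)
    state = solve_network(net, cond, bnd)

    total_in = sum(q for q in bnd.values() if q > 0)
    residual = max((abs(r) for r in state.interior_residuals(net).values()),
                   default=0.0)
    if residual > 1e-9 * max(total_in, 1e-30):
        raise AssertionError(
            f"interior mass-balance residual {residual:.3e} exceeds tolerance")
    return state
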