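"""Canonical murine circle-of-Willis template.

The template encodes the anatomy used throughout the package: four
afferent vessels (left/right common carotid and vertebral arteries), the
basilar trunk, both internal carotids, and the communicating ring
(ACA/AcoA anteriorly, PCA/PcoA posteriorly) with MCA, ACA, PCA and
superior-cerebellar efferents.

Registry conventions
--------------------
* 22 numbered cross-sectional planes, two per major vessel run (the
  eleven runs BA, ICA_L, ICA_R, ACA_L, ACA_R, MCA_L, MCA_R, PcoA_R,
  PcoA_L, PCA_L, PCA_R).  Planes 1 (basilar base), 3 (left ICA, cervical
  C1) and 6 (right ICA, C1) are anatomically anchored; the remaining
  placements are a documented package convention and are overridable.
* 7 numbered inter-vessel angles: 1 ACA_L-MCA_L, 2 ACA_R-MCA_R,
  3 ACA_L-PcoA_L, 4 ACA_R-PcoA_R, 5 ICA_L-PcoA_L, 6 ICA_R-PcoA_R,
  7 PCA_L-PCA_R.
* 8 ordered outlets; outlets 7 and 8 are the posterior cerebral
  efferents, which sit closest to the basilar bifurcation and are the
  ones extended by 1 mm in the simulation protocol.
"""

from __future__ import annotations

import numpy as np

from .network import Node, SectionPlane, VascularNetwork, VesselSegment, set_vessel_angle

# plane index -> (segment name, axial fraction along the segment)
SECTION_REGISTRY: dict[int, tuple[str, float]] = {
    1: ("BA", 0.10), 2: ("BA", 0.90),
    3: ("ICA_L", 0.25), 4: ("ICA_L", 0.75),
    5: ("ICA_R", 0.25), 6: ("ICA_R", 0.75),
    7: ("ACA_L", 0.25), 8: ("ACA_L", 0.75),
    9: ("ACA_R", 0.25), 10: ("ACA_R", 0.75),
    11: ("MCA_L", 0.25), 12: ("MCA_L", 0.75),
    13: ("MCA_R", 0.25), 14: ("MCA_R", 0.75),
    15: ("PcoA_R", 0.25), 16: ("PcoA_R", 0.75),
    17: ("PcoA_L", 0.25), 18: ("PcoA_L", 0.75),
    19: ("PCA_L", 0.30), 20: ("PCA_L_dist", 0.50),
    21: ("PCA_R", 0.30), 22: ("PCA_R_dist", 0.50),
}

# consecutive same-run plane pairs; each run carries one mass flow and one
# hydraulic resistance, giving the 73-parameter feature registry
# (7 angles + 22 areas + 11 mass flows + 22 max velocities + 11 resistances)
VESSEL_PLANE_PAIRS: list[tuple[int, int]] = [
    (1, 2), (3, 4), (5, 6), (7, 8), (9, 10), (11, 12),
    (13, 14), (15, 16), (17, 18), (19, 20), (21, 22),
]

ANGLE_REGISTRY: dict[int, tuple[str, str]] = {
    1: ("ACA_L", "MCA_L"),
    2: ("ACA_R", "MCA_R"),
    3: ("ACA_L", "PcoA_L"),
    4: ("ACA_R", "PcoA_R"),
    5: ("ICA_L", "PcoA_L"),
    6: ("ICA_R", "PcoA_R"),
    7: ("PCA_L", "PCA_R"),
}

# control-like default lumen areas per plane, mm^2
DEFAULT_SECTION_AREAS: dict[int, float] = {
    1: 0.06, 2: 0.06,
    3: 0.12, 4: 0.11,
    5: 0.11, 6: 0.10,
    7: 0.05, 8: 0.05,
    9: 0.05, 10: 0.05,
    11: 0.07, 12: 0.07,
    13: 0.07, 14: 0.07,
    15: 0.03, 16: 0.03,
    17: 0.03, 18: 0.03,
    19: 0.05, 20: 0.045,
    21: 0.05, 22: 0.045,
}

DEFAULT_ANGLES_DEG: dict[int, float] = {
    1: 70.0, 2: 67.6, 3: 105.0, 4: 105.0, 5: 95.0, 6: 95.0, 7: 110.0,
}

# afferent and efferent vessels without numbered planes, mm^2
_FIXED_AREAS = {
    "CCA_L": 0.20, "CCA_R": 0.20,
    "VA_L": 0.04, "VA_R": 0.04,
    "ACA_L_dist": 0.045, "ACA_R_dist": 0.045,
    "AcoA": 0.02,
    "SCA_L": 0.02, "SCA_R": 0.02,
}

# name -> (from, to, length mm)
_TOPOLOGY: list[tuple[str, str, str, float]] = [
    ("CCA_L", "CCA_L_in", "J_CCA_L", 6.0),
    ("CCA_R", "CCA_R_in", "J_CCA_R", 6.0),
    ("ICA_L", "J_CCA_L", "J_ICA_L", 2.0),
    ("ICA_R", "J_CCA_R", "J_ICA_R", 2.0),
    ("VA_L", "VA_L_in", "J_BA0", 5.0),
    ("VA_R", "VA_R_in", "J_BA0", 5.0),
    ("BA", "J_BA0", "J_BA1", 3.0),
    ("PCA_L", "J_BA1", "J_PCA_L", 1.0),
    ("PCA_R", "J_BA1", "J_PCA_R", 1.0),
    ("PCA_L_dist", "J_PCA_L", "PCA_L_out", 1.2),
    ("PCA_R_dist", "J_PCA_R", "PCA_R_out", 1.2),
    ("PcoA_L", "J_ICA_L", "J_PCA_L", 1.2),
    ("PcoA_R", "J_ICA_R", "J_PCA_R", 1.2),
    ("ACA_L", "J_ICA_L", "J_ACA_L", 1.5),
    ("ACA_R", "J_ICA_R", "J_ACA_R", 1.5),
    ("AcoA", "J_ACA_L", "J_ACA_R", 0.8),
    ("ACA_L_dist", "J_ACA_L", "ACA_L_out", 1.0),
    ("ACA_R_dist", "J_ACA_R", "ACA_R_out", 1.0),
    ("MCA_L", "J_ICA_L", "MCA_L_out", 2.0),
    ("MCA_R", "J_ICA_R", "MCA_R_out", 2.0),
    ("SCA_L", "J_BA1", "SCA_L_out", 1.0),
    ("SCA_R", "J_BA1", "SCA_R_out", 1.0),
]

_POSITIONS: dict[str, tuple[float, float, float]] = {
    "CCA_L_in": (-2.0, -9.0, -3.0), "CCA_R_in": (2.0, -9.0, -3.0),
    "VA_L_in": (-1.0, -8.0, -2.0), "VA_R_in": (1.0, -8.0, -2.0),
    "J_CCA_L": (-2.0, -4.0, 0.0), "J_CCA_R": (2.0, -4.0, 0.0),
    "J_ICA_L": (-1.5, -2.0, 0.5), "J_ICA_R": (1.5, -2.0, 0.5),
    "J_BA0": (0.0, -6.0, 0.0), "J_BA1": (0.0, -3.0, 0.0),
    "J_PCA_L": (-1.0, -2.8, 0.2), "J_PCA_R": (1.0, -2.8, 0.2),
    "J_ACA_L": (-0.6, -0.8, 0.8), "J_ACA_R": (0.6, -0.8, 0.8),
    "MCA_L_out": (-3.0, -1.5, 1.0), "MCA_R_out": (3.0, -1.5, 1.0),
    "ACA_L_out": (-0.4, 0.5, 1.2), "ACA_R_out": (0.4, 0.5, 1.2),
    "PCA_L_out": (-2.0, -3.5, 0.8), "PCA_R_out": (2.0, -3.5, 0.8),
    "SCA_L_out": (-0.8, -4.0, 0.5), "SCA_R_out": (0.8, -4.0, 0.5),
}

INLET_NODES = ["CCA_L_in", "CCA_R_in", "VA_L_in", "VA_R_in"]
# outlet order fixes the numbering used by the protocol (7 and 8 = PCA efferents)
OUTLET_NODES = ["ACA_L_out", "ACA_R_out", "MCA_L_out", "MCA_R_out",
                "SCA_L_out", "SCA_R_out", "PCA_L_out", "PCA_R_out"]

# default inlet mean velocities, cm/s (carotids from phase-contrast-scale
# control values, vertebrals a package convention)
DEFAULT_INLET_VELOCITIES = {
    "CCA_L_in": 12.0, "CCA_R_in": 12.0,
    "VA_L_in": 5.7, "VA_R_in": 5.7,
}


def build_cow_template(section_areas: dict[int, float] | None = None,
                       angles_deg: dict[int, float] | None = None) -> VascularNetwork:
    """Assemble the canonical network.

    ``section_areas`` overrides per-plane lumen areas (mm^2); the area of a
    segment carrying planes is the mean of its plane areas.  ``angles_deg``
    overrides registered bifurcation angles.
    """
    areas = dict(DEFAULT_SECTION_AREAS)
    if section_areas:
        areas.update(section_areas)
    angles = dict(DEFAULT_ANGLES_DEG)
    if angles_deg:
        angles.update(angles_deg)

    net = VascularNetwork()
    terminal_kind = {nid: "inlet" for nid in INLET_NODES}
    terminal_kind.update({nid: "outlet" for nid in OUTLET_NODES})
    for nid, pos in _POSITIONS.items():
        net.nodes[nid] = Node(nid, np.array(pos, dtype=float),
                              terminal_kind.get(nid, "junction"))

    plane_by_segment: dict[str, list[int]] = {}
    for idx, (segname, _) in SECTION_REGISTRY.items():
        plane_by_segment.setdefault(segname, []).append(idx)

    for name, a, b, length in _TOPOLOGY:
        if name in plane_by_segment:
            area = float(np.mean([areas[i] for i in plane_by_segment[name]]))
        else:
            area = _FIXED_AREAS[name]
        chord = net.nodes[b].position - net.nodes[a].position
        u = chord / np.linalg.norm(chord)
        net.segments[name] = VesselSegment(
            id=name, name=name, from_node=a, to_node=b,
            length=length, area=area, direction={a: u, b: -u})

    for idx, (segname, frac) in SECTION_REGISTRY.items():
        net.sections[idx] = SectionPlane(idx, segname, frac, areas[idx])

    net.inlets = list(INLET_NODES)
    net.outlets = list(OUTLET_NODES)
    net.angles = dict(ANGLE_REGISTRY)

    for idx, deg in angles.items():
        set_vessel_angle(net, idx, deg)
    return net


def random_cow_variant(seed: int) -> tuple[VascularNetwork, dict[str, float]]:
    """A randomly perturbed but valid network plus inlet velocities.

    Used for conservation/robustness sweeps: plane areas and segment
    lengths are jittered multiplicatively, registered angles redrawn, and
    with some probability one communicating vessel (AcoA or one PcoA) is
    removed — the classic incomplete-ring variants, which keep the graph
    connected.
    """
    rng = np.random.default_rng(seed)
    areas = {i: a * rng.lognormal(0.0, 0.2)
             for i, a in DEFAULT_SECTION_AREAS.items()}
    angles = {i: float(rng.uniform(40.0, 130.0)) for i in ANGLE_REGISTRY}
    net = build_cow_template(areas, angles)
    for seg in net.segments.values():
        seg.length *= float(rng.uniform(0.7, 1.4))
        if seg.name not in {n for n, _ in SECTION_REGISTRY.values()}:
            seg.area *= float(rng.lognormal(0.0, 0.15))

    # incomplete-ring variant: the AcoA is the one communicating vessel that
    # carries no registered plane or angle, so removing it keeps both
    # registries intact while still exercising a different ring topology
    if rng.random() < 0.3:
        del net.segments["AcoA"]

    inlets = {nid: float(rng.uniform(4.0, 18.0)) for nid in net.inlets}
    return net, inlets
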