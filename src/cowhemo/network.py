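"""Vascular-network data model for murine circle-of-Willis geometries.

A network is a directed graph of straight vessel segments between 3-D
nodes, plus two registries of derived geometric measurements:

* 22 numbered cross-sectional planes (``SectionPlane``), each pinned to a
  segment at an axial fraction and carrying its own orthogonal lumen area;
* 7 numbered inter-vessel angles (``AngleRegistry``), each an ordered pair
  of segment names sharing a junction node.

Segment endpoint *directions* are authoritative local tangents: they are
initialised from node-to-node chords but may be rotated independently
(``set_vessel_angle``) so that bifurcation angles can be prescribed
without moving nodes.  Curved centerlines are folded into ``length``.
"""

from __future__ import annotations

import json
import math
from copy import deepcopy
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

SCHEMA = "cowhemo-net-1"

N_SECTIONS = 22
N_ANGLES = 7

_KINDS = ("junction", "inlet", "outlet")


class NetworkStructureError(ValueError):
    """Raised when an operation is asked about structure a network lacks."""


@dataclass
class Node:
    id: str
    position: np.ndarray  # (3,) mm
    kind: str = "junction"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class VesselSegment:
    """Straight vessel between two nodes.

    ``direction`` maps each endpoint node id to the unit tangent pointing
    *away* from that node along the vessel.
    """

    id: str
    name: str
    from_node: str
    to_node: str
    length: float  # mm
    area: float    # mm^2
    direction: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.direction = {k: np.asarray(v, dtype=float) for k, v in self.direction.items()}


@dataclass
class SectionPlane:
    index: int            # 1..22
    segment_id: str
    axial_position: float  # fraction in [0, 1] along the segment
    area: float            # mm^2


@dataclass
class VascularNetwork:
    nodes: dict[str, Node] = field(default_factory=dict)
    segments: dict[str, VesselSegment] = field(default_factory=dict)
    sections: dict[int, SectionPlane] = field(default_factory=dict)
    inlets: list[str] = field(default_factory=list)     # node ids
    outlets: list[str] = field(default_factory=list)    # node ids, ordered
    angles: dict[int, tuple[str, str]] = field(default_factory=dict)  # 1..7 -> segment names

    # -- convenience ------------------------------------------------------
    def segment_by_name(self, name: str) -> VesselSegment:
        for seg in self.segments.values():
            if seg.name == name:
                return seg
        raise KeyError(f"no segment named {name!r}")

    def incident_segments(self, node_id: str) -> list[VesselSegment]:
        return [s for s in self.segments.values()
                if node_id in (s.from_node, s.to_node)]

    def terminal_segment(self, node_id: str) -> VesselSegment:
        """The single segment incident to an inlet/outlet terminal."""
        inc = self.incident_segments(node_id)
        if len(inc) != 1:
            raise NetworkStructureError(
                f"node {node_id!r} has {len(inc)} incident segments, expected 1")
        return inc[0]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for seg in self.segments.values():
            g.add_edge(seg.from_node, seg.to_node, id=seg.id)
        return g

    def copy(self) -> "VascularNetwork":
        return deepcopy(self)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA,
            "nodes": [
                {"id": n.id, "position": list(map(float, n.position)), "kind": n.kind}
                for n in self.nodes.values()
            ],
            "segments": [
                {
                    "id": s.id, "name": s.name,
                    "from_node": s.from_node, "to_node": s.to_node,
                    "length": s.length, "area": s.area,
                    "direction": {k: list(map(float, v)) for k, v in s.direction.items()},
                }
                for s in self.segments.values()
            ],
            "sections": [
                {"index": p.index, "segment_id": p.segment_id,
                 "axial_position": p.axial_position, "area": p.area}
                for p in self.sections.values()
            ],
            "inlets": list(self.inlets),
            "outlets": list(self.outlets),
            "angles": {str(k): list(v) for k, v in self.angles.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VascularNetwork":
        if d.get("schema") != SCHEMA:
            raise ValueError(f"unsupported network schema: {d.get('schema')!r}")
        net = cls()
        for nd in d["nodes"]:
            net.nodes[nd["id"]] = Node(nd["id"], np.array(nd["position"]), nd["kind"])
        for sd in d["segments"]:
            net.segments[sd["id"]] = VesselSegment(
                sd["id"], sd["name"], sd["from_node"], sd["to_node"],
                sd["length"], sd["area"],
                {k: np.array(v) for k, v in sd["direction"].items()})
        for pd in d["sections"]:
            net.sections[pd["index"]] = SectionPlane(
                pd["index"], pd["segment_id"], pd["axial_position"], pd["area"])
        net.inlets = list(d["inlets"])
        net.outlets = list(d["outlets"])
        net.angles = {int(k): tuple(v) for k, v in d["angles"].items()}
        return net

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "VascularNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def validate_network(net: VascularNetwork) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    errs: list[str] = []

    for n in net.nodes.values():
        if n.kind not in _KINDS:
            errs.append(f"node {n.id}: unknown kind {n.kind!r}")
        if n.position.shape != (3,) or not np.all(np.isfinite(n.position)):
            errs.append(f"node {n.id}: position must be a finite 3-vector")

    deg: dict[str, int] = {nid: 0 for nid in net.nodes}
    for seg in net.segments.values():
        for nid in (seg.from_node, seg.to_node):
            if nid not in net.nodes:
                errs.append(f"segment {seg.id}: unknown node {nid!r}")
            else:
                deg[nid] += 1
        if not seg.length > 0:
            errs.append(f"segment {seg.id}: length must be > 0 (got {seg.length})")
        if not seg.area > 0:
            errs.append(f"segment {seg.id}: area must be > 0 (got {seg.area})")
        for nid, vec in seg.direction.items():
            if abs(np.linalg.norm(vec) - 1.0) > 1e-9:
                errs.append(f"segment {seg.id}: direction at {nid} is not a unit vector")
        if set(seg.direction) != {seg.from_node, seg.to_node}:
            errs.append(f"segment {seg.id}: directions must be given at both endpoints")

    for n in net.nodes.values():
        if n.kind in ("inlet", "outlet") and deg.get(n.id, 0) != 1:
            errs.append(f"{n.kind} node {n.id} has degree {deg.get(n.id, 0)}, expected 1")
    for nid in net.inlets:
        if net.nodes.get(nid) is None or net.nodes[nid].kind != "inlet":
            errs.append(f"inlet list entry {nid!r} is not an inlet node")
    for nid in net.outlets:
        if net.nodes.get(nid) is None or net.nodes[nid].kind != "outlet":
            errs.append(f"outlet list entry {nid!r} is not an outlet node")
    if not net.inlets:
        errs.append("network has no inlets")
    if not net.outlets:
        errs.append("network has no outlets")

    for p in net.sections.values():
        if not (1 <= p.index <= N_SECTIONS):
            errs.append(f"section {p.index}: index out of range 1..{N_SECTIONS}")
        if p.segment_id not in net.segments:
            errs.append(f"section {p.index}: unknown segment {p.segment_id!r}")
        if not (0.0 <= p.axial_position <= 1.0):
            errs.append(f"section {p.index}: axial position outside [0, 1]")
        if not p.area > 0:
            errs.append(f"section {p.index}: area must be > 0")

    if net.angles:
        if len(net.angles) != N_ANGLES:
            errs.append(f"angle registry has {len(net.angles)} entries, expected {N_ANGLES}")
        for idx, (a, b) in net.angles.items():
            try:
                shared = _shared_node(net, a, b)
            except (KeyError, NetworkStructureError) as exc:
                errs.append(f"angle {idx}: {exc}")
                continue
            if shared is None:
                errs.append(f"angle {idx}: segments {a} and {b} share no node")

    if net.nodes and not nx.is_connected(net.graph()):
        errs.append("network graph is not connected")

    return errs


def _shared_node(net: VascularNetwork, name_a: str, name_b: str) -> str | None:
    sa, sb = net.segment_by_name(name_a), net.segment_by_name(name_b)
    shared = {sa.from_node, sa.to_node} & {sb.from_node, sb.to_node}
    return next(iter(shared)) if shared else None


def vessel_angle(net: VascularNetwork, pair_index: int) -> float:
    """Angle in degrees between the two registered segments at their shared node.

    Uses the locally stored endpoint tangents (both pointing away from the
    junction), so the value reflects the bifurcation geometry rather than
    global chords.  Symmetric in the pair; always in [0, 180].
    """
    if pair_index not in net.angles:
        raise KeyError(f"no angle registered under index {pair_index}")
    name_a, name_b = net.angles[pair_index]
    shared = _shared_node(net, name_a, name_b)
    if shared is None:
        raise NetworkStructureError(
            f"segments {name_a} and {name_b} do not share a junction node")
    va = net.segment_by_name(name_a).direction[shared]
    vb = net.segment_by_name(name_b).direction[shared]
    c = float(np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def set_vessel_angle(net: VascularNetwork, pair_index: int, degrees: float) -> None:
    """Rotate the second segment's junction tangent so the pair angle equals
    ``degrees``, keeping the first segment's tangent fixed.

    The rotation stays in the plane spanned by the two current tangents (a
    fixed perpendicular is used when they are collinear), so repeated calls
    are stable.  In-place.
    """
    if not (0.0 <= degrees <= 180.0):
        raise ValueError("angle must be in [0, 180] degrees")
    name_a, name_b = net.angles[pair_index]
    shared = _shared_node(net, name_a, name_b)
    if shared is None:
        raise NetworkStructureError(
            f"segments {name_a} and {name_b} do not share a junction node")
    sa, sb = net.segment_by_name(name_a), net.segment_by_name(name_b)
    u = sa.direction[shared] / np.linalg.norm(sa.direction[shared])
    v = sb.direction[shared]
    perp = v - np.dot(v, u) * u
    if np.linalg.norm(perp) < 1e-12:
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, u)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        perp = trial - np.dot(trial, u) * u
    perp = perp / np.linalg.norm(perp)
    theta = math.radians(degrees)
    sb.direction[shared] = math.cos(theta) * u + math.sin(theta) * perp


def section_area(net: VascularNetwork, index: int) -> float:
    """Stored orthogonal lumen area (mm^2) at the numbered sectional plane."""
    if index not in net.sections:
        raise KeyError(f"no section plane with index {index}")
    return net.sections[index].area


def equivalent_radius(area: float) -> float:
    """Radius (mm) of the circle with the given lumen area (mm^2)."""
    if not area > 0:
        raise ValueError(f"area must be > 0, got {area}")
    return math.sqrt(area / math.pi)
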