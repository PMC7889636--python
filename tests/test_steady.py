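"""Steady network solver against closed forms and hand-assembled oracles."""

import math

import numpy as np
import pytest

from cowhemo import (BloodProperties, boundary_flows, build_cow_template,
                     lengthen_outlets, segment_conductance, solve_steady,
                     validate_network)
from cowhemo.network import Node, NetworkStructureError, VascularNetwork, VesselSegment
from cowhemo.units import PA_PER_MMHG


def _line_network(n_nodes, lengths, areas, inlet="n0", outlet=None):
    """Chain of segments n0-n1-...; first node inlet, last outlet."""
    outlet = outlet or f"n{n_nodes - 1}"
    net = VascularNetwork()
    for i in range(n_nodes):
        kind = "inlet" if f"n{i}" == inlet else ("outlet" if f"n{i}" == outlet else "junction")
        net.nodes[f"n{i}"] = Node(f"n{i}", np.array([float(i), 0, 0]), kind)
    for i in range(n_nodes - 1):
        a, b = f"n{i}", f"n{i + 1}"
        net.segments[f"s{i}"] = VesselSegment(
            f"s{i}", f"s{i}", a, b, lengths[i], areas[i],
            {a: np.array([1.0, 0, 0]), b: np.array([-1.0, 0, 0])})
    net.inlets, net.outlets = [inlet], [outlet]
    return net


def tube(length=10.0, area=math.pi * 0.04):  # r = 0.2 mm
    return _line_network(2, [length], [area])


def test_conductance_matches_hagen_poiseuille(blood):
    net = tube()
    seg = net.segments["s0"]
    r = math.sqrt(seg.area / math.pi)
    g_pa = math.pi * r ** 4 / (8 * blood.dynamic_viscosity * seg.length)
    assert segment_conductance(seg, blood) == pytest.approx(g_pa * PA_PER_MMHG, rel=1e-12)


def test_conductance_scaling_laws(blood):
    seg = tube().segments["s0"]
    g = segment_conductance(seg, blood)
    double = VesselSegment("d", "d", "a", "b", 2 * seg.length, seg.area, {})
    assert segment_conductance(double, blood) == pytest.approx(g / 2, rel=1e-12)
    fat = VesselSegment("f", "f", "a", "b", seg.length, 4 * seg.area, {})
    assert segment_conductance(fat, blood) == pytest.approx(16 * g, rel=1e-12)


def _y_network(daughter_areas=(0.05, 0.05)):
    net = VascularNetwork()
    for nid, kind, pos in [("in", "inlet", [0, 0, 0]), ("j", "junction", [1, 0, 0]),
                           ("o1", "outlet", [2, 1, 0]), ("o2", "outlet", [2, -1, 0])]:
        net.nodes[nid] = Node(nid, np.array(pos, dtype=float), kind)
    u = np.array([1.0, 0, 0])
    net.segments["parent"] = VesselSegment("parent", "parent", "in", "j", 2.0, 0.1,
                                           {"in": u, "j": -u})
    for k, (o, a) in enumerate(zip(("o1", "o2"), daughter_areas)):
        d = np.array([1.0, 1.0 - 2 * k, 0]); d = d / np.linalg.norm(d)
        net.segments[o + "_seg"] = VesselSegment(o + "_seg", o + "_seg", "j", o, 3.0, a,
                                                 {"j": d, o: -d})
    net.inlets, net.outlets = ["in"], ["o1", "o2"]
    return net


def test_boundary_flows_equal_area_split():
    net = _y_network((0.05, 0.05))
    bf = boundary_flows(net, {"in": 10.0})
    assert bf["in"] == pytest.approx(10.0)  # 100 mm/s * 0.1 mm^2
    assert bf["o1"] == pytest.approx(-5.0) and bf["o2"] == pytest.approx(-5.0)
    assert sum(bf.values()) == 0.0


def test_boundary_flows_area_proportional_split():
    net = _y_network((0.08, 0.04))
    bf = boundary_flows(net, {"in": 10.0})
    assert bf["o1"] == pytest.approx(-10.0 * 2 / 3, rel=1e-12)
    assert bf["o2"] == pytest.approx(-10.0 * 1 / 3, rel=1e-12)


def test_inlet_flow_is_velocity_times_area():
    net = _y_network()
    net.segments["parent"].area = 0.2
    bf = boundary_flows(net, {"in": 10.0})
    assert bf["in"] == pytest.approx(20.0, rel=1e-12)  # 10 cm/s on 0.2 mm^2


def test_boundary_flows_require_all_inlets(template_net):
    with pytest.raises(ValueError, match="CCA_L_in"):
        boundary_flows(template_net, {"VA_L_in": 5.0})


def test_single_tube_matches_poiseuille(blood):
    net = tube()
    state = solve_steady(net, {"n0": 10.0}, blood)
    q = state.flows["s0"]
    g = segment_conductance(net.segments["s0"], blood)
    dp = state.pressures["n0"] - state.pressures["n1"]
    assert dp == pytest.approx(q / g, rel=1e-12)
    assert q == pytest.approx(100.0 * net.segments["s0"].area, rel=1e-12)


def test_symmetric_bifurcation_splits_evenly(blood):
    state = solve_steady(_y_network((0.05, 0.05)), {"in": 8.0}, blood)
    assert state.flows["o1_seg"] == pytest.approx(state.flows["o2_seg"], rel=1e-12)


def test_loop_network_matches_hand_assembled_system(blood):
    """Minimal ring: two paths from inlet junction to outlet junction.

    The oracle assembles the same nodal equations by hand as a dense
    matrix, independent of the solver's graph machinery.
    """
    net = VascularNetwork()
    coords = {"in": [0, 0, 0], "a": [1, 0, 0], "b": [2, 1, 0], "c": [2, -1, 0],
              "d": [3, 0, 0], "out": [4, 0, 0]}
    kinds = {"in": "inlet", "out": "outlet"}
    for nid, pos in coords.items():
        net.nodes[nid] = Node(nid, np.array(pos, dtype=float), kinds.get(nid, "junction"))
    u = np.array([1.0, 0, 0])
    spec = [("s_in", "in", "a", 2.0, 0.10), ("s_top", "a", "b", 3.0, 0.04),
            ("s_bot", "a", "c", 2.5, 0.06), ("s_top2", "b", "d", 3.0, 0.05),
            ("s_bot2", "c", "d", 2.5, 0.05), ("s_out", "d", "out", 2.0, 0.09)]
    for sid, fa, fb, L, A in spec:
        net.segments[sid] = VesselSegment(sid, sid, fa, fb, L, A, {fa: u, fb: -u})
    net.inlets, net.outlets = ["in"], ["out"]
    assert validate_network(net) == []

    state = solve_steady(net, {"in": 12.0}, blood)

    # oracle: nodal analysis assembled by hand
    g = {sid: segment_conductance(net.segments[sid], blood) for sid in net.segments}
    q_in = 120.0 * 0.10
    nodes = ["in", "a", "b", "c", "d"]  # "out" grounded
    A_mat = np.zeros((5, 5))
    incid = {"s_in": ("in", "a"), "s_top": ("a", "b"), "s_bot": ("a", "c"),
             "s_top2": ("b", "d"), "s_bot2": ("c", "d"), "s_out": ("d", None)}
    idx = {n: i for i, n in enumerate(nodes)}
    for sid, (na, nb) in incid.items():
        ga = g[sid]
        A_mat[idx[na], idx[na]] += ga
        if nb is not None:
            A_mat[idx[nb], idx[nb]] += ga
            A_mat[idx[na], idx[nb]] -= ga
            A_mat[idx[nb], idx[na]] -= ga
    b_vec = np.zeros(5)
    b_vec[idx["in"]] = q_in
    p = np.linalg.solve(A_mat, b_vec)

    for sid, (na, nb) in incid.items():
        pa = p[idx[na]]
        pb = p[idx[nb]] if nb is not None else 0.0
        assert state.flows[sid] == pytest.approx(g[sid] * (pa - pb), rel=1e-10)


def test_tree_flows_are_combinatorial(blood):
    """On an acyclic network every flow is fixed by the boundary flows."""
    net = _y_network((0.08, 0.04))
    bf = boundary_flows(net, {"in": 10.0})
    state = solve_steady(net, {"in": 10.0}, blood)
    assert state.flows["parent"] == pytest.approx(bf["in"], rel=1e-12)
    assert state.flows["o1_seg"] == pytest.approx(-bf["o1"], rel=1e-12)
    assert state.flows["o2_seg"] == pytest.approx(-bf["o2"], rel=1e-12)


def test_linearity_in_inlet_velocities(template_net, blood, default_velocities):
    s1 = solve_steady(template_net, default_velocities, blood)
    s2 = solve_steady(template_net, {k: 3.0 * v for k, v in default_velocities.items()},
                      blood)
    for sid in s1.flows:
        assert s2.flows[sid] == pytest.approx(3.0 * s1.flows[sid], rel=1e-9, abs=1e-12)


def test_interior_conservation_on_template(template_net, blood, default_velocities):
    state = solve_steady(template_net, default_velocities, blood)
    total_in = sum(q for q in state.boundary.values() if q > 0)
    worst = max(abs(r) for r in state.interior_residuals(template_net).values())
    assert worst < 1e-9 * total_in


def test_ica_narrowing_increases_its_pressure_drop(blood, default_velocities):
    """Rayleigh-type monotonicity under fixed boundary flows."""
    base = build_cow_template()
    s0 = solve_steady(base, default_velocities, blood)
    dp0 = s0.pressures["J_CCA_R"] - s0.pressures["J_ICA_R"]
    for factor in (0.8, 0.6, 0.4):
        net = build_cow_template()
        net.segments["ICA_R"].area *= factor
        s = solve_steady(net, default_velocities, blood)
        dp = s.pressures["J_CCA_R"] - s.pressures["J_ICA_R"]
        assert dp >= dp0 - 1e-12
        dp0 = dp


def test_lengthen_outlets_extends_named_terminals(template_net):
    ids = template_net.outlets[6:8]
    before = {nid: template_net.terminal_segment(nid).length for nid in ids}
    out = lengthen_outlets(template_net, ids, 1.0)
    for nid in ids:
        assert out.terminal_segment(nid).length == pytest.approx(before[nid] + 1.0)
    # untouched elsewhere
    assert out.segments["BA"].length == template_net.segments["BA"].length


def test_lengthen_outlets_zero_is_identity(template_net):
    out = lengthen_outlets(template_net, template_net.outlets[:2], 0.0)
    assert out.to_dict() == template_net.to_dict()


def test_lengthen_outlets_rejects_non_outlet(template_net):
    with pytest.raises(NetworkStructureError):
        lengthen_outlets(template_net, ["J_BA1"], 1.0)


def test_extension_leaves_flows_and_upstream_pressures_unchanged(
        blood, default_velocities):
    """With area-proportional boundary flows fixed, extending the PCA
    efferents only moves the pressure at those terminals."""
    base = build_cow_template()
    ext = lengthen_outlets(base, base.outlets[6:8], 1.0)
    s0 = solve_steady(base, default_velocities, blood)
    s1 = solve_steady(ext, default_velocities, blood)
    for sid in s0.flows:
        assert s1.flows[sid] == pytest.approx(s0.flows[sid], rel=1e-9, abs=1e-12)
    changed = {"PCA_L_out", "PCA_R_out"}
    for nid in s0.pressures:
        if nid in changed:
            assert abs(s1.pressures[nid] - s0.pressures[nid]) > 0
        else:
            assert s1.pressures[nid] == pytest.approx(s0.pressures[nid],
                                                      rel=1e-9, abs=1e-12)


def test_blood_properties_validation():
    with pytest.raises(ValueError):
        BloodProperties(density=0.0)
    b = BloodProperties()
    assert b.dynamic_viscosity == pytest.approx(3.4965e-3, rel=1e-12)
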