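"""Formula-defined hemodynamic metrics over solved network states.

Three section-plane metrics drive the downstream statistics:

* mass flow  Q_i = rho * integral of (v . n) over plane i   [mg/s]
* peak velocity v_i^max over plane i                        [cm/s]
* hydraulic resistance R_ij = dP_ij / Q_i                   [mmHg*s/g]

dP_ij defaults to the *total* pressure drop (static + dynamic head
rho v^2 / 2 from the plane-mean velocity); a static-only variant is
available since solver conventions differ on this point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .network import SectionPlane, VascularNetwork
from .steady import BloodProperties, PressureFlowState
from .transient import TimeSeriesState, max_velocity
from .units import pa_to_mmhg

log = logging.getLogger(__name__)

MG_PER_G = 1000.0


class UndefinedResistanceError(ZeroDivisionError):
    """R_ij is undefined where the reference mass flow vanishes."""


def _plane(net: VascularNetwork, section: SectionPlane | int) -> SectionPlane:
    if isinstance(section, int):
        if section not in net.sections:
            raise KeyError(f"no section plane with index {section}")
        return net.sections[section]
    return section


def mass_flow(state: PressureFlowState, net: VascularNetwork,
              section: SectionPlane | int, blood: BloodProperties,
              normal_sign: int = 1) -> float:
    """Mass flow (mg/s) through a sectional plane.

    The plane normal is oriented with the carrying segment (from -> to);
    ``normal_sign=-1`` flips it, negating the result.
    """
    plane = _plane(net, section)
    q_vol = state.flows[plane.segment_id]          # mm^3/s, signed by segment
    return normal_sign * blood.density * MG_PER_G * q_vol


def plane_pressure(state: PressureFlowState, net: VascularNetwork,
                   section: SectionPlane | int, blood: BloodProperties,
                   kind: str = "total") -> float:
    """Pressure (mmHg) at a plane: static interpolated along the segment,
    plus the dynamic head of the plane-mean velocity when ``kind='total'``."""
    plane = _plane(net, section)
    seg = net.segments[plane.segment_id]
    p_static = (state.pressures[seg.from_node]
                + plane.axial_position * (state.pressures[seg.to_node]
                                          - state.pressures[seg.from_node]))
    if kind == "static":
        return p_static
    if kind != "total":
        raise ValueError(f"unknown pressure kind {kind!r}")
    v_mean = state.flows[plane.segment_id] / plane.area  # mm/s
    q_dyn_pa = 0.5 * blood.density * v_mean ** 2         # g/(mm s^2) == Pa
    return p_static + pa_to_mmhg(q_dyn_pa)


def hydraulic_resistance(state: PressureFlowState, net: VascularNetwork,
                         i: SectionPlane | int, j: SectionPlane | int,
                         blood: BloodProperties,
                         pressure: str = "total") -> float:
    """R_ij = dP_ij / Q_i in mmHg*s/g (mass flow taken at plane i)."""
    q_i = mass_flow(state, net, i, blood) / MG_PER_G  # g/s
    if q_i == 0.0:
        pi = _plane(net, i)
        raise UndefinedResistanceError(
            f"mass flow through plane {pi.index} is zero; R is undefined")
    dp = (plane_pressure(state, net, i, blood, pressure)
          - plane_pressure(state, net, j, blood, pressure))
    return dp / q_i


@dataclass
class MetricSet:
    """Per-plane and per-pair metrics with deterministic ordering."""

    mode: str
    mass_flows: dict[tuple[int, int], float] = field(default_factory=dict)
    max_velocities: dict[int, float] = field(default_factory=dict)
    resistances: dict[tuple[int, int], float] = field(default_factory=dict)
    areas: dict[int, float] = field(default_factory=dict)
    angles: dict[int, float] = field(default_factory=dict)

    def to_frame(self, animal_id: str = "") -> pd.DataFrame:
        rows = []

        def add(name, value, units):
            rows.append({"animal_id": animal_id, "feature": name,
                         "value": value, "units": units, "mode": self.mode})

        for idx in sorted(self.angles):
            add(f"angle_{idx}", self.angles[idx], "degree")
        for idx in sorted(self.areas):
            add(f"area_S{idx}", self.areas[idx], "mm^2")
        for (i, j) in sorted(self.mass_flows):
            add(f"Q_{i}_{j}", self.mass_flows[(i, j)], "mg/s")
        for idx in sorted(self.max_velocities):
            add(f"vmax_S{idx}", self.max_velocities[idx], "cm/s")
        for (i, j) in sorted(self.resistances):
            add(f"R_{i}_{j}", self.resistances[(i, j)], "mmHg*s/g")
        return pd.DataFrame(rows)


def default_resistance_pairs(net: VascularNetwork) -> list[tuple[int, int]]:
    """Consecutive same-vessel plane pairs present in the network."""
    from .template import VESSEL_PLANE_PAIRS
    return [(i, j) for i, j in VESSEL_PLANE_PAIRS
            if i in net.sections and j in net.sections]


def compute_metric_set(state, net: VascularNetwork, blood: BloodProperties,
                       pairs: list[tuple[int, int]] | None = None,
                       mode: str = "steady",
                       pressure: str = "total") -> MetricSet:
    """Evaluate every registered metric on a solved state.

    ``state`` is a PressureFlowState (steady) or TimeSeriesState
    (transient; mass flows and resistances then use the cycle-averaged
    fields, peak velocities the time-resolved Womersley profile).
    Per-metric failures (e.g. a zero-flow branch) are logged and stored
    as missing values rather than aborting the set.
    """
    if mode not in ("steady", "transient"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "transient" and not isinstance(state, TimeSeriesState):
        raise TypeError("transient metrics need a TimeSeriesState")
    avg = state.average if isinstance(state, TimeSeriesState) else state
    if pairs is None:
        pairs = default_resistance_pairs(net)

    ms = MetricSet(mode=mode)
    from .network import vessel_angle
    for idx in sorted(net.angles):
        ms.angles[idx] = vessel_angle(net, idx)
    for idx, plane in sorted(net.sections.items()):
        ms.areas[idx] = plane.area
        ms.max_velocities[idx] = max_velocity(
            state if mode == "transient" else avg, net, plane, blood, mode=mode)
    for (i, j) in pairs:
        ms.mass_flows[(i, j)] = mass_flow(avg, net, i, blood)
        try:
            ms.resistances[(i, j)] = hydraulic_resistance(
                avg, net, i, j, blood, pressure=pressure)
        except UndefinedResistanceError as exc:
            log.warning("R_%d_%d undefined: %s", i, j, exc)
            ms.resistances[(i, j)] = float("nan")
    return ms
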