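"""Synthetic cohort generation calibrated to published group statistics.

Two complementary paths produce virtual animals:

* the **geometry path** (``sample_animal`` / ``sample_cohort``): a circle-
  of-Willis template whose plane areas and bifurcation angles are drawn
  feature-wise from Normal(mean, SE*sqrt(n)) and truncated to physical
  ranges by resampling, plus per-inlet mean velocities.  These animals
  feed the flow solvers, which then induce physically consistent
  correlations between geometry and hemodynamics.
* the **distribution path** (``direct_feature_matrix``): the 73-parameter
  feature matrix is drawn directly from the group distributions with no
  solver in between, i.e. exactly the printed marginals (untruncated, so
  sample moments are unbiased).

Features are sampled independently except the left/right inlet-velocity
pairs, which share a latent per-animal base (correlation ``coupling``) so
that bilateral differences are a clean within-animal contrast.  The
right-carotid deficit of the 2-month diabetic arm comes from the
parameter table and can be switched off.

Seeds: every animal and every stage derives its own stream from the
master seed by hashing the (stage, identifier) tokens, so results do not
depend on execution order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import VascularNetwork, validate_network
from .params import (GROUP_SIZES, GROUPS, INLET_VELOCITY_FEATURES,
                     GroupParamTable, feature_registry)
from .template import ANGLE_REGISTRY, DEFAULT_SECTION_AREAS, build_cow_template

# inlet-velocity feature -> inlet terminal node
VELOCITY_NODE = {"v_CCA_L": "CCA_L_in", "v_CCA_R": "CCA_R_in",
                 "v_VA_L": "VA_L_in", "v_VA_R": "VA_R_in"}
VELOCITY_PAIRS = [("v_CCA_L", "v_CCA_R"), ("v_VA_L", "v_VA_R")]

_MAX_RESAMPLE = 1000


def derive_seed(master: int, *tokens) -> int:
    """Deterministic 31-bit child seed from a master seed and tokens."""
    h = hashlib.sha256(repr((int(master),) + tuple(tokens)).encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


@dataclass
class VirtualAnimal:
    id: str
    group: str
    network: VascularNetwork
    inlet_velocities: dict[str, float]  # inlet node id -> cm/s


@dataclass
class CohortConfig:
    counts: dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    seed: int = 0
    asymmetry: bool = True   # keep the 2-month diabetic right-CCA deficit
    coupling: float = 0.9    # latent L/R correlation of inlet velocities

    def __post_init__(self):
        for g, c in self.counts.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if c < 1:
                raise ValueError(f"group {g} count must be >= 1")


def _truncated_normal(rng, mean, sd, low=0.0, high=np.inf) -> float:
    for _ in range(_MAX_RESAMPLE):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    raise RuntimeError(f"could not draw a value in ({low}, {high}) "
                       f"around {mean} +/- {sd}")


def _velocity_pair_rows(params: GroupParamTable, group: str, asymmetry: bool):
    for left, right in VELOCITY_PAIRS:
        rl = params.row(left, group, "input")
        rr = params.row(right, group, "input")
        mean_r = rl.mean if (group == "2d" and not asymmetry) else rr.mean
        yield left, right, (rl.mean, rl.sd), (mean_r, rr.sd)


def _sample_pair(rng, stats_l, stats_r, coupling):
    ml, sl = stats_l
    mr, sr = stats_r
    a, b = np.sqrt(coupling), np.sqrt(1.0 - coupling)
    for _ in range(_MAX_RESAMPLE):
        z, el, er = rng.normal(size=3)
        vl = ml + sl * (a * z + b * el)
        vr = mr + sr * (a * z + b * er)
        if vl > 0 and vr > 0:
            return float(vl), float(vr)
    raise RuntimeError("could not draw positive inlet velocities")


def group_template(params: GroupParamTable, group: str) -> VascularNetwork:
    """The template evaluated at a group's mean areas and angles (no noise)."""
    areas = {i: params.row(f"area_S{i}", group, "geom").mean
             for i in sorted(DEFAULT_SECTION_AREAS)}
    angles = {i: params.row(f"angle_{i}", group, "geom").mean
              for i in sorted(ANGLE_REGISTRY)}
    return build_cow_template(areas, angles)


def group_mean_velocities(params: GroupParamTable, group: str,
                          asymmetry: bool = True) -> dict[str, float]:
    """Group-mean inlet velocities keyed by inlet node id."""
    out = {}
    for left, right, sl, sr in _velocity_pair_rows(params, group, asymmetry):
        out[VELOCITY_NODE[left]] = sl[0]
        out[VELOCITY_NODE[right]] = sr[0]
    return out


def sample_animal(params: GroupParamTable, group: str, seed: int,
                  asymmetry: bool = True, coupling: float = 0.9,
                  animal_id: str | None = None) -> VirtualAnimal:
    """One virtual animal: sampled geometry plus inlet velocities."""
    rng = np.random.default_rng(seed)

    areas = {}
    for idx in sorted(DEFAULT_SECTION_AREAS):
        r = params.row(f"area_S{idx}", group, "geom")
        areas[idx] = _truncated_normal(rng, r.mean, r.sd, low=0.0)
    angles = {}
    for idx in sorted(ANGLE_REGISTRY):
        r = params.row(f"angle_{idx}", group, "geom")
        angles[idx] = _truncated_normal(rng, r.mean, r.sd, low=0.0, high=180.0)

    net = build_cow_template(areas, angles)

    velocities: dict[str, float] = {}
    for left, right, sl, sr in _velocity_pair_rows(params, group, asymmetry):
        vl, vr = _sample_pair(rng, sl, sr, coupling)
        velocities[VELOCITY_NODE[left]] = vl
        velocities[VELOCITY_NODE[right]] = vr

    problems = validate_network(net)
    if problems:
        raise RuntimeError(f"sampled network invalid: {problems}")
    return VirtualAnimal(id=animal_id or f"{group}_{seed}", group=group,
                         network=net, inlet_velocities=velocities)


def sample_cohort(cfg: CohortConfig, params: GroupParamTable) -> list[VirtualAnimal]:
    """Virtual animals for every configured group, reproducible per animal."""
    animals = []
    for group in GROUPS:
        for k in range(cfg.counts.get(group, 0)):
            aid = f"{group}_{k + 1:02d}"
            seed = derive_seed(cfg.seed, "animal", group, k)
            animals.append(sample_animal(params, group, seed,
                                         asymmetry=cfg.asymmetry,
                                         coupling=cfg.coupling, animal_id=aid))
    return animals


def sample_feature_values(params: GroupParamTable, feature: str, group: str,
                          mode: str, n: int, rng) -> np.ndarray:
    """n untruncated draws of one feature column (distribution path)."""
    r = params.matrix_row(feature, group, mode)
    return rng.normal(r.mean, r.sd, size=n)


def direct_feature_matrix(cfg: CohortConfig, params: GroupParamTable,
                          mode: str = "steady",
                          include_inlet_velocities: bool = False) -> pd.DataFrame:
    """Animals x features matrix drawn straight from the group distributions.

    Columns are the 73 registered parameters (plus the four inlet
    velocities when requested) and a leading ``group`` column; the index
    is the animal id.  No solver is involved, so column moments match the
    parameter table exactly in expectation.
    """
    feats = feature_registry(mode)
    rng = np.random.default_rng(derive_seed(cfg.seed, "direct", mode))

    blocks = []
    for group in GROUPS:
        n = cfg.counts.get(group, 0)
        if n == 0:
            continue
        data = {"group": [group] * n}
        for f in feats:
            data[f] = sample_feature_values(params, f, group, mode, n, rng)
        if include_inlet_velocities:
            for left, right, sl, sr in _velocity_pair_rows(params, group, cfg.asymmetry):
                a, b = np.sqrt(cfg.coupling), np.sqrt(1.0 - cfg.coupling)
                z = rng.normal(size=n)
                data[left] = sl[0] + sl[1] * (a * z + b * rng.normal(size=n))
                data[right] = sr[0] + sr[1] * (a * z + b * rng.normal(size=n))
        idx = [f"{group}_{k + 1:02d}" for k in range(n)]
        blocks.append(pd.DataFrame(data, index=idx))
    out = pd.concat(blocks)
    out.index.name = "animal_id"
    return out
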