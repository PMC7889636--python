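"""Per-feature, per-group summary statistics driving the synthetic cohort.

The packaged CSV (``data/group_params_published.csv``) transcribes every
group mean +/- SE printed in the study's results: internal-carotid and
basilar lumen areas, the right ACA-MCA angle, and the steady/transient
hemodynamic rows (hydraulic resistance between planes 5 and 6, peak
velocities at planes 1/13/15/16/22, mass flow between planes 15 and 16).

The statistical feature space is the 73-parameter registry: 7 angles,
22 plane areas, 11 per-vessel mass flows, 22 plane peak velocities and
11 per-vessel resistances.  Rows the source text leaves to its
supplement (every remaining feature, and the four inlet velocities) are
filled with documented placeholder distributions, tagged
``source=placeholder`` and identical across groups unless a published
row or the inlet-velocity rules below say otherwise, so that synthetic
group differences come only from published effects:

* carotid inflow: controls 12 cm/s both sides; the 1-month diabetic arm
  20% lower bilaterally; the 2-month diabetic arm 20% lower on the
  right side only (the published asymmetry pattern);
* vertebral inflow: 5.7 cm/s everywhere;
* features with a published control (2c) row reuse it as the
  placeholder for the unpublished groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .template import (DEFAULT_ANGLES_DEG, DEFAULT_SECTION_AREAS,
                       VESSEL_PLANE_PAIRS)

GROUPS = ("1c", "1d", "2c", "2d")
GROUP_SIZES = {"1c": 7, "1d": 5, "2c": 10, "2d": 9}

MODES = ("steady", "transient")

INLET_VELOCITY_FEATURES = ("v_CCA_L", "v_CCA_R", "v_VA_L", "v_VA_R")

# side-resolved placeholder rules for the supplement-only inlet velocities
_CCA_BASE, _CCA_DEFICIT = 12.0, 0.8
_VA_BASE = 5.7
_CCA_SE, _VA_SE = 0.8, 0.5


def feature_registry(mode: str) -> list[str]:
    """Ordered names of the 73 statistical parameters for one mode."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    feats = [f"angle_{i}" for i in sorted(DEFAULT_ANGLES_DEG)]
    feats += [f"area_S{i}" for i in sorted(DEFAULT_SECTION_AREAS)]
    feats += [f"Q_{i}_{j}" for i, j in VESSEL_PLANE_PAIRS]
    feats += [f"vmax_S{i}" for i in sorted(DEFAULT_SECTION_AREAS)]
    feats += [f"R_{i}_{j}" for i, j in VESSEL_PLANE_PAIRS]
    return feats


def _mode_of(feature: str) -> str:
    """geom for geometry, input for inlet velocities, else hemodynamic."""
    if feature.startswith(("angle_", "area_")):
        return "geom"
    if feature in INLET_VELOCITY_FEATURES:
        return "input"
    return "hemo"


# class defaults for features without any published anchor
_Q_BASE = {(1, 2): 5.0, (3, 4): 8.0, (5, 6): 7.5, (7, 8): 3.0, (9, 10): 3.0,
           (11, 12): 4.0, (13, 14): 4.0, (15, 16): 4.7, (17, 18): 4.7,
           (19, 20): 3.0, (21, 22): 3.0}
_R_BASE = {(1, 2): 35.0, (3, 4): 55.0, (5, 6): 57.0, (7, 8): 75.0, (9, 10): 75.0,
           (11, 12): 60.0, (13, 14): 60.0, (15, 16): 150.0, (17, 18): 150.0,
           (19, 20): 70.0, (21, 22): 70.0}
_VMAX_BASE = 12.0


def _class_default(feature: str) -> tuple[float, float]:
    """(mean, se) placeholder for a feature with no published row at all."""
    if feature.startswith("angle_"):
        return DEFAULT_ANGLES_DEG[int(feature.split("_")[1])], 3.0
    if feature.startswith("area_S"):
        m = DEFAULT_SECTION_AREAS[int(feature[6:])]
        return m, 0.08 * m
    if feature.startswith("vmax_S"):
        return _VMAX_BASE, 1.5
    if feature.startswith("Q_"):
        _, i, j = feature.split("_")
        m = _Q_BASE[(int(i), int(j))]
        return m, 0.1 * m
    if feature.startswith("R_"):
        _, i, j = feature.split("_")
        m = _R_BASE[(int(i), int(j))]
        return m, 0.1 * m
    raise KeyError(f"no placeholder rule for feature {feature!r}")


def _velocity_rows() -> list[dict]:
    rows = []
    for group in GROUPS:
        n = GROUP_SIZES[group]
        for side in ("L", "R"):
            mean = _CCA_BASE
            if group == "1d" or (group == "2d" and side == "R"):
                mean = _CCA_BASE * _CCA_DEFICIT
            rows.append({"feature": f"v_CCA_{side}", "group": group,
                         "mode": "input", "mean": mean, "se": _CCA_SE,
                         "n": n, "source": "placeholder"})
            rows.append({"feature": f"v_VA_{side}", "group": group,
                         "mode": "input", "mean": _VA_BASE, "se": _VA_SE,
                         "n": n, "source": "placeholder"})
    return rows


@dataclass(frozen=True)
class ParamRow:
    feature: str
    group: str
    mode: str
    mean: float
    se: float
    n: int
    source: str

    @property
    def sd(self) -> float:
        """Population SD implied by the printed SE: sd = se * sqrt(n)."""
        return self.se * np.sqrt(self.n)


class GroupParamTable:
    """Lookup of (feature, group, mode) -> mean/SE/n, with provenance."""

    def __init__(self, frame: pd.DataFrame):
        required = {"feature", "group", "mode", "mean", "se", "n", "source"}
        if not required.issubset(frame.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        if (frame["se"] <= 0).any():
            raise ValueError("all SE values must be > 0")
        bad = ~frame["group"].isin(GROUPS)
        if bad.any():
            raise ValueError(f"unknown groups: {sorted(frame.loc[bad, 'group'].unique())}")
        dup = frame.duplicated(["feature", "group", "mode"])
        if dup.any():
            raise ValueError("duplicate (feature, group, mode) rows")
        self.frame = frame.reset_index(drop=True)
        self._index = {
            (r.feature, r.group, r.mode): ParamRow(r.feature, r.group, r.mode,
                                                   float(r.mean), float(r.se),
                                                   int(r.n), r.source)
            for r in frame.itertuples()
        }

    # -- construction -----------------------------------------------------
    @classmethod
    def published_rows(cls) -> pd.DataFrame:
        with resources.files("cowhemo.data").joinpath("group_params_published.csv").open() as fh:
            return pd.read_csv(fh)

    @classmethod
    def packaged(cls) -> "GroupParamTable":
        """Full table: published rows completed with placeholder rows."""
        published = cls.published_rows()
        by_key = {(r.feature, r.group, r.mode): r for r in published.itertuples()}

        rows = [dict(r._asdict()) for r in published.itertuples(index=False)]

        geo = [f for f in feature_registry("steady") if _mode_of(f) == "geom"]
        hemo = [f for f in feature_registry("steady") if _mode_of(f) == "hemo"]
        wanted = [(f, "geom") for f in geo]
        wanted += [(f, mode) for f in hemo for mode in MODES]

        for feature, mode in wanted:
            for group in GROUPS:
                if (feature, group, mode) in by_key:
                    continue
                anchor = by_key.get((feature, "2c", mode)) or by_key.get((feature, "1c", mode))
                if anchor is not None:
                    mean, se = float(anchor.mean), float(anchor.se)
                else:
                    mean, se = _class_default(feature)
                rows.append({"feature": feature, "group": group, "mode": mode,
                             "mean": mean, "se": se, "n": GROUP_SIZES[group],
                             "source": "placeholder"})
        rows.extend(_velocity_rows())
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path) -> "GroupParamTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # -- access -----------------------------------------------------------
    def row(self, feature: str, group: str, mode: str | None = None) -> ParamRow:
        if mode is None:
            mode = _mode_of(feature)
            if mode == "hemo":
                raise ValueError(f"{feature!r} needs an explicit mode (steady/transient)")
        key = (feature, group, mode)
        if key not in self._index:
            raise KeyError(f"no table row for feature={feature!r} group={group!r} "
                           f"mode={mode!r}")
        return self._index[key]

    def matrix_row(self, feature: str, group: str, mode: str) -> ParamRow:
        """Row for a feature-matrix column: geometry and inlet velocities are
        mode independent, hemodynamic features use the requested mode."""
        kind = _mode_of(feature)
        return self.row(feature, group, kind if kind in ("geom", "input") else mode)

    def published_subset(self) -> pd.DataFrame:
        return self.frame[self.frame["source"] == "published"].reset_index(drop=True)
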