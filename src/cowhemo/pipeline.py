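"""End-to-end orchestration: cohort -> solver -> metrics -> statistics.

The simulation protocol applied to each virtual animal mirrors the
study design: outlets 7 and 8 (the posterior cerebral efferents, close
to the basilar bifurcation) are extended by 1 mm, then both a steady and
a pulsatile solve are run and the 73-parameter metric set extracted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import (CohortConfig, VirtualAnimal, derive_seed,
                     direct_feature_matrix, VELOCITY_PAIRS)
from .metrics import compute_metric_set
from .params import GroupParamTable, feature_registry
from .steady import BloodProperties, lengthen_outlets, solve_steady
from .stats import (anova_on_scores, fit_plsda, paired_asymmetry_test,
                    two_group_ttest, benjamini_hochberg)
from .transient import TransientConfig, Waveform, solve_transient

log = logging.getLogger(__name__)

OUTLET_EXTENSION_MM = 1.0


def protocol_network(animal: VirtualAnimal):
    """Animal's network with the protocol's 1 mm outlet extensions."""
    net = animal.network
    return lengthen_outlets(net, net.outlets[6:8], OUTLET_EXTENSION_MM)


def solve_animal(animal: VirtualAnimal, blood: BloodProperties | None = None,
                 mode: str = "steady", waveform: Waveform | None = None,
                 cfg: TransientConfig | None = None) -> pd.DataFrame:
    """Solve one animal and return its tidy metric rows."""
    blood = blood or BloodProperties()
    net = protocol_network(animal)
    if mode == "steady":
        state = solve_steady(net, animal.inlet_velocities, blood)
    elif mode == "transient":
        state = solve_transient(net, animal.inlet_velocities, blood,
                                waveform=waveform, cfg=cfg)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ms = compute_metric_set(state, net, blood, mode=mode)
    return ms.to_frame(animal_id=animal.id)


def cohort_metrics(animals: list[VirtualAnimal], mode: str = "steady",
                   blood: BloodProperties | None = None,
                   waveform: Waveform | None = None,
                   cfg: TransientConfig | None = None) -> pd.DataFrame:
    """Tidy metrics for a whole cohort; per-animal failures are logged
    and skipped so one bad geometry does not abort the run."""
    frames = []
    for animal in animals:
        try:
            df = solve_animal(animal, blood=blood, mode=mode,
                              waveform=waveform, cfg=cfg)
        except Exception:  # noqa: BLE001 - per-animal isolation is the point
            log.exception("solve failed for animal %s; skipping", animal.id)
            continue
        df.insert(1, "group", animal.group)
        frames.append(df)
    if not frames:
        raise RuntimeError("no animal could be solved")
    return pd.concat(frames, ignore_index=True)


def metrics_to_matrix(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy metric rows into an animals x features matrix."""
    wide = tidy.pivot_table(index="animal_id", columns="feature",
                            values="value", aggfunc="first")
    groups = tidy.drop_duplicates("animal_id").set_index("animal_id")["group"]
    wide.insert(0, "group", groups)
    return wide


def ttest_table(matrix: pd.DataFrame, group_a: str, group_b: str,
                variant: str = "student", features=None,
                bh_correct: bool = False) -> pd.DataFrame:
    """Per-feature two-group t-tests over all (or selected) features."""
    if features is None:
        features = [c for c in matrix.columns if c != "group"]
    rows = []
    for f in features:
        try:
            rows.append(two_group_ttest(matrix, f, group_a, group_b,
                                        variant=variant).as_dict())
        except Exception as exc:  # degenerate feature columns are reported
            log.warning("t-test failed for %s: %s", f, exc)
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        out["pvalue_bh"] = benjamini_hochberg(out["pvalue"].to_numpy())
    return out


def count_significant(table: pd.DataFrame, alpha: float = 0.05,
                      column: str = "pvalue") -> int:
    return int((table[column] <= alpha).sum())


def asymmetry_table(matrix: pd.DataFrame, pairs=VELOCITY_PAIRS,
                    groups=("1c", "1d", "2c", "2d")) -> pd.DataFrame:
    """Paired L/R tests for every pair and group present in the matrix."""
    rows = []
    present = set(matrix["group"])
    for group in groups:
        if group not in present:
            continue
        for left, right in pairs:
            if left not in matrix.columns or right not in matrix.columns:
                continue
            rows.append(paired_asymmetry_test(matrix, left, right, group).as_dict())
    return pd.DataFrame(rows)


def stats_bundle(matrix: pd.DataFrame, seed: int = 0,
                 variant: str = "student", n_components: int = 2) -> dict:
    """The full statistics stage on one feature matrix.

    Returns a dict of DataFrames: pairwise t-tests for the two
    same-duration comparisons, PLS-DA scores with group means +/- SE,
    the two-way ANOVA on the score axes, and the L/R asymmetry tests.
    """
    feats = [c for c in matrix.columns if c != "group"
             and not c.startswith("v_")]
    ttests = {}
    for ga, gb in (("1c", "1d"), ("2c", "2d")):
        if {ga, gb} <= set(matrix["group"]):
            ttests[f"{ga}_vs_{gb}"] = ttest_table(matrix, ga, gb,
                                                  variant=variant, features=feats)

    model = fit_plsda(matrix[feats], matrix["group"], n_components=n_components)
    scores = model.scores_frame(matrix["group"], index=matrix.index)
    score_summary = (scores.groupby("group")
                     .agg(["mean", "sem"])
                     .rename(columns={"sem": "se"}))
    if set(matrix["group"]) == {"1c", "1d", "2c", "2d"}:
        anova = anova_on_scores(scores)
    else:
        log.warning("ANOVA skipped: needs all four pathology x duration cells")
        anova = pd.DataFrame(columns=["axis", "effect", "F", "df1", "df2", "pvalue"])
    asym = asymmetry_table(matrix)
    return {"ttests": ttests, "pls_model": model, "scores": scores,
            "score_summary": score_summary, "anova": anova, "asymmetry": asym}


def replicate_flag_counts(params: GroupParamTable, n_replicates: int = 100,
                          master_seed: int = 0, mode: str = "steady",
                          alpha: float = 0.05) -> pd.DataFrame:
    """Flagged-feature counts per comparison over seeded cohort replicates.

    For each replicate a fresh direct-path cohort at the study group
    sizes is drawn and every registered feature t-tested for the
    1-month and the 2-month control/diabetes comparisons; the asymmetry
    test is run per group on the inlet-velocity pairs.
    """
    feats = feature_registry(mode)
    rows = []
    for rep in range(n_replicates):
        cfg = CohortConfig(seed=derive_seed(master_seed, "replicate", rep))
        matrix = direct_feature_matrix(cfg, params, mode=mode,
                                       include_inlet_velocities=True)
        rec = {"replicate": rep}
        for ga, gb in (("1c", "1d"), ("2c", "2d")):
            tab = ttest_table(matrix, ga, gb, features=feats)
            rec[f"flags_{ga}_vs_{gb}"] = count_significant(tab, alpha)
        asym = asymmetry_table(matrix, pairs=[("v_CCA_L", "v_CCA_R")])
        for _, r in asym.iterrows():
            rec[f"asym_reject_{r['groups']}"] = bool(r["pvalue"] <= alpha)
        rows.append(rec)
    return pd.DataFrame(rows)
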