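"""Group-discrimination statistics for vascular feature matrices.

The pipeline mirrors a conventional small-cohort analysis: per-feature
normality screening (Kolmogorov-Smirnov with estimated parameters, i.e.
the Lilliefors situation, with a Monte-Carlo calibrated p-value), Student
t-tests between arms (pooled by default, Welch optional), paired
left/right asymmetry tests, PLS-DA via NIPALS with variable-importance
(VIP) backward elimination under a cross-validated accuracy guard, and a
two-way ANOVA (pathology x duration) on the PLS scores.

No multiple-testing correction is applied by default — per-feature raw
p-values across the 73 parameters are reported as-is, with an optional
Benjamini-Hochberg switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


class DegenerateSampleError(ValueError):
    pass


@dataclass
class TestResult:
    feature: str
    groups: tuple[str, ...]
    statistic: float
    df: float
    pvalue: float
    group_stats: dict[str, tuple[float, float]] = field(default_factory=dict)  # mean, SE
    kind: str = ""

    def as_dict(self) -> dict:
        d = {"feature": self.feature, "groups": "/".join(self.groups),
             "statistic": self.statistic, "df": self.df, "pvalue": self.pvalue,
             "kind": self.kind}
        for g, (m, s) in self.group_stats.items():
            d[f"mean_{g}"] = m
            d[f"se_{g}"] = s
        return d


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

def _lilliefors_stat(x: np.ndarray) -> float:
    x = np.sort(x)
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    up = np.arange(1, n + 1) / n - cdf
    lo = cdf - np.arange(0, n) / n
    return float(max(up.max(), lo.max()))


def ks_normality(values, feature: str = "", group: str = "",
                 n_mc: int = 10_000, seed: int = 0) -> TestResult:
    """KS test of normality with plug-in mean/SD.

    Because the parameters are estimated from the sample, the classical
    KS null distribution is anti-conservative; the p-value is therefore
    calibrated by Monte Carlo (``n_mc`` standard-normal samples of the
    same size, same estimator).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise DegenerateSampleError("normality test needs at least 3 finite values")
    if np.std(x, ddof=1) == 0:
        raise DegenerateSampleError("sample has zero variance")
    d_obs = _lilliefors_stat(x)

    rng = np.random.default_rng(seed)
    sims = rng.normal(size=(n_mc, x.size))
    zs = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
    zs.sort(axis=1)
    cdf = sps.norm.cdf(zs)
    grid_hi = np.arange(1, x.size + 1) / x.size
    grid_lo = np.arange(0, x.size) / x.size
    d_null = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
    p = (1 + np.sum(d_null >= d_obs)) / (n_mc + 1)
    return TestResult(feature=feature, groups=(group,), statistic=d_obs,
                      df=float(x.size), pvalue=float(p),
                      group_stats={group: (float(x.mean()),
                                           float(x.std(ddof=1) / np.sqrt(x.size)))},
                      kind="ks_normality")


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def _group_values(matrix: pd.DataFrame, feature: str, group: str) -> np.ndarray:
    if feature not in matrix.columns:
        raise KeyError(f"feature {feature!r} not in matrix")
    v = matrix.loc[matrix["group"] == group, feature].to_numpy(dtype=float)
    return v[np.isfinite(v)]


def two_group_ttest(matrix: pd.DataFrame, feature: str, group_a: str,
                    group_b: str, variant: str = "student") -> TestResult:
    """Two-sided two-sample t-test on one feature column.

    ``variant='student'`` pools variances (the classical test);
    ``variant='welch'`` drops the equal-variance assumption.
    """
    a = _group_values(matrix, feature, group_a)
    b = _group_values(matrix, feature, group_b)
    if a.size < 2 or b.size < 2:
        raise DegenerateSampleError("need >=2 values per group")
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        # identical constant samples: no evidence against equality
        res_stat, res_p = 0.0, 1.0
    else:
        res_stat, res_p = float(res.statistic), float(res.pvalue)
    df = float(res.df) if hasattr(res, "df") else a.size + b.size - 2
    return TestResult(feature=feature, groups=(group_a, group_b),
                      statistic=res_stat, df=float(df), pvalue=res_p,
                      group_stats={
                          group_a: (float(a.mean()), float(a.std(ddof=1) / np.sqrt(a.size))),
                          group_b: (float(b.mean()), float(b.std(ddof=1) / np.sqrt(b.size)))},
                      kind=f"ttest_{variant}")


def ttest_from_summary(mean_a: float, se_a: float, n_a: int,
                       mean_b: float, se_b: float, n_b: int,
                       variant: str = "student",
                       feature: str = "", groups=("A", "B")) -> TestResult:
    """t-test from printed summary statistics (mean, SE, n) per group.

    Lets published result-table rows be re-tested directly.
    """
    sd_a, sd_b = se_a * np.sqrt(n_a), se_b * np.sqrt(n_b)
    stat, p = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                       equal_var=(variant == "student"))
    if variant == "student":
        df = n_a + n_b - 2
    else:
        va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
        df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    return TestResult(feature=feature, groups=tuple(groups), statistic=float(stat),
                      df=float(df), pvalue=float(p),
                      group_stats={groups[0]: (mean_a, se_a), groups[1]: (mean_b, se_b)},
                      kind=f"ttest_{variant}_summary")


def paired_asymmetry_test(matrix: pd.DataFrame, left_feature: str,
                          right_feature: str, group: str) -> TestResult:
    """Paired t-test on within-animal left-minus-right differences."""
    sub = matrix[matrix["group"] == group]
    left = sub[left_feature].to_numpy(dtype=float)
    right = sub[right_feature].to_numpy(dtype=float)
    if left.size != right.size or left.size < 2:
        raise DegenerateSampleError("need >=2 complete L/R pairs")
    if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
        raise DegenerateSampleError("missing values break the L/R pairing")
    d = left - right
    n = d.size
    if np.all(d == 0.0):
        stat, p = 0.0, 1.0
    elif d.std(ddof=1) == 0:
        raise DegenerateSampleError("constant nonzero L-R offset has zero variance")
    else:
        stat, p = sps.ttest_rel(left, right)
        stat, p = float(stat), float(p)
    return TestResult(feature=f"{left_feature}-{right_feature}", groups=(group,),
                      statistic=stat, df=float(n - 1), pvalue=p,
                      group_stats={group: (float(d.mean()),
                                           float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0)},
                      kind="paired_t")


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional switch; off by default upstream)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """NIPALS PLS2 fit against one-hot group membership.

    Matrices follow the standard notation: X weights W (p x k), X
    loadings P (p x k), Y loadings Q (g x k), X scores T (n x k).
    """

    features: list[str]
    classes: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    ssy_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def rotations(self) -> np.ndarray:
        """R = W (P^T W)^{-1}; new scores are X_scaled @ R."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    def transform(self, X) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        return Xs @ self.rotations()

    def predict_class(self, X) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        yhat = Xs @ (self.rotations() @ self.Q.T) + self.y_mean
        return np.asarray(self.classes)[np.argmax(yhat, axis=1)]

    def scores_frame(self, labels, index=None) -> pd.DataFrame:
        cols = {f"Y{k + 1}": self.T[:, k] for k in range(self.n_components)}
        df = pd.DataFrame(cols, index=index)
        df.insert(0, "group", list(labels))
        return df

    def vip(self) -> np.ndarray:
        """Variable importance in projection, one value per feature."""
        w_norm = self.W / np.linalg.norm(self.W, axis=0, keepdims=True)
        ssy = self.ssy_explained
        p = self.W.shape[0]
        return np.sqrt(p * (w_norm ** 2 @ ssy) / ssy.sum())


def _one_hot(labels) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        y[i, classes.index(lab)] = 1.0
    return y, classes


def fit_plsda(X, labels, n_components: int = 2, max_iter: int = 10_000,
              tol: float = 1e-10) -> PlsModel:
    """PLS-DA by NIPALS: alternating weight/score regressions with
    deflation, on autoscaled X against centred one-hot Y."""
    if isinstance(X, pd.DataFrame):
        features = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        features = [f"x{i}" for i in range(Xa.shape[1])]
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("PLS-DA needs at least two groups")
    if Xa.shape[0] != len(labels):
        raise ValueError("X rows and labels disagree")

    x_mean = Xa.mean(axis=0)
    x_std = Xa.std(axis=0, ddof=1)
    x_std = np.where(x_std > 0, x_std, 1.0)  # constant columns get zero weight anyway
    Xs = (Xa - x_mean) / x_std

    Y, classes = _one_hot(labels)
    y_mean = Y.mean(axis=0)
    Ys = Y - y_mean

    n, p = Xs.shape
    k_max = min(n_components, p, n - 1)
    W = np.zeros((p, k_max))
    P = np.zeros((p, k_max))
    Q = np.zeros((len(classes), k_max))
    T = np.zeros((n, k_max))
    ssy = np.zeros(k_max)

    Xd, Yd = Xs.copy(), Ys.copy()
    for k in range(k_max):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        if np.allclose(u, 0):
            u = Yd[:, 0] + 1e-12
        t_old = None
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise FloatingPointError("NIPALS collapse: zero weight vector")
            w /= nw
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                raise FloatingPointError("NIPALS collapse: zero score vector")
            q = Yd.T @ t / tt
            u = Yd @ q / max(q @ q, 1e-300)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        else:
            raise FloatingPointError(
                f"NIPALS did not converge in {max_iter} iterations (component {k + 1})")
        pk = Xd.T @ t / tt
        W[:, k], P[:, k], Q[:, k], T[:, k] = w, pk, q, t
        ssy[k] = tt * (q @ q)
        Xd = Xd - np.outer(t, pk)
        Yd = Yd - np.outer(t, q)

    return PlsModel(features=features, classes=classes, x_mean=x_mean,
                    x_std=x_std, y_mean=y_mean, W=W, P=P, Q=Q, T=T,
                    ssy_explained=ssy)


# ---------------------------------------------------------------------------
# stepwise variable elimination
# ---------------------------------------------------------------------------

@dataclass
class EliminationResult:
    retained: list[str]
    model: PlsModel
    cv_accuracy: float
    stable: bool
    history: list[tuple[str, float]] = field(default_factory=list)


def _stratified_folds(labels, n_folds, rng):
    labels = np.asarray(labels)
    folds = [[] for _ in range(n_folds)]
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.asarray(sorted(f)) for f in folds if len(f)]


def cross_validated_accuracy(X: pd.DataFrame, labels, n_components=2,
                             n_folds=5, seed=0) -> float:
    """Stratified k-fold accuracy of PLS-DA class prediction."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(list(labels))
    folds = _stratified_folds(labels, min(n_folds, len(labels)), rng)
    hits = 0
    for fold in folds:
        mask = np.ones(len(labels), dtype=bool)
        mask[fold] = False
        model = fit_plsda(X.iloc[mask], labels[mask],
                          n_components=min(n_components, X.shape[1]))
        pred = model.predict_class(X.iloc[fold])
        hits += int(np.sum(pred == labels[fold]))
    return hits / len(labels)


def stepwise_elimination(X: pd.DataFrame, labels, n_components: int = 2,
                         tol: float = 0.05, n_folds: int = 5, seed: int = 0,
                         min_features: int = 1) -> EliminationResult:
    """Backward VIP-guided variable elimination.

    Repeatedly removes the lowest-VIP feature as long as cross-validated
    classification accuracy does not degrade by more than ``tol`` below
    the best accuracy seen so far.  ``tol=inf`` therefore strips the
    model down to ``min_features``.  Deterministic for a fixed seed
    (which fixes the CV folds).
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    feats = list(X.columns)
    labels = np.asarray(list(labels))
    initial = cross_validated_accuracy(X, labels, n_components, n_folds, seed)
    best = initial
    history: list[tuple[str, float]] = []

    while len(feats) > min_features:
        model = fit_plsda(X[feats], labels,
                          n_components=min(n_components, len(feats)))
        vic = model.vip()
        candidate = feats[int(np.argmin(vic))]
        trial = [f for f in feats if f != candidate]
        acc = cross_validated_accuracy(X[trial], labels,
                                       min(n_components, len(trial)),
                                       n_folds, seed)
        if acc >= best - tol:
            feats = trial
            best = max(best, acc)
            history.append((candidate, acc))
        else:
            break

    final = fit_plsda(X[feats], labels, n_components=min(n_components, len(feats)))
    final_acc = cross_validated_accuracy(X[feats], labels,
                                         min(n_components, len(feats)),
                                         n_folds, seed)
    chance = max(np.bincount(pd.factorize(labels)[0])) / len(labels)
    # stability is judged on the pre-elimination model: the post-selection
    # accuracy is optimistically biased by the search itself
    return EliminationResult(retained=feats, model=final, cv_accuracy=final_acc,
                             stable=bool(initial > chance + 0.1),
                             history=history)


# ---------------------------------------------------------------------------
# two-way ANOVA on PLS scores
# ---------------------------------------------------------------------------

def group_factors(groups) -> pd.DataFrame:
    """Split arm labels like '2d' into pathology and duration factors."""
    groups = list(groups)
    for g in groups:
        if len(g) != 2 or g[0] not in "12" or g[1] not in "cd":
            raise ValueError(f"cannot parse arm label {g!r}")
    return pd.DataFrame({
        "pathology": ["diabetes" if g[1] == "d" else "control" for g in groups],
        "duration": [int(g[0]) for g in groups],
    })


def anova_on_scores(scores: pd.DataFrame, include_interaction: bool = False,
                    typ: int = 2) -> pd.DataFrame:
    """Two-way ANOVA (pathology, duration) per score axis.

    Default is the additive model with Type II sums of squares on the
    unbalanced 2x2 design; with 31 animals this gives the residual
    df = 28 of a main-effects analysis.  The interaction term can be
    added, at the cost of one residual df.
    """
    axes = [c for c in scores.columns if c.startswith("Y")]
    if not axes:
        raise ValueError("scores frame has no Y columns")
    fac = group_factors(scores["group"])
    cells = fac.value_counts()
    if len(cells) < 4 or (cells < 2).any():
        raise ValueError("each pathology x duration cell needs >= 2 animals")

    rows = []
    rhs = "C(pathology) + C(duration)"
    if include_interaction:
        rhs += " + C(pathology):C(duration)"
    for axis in axes:
        df = fac.copy()
        df["score"] = scores[axis].to_numpy(dtype=float)
        if np.allclose(df["score"].var(ddof=0), 0.0):
            for effect in ("pathology", "duration"):
                rows.append({"axis": axis, "effect": effect, "F": 0.0,
                             "df1": 1, "df2": len(df) - 3, "pvalue": 1.0})
            continue
        fit = smf.ols(f"score ~ {rhs}", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=typ)
        for term in tab.index:
            if term == "Residual":
                continue
            effect = (term.replace("C(", "").replace(")", "")
                      .replace(":", "x"))
            rows.append({"axis": axis, "effect": effect,
                         "F": float(tab.loc[term, "F"]),
                         "df1": int(tab.loc[term, "df"]),
                         "df2": int(fit.df_resid),
                         "pvalue": float(tab.loc[term, "PR(>F)"])})
    return pd.DataFrame(rows)
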