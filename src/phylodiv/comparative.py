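"""Benchmarking framework for ranking diversity measures.

Given a samples-by-measures matrix and per-sample metadata, quantifies how
well each measure tracks community state: pairwise Pearson correlation and
its 1-r hierarchical clustering, leave-one-out logistic-regression accuracy
against a binary label, linear R^2 against a continuous score, t-test/ANOVA
stratification p-values, and mean-rank aggregation across those metrics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = [
    "pearson_matrix",
    "cluster_measures",
    "linkage_to_newick",
    "loo_logistic_accuracy",
    "linear_r2",
    "welch_t_pvalue",
    "anova_pvalue",
    "mean_rank_report",
]


def pearson_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every pair of measure columns; unit diagonal."""
    if m.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlation")
    arr = m.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("measure matrix contains non-finite values")
    sd = arr.std(axis=0)
    constant = [c for c, s in zip(m.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant measure column(s): {constant}")
    r = np.corrcoef(arr, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=m.columns, columns=m.columns)


def cluster_measures(r: pd.DataFrame, linkage: str = "complete"):
    """Agglomerative clustering of measures with distance d = 1 - r.

    Measures are ordered lexicographically before clustering so merge-order
    ties resolve deterministically. Returns ``(Z, labels)`` where ``Z`` is a
    SciPy linkage matrix over ``labels``.
    """
    arr = r.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    labels = sorted(str(c) for c in r.columns)
    rs = r.loc[labels, labels].to_numpy(dtype=float)
    d = 1.0 - rs
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    condensed = d[np.triu_indices_from(d, k=1)]
    Z = hierarchy.linkage(condensed, method=linkage)
    return Z, labels


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as Newick; branch lengths are merge-height
    increments so leaf-to-root distance equals the final merge height."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def render(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        a, b = int(a), int(b)
        return (
            f"({render(a)}:{heights[i] - heights[a]:.6g},"
            f"{render(b)}:{heights[i] - heights[b]:.6g})"
        )

    for idx, row in enumerate(Z):
        heights[n + idx] = float(row[2])
    return render(n + len(Z) - 1) + ";"


def loo_logistic_accuracy(values, labels, max_iter: int = 200) -> float:
    """Leave-one-out accuracy of a single-predictor logistic regression.

    Each held-out sample is classified at probability cutoff 0.5 by an
    intercept + slope model fit on the rest (bounded-iteration L-BFGS,
    unpenalized). Under complete separation the fitted direction still
    classifies correctly; constant predictors degrade to the majority class
    with a warning.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and labels must be 1-D and the same length")
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if np.ptp(x) == 0:
        warnings.warn("constant predictor: accuracy equals the majority-class frequency", UserWarning)
    correct = 0
    idx = np.arange(x.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i in idx:
            mask = idx != i
            xt, yt = x[mask], y[mask]
            if np.unique(yt).size < 2:
                # held-out point is the sole member of its class
                pred = np.bincount(yt).argmax()
            elif np.ptp(xt) == 0:
                pred = np.bincount(yt).argmax()
            else:
                # near-unpenalized fit; the tiny ridge keeps complete
                # separation finite while leaving the decision direction intact
                clf = LogisticRegression(C=1e12, solver="lbfgs", max_iter=max_iter)
                clf.fit(xt[:, None], yt)
                pred = int(clf.predict(x[i : i + 1, None])[0])
            correct += int(pred == y[i])
    return correct / x.size


def linear_r2(x, y) -> float:
    """Coefficient of determination of the least-squares line y ~ x."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(xa) == 0:
        raise ValueError("constant predictor")
    r = stats.pearsonr(xa, ya).statistic
    return float(r * r)


def welch_t_pvalue(group_a, group_b, equal_var: bool = False) -> float:
    """Two-sided t-test p-value; Welch (unequal variance) by default."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def anova_pvalue(values, strata, second_factor=None) -> float:
    """Fixed-effects ANOVA p-value across strata.

    One-way F-test by default; with ``second_factor`` an additive two-factor
    ANOVA is fit and the first factor's p-value reported.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(strata)
    levels, counts = np.unique(s, return_counts=True)
    if levels.size < 2:
        raise ValueError("need at least 2 strata")
    small = levels[counts < 2]
    if small.size:
        raise ValueError(f"strata with fewer than 2 samples: {small.tolist()}")
    if second_factor is None:
        groups = [v[s == lev] for lev in levels]
        return float(stats.f_oneway(*groups).pvalue)
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"value": v, "factor1": s.astype(str), "factor2": np.asarray(second_factor).astype(str)})
    model = ols("value ~ C(factor1) + C(factor2)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return float(table.loc["C(factor1)", "PR(>F)"])


def mean_rank_report(metrics: pd.DataFrame, orientations: dict[str, str]) -> pd.DataFrame:
    """Rank measures on each metric and order by mean rank.

    ``metrics`` has one row per measure and one column per metric;
    ``orientations`` maps each metric to ``higher_better`` or
    ``lower_better``. Rank 1 is best; ties get average ranks. Returns the
    metric columns plus ``rank_<metric>`` columns and ``mean_rank``, rows
    sorted ascending by mean rank.
    """
    missing_cols = set(orientations) - set(metrics.columns)
    if missing_cols:
        raise ValueError(f"metrics table lacks columns: {sorted(missing_cols)}")
    if metrics[list(orientations)].isna().any().any():
        bad = metrics[list(orientations)].isna().stack()
        loc = bad[bad].index[0]
        raise ValueError(f"missing metric value for measure {loc[0]!r}, metric {loc[1]!r}")
    out = metrics.copy()
    rank_cols = []
    for metric, orient in orientations.items():
        if orient not in ("higher_better", "lower_better"):
            raise ValueError(f"bad orientation {orient!r} for metric {metric!r}")
        asc = orient == "lower_better"
        ranks = metrics[metric].rank(ascending=asc, method="average")
        col = f"rank_{metric}"
        out[col] = ranks
        rank_cols.append(col)
    out["mean_rank"] = out[rank_cols].mean(axis=1)
    return out.sort_values("mean_rank", kind="mergesort")
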