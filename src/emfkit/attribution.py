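"""Driver attribution battery for multifunctionality.

Five complementary views of how plot-level drivers (grouped as microbial
activity MA, diversity Div, indicator taxa, and environment Env) explain
an EMF response:

* variance partitioning over driver groups — unique and shared adjusted-R²
  components by inclusion–exclusion over all union models;
* LMG relative importance — each predictor's average sequential R²
  contribution over all orderings (shares sum to the full-model R²);
* partial correlation — each driver against the response controlling the
  others, with t-based p-values;
* Mantel tests between distance matrices (Spearman, label permutations);
* random-forest permutation importance with a y-permutation significance
  test (out-of-bag MSE increase).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor


# ---------------------------------------------------------------------------
# helpers


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Keep a maximal linearly independent subset of columns (QR pivoting)."""
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return X
    keep: list[str] = []
    base = np.ones((len(X), 1))
    for col in X.columns:
        cand = np.column_stack([base, X[col].to_numpy(float)])
        if np.linalg.matrix_rank(cand) > base.shape[1]:
            keep.append(col)
            base = cand
    dropped = [c for c in X.columns if c not in keep]
    warnings.warn(f"collinear predictors dropped: {dropped}", stacklevel=3)
    return X[keep]


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """OLS R² with intercept; empty predictor set gives 0."""
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("response has no variance")
    return 1.0 - (resid @ resid) / tss


def _adj_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment; may be (slightly) negative by construction."""
    if n - p - 1 <= 0:
        raise ValueError("not enough observations for the adjusted R²")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


# ---------------------------------------------------------------------------
# variance partitioning


def variance_partition(
    y: pd.Series, X: pd.DataFrame, groups: dict[str, list[str]]
) -> dict:
    """Unique and shared adjusted-R² components across predictor groups.

    Fits OLS models for every non-empty union of groups and decomposes
    the full-model adjusted R² into one component per non-empty subset
    of groups (exactly-shared fractions) by Möbius inversion; components
    can be slightly negative and are reported as-is.  Returns a dict
    with `components` (keyed by tuples of group names), `full_adj_r2`
    and `residual`.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    seen: set[str] = set()
    for gname, cols in groups.items():
        if not cols:
            raise ValueError(f"group {gname!r} is empty")
        overlap = seen & set(cols)
        if overlap:
            raise ValueError(f"groups must be disjoint; shared: {sorted(overlap)}")
        seen |= set(cols)
    yv = y.to_numpy(float)
    n = len(yv)

    f_cache: dict[frozenset, float] = {frozenset(): 0.0}

    def f(subset: frozenset) -> float:
        if subset not in f_cache:
            cols = [c for gname in names if gname in subset for c in groups[gname]]
            Xs = _drop_collinear(X[cols])
            f_cache[subset] = _adj_r2(_r2(yv, Xs.to_numpy(float)), n, Xs.shape[1])
        return f_cache[subset]

    all_set = frozenset(names)
    full = f(all_set)
    components: dict[tuple, float] = {}
    for r in range(1, len(names) + 1):
        for sub in itertools.combinations(names, r):
            s = frozenset(sub)
            val = 0.0
            for k in range(len(sub) + 1):
                for u in itertools.combinations(sub, k):
                    h = full - f(all_set - frozenset(u))
                    val += (-1) ** (len(sub) - len(u)) * h
            components[tuple(sorted(sub))] = val
    return {"components": components, "full_adj_r2": full, "residual": 1.0 - full}


def unique_fractions(vpa: dict) -> dict[str, float]:
    """Convenience view: the singleton (unique) components per group."""
    return {k[0]: v for k, v in vpa["components"].items() if len(k) == 1}


# ---------------------------------------------------------------------------
# LMG relative importance


def lmg_importance(
    y: pd.Series,
    X: pd.DataFrame,
    sample_orderings: int | None = None,
    seed: int | None = None,
) -> pd.Series:
    """LMG shares: average sequential R² contribution over orderings.

    Exact enumeration is limited to p <= 8 predictors; beyond that pass
    `sample_orderings` to average over randomly drawn orderings instead.
    Shares are on the R² scale and sum to the full-model R² exactly (up
    to float rounding) in the exact mode.
    """
    p = X.shape[1]
    if p < 1:
        raise ValueError("need at least one predictor")
    if len(y) <= p + 1:
        raise ValueError("need n > p + 1 observations")
    cols = list(X.columns)
    yv = y.to_numpy(float)
    xv = X.to_numpy(float)

    if p > 8 and sample_orderings is None:
        raise ValueError(
            "exact LMG enumeration is limited to 8 predictors; "
            "pass sample_orderings (with a seed) for the sampling mode"
        )

    if sample_orderings is None:
        r2_cache: dict[frozenset, float] = {}

        def r2_of(subset: frozenset) -> float:
            if subset not in r2_cache:
                idx = [cols.index(c) for c in subset]
                r2_cache[subset] = _r2(yv, xv[:, idx])
            return r2_cache[subset]

        shares = dict.fromkeys(cols, 0.0)
        others = {c: [o for o in cols if o != c] for c in cols}
        for c in cols:
            for k in range(p):
                w = math.factorial(k) * math.factorial(p - k - 1) / math.factorial(p)
                for sub in itertools.combinations(others[c], k):
                    s = frozenset(sub)
                    shares[c] += w * (r2_of(s | {c}) - r2_of(s))
        return pd.Series(shares, name="lmg")

    rng = np.random.default_rng(seed)
    shares_arr = np.zeros(p)
    for _ in range(sample_orderings):
        order = rng.permutation(p)
        prev = 0.0
        for k in range(p):
            cur = _r2(yv, xv[:, order[: k + 1]])
            shares_arr[order[k]] += cur - prev
            prev = cur
    return pd.Series(shares_arr / sample_orderings, index=cols, name="lmg")


# ---------------------------------------------------------------------------
# partial correlation


def partial_correlation(
    y: pd.Series, x: pd.Series, controls: pd.DataFrame | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of y and x given controls.

    Computed from the residuals of y and x on the controls; the p-value
    uses a t reference with n − #controls − 2 degrees of freedom.  With
    no controls this is the plain Pearson correlation.
    """
    if controls is not None and x.name in controls.columns:
        raise ValueError(f"x ({x.name!r}) may not appear among the controls")
    yv, xv = y.to_numpy(float), x.to_numpy(float)
    k = 0 if controls is None else controls.shape[1]
    n = len(yv)
    if n <= k + 3:
        raise ValueError("need n > #controls + 3")
    if k:
        z = np.column_stack([np.ones(n), controls.to_numpy(float)])
        yv = yv - z @ np.linalg.lstsq(z, yv, rcond=None)[0]
        xv = xv - z @ np.linalg.lstsq(z, xv, rcond=None)[0]
    r = float(np.corrcoef(xv, yv)[0, 1])
    df = n - k - 2
    r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_c * math.sqrt(df / (1 - r_c**2))
    return r, float(2 * stats.t.sf(abs(t), df))


def partial_correlation_table(
    y: pd.Series, X: pd.DataFrame
) -> pd.DataFrame:
    """Each variable vs y, controlling all the others in turn."""
    rows = {}
    for c in X.columns:
        r, p = partial_correlation(y, X[c], X.drop(columns=[c]))
        rows[c] = {"r_partial": r, "p": p}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Mantel test


def _condensed(d: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(d.shape[0], k=1)
    return d[iu, ju]


def mantel(
    d1,
    d2,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation of two distance matrices with a permutation test.

    Rows and columns of the second matrix are permuted jointly; the
    one-sided p is (1 + #{r_perm >= r_obs}) / (1 + n_perm).  Spearman
    correlates the ranks of the upper-triangle entries (the default, as
    for community distance matrices); `pearson` is also accepted.
    """
    a = np.asarray(getattr(d1, "values", d1), float)
    b = np.asarray(getattr(d2, "values", d2), float)
    n = a.shape[0]
    if a.shape != b.shape or a.shape != (n, n):
        raise ValueError("matrices must be square and the same size")
    for m in (a, b):
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("matrices must be symmetric with zero diagonal")
    if n < 4:
        raise ValueError("need at least 4 objects")

    v1, v2 = _condensed(a), _condensed(b)
    if method == "spearman":
        v1, v2 = stats.rankdata(v1), stats.rankdata(v2)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    def _corr(u: np.ndarray, w: np.ndarray) -> float:
        return float(np.corrcoef(u, w)[0, 1])

    obs = _corr(v1, v2)
    iu, ju = np.triu_indices(n, k=1)
    pair_idx = np.zeros((n, n), int)
    pair_idx[iu, ju] = np.arange(len(iu))
    pair_idx = pair_idx + pair_idx.T

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = v2[pair_idx[np.ix_(perm, perm)][iu, ju]]
        if _corr(v1, v2p) >= obs - 1e-12:
            count += 1
    return obs, (1.0 + count) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# random forest importance


def _fit_forest(
    yv: np.ndarray, xv: np.ndarray, n_trees: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean out-of-bag MSE increase per feature under feature permutation."""
    n, p = xv.shape
    imp = np.zeros(p)
    used = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), np.unique(boot))
        tree = DecisionTreeRegressor(
            max_features=max(1, p // 3), random_state=int(rng.integers(2**31))
        )
        tree.fit(xv[boot], yv[boot])
        if oob.size < 2:
            continue
        base = np.mean((yv[oob] - tree.predict(xv[oob])) ** 2)
        for j in range(p):
            xp = xv[oob].copy()
            xp[:, j] = xp[rng.permutation(oob.size), j]
            imp[j] += np.mean((yv[oob] - tree.predict(xp)) ** 2) - base
            used[j] += 1
    return imp / np.maximum(used, 1)


def rf_importance(
    y: pd.Series,
    X: pd.DataFrame,
    n_trees: int = 100,
    n_perm: int = 99,
    seed: int | None = None,
) -> pd.DataFrame:
    """Regression-forest permutation importance with significance.

    Importance is the mean out-of-bag MSE increase when a feature is
    permuted.  Significance refits the forest on `n_perm` y-permuted
    datasets; p = (1 + #{null >= observed}) / (1 + n_perm) per feature.
    """
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    yv = y.to_numpy(float)
    if np.all(yv == yv[0]):
        raise ValueError("constant response")
    xv = X.to_numpy(float)
    rng = np.random.default_rng(seed)
    obs = _fit_forest(yv, xv, n_trees, rng)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        null = _fit_forest(rng.permutation(yv), xv, n_trees, rng)
        exceed += null >= obs - 1e-15
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({"importance": obs, "p": p}, index=X.columns)
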