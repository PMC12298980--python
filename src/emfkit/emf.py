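"""Ecosystem multifunctionality (EMF) indices and effect sizes.

Two EMF metrics are computed per plot from a plots × functions table:

* **avgFunc** — each function is min–max scaled to [0, 1] (after applying
  its direction, −1 for functions where lower raw values mean better
  functioning) and the plot's score is the arithmetic mean over functions.
* **multithreshold counts (MF-t%)** — for each function a reference
  maximum is taken as the mean of its top-2 direction-adjusted values;
  MF-t% is the number of functions on a plot reaching t% of that
  reference, for t in {20, 40, 60, 80} by default.

Group contrasts use the Kruskal–Wallis H test, and the change between two
study years is summarised as a per-year relative effect::

    effect = (mean(Y_i) - mean(Y_j)) / ((i - j) * mean(Y_j))

with a percentile bootstrap over plots for the 95% interval.  For the
default design, the installation contrast is i=1 vs j=0 and the running
contrast i=6 vs j=1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_THRESHOLDS = (20, 40, 60, 80)


@dataclass
class FunctionMatrix:
    """Plots × ecosystem functions with per-function category and direction."""

    values: pd.DataFrame
    category: dict[str, str]
    direction: dict[str, int] = field(default_factory=dict)
    standardized: bool = False

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        missing = [c for c in cols if c not in self.category]
        if missing:
            raise ValueError(f"functions without a category: {missing}")
        self.direction = {c: int(self.direction.get(c, 1)) for c in cols}
        bad = [c for c, d in self.direction.items() if d not in (-1, 1)]
        if bad:
            raise ValueError(f"direction must be +1 or -1: {bad}")
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise ValueError("function values must be finite")

    @property
    def plot_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def function_ids(self) -> list[str]:
        return list(self.values.columns)

    def directed_values(self) -> pd.DataFrame:
        d = pd.Series(self.direction)[self.values.columns]
        return self.values * d


def standardize_functions(fm: FunctionMatrix) -> FunctionMatrix:
    """Min–max scale each function to [0, 1] after applying its direction.

    Constant columns carry no contrast; they are mapped to 0.5 with a
    warning instead of failing, so degenerate synthetic inputs survive.
    """
    if len(fm.values) < 2:
        raise ValueError("standardization needs at least 2 plots")
    v = fm.directed_values()
    rng_ = v.max() - v.min()
    const = rng_ == 0
    if const.any():
        warnings.warn(
            f"constant function columns mapped to 0.5: {list(v.columns[const])}",
            stacklevel=2,
        )
    out = (v - v.min()) / rng_.replace(0, np.nan)
    out[v.columns[const]] = 0.5
    return replace(
        fm,
        values=out,
        direction={c: 1 for c in v.columns},
        standardized=True,
    )


def avg_multifunctionality(std: FunctionMatrix) -> pd.Series:
    """avgFunc: per-plot mean of the 0–1 standardized functions."""
    v = std.values.to_numpy(float)
    if v.min() < -1e-9 or v.max() > 1 + 1e-9:
        raise ValueError("avgFunc requires standardized functions in [0, 1]")
    return pd.Series(std.values.mean(axis=1), index=std.values.index, name="avgFunc")


def threshold_multifunctionality(
    fm: FunctionMatrix,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
    top_n: int = 2,
) -> pd.DataFrame:
    """MF-t% counts: functions reaching t% of their reference maximum.

    The reference maximum of a function is the mean of its `top_n` largest
    direction-adjusted observed values.  With an all-zero column the
    reference is 0 and every plot trivially meets every threshold (0 >= 0);
    that boundary is intentional and documented rather than special-cased.
    """
    if len(fm.values) < 2:
        raise ValueError("need at least 2 plots")
    for t in thresholds:
        if not 0 < t <= 100:
            raise ValueError(f"threshold {t} outside (0, 100]")
    v = fm.directed_values()
    ref = v.apply(lambda col: col.nlargest(min(top_n, len(col))).mean())
    out = {}
    for t in sorted(thresholds):
        out[f"MF-{t}%"] = (v >= (t / 100.0) * ref).sum(axis=1)
    return pd.DataFrame(out, index=v.index)


def emf_profile(
    fm: FunctionMatrix, thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Per-plot EMF profile: avgFunc, MF-t% counts and category means."""
    std = fm if fm.standardized else standardize_functions(fm)
    prof = pd.DataFrame({"avgFunc": avg_multifunctionality(std)})
    prof = prof.join(threshold_multifunctionality(fm, thresholds))
    cats = pd.Series(std.category)[std.values.columns]
    for cat in dict.fromkeys(cats):
        prof[cat] = std.values.loc[:, (cats == cat).to_numpy()].mean(axis=1)
    return prof


@dataclass
class EffectSizeResult:
    indicator_id: str
    period: str
    effect: float
    ci_low: float
    ci_high: float
    i: int
    j: int
    n_boot: int
    seed: int | None


def annual_effect_size(
    values_i,
    values_j,
    i: int,
    j: int,
    n_boot: int = 2000,
    seed: int | None = None,
    indicator_id: str = "",
    period: str | None = None,
) -> EffectSizeResult:
    """Per-year relative change between year j and year i group means.

    The point estimate divides the mean difference by the span in years and
    the year-j mean; the interval is a percentile bootstrap resampling
    plots within each year independently.
    """
    yi = np.asarray(values_i, float)
    yj = np.asarray(values_j, float)
    if i <= j:
        raise ValueError("need i > j")
    if yi.size == 0 or yj.size == 0:
        raise ValueError("empty year samples")
    mj = yj.mean()
    if mj == 0:
        raise ZeroDivisionError("effect undefined: year-j mean is zero")

    def _eff(a: np.ndarray, b: np.ndarray) -> float:
        return (a.mean() - b.mean()) / ((i - j) * b.mean())

    rng = np.random.default_rng(seed)
    idx_i = rng.integers(0, yi.size, size=(n_boot, yi.size))
    idx_j = rng.integers(0, yj.size, size=(n_boot, yj.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = (yi[idx_i].mean(axis=1) - yj[idx_j].mean(axis=1)) / (
            (i - j) * yj[idx_j].mean(axis=1)
        )
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots.size else (np.nan, np.nan)
    if period is None:
        period = "installation" if (i, j) == (1, 0) else "running" if (i, j) == (6, 1) else f"{j}->{i}"
    return EffectSizeResult(
        indicator_id=indicator_id,
        period=period,
        effect=_eff(yi, yj),
        ci_low=float(lo),
        ci_high=float(hi),
        i=i,
        j=j,
        n_boot=n_boot,
        seed=seed,
    )


def compare_groups(values_by_group) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction across >= 2 groups.

    All-identical observations make H degenerate; that case returns
    (0.0, 1.0) rather than erroring.
    """
    groups = [np.asarray(v, float) for v in dict(values_by_group).values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def effect_size_table(
    profiles: pd.DataFrame,
    groups: pd.Series,
    periods: tuple[tuple[str, str, int, int], ...] = (("Y1", "Y0", 1, 0), ("Y6", "Y1", 6, 1)),
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Annual effect sizes of every profile column for each study period."""
    rows = []
    for k, (gi, gj, i, j) in enumerate(periods):
        for col in profiles.columns:
            res = annual_effect_size(
                profiles.loc[groups == gi, col],
                profiles.loc[groups == gj, col],
                i=i,
                j=j,
                n_boot=n_boot,
                seed=None if seed is None else seed + k,
                indicator_id=col,
            )
            rows.append(
                {
                    "indicator": col,
                    "period": res.period,
                    "effect": res.effect,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
            )
    return pd.DataFrame(rows)
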