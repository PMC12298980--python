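"""Microbial activity indices used as multifunctionality drivers.

From raw plot measurements — prokaryotic and fungal gene copies, microbial
biomass carbon (MBC, µg C g⁻¹ soil), soil organic carbon (SOC, g C kg⁻¹
soil) and carbon mineralization (µg CO₂-C g⁻¹ day⁻¹) — two derived
efficiency ratios are computed:

* metabolic quotient qCO₂ = carbon mineralization / MBC (day⁻¹); lower
  values mean higher carbon-use efficiency, so it enters the activity
  composite with reversed sign;
* Cmic/Corg = 100 · MBC / (1000 · SOC), microbial biomass as a percent of
  organic carbon (the 1000 converts SOC g kg⁻¹ to µg g⁻¹ scale).

The activity composite is PC1 of the z-scored indices (gene copies are
log10-transformed first since they span orders of magnitude), with its
sign anchored so the MBC loading is positive: higher composite = more
active community.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from emfkit.ordination import pca

REQUIRED = ("copies_pro", "copies_fun", "mbc", "soc", "c_min")


def compute_activity_indices(raw: pd.DataFrame) -> pd.DataFrame:
    """Append qCO₂ and Cmic/Corg to the raw measurement table.

    MBC is expected in µg C g⁻¹ and SOC in g C kg⁻¹; the unit conversion
    inside Cmic/Corg is explicit in the formula.  Non-positive
    denominators raise, naming the offending plots.
    """
    missing = [c for c in REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"missing activity columns: {missing}")
    if (raw[list(REQUIRED)].to_numpy(float) < 0).any():
        raise ValueError("activity measurements must be non-negative")
    for col in ("mbc", "soc"):
        bad = raw.index[raw[col] <= 0]
        if len(bad):
            raise ValueError(f"{col} must be positive; offending plots: {list(bad)}")
    out = raw.copy()
    out["qco2"] = out["c_min"] / out["mbc"]                  # per day
    out["cmic_corg"] = 100.0 * out["mbc"] / (1000.0 * out["soc"])  # percent
    return out


def activity_composite(
    indices: pd.DataFrame,
    reverse_qco2: bool = True,
    log_copies: bool = True,
) -> pd.Series:
    """PC1 of the z-scored activity indices, oriented as activity.

    qCO₂ is sign-reversed by default (a declining metabolic quotient
    signals increasing activity) and the component is anchored so the
    MBC loading is positive.
    """
    cols = [c for c in ("copies_pro", "copies_fun", "mbc", "qco2", "cmic_corg") if c in indices]
    if len(cols) < 2:
        raise ValueError("need at least 2 activity variables")
    if len(indices) < 3:
        raise ValueError("need at least 3 plots")
    x = indices[cols].astype(float).copy()
    if log_copies:
        for c in ("copies_pro", "copies_fun"):
            if c in x:
                x[c] = np.log10(x[c])
    if reverse_qco2 and "qco2" in x:
        x["qco2"] = -x["qco2"]
    const = x.std(ddof=1) == 0
    if const.any():
        warnings.warn(
            f"constant activity columns dropped: {list(x.columns[const])}", stacklevel=2
        )
        x = x.loc[:, ~const]
        if x.shape[1] < 2:
            raise ValueError("fewer than 2 varying activity variables")
    res = pca(x, n_components=1)
    score = res.scores["PC1"]
    if "mbc" in res.loadings.index and res.loadings.loc["mbc", "PC1"] < 0:
        score = -score
    return score.rename("MA")
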