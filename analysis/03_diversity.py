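#!/usr/bin/env python
"""Alpha diversity per domain and its correlation with multifunctionality.

Richness, Faith's PD for all domains, FDis for plants (Gower traits) and
guild richness for fungi; then per-metric OLS slopes against avgFunc.
Writes results/diversity/{diversity,diversity_emf_fits}.tsv.
"""

from pathlib import Path

import pandas as pd
from scipy import stats

from emfkit import biodiversity
from emfkit.io import read_study_dir, read_tsv, write_tsv

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = read_study_dir(BASE / "study")
    out = BASE / "diversity"
    out.mkdir(parents=True, exist_ok=True)

    frames = []
    guilds = study["truth"]["taxa"]["fungus"].get("guild_map")
    for dom, ct in study["communities"].items():
        frames.append(
            biodiversity.diversity_profile(
                ct,
                tree=study["trees"][dom],
                traits=study.get("traits") if dom == "plant" else None,
                guild_map=guilds if dom == "fungus" else None,
                domain=dom,
            )
        )
    div = pd.concat(frames)
    write_tsv(div, out / "diversity.tsv", index_label="plot_id")

    avg = read_tsv(BASE / "emf" / "profiles.tsv")["avgFunc"]
    rows = []
    for dom, sub in div.groupby("domain"):
        for metric in ("richness", "faith_pd", "fdis", "guild_richness"):
            if metric not in sub or sub[metric].isna().any() or sub[metric].nunique() < 2:
                continue
            fit = stats.linregress(sub[metric], avg.loc[sub.index])
            rows.append(
                {
                    "domain": dom,
                    "metric": metric,
                    "slope": fit.slope,
                    "r2": fit.rvalue**2,
                    "p": fit.pvalue,
                }
            )
    fits = pd.DataFrame(rows)
    fits.to_csv(out / "diversity_emf_fits.tsv", sep="\t", index=False)
    print("diversity-avgFunc OLS fits:")
    print(fits.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
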