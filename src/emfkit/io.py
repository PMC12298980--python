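"""Reading and writing study directories.

All tables are UTF-8 tab-separated files with a '.' decimal separator;
trees are Newick text and the truth record is JSON.  A study directory
holds: functions.tsv (plots × functions), functions_meta.tsv (function →
category, direction), metadata.tsv, community_<domain>.tsv (taxa ×
samples counts), taxonomy_<domain>.tsv, tree_<domain>.nwk,
traits_plant.tsv, activity.tsv, drivers.tsv and truth.json.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from emfkit.emf import FunctionMatrix
from emfkit.synthetic import DOMAINS, SyntheticStudy


def write_tsv(df: pd.DataFrame, path: Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(study.functions.values, out / "functions.tsv", index_label="plot_id")
    meta = pd.DataFrame(
        {
            "category": pd.Series(study.functions.category),
            "direction": pd.Series(study.functions.direction),
        }
    )
    write_tsv(meta, out / "functions_meta.tsv", index_label="function_id")
    write_tsv(study.metadata, out / "metadata.tsv", index_label="plot_id")
    for dom in DOMAINS:
        write_tsv(study.communities[dom], out / f"community_{dom}.tsv", "taxon_id")
        write_tsv(study.taxonomies[dom], out / f"taxonomy_{dom}.tsv", "taxon_id")
        (out / f"tree_{dom}.nwk").write_text(study.trees[dom] + "\n")
    write_tsv(study.traits, out / "traits_plant.tsv", index_label="species")
    write_tsv(study.activity_raw, out / "activity.tsv", index_label="plot_id")
    write_tsv(study.drivers, out / "drivers.tsv", index_label="plot_id")
    (out / "truth.json").write_text(json.dumps(study.truth, indent=2, sort_keys=True))
    return out


def read_study_dir(indir: str | Path) -> dict:
    """Load a study directory into a dict of in-memory components.

    Only files that exist are loaded; `functions` is returned as a
    FunctionMatrix when both the values and meta tables are present.
    """
    d = Path(indir)
    out: dict = {}
    if (d / "functions.tsv").exists():
        values = read_tsv(d / "functions.tsv")
        meta = read_tsv(d / "functions_meta.tsv")
        out["functions"] = FunctionMatrix(
            values=values,
            category=meta["category"].to_dict(),
            direction=meta["direction"].astype(int).to_dict(),
        )
    if (d / "metadata.tsv").exists():
        out["metadata"] = read_tsv(d / "metadata.tsv")
    out["communities"], out["taxonomies"], out["trees"] = {}, {}, {}
    for dom in DOMAINS:
        if (d / f"community_{dom}.tsv").exists():
            out["communities"][dom] = read_tsv(d / f"community_{dom}.tsv")
        if (d / f"taxonomy_{dom}.tsv").exists():
            out["taxonomies"][dom] = read_tsv(d / f"taxonomy_{dom}.tsv")
        if (d / f"tree_{dom}.nwk").exists():
            out["trees"][dom] = (d / f"tree_{dom}.nwk").read_text().strip()
    if (d / "traits_plant.tsv").exists():
        out["traits"] = read_tsv(d / "traits_plant.tsv")
    if (d / "activity.tsv").exists():
        out["activity_raw"] = read_tsv(d / "activity.tsv")
    if (d / "drivers.tsv").exists():
        out["drivers"] = read_tsv(d / "drivers.tsv")
    if (d / "truth.json").exists():
        out["truth"] = json.loads((d / "truth.json").read_text())
    return out
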