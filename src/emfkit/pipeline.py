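"""End-to-end orchestration: simulate → emf → diversity → screen →
activity → attribute → sem → report.

A run is driven by a `RunConfig` (YAML-loadable, unknown keys rejected)
and writes a run directory with one subfolder per stage plus a
`manifest.json` recording the configuration, its hash, the per-stage
seeds and the package version.  Stage outputs are write-once; re-running
an identical config reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

import emfkit
from emfkit import activity as activity_mod
from emfkit import attribution, biodiversity, emf, psem, screen
from emfkit.design import StudyDesign
from emfkit.io import read_study_dir, write_study, write_tsv
from emfkit.ordination import pca
from emfkit.synthetic import generate_study

log = logging.getLogger("emfkit")

STAGES = ("simulate", "emf", "diversity", "screen", "activity", "attribute", "sem", "report")
ENV_VARS = ("SWC", "ST", "pH", "evaporation", "clay", "silt", "sand")


@dataclass
class RunConfig:
    out_dir: str
    simulate: dict | None = None       # StudyDesign kwargs; None → use `inputs`
    inputs: str | None = None          # path to an existing study directory
    seed: int = 0
    n_perm: int = 999
    n_boot: int = 2000
    prevalence: float = 0.20
    min_count: int = 4
    r_min: float = 0.6
    p_max: float = 0.05
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    mf_thresholds: tuple[int, ...] = (20, 40, 60, 80)
    dag: str | None = None             # edge-list text; None → shipped default

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of `simulate` and `inputs` must be set")
        self.mf_thresholds = tuple(int(t) for t in self.mf_thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mf_thresholds"] = list(self.mf_thresholds)
        return d

    def stage_seed(self, stage: str) -> int:
        # stable per-stage stream, derived from the master seed
        return (self.seed * 1009 + STAGES.index(stage) * 7919) % (2**31 - 1)


# ---------------------------------------------------------------------------
# composite driver table


def build_driver_table(
    metadata: pd.DataFrame,
    diversity: pd.DataFrame,
    activity_scores: pd.Series,
    indicator_scores: dict[str, pd.Series],
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Assemble the grouped plot × driver table used by the attribution battery.

    Composites keep the model small at 18 plots: MA is the activity PC1;
    Div the first two PCs of the α-diversity indices; Indicator the
    per-domain indicator-taxa PC1 scores; Env the first two PCs of the
    environmental covariates.
    """
    env = pca(metadata[list(ENV_VARS)], n_components=2).scores
    env.columns = ["Env_PC1", "Env_PC2"]
    pieces = [
        g.drop(columns="domain").add_suffix(f"_{dom}")
        for dom, g in diversity.groupby("domain")
    ]
    div_wide = pd.concat(pieces, axis=1).dropna(axis=1)
    div_wide = div_wide.loc[:, div_wide.std(ddof=1) > 0]
    div = pca(div_wide, n_components=2).scores
    div.columns = ["Div_PC1", "Div_PC2"]
    ind = pd.DataFrame(
        {f"{dom}_ind_PC1": s for dom, s in indicator_scores.items()}
    )
    X = pd.concat([activity_scores.rename("MA"), div, ind, env], axis=1)
    groups = {
        "MA": ["MA"],
        "Div": list(div.columns),
        "Indicator": list(ind.columns),
        "Env": list(env.columns),
    }
    return X, groups


def _indicator_scores(screen_result: dict, community: pd.DataFrame) -> pd.Series:
    """PC1 of the significant indicator taxa (top-IndVal fallback)."""
    iv = screen_result["indval"]
    sig = screen.significant_indicators(iv)
    if len(sig) < 2:
        sig = iv["indval"].nlargest(5).index
    filtered = screen_result["filtered"]
    return screen.indicator_composite(
        filtered.loc[sig], totals=community.sum(axis=0)
    ).scores["PC1"]


# ---------------------------------------------------------------------------
# stages


def run_pipeline(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "version": emfkit.__version__,
        "seeds": {s: config.stage_seed(s) for s in STAGES},
        "stages_completed": [],
    }
    state: dict = {}
    try:
        for stage in STAGES:
            log.info("stage %s", stage)
            _STAGE_FUNCS[stage](config, out, state)
            manifest["stages_completed"].append(stage)
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    if config.simulate is not None:
        kwargs = dict(config.simulate)
        kwargs.setdefault("seed", config.stage_seed("simulate"))
        study = generate_study(StudyDesign(**kwargs))
        write_study(study, out / "simulate")
        state.update(read_study_dir(out / "simulate"))
    else:
        state.update(read_study_dir(config.inputs))
        if "functions" not in state:
            raise FileNotFoundError(f"functions.tsv not found under {config.inputs}")


def _stage_emf(config: RunConfig, out: Path, state: dict) -> None:
    d = out / "emf"
    d.mkdir(exist_ok=True)
    fm = state["functions"]
    profiles = emf.emf_profile(fm, thresholds=config.mf_thresholds)
    write_tsv(profiles, d / "profiles.tsv", index_label="plot_id")
    groups = state["metadata"]["group"]
    effects = emf.effect_size_table(
        profiles, groups, n_boot=config.n_boot, seed=config.stage_seed("emf")
    )
    effects.to_csv(d / "effects.tsv", sep="\t", index=False)
    kw = {
        col: emf.compare_groups({g: profiles.loc[groups == g, col] for g in groups.unique()})
        for col in profiles.columns
    }
    write_tsv(
        pd.DataFrame(kw, index=["H", "p"]).T, d / "kruskal.tsv", index_label="index"
    )
    state["profiles"], state["effects"] = profiles, effects


def _stage_diversity(config: RunConfig, out: Path, state: dict) -> None:
    d = out / "diversity"
    d.mkdir(exist_ok=True)
    frames = []
    guilds = state.get("truth", {}).get("taxa", {}).get("fungus", {}).get("guild_map")
    for dom, ct in state["communities"].items():
        tree = state["trees"].get(dom)
        if tree is None:
            raise FileNotFoundError(f"tree for domain {dom!r} is required but missing")
        prof = biodiversity.diversity_profile(
            ct,
            tree=tree,
            traits=state.get("traits") if dom == "plant" else None,
            guild_map=guilds if dom == "fungus" else None,
            domain=dom,
        )
        frames.append(prof)
    div = pd.concat(frames)
    write_tsv(div, d / "diversity.tsv", index_label="plot_id")
    state["diversity"] = div


def _stage_screen(config: RunConfig, out: Path, state: dict) -> None:
    d = out / "screen"
    d.mkdir(exist_ok=True)
    groups = state["metadata"]["group"]
    state["screens"] = {}
    for k, dom in enumerate(("prokaryote", "fungus")):
        if dom not in state["communities"]:
            continue
        res = screen.screen_taxa(
            state["communities"][dom],
            groups,
            n_perm=config.n_perm,
            seed=config.stage_seed("screen") + k,
            prevalence=config.prevalence,
            min_count=config.min_count,
            r_min=config.r_min,
            p_max=config.p_max,
            rule=screen.KeystoneRule(config.zi_threshold, config.pi_threshold),
        )
        write_tsv(res["indval"], d / f"indicators_{dom}.tsv", "taxon_id")
        write_tsv(res["topology"], d / f"node_topology_{dom}.tsv", "taxon_id")
        write_tsv(res["abundance"], d / f"abundance_classes_{dom}.tsv", "taxon_id")
        nx.write_graphml(res["network"], d / f"network_{dom}.graphml")
        state["screens"][dom] = res


def _stage_activity(config: RunConfig, out: Path, state: dict) -> None:
    d = out / "activity"
    d.mkdir(exist_ok=True)
    indices = activity_mod.compute_activity_indices(state["activity_raw"])
    write_tsv(indices, d / "activity_indices.tsv", index_label="plot_id")
    state["activity_indices"] = indices
    state["MA"] = activity_mod.activity_composite(indices)


def _stage_attribute(config: RunConfig, out: Path, state: dict) -> None:
    d = out / "attribution"
    d.mkdir(exist_ok=True)
    ind_scores = {
        dom: _indicator_scores(res, state["communities"][dom])
        for dom, res in state["screens"].items()
    }
    X, groups = build_driver_table(
        state["metadata"], state["diversity"], state["MA"], ind_scores
    )
    y = state["profiles"]["avgFunc"]
    vpa = attribution.variance_partition(y, X, groups)
    pd.Series(
        {"+".join(k): v for k, v in vpa["components"].items()}
        | {"full_adj_r2": vpa["full_adj_r2"], "residual": vpa["residual"]}
    ).to_csv(d / "vpa.tsv", sep="\t", header=["value"], index_label="component")
    lmg = attribution.lmg_importance(y, X)
    write_tsv(lmg.to_frame(), d / "lmg.tsv", index_label="variable")
    pcor = attribution.partial_correlation_table(y, X)
    write_tsv(pcor, d / "partial_correlation.tsv", index_label="variable")
    rf = attribution.rf_importance(
        y, X, n_trees=100, n_perm=min(config.n_perm, 99), seed=config.stage_seed("attribute")
    )
    write_tsv(rf, d / "rf_importance.tsv", index_label="variable")

    mantel_rows = []
    fun_dist = biodiversity.beta_distance(state["functions"].values, metric="euclidean")
    for dom, ct in state["communities"].items():
        bc = biodiversity.beta_distance(ct, metric="bray-curtis")
        r, p = attribution.mantel(
            bc, fun_dist, n_perm=config.n_perm, seed=config.stage_seed("attribute")
        )
        mantel_rows.append({"pair": f"{dom}-vs-functions", "r": r, "p": p})
    pd.DataFrame(mantel_rows).to_csv(d / "mantel.tsv", sep="\t", index=False)
    state["drivers_X"], state["driver_groups"] = X, groups
    state["vpa"], state["lmg"] = vpa, lmg


def _sem_node_table(state: dict) -> pd.DataFrame:
    prof = state["profiles"]
    X = state["drivers_X"]
    cycling = prof[["C", "N", "P"]].mean(axis=1)
    return pd.DataFrame(
        {
            "Env": X["Env_PC1"],
            "MA": X["MA"],
            "Div": X["Div_PC1"],
            "Indicator": X.get("fungus_ind_PC1", X.filter(like="_ind_PC1").iloc[:, 0]),
            "PP": prof["PP"],
            "SNP": prof["SNP"],
            "Cycling": cycling,
            "EMF": prof["avgFunc"],
        }
    )


def _stage_sem(config: RunConfig, out: Path, state: dict) -> None:
    d = out / "sem"
    d.mkdir(exist_ok=True)
    dag = psem.DAGSpec.from_text(config.dag) if config.dag else psem.default_dag()
    nodes = _sem_node_table(state)
    groups = state["metadata"]["group"]
    periods = {
        "installation": nodes[groups.isin(["Y0", "Y1"]).to_numpy()],
        "running": nodes[groups.isin(["Y1", "Y6"]).to_numpy()],
    }
    fits = {}
    for name, data in periods.items():
        fit = psem.fit_psem(dag, data, response="EMF")
        fits[name] = fit
        fit.edges.to_csv(d / f"edges_{name}.tsv", sep="\t", index=False)
        fit.claims.to_csv(d / f"claims_{name}.tsv", sep="\t", index=False)
        write_tsv(fit.effects, d / f"effects_{name}.tsv", index_label="driver")
    lines = []
    for name, fit in fits.items():
        lines.append(
            f"{name}: Fisher's C = {fit.fisher_c:.3f} on {fit.df} df "
            f"(model p = {fit.model_p:.3f})"
        )
    (d / "summary.txt").write_text("\n".join(lines) + "\n")
    state["sem_fits"] = fits


def _recovery_scores(state: dict) -> dict:
    truth = state.get("truth")
    if not truth:
        return {}
    scores = {}
    for dom, res in state.get("screens", {}).items():
        planted = set(truth["taxa"][dom]["indicator_ids"])
        iv = res["indval"]
        called = set(screen.significant_indicators(iv))
        surviving = planted & set(iv.index)
        tp = len(called & planted)
        scores[f"indicator_sensitivity_{dom}"] = (
            tp / len(surviving) if surviving else float("nan")
        )
        scores[f"indicator_fdr_{dom}"] = (
            len(called - planted) / len(called) if called else 0.0
        )
    return scores


def _stage_report(config: RunConfig, out: Path, state: dict) -> None:
    write_report(out, state)


def write_report(run_dir: Path, state: dict | None = None) -> Path:
    """Render report.md summarising every completed stage of a run."""
    run_dir = Path(run_dir)
    expected = {
        "emf": ["profiles.tsv", "effects.tsv", "kruskal.tsv"],
        "diversity": ["diversity.tsv"],
        "activity": ["activity_indices.tsv"],
        "attribution": ["vpa.tsv", "lmg.tsv", "partial_correlation.tsv"],
        "sem": ["summary.txt"],
    }
    missing = [
        f"{stage}/{f}"
        for stage, files in expected.items()
        for f in files
        if not (run_dir / stage / f).exists()
    ]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing outputs: {missing}")

    lines = ["# emfkit run report", ""]
    effects = pd.read_csv(run_dir / "emf" / "effects.tsv", sep="\t")
    emf_rows = effects[effects["indicator"].str.startswith(("avgFunc", "MF-"))]
    lines += ["## Annual effect sizes on EMF indices", "", _md_table(emf_rows), ""]
    lines += ["## Diversity (first rows)", "", _md_table(pd.read_csv(run_dir / "diversity" / "diversity.tsv", sep="\t").head(6)), ""]
    lines += ["## Variance partitioning", "", _md_table(pd.read_csv(run_dir / "attribution" / "vpa.tsv", sep="\t")), ""]
    lines += ["## LMG relative importance", "", _md_table(pd.read_csv(run_dir / "attribution" / "lmg.tsv", sep="\t")), ""]
    lines += ["## Piecewise SEM", "", "```", (run_dir / "sem" / "summary.txt").read_text().rstrip(), "```", ""]
    if state is not None:
        rec = _recovery_scores(state)
        if rec:
            lines += ["## Recovery against planted truth", ""]
            lines += [f"- {k}: {v:.3f}" for k, v in rec.items()]
            lines.append("")
    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path


def _md_table(df: pd.DataFrame) -> str:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(lambda v: f"{v:.4g}")
    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "---|" * len(df.columns)
    rows = ["| " + " | ".join(map(str, r)) + " |" for r in df.itertuples(index=False)]
    return "\n".join([header, sep] + rows)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "emf": _stage_emf,
    "diversity": _stage_diversity,
    "screen": _stage_screen,
    "activity": _stage_activity,
    "attribute": _stage_attribute,
    "sem": _stage_sem,
    "report": _stage_report,
}
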