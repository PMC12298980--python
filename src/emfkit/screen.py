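"""Screens classifying taxa as indicator, keystone, abundant or rare.

Works on filtered taxa × samples ASV tables.  Indicator taxa follow the
IndVal approach: per taxon and site group, specificity A (the group's
share of the taxon's mean relative abundance) times fidelity B (the
fraction of the group's samples where the taxon occurs), with
IndVal = max over groups of sqrt(A·B) and significance by permuting
group labels.  Keystone taxa come from a co-occurrence network: nodes
whose within-module degree z-score Zi exceeds 2.5 or whose
participation coefficient Pi exceeds 0.62.  Abundant and rare taxa are
cut purely on overall relative abundance (>0.1% and <0.01%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from emfkit.ordination import PCAResult, pca

RARE_CUT = 1e-4       # overall relative abundance below 0.01%
ABUNDANT_CUT = 1e-3   # above 0.1%
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


def filter_asvs(
    ct: pd.DataFrame,
    prevalence: float = 0.20,
    min_count: int = 4,
    mode: str = "prevalence",
) -> pd.DataFrame:
    """Retain taxa meeting the prevalence/count rule; samples unchanged.

    Default mode keeps a taxon when it has >= `min_count` reads in at
    least ceil(prevalence · n_samples) samples.  The literal alternative
    (`mode="strict"`: >= min_count in *every* sample, plus the prevalence
    rule on presence) is available but discards nearly everything on
    sparse tables.
    """
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be in (0, 1]")
    arr = ct.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer) and not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    need = math.ceil(prevalence * ct.shape[1])
    if mode == "prevalence":
        keep = (ct >= min_count).sum(axis=1) >= need
    elif mode == "strict":
        keep = ((ct >= min_count).all(axis=1)) & ((ct > 0).sum(axis=1) >= need)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ct.loc[keep]


def classify_abundance(ct: pd.DataFrame) -> pd.DataFrame:
    """Overall relative abundance and rare / intermediate / abundant class.

    Boundaries are strict inequalities: exactly 0.01% or 0.1% of total
    reads is `intermediate`.
    """
    total = ct.to_numpy().sum()
    if total <= 0:
        raise ValueError("table has no reads")
    rel = ct.sum(axis=1) / total
    cls = pd.Series("intermediate", index=ct.index)
    cls[rel < RARE_CUT] = "rare"
    cls[rel > ABUNDANT_CUT] = "abundant"
    return pd.DataFrame({"overall_rel_abund": rel, "class": cls})


def _indval_stats(x: np.ndarray, presence: np.ndarray, gmat: np.ndarray):
    """IndVal per taxon given samples × taxa matrices and a group-mean matrix."""
    means = gmat @ x                       # groups × taxa
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, means / np.where(denom > 0, denom, 1.0), 0.0)
    b = gmat @ presence
    sq = np.sqrt(a * b)
    best = sq.argmax(axis=0)
    stat = sq.max(axis=0)
    return stat, best, a, b


def indval(
    ct: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Indicator value analysis over all taxa with a group-label permutation test.

    Counts are converted to per-sample relative abundances first, so
    sequencing-depth differences do not masquerade as indication.
    Permutation p-values use the add-one estimator
    (1 + #{perm >= obs}) / (1 + n_perm) and are BH-adjusted across taxa
    in the `q` column.
    """
    groups = pd.Series(np.asarray(groups), index=ct.columns)
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = groups.value_counts()
    if (sizes < 1).any() or len(sizes) != len(labels):
        raise ValueError("every group needs at least one sample")

    totals = ct.sum(axis=0).replace(0, np.nan)
    x = (ct / totals).fillna(0.0).T.to_numpy(float)   # samples × taxa
    presence = (x > 0).astype(float)
    n_samples = x.shape[0]
    gmat = np.zeros((len(labels), n_samples))
    for gi, g in enumerate(labels):
        members = (groups == g).to_numpy()
        gmat[gi, members] = 1.0 / members.sum()

    stat, best, a, b = _indval_stats(x, presence, gmat)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(stat)
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        pstat, *_ = _indval_stats(x[perm], presence[perm], gmat)
        exceed += pstat >= stat - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    q = multipletests(p, method="fdr_bh")[1]
    gi = best
    res = pd.DataFrame(
        {
            "best_group": [labels[i] for i in gi],
            "A": a[gi, np.arange(len(gi))],
            "B": b[gi, np.arange(len(gi))],
            "indval": stat,
            "p_perm": p,
            "q": q,
        },
        index=ct.index,
    )
    res.attrs["n_perm"] = n_perm
    res.attrs["seed"] = seed
    return res


def significant_indicators(indval_table: pd.DataFrame, alpha: float = 0.05) -> pd.Index:
    """Taxa whose BH-adjusted IndVal permutation p is at most `alpha`."""
    return indval_table.index[indval_table["q"] <= alpha]


def build_network(
    ct: pd.DataFrame,
    method: str = "spearman",
    r_min: float = 0.6,
    p_max: float = 0.05,
) -> nx.Graph:
    """Co-occurrence network on relative abundances.

    Edges join taxa with |rank correlation| >= `r_min` and BH-adjusted
    p <= `p_max`; the correlation sign is kept as an edge attribute.
    Constant taxa have undefined correlations and stay isolated.
    """
    if ct.shape[1] < 5:
        raise ValueError("need at least 5 samples")
    if method != "spearman":
        raise ValueError("only spearman correlation is supported")
    rel = (ct / ct.sum(axis=0)).to_numpy(float)
    taxa = list(ct.index)
    const = rel.std(axis=1) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant taxa left isolated (undefined correlation)",
            stacklevel=2,
        )
    g = nx.Graph()
    g.add_nodes_from(sorted(taxa))
    ok = np.where(~const)[0]
    if len(ok) >= 2:
        rho, pval = stats.spearmanr(rel[ok].T)
        if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to scalars
            rho = np.array([[1.0, rho], [rho, 1.0]])
            pval = np.array([[0.0, pval], [pval, 0.0]])
        iu, ju = np.triu_indices(len(ok), k=1)
        q = multipletests(pval[iu, ju], method="fdr_bh")[1]
        for (i, j, qq) in zip(iu, ju, q):
            r = rho[i, j]
            if abs(r) >= r_min and qq <= p_max:
                g.add_edge(
                    taxa[ok[i]],
                    taxa[ok[j]],
                    rho=float(r),
                    p=float(pval[i, j]),
                    q=float(qq),
                    sign=1 if r > 0 else -1,
                )
    return g


def detect_modules(graph: nx.Graph) -> dict:
    """Greedy (CNM) modularity modules; isolated nodes get singletons.

    Deterministic for a given node set: nodes are processed in sorted
    order and module ids are assigned by each module's smallest member.
    """
    nodes = sorted(graph.nodes)
    connected = [n for n in nodes if graph.degree(n) > 0]
    communities: list[set] = []
    if connected:
        sub = graph.subgraph(connected)
        if sub.number_of_edges() > 0:
            communities = [set(c) for c in nx.community.greedy_modularity_communities(sub)]
    communities += [{n} for n in nodes if graph.degree(n) == 0]
    communities.sort(key=lambda c: min(c))
    modules = {}
    for mid, comm in enumerate(communities):
        for n in comm:
            modules[n] = mid
    return modules


@dataclass
class KeystoneRule:
    zi_threshold: float = ZI_THRESHOLD
    pi_threshold: float = PI_THRESHOLD
    combine: str = "or"  # permissive reading of the Zi/Pi rule

    def __call__(self, zi: float, pi: float) -> bool:
        hit_z, hit_p = zi > self.zi_threshold, pi > self.pi_threshold
        return (hit_z or hit_p) if self.combine == "or" else (hit_z and hit_p)


def zi_pi(graph: nx.Graph, modules: dict, rule: KeystoneRule | None = None) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardizes a node's within-module degree against its module's
    mean and (population) SD, with SD = 0 giving Zi = 0; Pi = 1 − Σ over
    modules of the squared fraction of the node's edges into each
    module, with isolated nodes at Pi = 0.
    """
    if set(graph.nodes) - set(modules):
        raise ValueError("modules must cover every node")
    rule = rule or KeystoneRule()
    nodes = sorted(graph.nodes)
    within = {}
    per_module_counts = {}
    for n in nodes:
        counts: dict = {}
        for nb in graph.neighbors(n):
            counts[modules[nb]] = counts.get(modules[nb], 0) + 1
        per_module_counts[n] = counts
        within[n] = counts.get(modules[n], 0)

    rows = []
    for n in nodes:
        mid = modules[n]
        members = [m for m in nodes if modules[m] == mid]
        kw = np.array([within[m] for m in members], float)
        sd = kw.std()
        zi = (within[n] - kw.mean()) / sd if sd > 0 else 0.0
        k = graph.degree(n)
        if k == 0:
            pi = 0.0
        else:
            pi = 1.0 - sum((c / k) ** 2 for c in per_module_counts[n].values())
        rows.append(
            {
                "taxon_id": n,
                "module_id": mid,
                "zi": zi,
                "pi": pi,
                "is_keystone": rule(zi, pi),
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def indicator_composite(
    ct_indicators: pd.DataFrame, totals: pd.Series | None = None
) -> PCAResult:
    """PCA summary of the indicator taxa (samples scored on PC1/PC2).

    Input is the taxa × samples table restricted to indicator taxa;
    per-sample relative abundances (w.r.t. `totals`, by default the
    subset's own sample sums) are z-scored per taxon before PCA.
    Component signs are fixed so the largest loading is positive.
    """
    if ct_indicators.shape[0] < 2:
        raise ValueError("need at least 2 indicator taxa")
    totals = ct_indicators.sum(axis=0) if totals is None else totals
    rel = (ct_indicators / totals).T  # samples × taxa
    return pca(rel)


def screen_taxa(
    ct: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    prevalence: float = 0.20,
    min_count: int = 4,
    r_min: float = 0.6,
    p_max: float = 0.05,
    rule: KeystoneRule | None = None,
) -> dict:
    """Full screen: filter, then indicator / keystone / abundance tables."""
    filtered = filter_asvs(ct, prevalence=prevalence, min_count=min_count)
    iv = indval(filtered, groups, n_perm=n_perm, seed=seed)
    graph = build_network(filtered, r_min=r_min, p_max=p_max)
    modules = detect_modules(graph)
    topo = zi_pi(graph, modules, rule=rule)
    classes = classify_abundance(filtered)
    return {
        "filtered": filtered,
        "indval": iv,
        "network": graph,
        "modules": modules,
        "topology": topo,
        "abundance": classes,
    }
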