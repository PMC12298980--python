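"""Synthetic studies with known ground truth.

Emulates the statistical structure of a grouped solar-facility plot
study so every downstream stage (EMF indices, diversity, taxa screens,
attribution, piecewise SEM) can be exercised and scored against a truth
record:

* plot-level functions with within-category correlation, per-group mean
  shifts, and a latent driver signal (microbial activity and indicator
  taxa as true drivers);
* compositional ASV tables from a heavy-tailed (log-normal base
  abundance) model with multinomial read sampling, planted
  group-enriched indicator taxa, and latent-factor co-occurrence
  modules;
* random bifurcating trees, plant trait tables, and raw microbial
  activity measurements coupled to the latent activity driver.

All randomness flows from one `numpy` Generator derived from the design
seed; no global RNG state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from emfkit.design import DEFAULT_DRIVER_DAG, StudyDesign
from emfkit.emf import FunctionMatrix
from emfkit.psem import DAGSpec

DOMAINS = ("prokaryote", "fungus", "plant")
_PREFIX = {"prokaryote": "Pro_ASV", "fungus": "Fun_ASV", "plant": "Plant_sp"}
_PHYLA = {
    "prokaryote": [
        "Proteobacteria",
        "Actinobacteriota",
        "Acidobacteriota",
        "Chloroflexi",
        "Bacteroidota",
        "Verrucomicrobiota",
    ],
    "fungus": [
        "Ascomycota",
        "Basidiomycota",
        "Mortierellomycota",
        "Glomeromycota",
        "Chytridiomycota",
    ],
    "plant": ["Poaceae", "Asteraceae", "Fabaceae", "Chenopodiaceae", "Rosaceae"],
}
_GUILDS = [
    "Arbuscular Mycorrhizal",
    "Plant Pathogen",
    "Saprotroph",
    "Endophyte",
    "Ectomycorrhizal",
    "Animal Pathogen",
]
_CONFIDENCE = ["Highly Probable", "Probable", "Possible"]

#: relative-abundance floors the generator enforces so the rare (<0.01%)
#: and abundant (>0.1%) screens always have members
_DOMINANT_FRAC = 3e-3
_RARE_FRAC = 6e-5


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# functions + metadata


def generate_functions(
    design: StudyDesign,
    rng: np.random.Generator | None = None,
    drivers: pd.DataFrame | None = None,
) -> tuple[FunctionMatrix, pd.DataFrame]:
    """Plot × function measurements plus plot metadata.

    Function z-scores are `shift + noise_sd * (sqrt(rho) f_cat +
    sqrt(1-rho) eps)` with one shared latent factor per category and
    plot, so within-category correlation is `rho_cat`.  When a `drivers`
    table is given, the weighted driver signal is added to every
    function with loading `driver_function_loading`.  Raw values are an
    affine per-function rescaling of the z-scores into arbitrary native
    units (the EMF standardization absorbs it).
    """
    rng = design.rng() if rng is None else rng
    n, m = design.n_plots, design.n_functions
    fids = design.function_ids()
    cat_of = design.category_map()
    cats = list(design.categories)

    shift = np.zeros((n, m))
    for gi, g in enumerate(design.group_labels):
        eff = design.effect_profile.get(g, 0.0)
        eff = np.broadcast_to(np.asarray(eff, float), (m,))
        rows = slice(gi * design.plots_per_group, (gi + 1) * design.plots_per_group)
        shift[rows] = eff

    f_cat = rng.normal(size=(n, len(cats)))
    cat_idx = np.array([cats.index(cat_of[f]) for f in fids])
    eps = rng.normal(size=(n, m))
    rho = design.rho_cat
    z = shift + design.noise_sd * (
        np.sqrt(rho) * f_cat[:, cat_idx] + np.sqrt(1 - rho) * eps
    )
    if drivers is not None:
        s = np.zeros(n)
        for d, beta in design.driver_effects.items():
            s += beta * drivers[d].to_numpy(float)
        z = z + design.driver_function_loading * s[:, None]

    scale = np.exp(rng.normal(1.0, 0.5, size=m))
    offset = rng.uniform(5.0, 50.0, size=m)
    values = pd.DataFrame(offset + scale * z, index=design.plot_ids(), columns=fids)
    fm = FunctionMatrix(values=values, category=cat_of)

    gidx = np.repeat(np.arange(design.n_groups), design.plots_per_group)
    env = drivers["Env"].to_numpy(float) if drivers is not None else np.zeros(n)
    texture = rng.dirichlet([10.0, 28.0, 62.0], size=n)
    texture = texture / texture.sum(axis=1, keepdims=True) * 100.0
    meta = pd.DataFrame(
        {
            "group": design.groups(),
            "SWC": 8.0 + 2.0 * gidx + 1.5 * env + rng.normal(0, 0.8, n),
            "ST": 14.0 - 1.2 * gidx + rng.normal(0, 0.6, n),
            "pH": 8.1 + rng.normal(0, 0.15, n),
            "evaporation": 1700.0 - 60.0 * gidx + rng.normal(0, 40.0, n),
            "clay": texture[:, 0],
            "silt": texture[:, 1],
            "sand": texture[:, 2],
        },
        index=design.plot_ids(),
    )
    return fm, meta


# ---------------------------------------------------------------------------
# communities


def generate_community(
    design: StudyDesign,
    domain: str,
    rng: np.random.Generator | None = None,
    enrichment: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Taxa × samples counts, taxonomy, and the planted truth for one domain.

    Base abundances are log-normal (heavy-tailed); each taxon belongs to
    a latent module whose per-sample Gaussian factor induces
    co-occurrence; planted indicator taxa get a multiplicative
    enrichment in their assigned group.  Reads are multinomial at the
    configured depth (plants: small Poisson quadrat counts capped at 40).
    One dominant and one ultra-rare taxon are pinned at the probability
    level so the abundant (>0.1%) and rare (<0.01%) classes are never
    empty.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    enrichment = design.enrichment if enrichment is None else float(enrichment)
    rng = design.rng() if rng is None else rng
    n_taxa = {
        "prokaryote": design.n_taxa_pro,
        "fungus": design.n_taxa_fun,
        "plant": design.n_taxa_plant,
    }[domain]
    n_ind = design.n_indicator_planted if domain != "plant" else 0
    if n_ind > 0 and enrichment <= 1:
        raise ValueError("planted-indicator enrichment must exceed 1")
    if n_ind > n_taxa - 2:
        raise ValueError("more planted indicators than available taxa")

    taxa = [f"{_PREFIX[domain]}{i:04d}" for i in range(n_taxa)]
    samples = design.plot_ids()
    groups = np.array(design.groups())

    a = rng.normal(0.0, design.base_sigma, n_taxa)
    w = np.exp(a)
    w[0] = _DOMINANT_FRAC / (1 - _DOMINANT_FRAC) * w[1:].sum()
    w[-1] = _RARE_FRAC / (1 - _RARE_FRAC) * w[:-1].sum()

    module = np.minimum(
        np.arange(n_taxa) * design.n_modules // n_taxa, design.n_modules - 1
    )
    factors = rng.normal(size=(design.n_modules, len(samples)))

    planted = rng.choice(np.arange(1, n_taxa - 1), size=n_ind, replace=False)
    planted.sort()
    ind_group = {
        taxa[k]: design.group_labels[i % design.n_groups]
        for i, k in enumerate(planted)
    }

    logw = np.log(w)[:, None] + design.module_loading * factors[module, :]
    logw = logw + rng.normal(0, 0.4, size=(n_taxa, len(samples)))
    for k in planted:
        in_group = groups == ind_group[taxa[k]]
        logw[k, in_group] += np.log(enrichment)
    p = np.exp(logw - logw.max(axis=0))
    p = p / p.sum(axis=0)

    if domain == "plant":
        counts = np.minimum(rng.poisson(p * 150.0), 40)
    else:
        counts = np.column_stack(
            [rng.multinomial(design.depth, p[:, s]) for s in range(len(samples))]
        )
    table = pd.DataFrame(counts, index=taxa, columns=samples)

    phyla = _PHYLA[domain]
    tax_rows = []
    for i, t in enumerate(taxa):
        ph = phyla[int(rng.integers(len(phyla)))]
        tax_rows.append({"taxon_id": t, "taxonomy": f"p__{ph};g__gen{i:04d}"})
    taxonomy = pd.DataFrame(tax_rows).set_index("taxon_id")

    truth: dict = {
        "indicator_ids": [taxa[k] for k in planted],
        "indicator_group": ind_group,
        "modules": {t: int(m) for t, m in zip(taxa, module)},
    }
    if domain == "fungus":
        truth["guild_map"] = {
            t: {
                "guild": _GUILDS[int(rng.integers(len(_GUILDS)))],
                "confidence": _CONFIDENCE[int(rng.integers(len(_CONFIDENCE)))],
            }
            for t in taxa
        }
    return table, taxonomy, truth


def generate_tree(taxa_ids, rng=None) -> str:
    """Random bifurcating tree over the given tips, as a Newick string.

    Coalescent-style: lineages merge uniformly at random with
    exponential waiting times (rate = number of open pairs), giving
    strictly positive branch lengths and each tip exactly once.
    """
    taxa = list(taxa_ids)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon ids")
    rng = _as_rng(rng)
    nodes = [(str(t), 0.0) for t in taxa]
    t_now = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t_now += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = f"({na}:{t_now - ha:.8g},{nb}:{t_now - hb:.8g})"
        nodes = [nodes[x] for x in range(k) if x not in (i, j)] + [(merged, t_now)]
    return nodes[0][0] + ";"


# ---------------------------------------------------------------------------
# linear SEM data


def generate_sem_system(
    dag: DAGSpec,
    coefficients: dict[tuple[str, str], float],
    n: int,
    rng=None,
) -> pd.DataFrame:
    """Sample a standardized linear-Gaussian system consistent with `dag`.

    Variables are generated in topological order as the beta-weighted sum
    of parents plus Gaussian noise whose variance is set analytically so
    every variable has population variance exactly 1 (hence the
    coefficients are path coefficients and the path-tracing rules hold).
    """
    rng = _as_rng(rng)
    for u, v in coefficients:
        if not dag.graph.has_edge(u, v):
            raise ValueError(f"coefficient for non-edge ({u}, {v})")
    order = list(nx.lexicographical_topological_sort(dag.graph))
    idx = {v: i for i, v in enumerate(order)}
    cov = np.zeros((len(order), len(order)))
    data = np.zeros((n, len(order)))
    for v in order:
        pars = dag.parents(v)
        b = np.array([coefficients.get((p, v), 0.0) for p in pars])
        if pars:
            pidx = [idx[p] for p in pars]
            var_expl = b @ cov[np.ix_(pidx, pidx)] @ b
            if var_expl >= 1.0 - 1e-12:
                raise ValueError(f"coefficients into {v!r} leave no residual variance")
            sigma = np.sqrt(1.0 - var_expl)
            data[:, idx[v]] = data[:, pidx] @ b + sigma * rng.normal(size=n)
            for u in order:
                cov[idx[v], idx[u]] = cov[idx[u], idx[v]] = b @ cov[pidx, idx[u]]
            cov[idx[v], idx[v]] = 1.0
        else:
            data[:, idx[v]] = rng.normal(size=n)
            cov[idx[v], idx[v]] = 1.0
    return pd.DataFrame(data, columns=order)


# ---------------------------------------------------------------------------
# full study


@dataclass
class SyntheticStudy:
    design: StudyDesign
    functions: FunctionMatrix
    metadata: pd.DataFrame
    communities: dict[str, pd.DataFrame]
    taxonomies: dict[str, pd.DataFrame]
    trees: dict[str, str]
    traits: pd.DataFrame
    activity_raw: pd.DataFrame
    drivers: pd.DataFrame
    truth: dict = field(default_factory=dict)


def driver_dag() -> DAGSpec:
    edges = [e for e in DEFAULT_DRIVER_DAG]
    return DAGSpec(edges=edges)


def generate_study(design: StudyDesign | None = None) -> SyntheticStudy:
    """Generate one complete study (functions, communities, trees, traits,
    activity) together with the truth record that scores recovery."""
    design = StudyDesign() if design is None else design
    rng = design.rng()

    dag = driver_dag()
    drivers = generate_sem_system(dag, dict(DEFAULT_DRIVER_DAG), design.n_plots, rng)
    drivers.index = design.plot_ids()

    fm, meta = generate_functions(design, rng, drivers=drivers)

    communities, taxonomies, trees, truth_taxa = {}, {}, {}, {}
    for dom in DOMAINS:
        table, tax, tr = generate_community(design, dom, rng)
        communities[dom], taxonomies[dom] = table, tax
        trees[dom] = generate_tree(table.index, rng)
        truth_taxa[dom] = tr

    species = list(communities["plant"].index)
    traits = pd.DataFrame(
        {
            "height": np.exp(rng.normal(2.8, 0.6, len(species))),
            "SLA": np.clip(rng.normal(15.0, 4.0, len(species)), 2.0, None),
        },
        index=species,
    )

    ma = drivers["MA"].to_numpy(float)
    n = design.n_plots
    mbc = np.exp(5.7 + 0.30 * ma + rng.normal(0, 0.10, n))          # µg C / g
    soc = np.exp(2.30 + 0.20 * ma + rng.normal(0, 0.10, n))         # g C / kg
    qco2 = np.exp(-1.20 - 0.30 * ma + rng.normal(0, 0.10, n))       # 1 / day
    activity_raw = pd.DataFrame(
        {
            "copies_pro": 10 ** (8.5 + 0.25 * ma + rng.normal(0, 0.08, n)),
            "copies_fun": 10 ** (7.5 + 0.30 * ma + rng.normal(0, 0.08, n)),
            "mbc": mbc,
            "soc": soc,
            "c_min": qco2 * mbc,                                     # µg CO2-C / g / day
        },
        index=design.plot_ids(),
    )

    truth = {
        "seed": design.seed,
        "group_effects": {g: design.effect_profile.get(g, 0.0) for g in design.group_labels},
        "driver_effects": dict(design.driver_effects),
        "driver_paths": {f"{u}->{v}": b for (u, v), b in DEFAULT_DRIVER_DAG.items()},
        "drivers": {c: drivers[c].round(10).tolist() for c in drivers.columns},
        "taxa": truth_taxa,
    }
    return SyntheticStudy(
        design=design,
        functions=fm,
        metadata=meta,
        communities=communities,
        taxonomies=taxonomies,
        trees=trees,
        traits=traits,
        activity_raw=activity_raw,
        drivers=drivers,
        truth=truth,
    )


def truth_to_json(truth: dict) -> str:
    return json.dumps(truth, indent=2, sort_keys=True)


def truth_from_json(text: str) -> dict:
    return json.loads(text)
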