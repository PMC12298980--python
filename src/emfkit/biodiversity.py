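"""Taxonomic, phylogenetic and functional diversity.

Per-sample α-diversity: richness (taxa with nonzero counts), Faith's
phylogenetic diversity (total branch length of the minimal subtree
spanning the present tips and the root), and functional dispersion
(FDis: abundance-weighted mean distance of species to the
abundance-weighted trait centroid, computed in a principal-coordinates
embedding of the Gower trait distance).  β-diversity distance matrices
(Bray–Curtis on relative abundances, Euclidean on z-scored function
columns) feed the Mantel tests downstream.
"""

from __future__ import annotations

import io
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from emfkit.ordination import pcoa_embed


def richness(ct: pd.DataFrame) -> pd.Series:
    """Number of taxa with count > 0 per sample (columns are samples)."""
    if (ct.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return (ct > 0).sum(axis=0).rename("richness")


def faith_pd(ct: pd.DataFrame, tree: str | TreeNode, include_root: bool = True) -> pd.Series:
    """Faith's PD per sample from a taxa × samples table and a Newick tree.

    Sums the lengths of every edge whose subtree contains at least one
    present taxon; with ``include_root`` (the classic definition) that is
    the path set connecting the present tips to the root.  With
    ``include_root=False`` edges above the most recent common ancestor of
    the present tips are excluded.  Samples with no taxa score 0.
    """
    if isinstance(tree, str):
        tree = TreeNode.read(io.StringIO(tree), convert_underscores=False)
    tips = {t.name for t in tree.tips()}
    present_any = ct.index[(ct > 0).any(axis=1)]
    missing = [t for t in present_any if t not in tips]
    if missing:
        raise ValueError(f"taxa absent from the tree: {missing[:5]}")

    out = {}
    for sample in ct.columns:
        present = set(ct.index[ct[sample] > 0])
        if not present:
            out[sample] = 0.0
            continue
        root = tree if include_root or len(present) == 1 else tree.lca(
            [tree.find(t) for t in present]
        )
        # one bottom-up pass: an edge counts iff its subtree holds a present tip
        has_present: dict[int, bool] = {}
        pd_sum = 0.0
        for n in root.postorder(include_self=False):
            if n.is_tip():
                hit = n.name in present
            else:
                hit = any(has_present[id(c)] for c in n.children)
            has_present[id(n)] = hit
            if hit and n.length:
                pd_sum += n.length
        out[sample] = pd_sum
    return pd.Series(out, name="faith_pd")


def gower_distance(traits: pd.DataFrame) -> pd.DataFrame:
    """Gower distance between species over mixed quantitative/categorical traits.

    Quantitative traits contribute |x−y| / range, categorical traits a
    0/1 mismatch; missing values drop the trait for that pair with
    re-weighting over the remaining traits.  Zero-range traits are
    excluded with a warning.
    """
    if traits.shape[1] < 1:
        raise ValueError("need at least one trait")
    n = len(traits)
    contrib = np.zeros((n, n))
    weight = np.zeros((n, n))
    used = 0
    for col in traits.columns:
        x = traits[col]
        if pd.api.types.is_numeric_dtype(x):
            rng = np.nanmax(x.to_numpy(float)) - np.nanmin(x.to_numpy(float))
            if rng == 0:
                warnings.warn(f"zero-range trait {col!r} excluded", stacklevel=2)
                continue
            v = x.to_numpy(float)
            d = np.abs(v[:, None] - v[None, :]) / rng
            ok = np.isfinite(v)[:, None] & np.isfinite(v)[None, :]
        else:
            v = x.to_numpy(object)
            ok = np.array([[a is not None and b is not None for b in v] for a in v])
            d = np.array([[0.0 if a == b else 1.0 for b in v] for a in v])
        contrib += np.where(ok, d, 0.0)
        weight += ok.astype(float)
        used += 1
    if used == 0:
        raise ValueError("no usable traits")
    if (weight == 0).any():
        raise ValueError("some species pairs share no observed trait")
    dist = contrib / weight
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=traits.index, columns=traits.index)


def functional_dispersion(ct: pd.DataFrame, dist: pd.DataFrame) -> pd.Series:
    """FDis per sample: weighted mean distance to the weighted centroid.

    Species are embedded by classical PCoA of the distance matrix
    (negative eigenvalues truncated); each sample's centroid is the
    abundance-weighted mean of its present species' coordinates.
    Samples with zero or one present species score 0.
    """
    present_any = ct.index[(ct > 0).any(axis=1)]
    missing = [t for t in present_any if t not in dist.index]
    if missing:
        raise ValueError(f"species absent from the distance matrix: {missing[:5]}")
    coords = pcoa_embed(dist.loc[dist.index, dist.index].to_numpy(float))
    coord = pd.DataFrame(coords, index=dist.index)
    out = {}
    for sample in ct.columns:
        ab = ct[sample]
        ab = ab[ab > 0]
        if len(ab) <= 1:
            out[sample] = 0.0
            continue
        w = ab.to_numpy(float) / ab.sum()
        x = coord.loc[ab.index].to_numpy(float)
        centroid = w @ x
        out[sample] = float(w @ np.sqrt(((x - centroid) ** 2).sum(axis=1)))
    return pd.Series(out, name="fdis")


def guild_richness(
    ct: pd.DataFrame,
    guild_map: dict,
    min_confidence: tuple[str, ...] = ("Highly Probable", "Probable"),
) -> pd.Series:
    """Distinct guilds among present taxa, counting only confident assignments.

    `guild_map` maps taxon → {"guild": ..., "confidence": ...} (or a bare
    guild string, then confidence is assumed acceptable).
    """
    accepted = {}
    for taxon, entry in guild_map.items():
        if isinstance(entry, str):
            accepted[taxon] = entry
        elif entry.get("confidence") in min_confidence:
            accepted[taxon] = entry["guild"]
    out = {}
    for sample in ct.columns:
        present = ct.index[ct[sample] > 0]
        out[sample] = len({accepted[t] for t in present if t in accepted})
    return pd.Series(out, name="guild_richness")


def beta_distance(table: pd.DataFrame, metric: str = "bray-curtis") -> pd.DataFrame:
    """Pairwise sample distances.

    `bray-curtis` treats the input as a taxa × samples count table and
    works on per-sample relative abundances; `euclidean` treats it as a
    samples × variables table and z-scores the columns first.
    """
    if metric == "bray-curtis":
        if table.shape[1] < 2:
            raise ValueError("need at least 2 samples")
        totals = table.sum(axis=0)
        if (totals == 0).any():
            empty = list(table.columns[totals == 0])
            raise ValueError(f"Bray–Curtis undefined for empty samples: {empty}")
        rel = (table / totals).T  # samples × taxa
        d = squareform(pdist(rel.to_numpy(float), metric="braycurtis"))
        ids = list(table.columns)
    elif metric == "euclidean":
        if table.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        sd = table.std(ddof=1)
        keep = table.columns[sd > 0]
        z = (table[keep] - table[keep].mean()) / sd[keep]
        d = squareform(pdist(z.to_numpy(float), metric="euclidean"))
        ids = list(table.index)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=ids, columns=ids)


def diversity_profile(
    ct: pd.DataFrame,
    tree: str | TreeNode | None = None,
    traits: pd.DataFrame | None = None,
    guild_map: dict | None = None,
    domain: str = "",
) -> pd.DataFrame:
    """Assemble the per-sample α-diversity table for one organism domain."""
    prof = pd.DataFrame({"richness": richness(ct)})
    if tree is not None:
        prof["faith_pd"] = faith_pd(ct, tree)
    if traits is not None:
        prof["fdis"] = functional_dispersion(ct, gower_distance(traits))
    if guild_map is not None:
        prof["guild_richness"] = guild_richness(ct, guild_map)
    if domain:
        prof.insert(0, "domain", domain)
    return prof
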