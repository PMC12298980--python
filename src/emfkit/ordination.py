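"""Shared ordination helpers: PCA on z-scored columns and classical PCoA.

Both are used in several places (indicator composites, activity composites,
SEM composite variables, functional dispersion), so they live here with a
single sign convention: every component is flipped, if needed, so that its
largest-magnitude loading is positive.  That makes scores reproducible
across BLAS builds, where eigenvector signs are otherwise arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PCAResult:
    scores: pd.DataFrame        # samples × components
    loadings: pd.DataFrame      # variables × components
    explained_ratio: np.ndarray


def zscore_columns(df: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    sd = df.std(ddof=ddof)
    if (sd == 0).any():
        bad = list(df.columns[sd == 0])
        raise ValueError(f"constant columns cannot be z-scored: {bad}")
    return (df - df.mean()) / sd


def pca(df: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of z-scored columns via SVD, with deterministic component signs."""
    z = zscore_columns(df).to_numpy(float)
    n, p = z.shape
    if n < 2 or p < 1:
        raise ValueError("PCA needs at least 2 rows and 1 column")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(n - 1, p) if n_components is None else min(n_components, min(n - 1, p))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign anchor: largest |loading| positive per component
    for c in range(k):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    scores = u * s
    ev = s**2
    total = np.sum(np.linalg.svd(z, compute_uv=False) ** 2)
    names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=df.index, columns=names),
        loadings=pd.DataFrame(vt.T, index=df.columns, columns=names),
        explained_ratio=ev / total,
    )


def pcoa_embed(dist: np.ndarray) -> np.ndarray:
    """Classical principal-coordinates embedding of a distance matrix.

    Gower-centres the squared distances and eigendecomposes; axes with
    negative eigenvalues are truncated (dropped) rather than corrected.
    Returns an n × k coordinate matrix whose pairwise Euclidean distances
    reproduce the input when it is Euclidean-embeddable.
    """
    d = np.asarray(dist, float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    b = a - row - row.T + a.mean()
    w, v = np.linalg.eigh(b)
    keep = w > max(1e-10, 1e-8 * abs(w).max() if w.size else 0)
    return v[:, keep] * np.sqrt(w[keep])
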