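"""Piecewise structural equation modelling with d-separation tests.

A structural model over observed plot-level variables is declared as a
DAG.  Each endogenous node is fitted by its own OLS regression on its
parents; coefficients are reported on the standardized (beta) scale.  The
model as a whole is evaluated through its basis set of independence
claims: every non-adjacent ordered pair (u, v), with u topologically
before v, yields the claim u ⟂ v | parents(v) ∪ parents(u), tested as the
p-value of u when added to v's parental regression.  Claim p-values are
combined into Fisher's C = −2 Σ ln p, which is chi-square distributed
with 2k degrees of freedom when the causal structure is correct; a small
tail probability rejects the structure.

Direct, indirect and total standardized effects on a response are
obtained by path enumeration: the indirect effect of a driver is the sum
over all directed paths (excluding the direct edge) of the products of
path coefficients, and total = direct + indirect.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

COND_WARN = 1e6


@dataclass
class DAGSpec:
    """Directed acyclic structure: edges plus optionally isolated nodes."""

    edges: list[tuple[str, str]]
    nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structure contains a directed cycle")
        self._graph = g
        self.nodes = list(g.nodes)

    @classmethod
    def from_text(cls, text: str) -> "DAGSpec":
        """Parse an edge list, one `A -> B` per line; blank/# lines skipped."""
        edges = []
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "->" not in line:
                raise ValueError(f"cannot parse edge line: {line!r}")
            a, b = (s.strip() for s in line.split("->", 1))
            edges.append((a, b))
        return cls(edges=edges)

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    def parents(self, v: str) -> list[str]:
        return sorted(self._graph.predecessors(v))

    def endogenous(self) -> list[str]:
        return [v for v in nx.lexicographical_topological_sort(self._graph) if self._graph.in_degree(v)]

    def exogenous(self) -> list[str]:
        return [v for v in self.nodes if self._graph.in_degree(v) == 0]


@dataclass(frozen=True)
class IndependenceClaim:
    u: str
    v: str
    conditioning: tuple[str, ...]


def basis_set(dag: DAGSpec) -> list[IndependenceClaim]:
    """The d-separation basis set of a DAG.

    One claim per non-adjacent unordered pair, with the topologically
    earlier variable as u and conditioning on parents(v) ∪ parents(u).
    """
    g = dag.graph
    order = list(nx.lexicographical_topological_sort(g))
    pos = {n: k for k, n in enumerate(order)}
    claims = []
    for a, b in itertools.combinations(order, 2):
        if g.has_edge(a, b) or g.has_edge(b, a):
            continue
        u, v = (a, b) if pos[a] < pos[b] else (b, a)
        cond = sorted((set(g.predecessors(v)) | set(g.predecessors(u))) - {u, v})
        claims.append(IndependenceClaim(u=u, v=v, conditioning=tuple(cond)))
    return claims


def _ols(y: np.ndarray, x: np.ndarray, node: str) -> tuple[np.ndarray, np.ndarray]:
    """OLS with intercept; returns (coefs, p-values) for the x columns."""
    n, p = x.shape
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"singular regression for node {node!r}")
    cond = np.linalg.cond(design)
    if cond > COND_WARN:
        warnings.warn(
            f"ill-conditioned regression for node {node!r} (cond={cond:.3g}); "
            "collinear predictors retained",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = n - design.shape[1]
    if df <= 0:
        raise ValueError(f"not enough observations to fit node {node!r}")
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    return beta[1:], pvals[1:]


@dataclass
class PSEMResult:
    edges: pd.DataFrame       # source, target, beta (standardized), p
    claims: pd.DataFrame      # u, v, conditioning, p
    fisher_c: float
    df: int
    model_p: float
    effects: pd.DataFrame     # driver → direct, indirect, total on response
    response: str | None


def fit_psem(dag: DAGSpec, data: pd.DataFrame, response: str | None = None) -> PSEMResult:
    """Fit every local model, test the basis set, and decompose effects."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    missing = [n for n in dag.nodes if n not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    max_indeg = max((dag.graph.in_degree(v) for v in dag.nodes), default=0)
    if len(data) <= max_indeg + 2:
        raise ValueError("too few observations for the largest local model")

    sd = data[dag.nodes].std(ddof=1)
    edge_rows = []
    for v in dag.endogenous():
        pars = dag.parents(v)
        coefs, pvals = _ols(data[v].to_numpy(float), data[pars].to_numpy(float), v)
        for par, b, p in zip(pars, coefs, pvals):
            beta_std = b * sd[par] / sd[v] if sd[v] > 0 else np.nan
            edge_rows.append({"source": par, "target": v, "beta": beta_std, "p": p})
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "beta", "p"])

    claim_rows = []
    for cl in basis_set(dag):
        preds = list(cl.conditioning) + [cl.u]
        _, pvals = _ols(
            data[cl.v].to_numpy(float), data[preds].to_numpy(float), cl.v
        )
        claim_rows.append(
            {
                "u": cl.u,
                "v": cl.v,
                "conditioning": ",".join(cl.conditioning),
                "p": pvals[-1],
            }
        )
    claims = pd.DataFrame(claim_rows, columns=["u", "v", "conditioning", "p"])
    k = len(claims)
    if k:
        fisher_c = float(-2 * np.sum(np.log(np.clip(claims["p"], 1e-300, None))))
        model_p = float(stats.chi2.sf(fisher_c, 2 * k))
    else:  # saturated model: nothing to test
        fisher_c, model_p = 0.0, 1.0

    if response is None:
        sinks = [v for v in dag.nodes if dag.graph.out_degree(v) == 0 and dag.graph.in_degree(v)]
        response = sinks[0] if len(sinks) == 1 else None
    effects = _path_effects(dag, edges, response) if response else pd.DataFrame(
        columns=["direct", "indirect", "total"]
    )
    return PSEMResult(
        edges=edges,
        claims=claims,
        fisher_c=fisher_c,
        df=2 * k,
        model_p=model_p,
        effects=effects,
        response=response,
    )


def _path_effects(dag: DAGSpec, edges: pd.DataFrame, response: str) -> pd.DataFrame:
    beta = {(r.source, r.target): r.beta for r in edges.itertuples()}
    rows = {}
    for u in dag.nodes:
        if u == response or not nx.has_path(dag.graph, u, response):
            continue
        direct = beta.get((u, response), 0.0)
        indirect = 0.0
        for path in nx.all_simple_paths(dag.graph, u, response):
            if len(path) == 2:
                continue
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= beta[(a, b)]
            indirect += prod
        rows[u] = {"direct": direct, "indirect": indirect, "total": direct + indirect}
    return pd.DataFrame(rows).T.reindex(columns=["direct", "indirect", "total"])


@dataclass
class PeriodComparison:
    installation: PSEMResult
    running: PSEMResult
    delta: pd.DataFrame  # per-edge standardized coefficient difference


def compare_periods(
    dag: DAGSpec,
    data_installation: pd.DataFrame,
    data_running: pd.DataFrame,
    response: str | None = None,
) -> PeriodComparison:
    """Fit the same DAG on two period datasets and difference the paths."""
    a = fit_psem(dag, data_installation, response=response)
    b = fit_psem(dag, data_running, response=response)
    key = ["source", "target"]
    merged = a.edges.merge(b.edges, on=key, suffixes=("_installation", "_running"))
    merged["delta_beta"] = merged["beta_running"] - merged["beta_installation"]
    return PeriodComparison(installation=a, running=b, delta=merged[key + ["beta_installation", "beta_running", "delta_beta"]])


#: Default structural model over the composite drivers: the environment
#: composite feeds microbial activity, diversity and indicator taxa; those
#: feed the soil nutrient pool and nutrient cycling; PP, SNP and Cycling
#: feed overall multifunctionality, with direct MA and Indicator links kept.
DEFAULT_DAG_TEXT = """\
Env -> MA
Env -> Div
Env -> Indicator
Env -> PP
MA -> SNP
MA -> Cycling
Div -> SNP
Div -> Cycling
Indicator -> SNP
Indicator -> Cycling
SNP -> EMF
Cycling -> EMF
PP -> EMF
MA -> EMF
Indicator -> EMF
"""


def default_dag() -> DAGSpec:
    return DAGSpec.from_text(DEFAULT_DAG_TEXT)
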