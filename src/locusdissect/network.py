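"""Weighted co-expression networks, modules and key-driver enrichment.

An unsigned weighted network is built from expression: adjacency
a_ij = |cor(x_i, x_j)|^beta (soft power beta), smoothed into the
topological overlap matrix (TOM).  Modules come from average-linkage
clustering of 1 - TOM with a static height cut; each module is summarized
by its eigengene (first principal component, sign-oriented to correlate
positively with its members) for module-trait correlation.  Key drivers
are nodes whose graph neighborhood is enriched for a module's members
(hypergeometric upper tail with BH-FDR across nodes).

Nodes are (gene, tissue) pairs so the same gene can participate once per
tissue when matrices from several tissues are concatenated on shared
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .eqtl import bh_fdr, trait_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionGraph",
    "ModuleSet",
    "build_graph",
    "tom_from_adjacency",
    "detect_modules",
    "module_trait",
    "key_drivers",
    "GREY",
]

#: label for the pool of unassigned nodes
GREY = "grey"
DEFAULT_BETA = 6.0
DEFAULT_CUT_HEIGHT = 0.75
DEFAULT_MIN_SIZE = 10


@dataclass
class CoexpressionGraph:
    """Unsigned weighted co-expression graph over (gene, tissue) nodes."""

    nodes: list[tuple[str, str]]
    adjacency: np.ndarray
    tom: np.ndarray
    beta: float
    expression: pd.DataFrame | None = None  # nodes x samples, for eigengenes

    def __post_init__(self) -> None:
        m = len(self.nodes)
        for name in ("adjacency", "tom"):
            M = getattr(self, name)
            if M.shape != (m, m):
                raise ValueError(f"{name} shape {M.shape} does not match {m} nodes")
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if M.min() < -1e-12 or M.max() > 1 + 1e-12:
                raise ValueError(f"{name} entries must lie in [0, 1]")

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum of adjacency to all other nodes (self excluded)."""
        return self.adjacency.sum(axis=1) - np.diag(self.adjacency)


@dataclass
class ModuleSet:
    """Disjoint co-expression modules with eigengenes."""

    modules: dict[str, list[tuple[str, str]]]
    eigengenes: pd.DataFrame  # samples x modules, unit variance
    grey: list[tuple[str, str]] = field(default_factory=list)

    def module_of(self, node: tuple[str, str]) -> str:
        for mod, members in self.modules.items():
            if node in members:
                return mod
        return GREY


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an unsigned adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with the u-sum over u != i, j and self-adjacency excluded from
    connectivity; TOM_ii = 1.
    """
    A = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A  # diagonal of A is zero, so u = i, j terms vanish
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def build_graph(
    expr: dict[str, pd.DataFrame] | pd.DataFrame,
    beta: float = DEFAULT_BETA,
    min_shared_samples: int = 20,
) -> CoexpressionGraph:
    """Build the unsigned weighted network |cor|^beta and its TOM.

    ``expr`` is either one genes x samples matrix (single tissue, tissue
    label "") or a mapping tissue -> matrix; multi-tissue matrices are
    concatenated on their shared sample ids, and nodes are (gene, tissue)
    pairs.  Zero-variance genes are excluded with a log message.
    """
    if beta < 1:
        raise ValueError("soft power beta must be >= 1")
    if isinstance(expr, pd.DataFrame):
        expr = {"": expr}
    shared = None
    for df in expr.values():
        cols = set(df.columns)
        shared = cols if shared is None else shared & cols
    shared = sorted(shared)
    if len(shared) < min_shared_samples:
        raise ValueError(f"only {len(shared)} shared samples across tissues; need {min_shared_samples}")
    blocks, nodes = [], []
    for tissue, df in expr.items():
        sub = df[shared]
        sd = sub.std(axis=1, ddof=0)
        dead = sd[sd == 0].index
        if len(dead):
            logger.info("excluding %d zero-variance gene(s) in tissue %r", len(dead), tissue)
            sub = sub.drop(index=dead)
        blocks.append(sub.to_numpy(dtype=float))
        nodes.extend((g, tissue) for g in sub.index)
    X = np.vstack(blocks)
    corr = np.corrcoef(X)
    A = np.abs(corr) ** beta
    np.fill_diagonal(A, 0.0)
    tom = tom_from_adjacency(A)
    expr_df = pd.DataFrame(X, index=pd.MultiIndex.from_tuples(nodes), columns=shared)
    return CoexpressionGraph(nodes=nodes, adjacency=A, tom=tom, beta=beta, expression=expr_df)


def _eigengene(X: np.ndarray) -> np.ndarray:
    """First principal component of standardized member expression.

    Sign-oriented to positive mean correlation with the members; scaled to
    unit variance.
    """
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0, keepdims=True)
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    pc = vt[0]
    cors = (Z @ pc) / (np.linalg.norm(Z, axis=1) * np.linalg.norm(pc))
    if cors.mean() < 0:
        pc = -pc
    return pc / pc.std(ddof=0)


def detect_modules(
    graph: CoexpressionGraph,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters below ``min_size`` go to the grey pool.  Module ids are
    "M1", "M2", ... ordered by decreasing size (ties by first member) so
    the labelling is deterministic.
    """
    if min_size < 3:
        raise ValueError("min_size must be at least 3")
    dissim = 1.0 - graph.tom
    np.fill_diagonal(dissim, 0.0)
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    modules: dict[str, list[tuple[str, str]]] = {}
    grey: list[tuple[str, str]] = []
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    kept = [idx for idx in clusters.values() if len(idx) >= min_size]
    kept.sort(key=lambda idx: (-len(idx), idx[0]))
    for rank, idx in enumerate(kept, start=1):
        modules[f"M{rank}"] = [graph.nodes[i] for i in idx]
    for idx in clusters.values():
        if len(idx) < min_size:
            grey.extend(graph.nodes[i] for i in idx)
    eig = {}
    if graph.expression is not None:
        for mod, members in modules.items():
            X = graph.expression.loc[members].to_numpy(dtype=float)
            eig[mod] = _eigengene(X)
        eigengenes = pd.DataFrame(eig, index=graph.expression.columns)
    else:
        eigengenes = pd.DataFrame(index=pd.Index([], dtype=object))
    return ModuleSet(modules=modules, eigengenes=eigengenes, grey=grey)


def module_trait(modules: ModuleSet, traits: pd.DataFrame, min_samples: int = 10) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait."""
    rows = []
    for mod in modules.eigengenes.columns:
        res = trait_correlation(modules.eigengenes[mod], traits, min_samples=min_samples)
        res.insert(0, "module", mod)
        rows.append(res)
    if not rows:
        return pd.DataFrame(columns=["module", "trait", "r", "statistic", "p", "n", "fdr"])
    return pd.concat(rows, ignore_index=True)


def key_drivers(
    graph: CoexpressionGraph,
    modules: ModuleSet,
    depth: int = 1,
    tau: float | None = None,
    fdr_max: float = 0.05,
    min_neighborhood: int = 5,
) -> pd.DataFrame:
    """Neighborhood-module hypergeometric enrichment ("key driver") analysis.

    The weighted graph is binarized at edge weight >= ``tau`` (default:
    the top 1% of off-diagonal weights).  For each node, the set N_d of
    nodes within ``depth`` steps (excluding the node itself) is tested for
    enrichment of each module's members against the full node universe
    (hypergeometric upper tail), with BH-FDR across nodes within each
    module.  A node is flagged a key driver iff fdr <= ``fdr_max`` and
    |N_d| >= ``min_neighborhood``.
    """
    if depth not in (1, 2):
        raise ValueError("depth must be 1 or 2")
    A = graph.adjacency.copy()
    np.fill_diagonal(A, 0.0)
    if tau is None:
        off = A[np.triu_indices_from(A, k=1)]
        tau = float(np.quantile(off, 0.99))
    B = A >= tau
    np.fill_diagonal(B, False)
    if not B.any():
        raise ValueError("graph is empty after thresholding; lower tau")
    reach = B.copy()
    if depth == 2:
        reach = reach | (B @ B)
        np.fill_diagonal(reach, False)
    m = len(graph.nodes)
    node_index = {node: i for i, node in enumerate(graph.nodes)}
    rows = []
    for mod, members in modules.modules.items():
        member_idx = np.zeros(m, dtype=bool)
        member_idx[[node_index[n] for n in members]] = True
        K = int(member_idx.sum())
        pvals, meta = [], []
        for i in range(m):
            hood = reach[i].copy()
            hood[i] = False
            N = int(hood.sum())
            overlap = int((hood & member_idx).sum())
            p = float(stats.hypergeom.sf(overlap - 1, m, K, N)) if N > 0 else 1.0
            pvals.append(min(max(p, np.nextafter(0.0, 1.0)), 1.0))
            meta.append((graph.nodes[i], N, overlap))
        fdr = bh_fdr(np.asarray(pvals))
        for (node, N, overlap), p, q in zip(meta, pvals, fdr):
            rows.append(
                {
                    "node": node,
                    "module": mod,
                    "neighborhood": N,
                    "overlap": overlap,
                    "p": p,
                    "fdr": q,
                    "key_driver": bool(q <= fdr_max and N >= min_neighborhood),
                }
            )
    return pd.DataFrame(rows)
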