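"""Weighted gene co-expression network analysis (WGCNA-style), from scratch.

Pipeline: keep the genes with the largest expression variability (median
absolute deviation), raise the absolute Pearson correlation to a soft
power to obtain an unsigned adjacency, refine it into the topological
overlap matrix (TOM), cluster 1 - TOM with average-linkage hierarchical
clustering, cut the tree at a fixed height, and summarize each module by
its eigengene (first principal component of the standardized module
expression), which is then correlated with sample-level traits.

Defaults follow common practice for bulk RNA-seq module detection:
soft power 20 on an unsigned network, top 5000 genes by MAD, minimum
module size 30.  The static tree cut (default: the 0.995 quantile of the
merge heights) keeps module detection fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "Network",
    "select_top_mad",
    "soft_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_eigengenes",
    "module_trait_correlation",
]

GREY = "grey"


@dataclass
class Network:
    """Soft-thresholded co-expression network over a fixed gene set."""

    gene_ids: pd.Index
    adjacency: np.ndarray = field(repr=False)
    soft_power: int
    tom: np.ndarray | None = field(default=None, repr=False)

    @property
    def dissimilarity(self) -> np.ndarray:
        if self.tom is None:
            raise ValueError("TOM not computed; call topological_overlap first")
        return 1.0 - self.tom


def select_top_mad(matrix: pd.DataFrame, n: int = 5000) -> pd.DataFrame:
    """Keep the ``n`` genes with the largest median absolute deviation
    across samples; ties broken by gene order, output order preserved."""
    if n > len(matrix):
        raise ValueError(f"requested {n} genes but matrix has {len(matrix)}")
    mad = np.median(np.abs(matrix.to_numpy() - np.median(matrix.to_numpy(), axis=1, keepdims=True)), axis=1)
    order = np.argsort(-mad, kind="stable")[:n]
    keep = np.zeros(len(matrix), dtype=bool)
    keep[order] = True
    return matrix.loc[keep]


def soft_adjacency(matrix: pd.DataFrame, power: int = 20) -> Network:
    """Unsigned soft-threshold adjacency a_ij = |cor(x_i, x_j)|^power.

    Pearson correlation across samples; genes with zero variance get
    correlation 0 to every other gene (with a warning).  Diagonal is 1.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if power < 1:
        raise ValueError("power must be >= 1")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s); their correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor[flat, :] = 0.0
    cor[:, flat] = 0.0
    np.clip(np.abs(cor), 0.0, 1.0, out=cor)
    adj = cor**power
    np.fill_diagonal(adj, 1.0)
    return Network(gene_ids=matrix.index, adjacency=adj, soft_power=power)


def topological_overlap(network: Network) -> Network:
    """Topological overlap matrix of an adjacency.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu and TOM_ii = 1.
    """
    a = network.adjacency
    k = a.sum(axis=1) - np.diag(a)
    # shared-neighbour sums over u excluding u in {i, j}
    l = a @ a - a * np.diag(a)[:, None] - a * np.diag(a)[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    return Network(gene_ids=network.gene_ids, adjacency=a, soft_power=network.soft_power, tom=tom)


def detect_modules(
    dissimilarity: np.ndarray,
    gene_ids: pd.Index | list,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> pd.Series:
    """Average-linkage clustering of a TOM dissimilarity with a static cut.

    Returns a gene -> module-label Series; labels are "M1", "M2", ... in
    decreasing module size, with genes in clusters smaller than
    ``min_module_size`` assigned to "grey".  ``cut_height`` defaults to
    min(0.99, the 0.995 quantile of the merge heights): unrelated genes sit
    near TOM dissimilarity 1, so 0.99 separates any real module, while the
    quantile guard keeps the cut inside the dendrogram for tightly
    correlated data whose merges all happen lower down.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    if cut_height is None:
        cut_height = min(0.99, float(np.quantile(z[:, 2], 0.995)))
    raw = fcluster(z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size]
    # stable ordering: by size desc, then by cluster id for ties
    ordered = sorted(big.index, key=lambda c: (-big[c], c))
    rename = {c: f"M{i + 1}" for i, c in enumerate(ordered)}
    labels = [rename.get(c, GREY) for c in raw]
    return pd.Series(labels, index=pd.Index(gene_ids), name="module")


def module_eigengene(module_expr: pd.DataFrame) -> pd.Series:
    """Eigengene (first PC over samples) of one module's expression.

    Genes are standardized across samples first; the sign is oriented so
    the eigengene correlates positively with the module's mean standardized
    expression.  A single-gene module yields that gene's z-score.
    """
    if len(module_expr) == 0:
        raise ValueError("module is empty")
    x = module_expr.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    if len(module_expr) == 1:
        return pd.Series(z[0], index=module_expr.columns, name="ME")
    # first right singular vector = PC1 across samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    ref = z.mean(axis=0)
    if ref @ eig < 0:
        eig = -eig
    return pd.Series(eig, index=module_expr.columns, name="ME")


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Sample x module eigengene matrix for all non-grey modules."""
    cols = {}
    for label in sorted(labels.unique(), key=lambda s: (len(s), s)):
        if label == GREY:
            continue
        cols[label] = module_eigengene(expr.loc[labels.index[labels == label]])
    return pd.DataFrame(cols, index=expr.columns)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation (and two-sided p) of each eigengene with each
    trait; samples must align.  Constant traits yield r = 0, p = 1."""
    if not eigengenes.index.equals(traits.index):
        raise ValueError("eigengene and trait tables are not aligned on samples")
    r = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    for t in traits.columns:
        y = traits[t].to_numpy(dtype=float)
        if np.std(y) == 0:
            warnings.warn(f"trait {t!r} is constant; correlation undefined, reported as 0")
            r[t], p[t] = 0.0, 1.0
            continue
        for m in eigengenes.columns:
            res = stats.pearsonr(eigengenes[m].to_numpy(dtype=float), y)
            r.loc[m, t], p.loc[m, t] = res.statistic, res.pvalue
    return r, p
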