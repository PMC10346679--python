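"""Hypergeometric over-representation analysis of gene sets.

For a query set of n genes drawn from a universe of N, a term annotating K
genes, and an observed overlap of k, the enrichment p-value is the
upper-tail hypergeometric probability P(X >= k).  P-values are adjusted
across tested terms with Benjamini-Hochberg, and terms with FDR <= 0.05
are called significantly enriched.  Terms annotating fewer than 5 genes
are excluded before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .expression import benjamini_hochberg

__all__ = ["AnnotationMap", "read_gmt", "write_gmt", "hypergeom_enrich", "significant_terms"]


@dataclass
class AnnotationMap:
    """Term -> gene-set annotation with an explicit gene universe."""

    gene_sets: dict[str, set]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.gene_sets.values()) if self.gene_sets else set()
        for term, genes in self.gene_sets.items():
            extra = set(genes) - self.universe
            if extra:
                raise ValueError(f"term {term!r} annotates genes outside the universe: {sorted(extra)[:5]}")


def read_gmt(path) -> AnnotationMap:
    """Read a GMT file (term, description, then tab-separated gene ids)."""
    gene_sets, desc = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            gene_sets[parts[0]] = {g for g in parts[2:] if g}
            desc[parts[0]] = parts[1]
    return AnnotationMap(gene_sets=gene_sets, descriptions=desc)


def write_gmt(annotation: AnnotationMap, path) -> None:
    with open(path, "w") as fh:
        for term, genes in annotation.gene_sets.items():
            desc = annotation.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def hypergeom_enrich(
    query: set,
    annotation: AnnotationMap,
    min_term_size: int = 5,
    universe: set | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of a query set against every term.

    Query genes outside the universe are dropped with a warning.  Returns a
    DataFrame sorted by p-value with columns
    ``term, description, k, K, n, N, p_value, fdr``.
    """
    uni = set(universe) if universe is not None else set(annotation.universe)
    if not uni:
        raise ValueError("empty gene universe")
    q = set(query)
    outside = q - uni
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe dropped")
        q &= uni
    n, big_n = len(q), len(uni)
    rows = []
    for term in sorted(annotation.gene_sets):
        genes = annotation.gene_sets[term] & uni
        big_k = len(genes)
        if big_k < min_term_size:
            continue
        k = len(q & genes)
        rows.append(
            {"term": term, "description": annotation.descriptions.get(term, ""),
             "k": k, "K": big_k, "n": n, "N": big_n,
             "p_value": float(hypergeom.sf(k - 1, big_n, big_k, n))}
        )
    if not q or not rows:
        return pd.DataFrame(columns=["term", "description", "k", "K", "n", "N", "p_value", "fdr"])
    res = pd.DataFrame(rows)
    res["fdr"] = benjamini_hochberg(res["p_value"].to_numpy())
    return res.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)


def significant_terms(results: pd.DataFrame, fdr_max: float = 0.05) -> pd.DataFrame:
    """Terms passing the FDR threshold (inclusive)."""
    if results.empty:
        return results
    return results[results["fdr"] <= fdr_max].reset_index(drop=True)
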