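"""Gene-set over-representation analysis.

Upper-tail hypergeometric test of a query gene list against term -> gene maps
(GO-style namespaces or pathways), with Bonferroni and Benjamini-Hochberg
corrections applied within each namespace.  An optional EASE-style
conservative variant tests ``k - 1`` overlapping genes instead of ``k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetDb", "hypergeom_test", "correct", "gene_ratio", "enrich"]


@dataclass
class GeneSetDb:
    """Term -> gene map with namespace tags and a background universe."""

    terms: Dict[str, FrozenSet[str]]
    namespaces: Dict[str, str]
    universe: FrozenSet[str]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} has genes outside the universe")

    @classmethod
    def from_gene_sets(cls, sets, universe: Iterable[str] | None = None) -> "GeneSetDb":
        """Build from simulator GeneSet records or (term, namespace, genes) tuples."""
        terms, namespaces = {}, {}
        for s in sets:
            term, ns, genes = s.term, s.namespace, s.genes
            terms[term] = frozenset(genes)
            namespaces[term] = ns
        if universe is None:
            universe = frozenset().union(*terms.values()) if terms else frozenset()
        return cls(terms=terms, namespaces=namespaces, universe=frozenset(universe))


def hypergeom_test(
    query: Iterable[str],
    term_genes: Iterable[str],
    universe: Iterable[str],
    ease: bool = False,
) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``k`` is the query/term overlap, drawn from a universe of ``N`` genes of
    which ``K`` carry the term, in ``n`` query draws.  Query genes outside
    the universe are dropped with a warning.  ``ease=True`` computes the
    conservative EASE score, P(X >= k) with one overlapping gene removed.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
        query &= universe
    term = frozenset(term_genes) & universe
    k = len(query & term)
    N, K, n = len(universe), len(term), len(query)
    if ease and k > 0:
        k -= 1
    return float(hypergeom.sf(k - 1, N, K, n))


def correct(pvalues: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Bonferroni and Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([])
    bonf = np.minimum(1.0, p * p.size)
    bh = multipletests(p, method="fdr_bh")[1]
    return bonf, bh


def gene_ratio(k: int, n: int) -> float:
    """Overlap over annotated query size (the 'Gene.ratio' column)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return k / n


def enrich(
    query: Iterable[str],
    db: GeneSetDb,
    ease: bool = False,
) -> pd.DataFrame:
    """Test every term; corrections are applied within each namespace.

    Returns a table sorted by p-value with columns Term, namespace, k, K, n,
    N, gene_ratio, p, bonferroni, bh and the overlapping genes.
    """
    query = set(query) & db.universe
    n = len(query)
    rows = []
    for term, genes in sorted(db.terms.items()):
        overlap = sorted(query & genes)
        k = len(overlap)
        p = hypergeom_test(query, genes, db.universe, ease=ease)
        rows.append(
            dict(
                Term=term,
                namespace=db.namespaces.get(term, ""),
                k=k,
                K=len(genes),
                n=n,
                N=len(db.universe),
                gene_ratio=gene_ratio(k, n) if n else 0.0,
                p=p,
                genes=",".join(overlap),
            )
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["bonferroni"] = np.nan
    df["bh"] = np.nan
    for ns, grp in df.groupby("namespace"):
        bonf, bh = correct(grp["p"].to_numpy())
        df.loc[grp.index, "bonferroni"] = bonf
        df.loc[grp.index, "bh"] = bh
    return df.sort_values(["p", "Term"], ignore_index=True)
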