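"""Weight interpretation: ranking, top gene lists, over-representation tests.

The learned weight vector is the model's explanation of the feature: large
positive oriented weights mark genes whose detection pushes a cell toward
state1, large negative ones mark genes detected preferentially in state0.
Typical use ranks the weights, takes the top 50 per side for enrichment
against a gene-set collection, and the top 250 per side as the up/down
query signature for connectivity drug search.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection, GeneUniverse
from .model import FeatureModel

__all__ = ["rank_weights", "top_weights", "hypergeom_enrich"]


def rank_weights(model: FeatureModel) -> pd.DataFrame:
    """All genes with oriented weights, descending; ties broken by symbol.

    Returns a DataFrame with columns ``gene`` and ``weight`` that is a
    permutation of the model's universe, deterministically ordered.
    """
    wts = model.oriented_weights
    df = pd.DataFrame({"gene": wts.index, "weight": wts.to_numpy()})
    df = df.sort_values(
        ["weight", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def top_weights(
    ranked: pd.DataFrame, n: int = 250, side: str = "both"
) -> list[str] | tuple[list[str], list[str]]:
    """Top-n strictly positive and/or strictly negative weighted genes.

    Genes with weight exactly zero belong to neither side, so either list
    may be shorter than ``n``.  ``side='both'`` returns ``(positive,
    negative)``; the two lists are disjoint by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(ranked):
        warnings.warn(
            f"n={n} exceeds the universe size {len(ranked)}; truncating",
            stacklevel=2,
        )
    pos = ranked.loc[ranked["weight"] > 0, "gene"].head(n).tolist()
    neg_ranked = ranked.loc[ranked["weight"] < 0]
    # most negative first
    neg = neg_ranked.iloc[::-1]["gene"].head(n).tolist()
    if side == "positive":
        return pos
    if side == "negative":
        return neg
    if side == "both":
        return pos, neg
    raise ValueError("side must be 'positive', 'negative' or 'both'")


def hypergeom_enrich(
    query: list[str],
    sets: GeneSetCollection,
    universe: GeneUniverse,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    The background population is the model's gene universe (the input axis
    is the only space the query genes were drawn from).  For each term the
    p-value is ``P(X >= overlap)`` with population ``|universe|``, successes
    ``|set ∩ universe|`` and draws ``|query ∩ universe|``; q-values are
    Benjamini-Hochberg across all tested terms.  Results sorted by p.
    """
    uni = set(universe.symbols)
    dropped = [g for g in query if g not in uni]
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe were dropped",
            stacklevel=2,
        )
    q = [g for g in query if g in uni]
    if not q:
        return pd.DataFrame(
            columns=["term", "set_size", "overlap", "overlap_genes", "p", "q"]
        )
    qset = set(q)
    M, N = len(universe), len(q)
    rows = []
    for term, genes in sets.sets.items():
        in_uni = [g for g in genes if g in uni]
        K = len(in_uni)
        overlap = sorted(qset.intersection(in_uni))
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append(
            {
                "term": term,
                "set_size": K,
                "overlap": k,
                "overlap_genes": ",".join(overlap),
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return df
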