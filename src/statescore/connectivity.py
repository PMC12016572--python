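"""Connectivity-map style drug search against perturbagen signature databases.

A trained model's top positively and negatively weighted genes (default 250
per side) form an up/down query signature.  Each perturbagen in a reference
database is represented by a per-gene signed score (e.g. a moderated
z-statistic of the expression change it induces); the query is compared to
every signature with GSEA-style enrichment statistics:

* weighted connectivity score (WTCS) — the LINCS convention:
  ``(ES_up - ES_down) / 2`` when the two enrichment scores have opposite
  signs, else 0, with score-weighted running sums;
* raw connectivity score — the classic CMap convention: the difference of
  unweighted KS statistics for the up and down sets (zero when they share
  a sign), scaled per search to [-1, 1].

Positive scores mark perturbagens that mimic the state0 -> state1
transition (induction); negative scores mark reversers.  For a detrimental
transition the reversal search — ascending by score — puts candidate
therapeutics first.

The exact formulas follow the published CMap/LINCS connectivity-scoring
literature; the original papers name the scores without printing them.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GeneUniverse
from .errors import StateScoreError, ValidationError
from .model import FeatureModel

__all__ = [
    "QuerySignature",
    "ReferenceSignatureDB",
    "build_query",
    "es_running_sum",
    "wtcs",
    "cmap_raw",
    "search_db",
    "read_reference_db",
    "write_reference_db",
]


@dataclass
class QuerySignature:
    """Disjoint up/down gene lists querying a signature database."""

    up: list[str]
    down: list[str]

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValidationError("up and down query lists must be disjoint")

    @property
    def genes(self) -> set[str]:
        return set(self.up) | set(self.down)


@dataclass
class ReferenceSignatureDB:
    """Perturbagen signatures as per-gene signed scores over one universe.

    ``scores`` is genes x signatures (every signature covers the full
    reference universe); ``meta`` maps each signature column to its
    perturbagen name and cell-type tag.
    """

    ref_universe: GeneUniverse
    scores: pd.DataFrame
    meta: pd.DataFrame
    source: str = "custom"

    def __post_init__(self) -> None:
        if list(self.scores.index) != list(self.ref_universe.symbols):
            raise ValidationError("score rows must equal the reference universe")
        if self.scores.isna().any().any():
            raise ValidationError("every signature must cover the full universe")
        if self.scores.columns.duplicated().any():
            raise ValidationError("signature names must be unique")
        missing = set(self.scores.columns) - set(self.meta.index)
        if missing:
            raise ValidationError(f"signatures without metadata: {sorted(missing)[:5]}")

    @property
    def n_signatures(self) -> int:
        return self.scores.shape[1]


def build_query(model: FeatureModel, n: int = 250) -> QuerySignature:
    """Query signature from the model's top +/-n oriented weights.

    Only strictly positive (negative) weights qualify, so either side may
    hold fewer than ``n`` genes; an empty side is allowed but warned about.
    """
    from .interpret import rank_weights, top_weights

    pos, neg = top_weights(rank_weights(model), n=n, side="both")
    if not pos or not neg:
        warnings.warn(
            "query signature has an empty side (no strictly positive or "
            "negative weights)",
            stacklevel=2,
        )
    return QuerySignature(up=pos, down=neg)


def _ordered_genes(signature: pd.Series) -> pd.Series:
    """Signature sorted by descending score, ties by ascending gene name."""
    df = pd.DataFrame({"gene": signature.index, "score": signature.to_numpy()})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(df["score"].to_numpy(), index=df["gene"].to_numpy())


def es_running_sum(
    signature: pd.Series, gene_set: Sequence[str], weighted: bool = True
) -> float:
    """GSEA-style enrichment score of a gene set in a ranked signature.

    Genes are ordered by descending signed score.  Walking down the list,
    the running sum rises at set members (weighted: proportionally to
    |score|; unweighted: by 1/t) and falls by 1/(G-t) elsewhere; the ES is
    the extremum of largest magnitude, in [-1, 1].  Returns NaN when the
    set does not intersect the signature genes.
    """
    ordered = _ordered_genes(signature)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ordered.index), bool, len(ordered))
    t = int(hit.sum())
    G = len(ordered)
    if t == 0:
        return float("nan")
    if t == G:
        return 1.0
    if weighted:
        absval = np.abs(ordered.to_numpy())
        nr = absval[hit].sum()
        if nr == 0:
            # degenerate all-zero scores for the hits: fall back to equal steps
            inc = np.where(hit, 1.0 / t, 0.0)
        else:
            inc = np.where(hit, absval / nr, 0.0)
    else:
        inc = np.where(hit, 1.0 / t, 0.0)
    dec = np.where(hit, 0.0, 1.0 / (G - t))
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def wtcs(signature: pd.Series, q: QuerySignature) -> float:
    """Weighted connectivity score of a query against one signature.

    ``(ES_up - ES_down)/2`` when the two (weighted) enrichment scores have
    opposite signs, else 0.  If one side of the query does not intersect
    the signature, the score falls back to the single available ES.
    """
    es_up = es_running_sum(signature, q.up, weighted=True) if q.up else float("nan")
    es_down = (
        es_running_sum(signature, q.down, weighted=True) if q.down else float("nan")
    )
    return _combine(es_up, es_down, half=True)


def _combine(es_up: float, es_down: float, half: bool) -> float:
    if np.isnan(es_up) and np.isnan(es_down):
        return float("nan")
    if np.isnan(es_down):
        return float(es_up)
    if np.isnan(es_up):
        return float(-es_down)
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    diff = es_up - es_down
    return float(diff / 2.0) if half else float(diff)


def _cmap_ks(signature: pd.Series, gene_set: Sequence[str]) -> float:
    """Classic unweighted KS statistic of a gene set in a ranked signature.

    With V(j) the 1-based rank of the set's j-th gene (ascending ranks in
    the descending-score ordering), ``a = max_j(j/t - V(j)/G)`` and
    ``b = max_j(V(j)/G - (j-1)/t)``; the statistic is ``a`` if a >= b,
    else ``-b``.
    """
    ordered = _ordered_genes(signature)
    members = set(gene_set)
    positions = np.flatnonzero(
        np.fromiter((g in members for g in ordered.index), bool, len(ordered))
    )
    t = len(positions)
    G = len(ordered)
    if t == 0:
        return float("nan")
    j = np.arange(1, t + 1)
    V = positions + 1.0
    a = float((j / t - V / G).max())
    b = float((V / G - (j - 1) / t).max())
    return a if a >= b else -b


def cmap_raw(signature: pd.Series, q: QuerySignature) -> float:
    """CMap raw connectivity score: ``ks_up - ks_down`` or 0 on same sign."""
    ks_up = _cmap_ks(signature, q.up) if q.up else float("nan")
    ks_down = _cmap_ks(signature, q.down) if q.down else float("nan")
    return _combine(ks_up, ks_down, half=False)


def search_db(
    db: ReferenceSignatureDB,
    q: QuerySignature,
    method: str = "wtcs",
    direction: str = "reverse",
    min_coverage: float = 0.1,
) -> pd.DataFrame:
    """Score and rank every signature in a reference database.

    ``direction='reverse'`` ranks ascending by score (most negative first:
    drugs predicted to counteract the transition), ``'induce'`` descending.
    Refuses to rank when fewer than ``min_coverage`` of the query genes are
    present in the reference universe.  For ``method='raw'`` a per-search
    scaled score (raw divided by the search's extreme positive / negative
    raw) is added.  Ties are broken by perturbagen name, then signature id.
    """
    if method not in ("wtcs", "raw"):
        raise ValueError("method must be 'wtcs' or 'raw'")
    if direction not in ("reverse", "induce"):
        raise ValueError("direction must be 'reverse' or 'induce'")
    if db.n_signatures == 0:
        raise ValidationError("reference database is empty")
    ref = set(db.ref_universe.symbols)
    qgenes = q.genes
    if not qgenes:
        raise ValidationError("query signature is empty")
    covered = qgenes & ref
    coverage = len(covered) / len(qgenes)
    if not covered:
        raise StateScoreError("query covers no gene of the reference database")
    if coverage < min_coverage:
        raise StateScoreError(
            f"query coverage {coverage:.1%} below the {min_coverage:.0%} "
            "threshold; refusing to rank"
        )

    up = [g for g in q.up if g in ref]
    down = [g for g in q.down if g in ref]
    weighted = method == "wtcs"
    rows = []
    for sig_name in db.scores.columns:
        sig = db.scores[sig_name]
        if weighted:
            es_up = es_running_sum(sig, up, weighted=True) if up else float("nan")
            es_down = es_running_sum(sig, down, weighted=True) if down else float("nan")
            score = _combine(es_up, es_down, half=True)
        else:
            es_up = _cmap_ks(sig, up) if up else float("nan")
            es_down = _cmap_ks(sig, down) if down else float("nan")
            score = _combine(es_up, es_down, half=False)
        meta = db.meta.loc[sig_name]
        rows.append(
            {
                "signature": sig_name,
                "perturbagen": meta["perturbagen"],
                "cell_type": meta.get("cell_type", ""),
                "ES_up": es_up,
                "ES_down": es_down,
                "score": score,
                "coverage": coverage,
                "one_sided": bool(np.isnan(es_up) or np.isnan(es_down)),
            }
        )
    df = pd.DataFrame(rows)
    df = df[~df["score"].isna()].copy()
    if df.empty:
        raise StateScoreError("no signature could be scored against the query")

    if method == "raw":
        scaled = np.zeros(len(df))
        pos = df["score"] > 0
        neg = df["score"] < 0
        if pos.any():
            scaled[pos.to_numpy()] = df.loc[pos, "score"] / df.loc[pos, "score"].max()
        if neg.any():
            scaled[neg.to_numpy()] = df.loc[neg, "score"] / abs(
                df.loc[neg, "score"].min()
            )
        df["scaled"] = scaled

    ascending = direction == "reverse"
    df = df.sort_values(
        ["score", "perturbagen", "signature"],
        ascending=[ascending, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


# -- reference database interchange (TSV + sidecar metadata) -----------------


def read_reference_db(
    db_path: str | os.PathLike,
    meta_path: str | os.PathLike | None = None,
    source: str = "custom",
) -> ReferenceSignatureDB:
    """Read a genes x signatures TSV plus a (signature, perturbagen,
    cell_type) sidecar TSV; without a sidecar, perturbagen = signature."""
    scores = pd.read_csv(db_path, sep="\t", index_col=0)
    universe = GeneUniverse(tuple(str(g) for g in scores.index))
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        if "perturbagen" not in meta.columns:
            raise ValidationError("metadata needs a 'perturbagen' column")
        if "cell_type" not in meta.columns:
            meta["cell_type"] = ""
    else:
        meta = pd.DataFrame(
            {"perturbagen": scores.columns, "cell_type": ""}, index=scores.columns
        )
    return ReferenceSignatureDB(
        ref_universe=universe, scores=scores, meta=meta, source=source
    )


def write_reference_db(
    db: ReferenceSignatureDB,
    db_path: str | os.PathLike,
    meta_path: str | os.PathLike | None = None,
) -> None:
    db.scores.to_csv(db_path, sep="\t", index_label="gene")
    if meta_path is not None:
        db.meta.to_csv(meta_path, sep="\t", index_label="signature")
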