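"""Gene-set scoring baselines for benchmarking.

Reimplementations *in the spirit of* three widely used single-cell gene-set
scoring approaches — an AUCell-like recovery-curve AUC, a singscore-like
rank-percentile score, and a Seurat-like module score with bin-matched
control genes.  They reproduce the comparison design (given the same gene
set, how well does each score separate the two states?) but are not
bit-compatible ports of the original tools; hence the ``*_like`` names.

All three operate on the raw count matrix (not the binarized input the
state model consumes).  Expression-rank ties are broken by gene identifier
(the column index after sorting genes by name), which makes every score
deterministic *and* invariant to gene-column permutation of the input —
an index-based tie-break alone would not survive a column shuffle.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ScoreVector
from .errors import ValidationError

__all__ = ["aucell_like", "rank_percentile_score", "module_score"]


def _canonical(expr: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Counts with columns sorted by gene name (the tie-break canon)."""
    order = sorted(range(len(expr.gene_ids)), key=lambda j: expr.gene_ids[j])
    counts = expr.dense().astype(float)[:, order]
    return counts, [expr.gene_ids[j] for j in order]


def _member_mask(gene_ids: Sequence[str], gene_set: Sequence[str]) -> np.ndarray:
    members = set(gene_set)
    return np.fromiter((g in members for g in gene_ids), bool, len(gene_ids))


def aucell_like(
    expr: ExpressionMatrix, gene_set: Sequence[str], top_fraction: float = 0.05
) -> ScoreVector:
    """Recovery-curve AUC of the gene set within each cell's top-ranked genes.

    Per cell, genes are ranked by descending count (ties by gene name);
    the score is the area under the step curve counting set members
    recovered within the top ``ceil(top_fraction * G)`` ranks, divided by
    the maximal possible area, so scores lie in [0, 1]: 1 when all set
    genes occupy the top ranks, 0 when none appear in the top fraction.
    """
    if not (0 < top_fraction < 1):
        raise ValidationError("top_fraction must be in (0, 1)")
    counts, gene_ids = _canonical(expr)
    n, G = counts.shape
    member = _member_mask(gene_ids, gene_set)
    t = int(member.sum())
    if t == 0:
        warnings.warn("gene set has no overlap with the matrix; scores are 0")
        return ScoreVector(list(expr.cell_ids), np.zeros(n), name="aucell_like")
    k = math.ceil(top_fraction * G)
    # stable argsort of -counts: descending counts, ties by gene name
    order = np.argsort(-counts, axis=1, kind="stable")
    hits = member[order[:, :k]]
    running = np.cumsum(hits, axis=1)
    area = running.sum(axis=1).astype(float)
    max_area = float(sum(min(j, t) for j in range(1, k + 1)))
    return ScoreVector(list(expr.cell_ids), area / max_area, name="aucell_like")


def _ascending_ranks(counts: np.ndarray) -> np.ndarray:
    """Per-cell ranks 1..G of ascending count, ties by column position
    (columns are already in canonical gene-name order)."""
    order = np.argsort(counts, axis=1, kind="stable")
    ranks = np.empty_like(order)
    n, G = counts.shape
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, G + 1)[None, :]
    return ranks


def rank_percentile_score(
    expr: ExpressionMatrix,
    up: Sequence[str],
    down: Sequence[str] | None = None,
) -> ScoreVector:
    """Mean centered rank percentile of up genes, minus that of down genes.

    Each gene's centered percentile is ``(rank - (G+1)/2) / (G-1)`` with
    ascending count ranks, so it spans [-0.5, 0.5].  The score is the mean
    over up genes minus (when given) the mean over down genes; identical up
    and down lists therefore cancel to exactly zero.
    """
    if not up:
        raise ValidationError("up gene list must be non-empty")
    counts, gene_ids = _canonical(expr)
    n, G = counts.shape
    up_mask = _member_mask(gene_ids, up)
    if not up_mask.any():
        warnings.warn("up set has no overlap with the matrix; scores are 0")
        return ScoreVector(list(expr.cell_ids), np.zeros(n), name="singscore_like")
    ranks = _ascending_ranks(counts)
    centered = (ranks - (G + 1) / 2.0) / max(G - 1, 1)
    score = centered[:, up_mask].mean(axis=1)
    if down:
        down_mask = _member_mask(gene_ids, down)
        if down_mask.any():
            score = score - centered[:, down_mask].mean(axis=1)
    return ScoreVector(list(expr.cell_ids), score, name="singscore_like")


def module_score(
    expr: ExpressionMatrix,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ScoreVector:
    """Set mean expression minus a bin-matched control mean, per cell.

    Genes are binned into ``n_bins`` equal-frequency bins of dataset-mean
    expression; each set gene contributes up to ``n_ctrl`` control genes
    sampled (seeded, without replacement) from its own bin, so the control
    matches the set's expression-level profile.  Scores are centered near
    zero for sets with no state information.
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ValidationError("n_bins and n_ctrl must be >= 1")
    counts, gene_ids = _canonical(expr)
    n, G = counts.shape
    member = _member_mask(gene_ids, gene_set)
    if len(set(gene_set)) > G:
        raise ValidationError("gene set larger than the gene universe")
    if not member.any():
        warnings.warn("gene set has no overlap with the matrix; scores are 0")
        return ScoreVector(list(expr.cell_ids), np.zeros(n), name="module_score")

    gene_means = counts.mean(axis=0)
    # equal-frequency binning; duplicate edges collapse for degenerate data
    bins = pd.qcut(
        pd.Series(gene_means).rank(method="first"),
        q=min(n_bins, G),
        labels=False,
        duplicates="drop",
    ).to_numpy()

    rng = np.random.default_rng(seed)
    ctrl_cols: list[np.ndarray] = []
    for j in np.flatnonzero(member):
        pool = np.flatnonzero(bins == bins[j])
        size = min(n_ctrl, len(pool))
        ctrl_cols.append(rng.choice(pool, size=size, replace=False))
    ctrl = np.concatenate(ctrl_cols)
    score = counts[:, member].mean(axis=1) - counts[:, ctrl].mean(axis=1)
    return ScoreVector(list(expr.cell_ids), score, name="module_score")
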