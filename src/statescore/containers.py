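"""Core in-memory containers.

The input axis of every model is a :class:`GeneUniverse` — a fixed, ordered
list of gene symbols.  Raw digital-expression matrices are aligned onto that
axis and reduced to presence/absence (:class:`BinaryMatrix`) before any
modelling; the binary entry ``g[cell, i]`` records whether gene ``i`` of the
universe was detected (count above a threshold, default > 0) in that cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ValidationError


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered, unique list of gene symbols defining the model's input axis.

    The position of a symbol in ``symbols`` is the input-node index of the
    scoring sum; reordering the universe reorders the weight vector of any
    model built on it.  Comparison of symbols is exact (no case folding, no
    alias mapping).
    """

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValidationError("gene universe must contain at least one symbol")
        _check_unique(self.symbols, "gene symbols in universe")
        object.__setattr__(self, "symbols", tuple(self.symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def index(self) -> dict[str, int]:
        """Symbol -> position lookup."""
        return {s: i for i, s in enumerate(self.symbols)}

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneUniverse) and self.symbols == other.symbols


@dataclass
class ExpressionMatrix:
    """Cells x genes digital expression (UMI count) matrix.

    ``counts`` may be dense or scipy-sparse; entries must be non-negative.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: "np.ndarray | sparse.spmatrix"

    def __post_init__(self) -> None:
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        n, g = self.counts.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        mn = self.counts.min() if not sparse.issparse(self.counts) else (
            self.counts.data.min() if self.counts.nnz else 0
        )
        if mn < 0:
            raise ValidationError("expression counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.cell_ids, columns=self.gene_ids)


@dataclass
class BinaryMatrix:
    """Cells x universe presence/absence matrix (the model input).

    Column order equals the universe order.  ``universe_coverage`` is the
    fraction of universe genes that were present in the source expression
    matrix; ``constant_warning`` flags an empty intersection, in which case
    every downstream score degenerates to the model bias.
    """

    cell_ids: list[str]
    universe: GeneUniverse
    g: np.ndarray
    universe_coverage: float = 1.0
    constant_warning: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.cell_ids, "cell ids")
        self.g = np.asarray(self.g)
        if self.g.shape != (len(self.cell_ids), len(self.universe)):
            raise ValidationError(
                f"binary matrix shape {self.g.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.universe)} universe genes"
            )
        if not np.isin(self.g, (0, 1)).all():
            raise ValidationError("binary matrix entries must all be 0 or 1")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.g, index=self.cell_ids, columns=list(self.universe.symbols)
        )


@dataclass
class LabeledDataset:
    """A binary matrix plus one {0,1} state label per cell.

    By convention state1 is the feature-positive pole (e.g. exhausted,
    mesenchymal, hypoxic); trained models orient their score so state1 cells
    score high.
    """

    matrix: BinaryMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.matrix.n_cells,):
            raise ValidationError("need exactly one label per cell")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0 (state0) or 1 (state1)")

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells

    def class_counts(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())


@dataclass
class GeneSetCollection:
    """Named gene sets (a GMT file in memory)."""

    sets: Mapping[str, tuple[str, ...]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            _check_unique(genes, f"genes in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return tuple(self.sets[name])


@dataclass
class ScoreVector:
    """One real-valued score per cell, tagged with the producing method."""

    cell_ids: list[str]
    values: np.ndarray
    name: str = "score"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids),):
            raise ValidationError("need exactly one score per cell")
        if not np.isfinite(self.values).all():
            raise ValidationError("scores must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.cell_ids, name=self.name)

    def __len__(self) -> int:
        return len(self.cell_ids)


def align_and_binarize(
    expr: ExpressionMatrix, universe: GeneUniverse, threshold: float = 0.0
) -> BinaryMatrix:
    """Align an expression matrix onto a gene universe as presence/absence.

    Column ``i`` of the result is 1 where gene ``universe[i]`` has count
    strictly greater than ``threshold`` in that cell.  Universe genes missing
    from ``expr`` become all-zero columns; expression genes outside the
    universe are ignored.  An empty gene intersection produces an all-zero
    matrix carrying ``constant_warning=True`` (scores of any model applied to
    it are constant at the bias) plus a runtime warning.
    """
    pos = {gid: j for j, gid in enumerate(expr.gene_ids)}
    src = [pos.get(s, -1) for s in universe.symbols]
    src_arr = np.asarray(src)
    hit = src_arr >= 0
    coverage = float(hit.mean())

    n = len(expr.cell_ids)
    g = np.zeros((n, len(universe)), dtype=np.uint8)
    if hit.any():
        cols = src_arr[hit]
        if sparse.issparse(expr.counts):
            sub = expr.counts.tocsc()[:, cols]
            g[:, hit] = (sub > threshold).toarray().astype(np.uint8)
        else:
            g[:, hit] = (np.asarray(expr.counts)[:, cols] > threshold).astype(np.uint8)

    constant = not hit.any()
    if constant:
        warnings.warn(
            "no overlap between expression genes and the gene universe; "
            "scores will be constant at the model bias",
            stacklevel=2,
        )
    return BinaryMatrix(
        cell_ids=list(expr.cell_ids),
        universe=universe,
        g=g,
        universe_coverage=coverage,
        constant_warning=constant,
    )
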