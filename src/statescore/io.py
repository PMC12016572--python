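"""Readers and writers for the external formats the tool touches.

Supported inputs: 10x Genomics MatrixMarket triplet directories (v2
``genes.tsv`` and v3 ``features.tsv`` dialects, plain or gzipped), dense
TSV/CSV count tables, plain-text gene-universe lists, and GMT gene-set
collections.  Model files are versioned JSON, written by
:mod:`statescore.model`.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    GeneUniverse,
)
from .errors import FormatError, ValidationError

__all__ = [
    "read_mtx_dir",
    "write_mtx_dir",
    "read_dense",
    "read_gene_universe",
    "write_gene_universe",
    "read_gmt",
    "write_gmt",
    "read_labels",
    "write_labels",
]


def _find(path: Path, stems: Sequence[str]) -> Path | None:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = path / name
            if p.exists():
                return p
    return None


def _open_text(p: Path):
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p, "rt")


def read_mtx_dir(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a 10x-style MTX triplet directory as a cells x genes matrix.

    Expects ``matrix.mtx``, ``barcodes.tsv`` and either ``features.tsv``
    (3-column) or ``genes.tsv`` (2-column), each optionally gzipped.  Gene
    identifiers are taken from the symbol column (column 2).  The on-disk
    orientation (genes x cells, the 10x convention, or cells x genes) is
    resolved against the companion file lengths.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"not a directory: {path}")
    mtx = _find(path, ["matrix.mtx"])
    if mtx is None:
        raise FormatError(f"missing matrix.mtx[.gz] in {path}")
    barcodes_f = _find(path, ["barcodes.tsv"])
    if barcodes_f is None:
        raise FormatError(f"missing barcodes.tsv[.gz] in {path}")
    feats_f = _find(path, ["features.tsv", "genes.tsv"])
    if feats_f is None:
        raise FormatError(f"missing features.tsv[.gz] or genes.tsv[.gz] in {path}")

    with _open_text(mtx) as fh:
        try:
            m = spio.mmread(_io.StringIO(fh.read()))
        except Exception as e:  # malformed MatrixMarket
            raise FormatError(f"cannot parse MatrixMarket file {mtx}: {e}") from e
    m = sparse.csr_matrix(m)

    with _open_text(barcodes_f) as fh:
        barcodes = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
    with _open_text(feats_f) as fh:
        rows = [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]
    # v3 features.tsv: id, symbol, type; v2 genes.tsv: id, symbol.
    symbols = [r[1] if len(r) >= 2 else r[0] for r in rows]

    ng, nc = len(symbols), len(barcodes)
    if m.shape == (ng, nc):
        counts = m.T.tocsr()
    elif m.shape == (nc, ng):
        counts = m
    else:
        raise FormatError(
            f"matrix dimensions {m.shape} match neither genes x cells "
            f"({ng} x {nc}) nor cells x genes ({nc} x {ng})"
        )
    return ExpressionMatrix(cell_ids=barcodes, gene_ids=symbols, counts=counts)


def write_mtx_dir(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write an expression matrix as a 10x v2 triplet (genes x cells on disk)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    m = sparse.coo_matrix(expr.counts).T  # genes x cells, 10x convention
    spio.mmwrite(str(path / "matrix.mtx"), m, field="integer")
    (path / "barcodes.tsv").write_text("".join(c + "\n" for c in expr.cell_ids))
    (path / "genes.tsv").write_text(
        "".join(f"{g}\t{g}\n" for g in expr.gene_ids)
    )


def read_dense(
    path: str | os.PathLike,
    cells_in: str = "rows",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a dense count table (header row + id column) as cells x genes.

    ``cells_in`` says whether cells are the table's rows or columns; the
    result is always oriented cells x genes.  Delimiter defaults to tab for
    ``.tsv``/``.txt`` and comma for ``.csv``.
    """
    path = Path(path)
    if cells_in not in ("rows", "columns"):
        raise ValueError("cells_in must be 'rows' or 'columns'")
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.ParserError as e:
        raise FormatError(f"malformed table {path}: {e}") from e
    if df.isna().any().any():
        raise FormatError(f"table {path} is ragged or contains missing values")
    if cells_in == "columns":
        df = df.T
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise FormatError(f"table {path} contains non-numeric entries")
    if (vals < 0).any():
        raise ValidationError(f"table {path} contains negative counts")
    return ExpressionMatrix(
        cell_ids=[str(c) for c in df.index],
        gene_ids=[str(g) for g in df.columns],
        counts=vals,
    )


def read_gene_universe(path: str | os.PathLike) -> GeneUniverse:
    """Read a plain-text gene universe (one symbol per line, blanks dropped)."""
    with open(path) as fh:
        symbols = [ln.strip() for ln in fh]
    symbols = [s for s in symbols if s]
    seen: set[str] = set()
    dups = sorted({s for s in symbols if s in seen or seen.add(s)})
    if dups:
        raise ValidationError(f"duplicate symbols in gene universe {path}: {dups}")
    return GeneUniverse(tuple(symbols))


def write_gene_universe(universe: GeneUniverse, path: str | os.PathLike) -> None:
    Path(path).write_text("".join(s + "\n" for s in universe.symbols))


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: name, description, then genes, tab-separated.

    Duplicate genes within a line are dropped (first occurrence kept).
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name, desc = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = tuple(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_labels(path: str | os.PathLike) -> pd.Series:
    """Read a two-column TSV (cell_id, label in {0,1}) as a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"label file {path} needs cell_id and label columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    if not np.isin(s.to_numpy(), (0, 1)).all():
        raise ValidationError(f"labels in {path} must be 0 or 1")
    return s.astype(int)


def write_labels(labels: pd.Series, path: str | os.PathLike) -> None:
    pd.DataFrame({"cell_id": labels.index, "label": labels.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )
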