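"""Count-matrix container, 10x-style MTX triplet IO, cell QC and normalization.

QC follows the three-criterion rule used for droplet scRNA-seq screening:
cells with low total UMI counts, low detected genes, or a high fraction of
counts on an apoptotic gene panel are excluded before clustering.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import CONDITIONS

MTX_NAME = "matrix.mtx"
FEATURES_NAME = "features.tsv"
BARCODES_NAME = "barcodes.tsv"


class MatrixFormatError(ValueError):
    """Raised for malformed or inconsistent MTX triplets."""


class QCError(ValueError):
    """Raised when quality control empties a matrix."""


@dataclass
class CountMatrix:
    """Raw UMI counts, cells x genes, tagged by condition."""

    counts: sp.csr_matrix            # cells x genes, integer
    cell_ids: list[str]
    gene_symbols: list[str]
    condition: str

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids):
            raise MatrixFormatError(
                f"{n_cells} matrix rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_symbols):
            raise MatrixFormatError(
                f"{n_genes} matrix columns but {len(self.gene_symbols)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise MatrixFormatError("duplicate cell ids")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise MatrixFormatError("duplicate gene symbols")
        if self.condition not in CONDITIONS:
            raise MatrixFormatError(f"unknown condition {self.condition!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise MatrixFormatError("negative counts")
        if not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise MatrixFormatError("non-integer counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_symbols)}

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def detected_genes(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask, dtype=bool)
        return CountMatrix(
            counts=self.counts[mask],
            cell_ids=[c for c, keep in zip(self.cell_ids, mask) if keep],
            gene_symbols=list(self.gene_symbols),
            condition=self.condition,
        )


@dataclass
class QCReport:
    """Per-cell QC metrics and pass flags for one input matrix."""

    table: pd.DataFrame              # cell_id, total_counts, detected_genes,
                                     # apoptotic_fraction, pass
    min_counts: int
    min_genes: int
    max_apoptotic: float
    apoptotic_panel: list[str]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class NormalizedMatrix:
    """log1p library-size-normalized expression with its metadata.

    ``expr[c, g] = log(1 + scale * counts[c, g] / total_counts[c])``,
    natural log.  ``linear()`` inverts the log, returning counts-per-``scale``
    values, the unit in which cluster average expression is conventionally
    printed.
    """

    expr: sp.csr_matrix
    cell_ids: list[str]
    gene_symbols: list[str]
    condition: str
    scale: float = 1e4
    log_base: str = "e"
    pseudocount: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_symbols)}

    def linear(self) -> sp.csr_matrix:
        out = self.expr.copy()
        out.data = np.expm1(out.data)
        return out

    def dense(self) -> np.ndarray:
        return np.asarray(self.expr.todense())


# --------------------------------------------------------------------- IO

def write_count_matrix(m: CountMatrix, outdir) -> None:
    """Write the 10x-style triplet (genes x cells MatrixMarket + TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(m.counts.T).astype(np.int64)
    # mmwrite via an in-memory buffer so the field type is integer and the
    # output is byte-stable across scipy minor versions
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, mat, field="integer")
    (outdir / MTX_NAME).write_bytes(buf.getvalue())
    (outdir / FEATURES_NAME).write_text("".join(f"{g}\n" for g in m.gene_symbols))
    (outdir / BARCODES_NAME).write_text("".join(f"{c}\n" for c in m.cell_ids))


def read_count_matrix(path, condition: str) -> CountMatrix:
    """Read an MTX triplet directory into a validated :class:`CountMatrix`.

    The on-disk matrix is genes x cells (10x convention) and is transposed
    to cells x genes in memory.
    """
    path = Path(path)
    for name in (MTX_NAME, FEATURES_NAME, BARCODES_NAME):
        if not (path / name).exists():
            raise MatrixFormatError(f"missing {name} in {path}")
    mat = scipy.io.mmread(path / MTX_NAME)
    genes = (path / FEATURES_NAME).read_text().splitlines()
    genes = [g.split("\t")[0] for g in genes if g]
    cells = [c for c in (path / BARCODES_NAME).read_text().splitlines() if c]
    if mat.shape != (len(genes), len(cells)):
        raise MatrixFormatError(
            f"matrix is {mat.shape} but triplet lists {len(genes)} genes "
            f"and {len(cells)} cells"
        )
    if len(cells) == 0:
        raise MatrixFormatError("no cells in triplet")
    if len(set(genes)) != len(genes):
        # de-duplicate by suffixing, as droplet pipelines do
        seen: dict[str, int] = {}
        out = []
        for g in genes:
            if g in seen:
                seen[g] += 1
                out.append(f"{g}.{seen[g]}")
            else:
                seen[g] = 0
                out.append(g)
        genes = out
    return CountMatrix(
        counts=sp.csr_matrix(mat.T),
        cell_ids=cells,
        gene_symbols=genes,
        condition=condition,
    )


# --------------------------------------------------------------------- QC

def qc_metrics(
    m: CountMatrix, apoptotic_panel: Iterable[str]
) -> pd.DataFrame:
    """Per-cell totals, detected genes and apoptotic-panel count fraction."""
    idx = m.gene_index()
    panel_cols = [idx[g] for g in apoptotic_panel if g in idx]
    totals = m.total_counts().astype(float)
    detected = m.detected_genes()
    if panel_cols:
        apo = np.asarray(m.counts[:, panel_cols].sum(axis=1)).ravel()
    else:
        apo = np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, apo / np.maximum(totals, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "total_counts": totals.astype(int),
            "detected_genes": detected,
            "apoptotic_fraction": frac,
        }
    )


def qc_filter(
    m: CountMatrix,
    min_counts: int = 500,
    min_genes: int = 200,
    apoptotic_panel: Optional[Iterable[str]] = None,
    max_apoptotic: float = 0.10,
) -> tuple[CountMatrix, QCReport]:
    """Drop cells failing any of the three QC criteria.

    A cell passes iff total_counts >= min_counts AND detected_genes >=
    min_genes AND apoptotic_fraction <= max_apoptotic.  Cell order is
    preserved; the report covers every input cell.
    """
    if min_counts < 0 or min_genes < 0 or max_apoptotic < 0:
        raise ValueError("QC thresholds must be non-negative")
    panel = list(apoptotic_panel) if apoptotic_panel is not None else []
    table = qc_metrics(m, panel)
    passed = (
        (table["total_counts"] >= min_counts)
        & (table["detected_genes"] >= min_genes)
        & (table["apoptotic_fraction"] <= max_apoptotic)
    )
    table = table.assign(**{"pass": passed})
    report = QCReport(
        table=table,
        min_counts=min_counts,
        min_genes=min_genes,
        max_apoptotic=max_apoptotic,
        apoptotic_panel=panel,
    )
    if not passed.any():
        raise QCError("empty after QC: no cell passed the thresholds")
    return m.subset_cells(passed.to_numpy()), report


def filter_genes(m: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Drop genes detected in fewer than ``min_cells`` cells."""
    if min_cells <= 0:
        return m
    per_gene = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    keep = per_gene >= min_cells
    return CountMatrix(
        counts=sp.csr_matrix(m.counts[:, keep]),
        cell_ids=list(m.cell_ids),
        gene_symbols=[g for g, k in zip(m.gene_symbols, keep) if k],
        condition=m.condition,
    )


# ------------------------------------------------------------ normalization

def normalize(
    m: CountMatrix, scale: float = 1e4, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Library-size normalize to ``scale`` counts per cell and log-transform.

    expr[c, g] = log(pseudocount + scale * counts[c, g] / total_counts[c]),
    natural log.  Requires every cell to have at least one count.
    """
    if scale <= 0 or pseudocount <= 0:
        raise ValueError("scale and pseudocount must be positive")
    totals = m.total_counts().astype(float)
    if (totals == 0).any():
        bad = [m.cell_ids[i] for i in np.flatnonzero(totals == 0)][:5]
        raise QCError(f"cells with zero total counts (e.g. {bad}); run QC first")
    expr = sp.csr_matrix(m.counts, dtype=np.float64, copy=True)
    row_scale = scale / totals
    expr = sp.diags(row_scale) @ expr
    expr = sp.csr_matrix(expr)
    if pseudocount == 1.0:
        expr.data = np.log1p(expr.data)
    else:
        # keeps expr = 0 exactly where counts = 0
        expr.data = np.log(pseudocount + expr.data) - np.log(pseudocount)
    return NormalizedMatrix(
        expr=expr,
        cell_ids=list(m.cell_ids),
        gene_symbols=list(m.gene_symbols),
        condition=m.condition,
        scale=scale,
        log_base="e",
        pseudocount=pseudocount,
    )
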