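"""Containers, loaders and preprocessing for cell × gene expression data.

The package works on three layers of the same matrix: raw UMI ``counts``,
library-size-scaled ``lognorm`` values (ln(1 + CPX)), and optionally
z-``scaled`` values.  :class:`ExpressionMatrix` carries the layer tag so
downstream stages can assert they receive the layer they expect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

_log = logging.getLogger("ribostate.datamodel")

LAYERS = ("counts", "lognorm", "scaled")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A cells × genes numeric matrix with identifiers and a layer tag.

    ``values`` may be dense (ndarray) or any scipy sparse matrix; it is
    normalised to CSR on construction when sparse.  Counts layers must be
    non-negative and integer-valued.
    """

    values: object
    cell_ids: Sequence[str]
    gene_ids: Sequence[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
        else:
            self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        if self.layer_tag not in LAYERS:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        n, g = self.values.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells / {len(self.gene_ids)} genes"
            )
        for kind, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique()
                raise ValueError(
                    f"duplicate {kind} identifiers: {list(dupes[:5])}"
                )
        data = self.values.data if sp.issparse(self.values) else self.values
        if data.size and np.min(data) < 0 and self.layer_tag != "scaled":
            raise ValueError(f"negative entries in {self.layer_tag} layer")
        if self.layer_tag == "counts" and data.size:
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts layer must be integer-valued")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Return the values as a dense float array (copy if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        idx = _as_index(mask_or_ids, self.cell_ids)
        return replace(
            self,
            values=self.values[idx, :],
            cell_ids=[self.cell_ids[i] for i in idx],
        )

    def subset_genes(self, mask_or_ids) -> "ExpressionMatrix":
        idx = _as_index(mask_or_ids, self.gene_ids)
        return replace(
            self,
            values=self.values[:, idx],
            gene_ids=[self.gene_ids[i] for i in idx],
        )


def _as_index(mask_or_ids, ids: Sequence[str]) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    if arr.dtype.kind in "iu":
        return arr
    lookup = {v: i for i, v in enumerate(ids)}
    return np.array([lookup[v] for v in arr], dtype=int)


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene identifiers."""

    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class QCConfig:
    """Cell-level quality-control thresholds.

    ``min_genes_per_cell`` removes cells with strictly fewer detected
    genes; the remaining criteria keep cells inclusively within bounds.
    Only the 200-gene rule reflects a stated protocol value; the rest are
    conventional defaults, exposed here so they are auditable.
    """

    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.2
    min_counts: int | None = None
    max_counts: int | None = None
    complexity_min: float | None = None

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if (
            self.min_counts is not None
            and self.max_counts is not None
            and self.min_counts >= self.max_counts
        ):
            raise ValueError("min_counts must be < max_counts")


def validate_cell_meta(meta: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Validate a cell-metadata table (cell_id, sample_id, optional labels)."""
    for col in ("cell_id", "sample_id"):
        if col not in meta.columns:
            raise ValueError(f"cell metadata lacks required column {col!r}")
    if meta["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id in metadata")
    if (meta["sample_id"].astype(str).str.len() == 0).any():
        raise ValueError("empty sample_id in metadata")
    if matrix is not None and set(meta["cell_id"]) != set(matrix.cell_ids):
        raise ValueError("metadata cell set does not match matrix cells")
    return meta


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

def load_counts(path, format: str = "mtx_dir", cells_as: str = "rows") -> ExpressionMatrix:
    """Load a counts matrix from a Matrix Market directory or a CSV file.

    An ``mtx_dir`` follows the 10x convention: ``matrix.mtx`` stores genes
    (features) as rows and cells (barcodes) as columns, with ``barcodes.tsv``
    and ``features.tsv`` sidecars.  For CSV, ``cells_as`` says whether cells
    are the rows or the columns of the file.
    """
    path = Path(path)
    if format == "mtx_dir":
        mtx = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
        for f in (mtx, barcodes, features):
            if not f.exists():
                raise FileNotFoundError(f"missing sidecar file {f}")
        m = sp.csr_matrix(scipy.io.mmread(mtx))
        cells = pd.read_csv(barcodes, header=None, sep="\t")[0].astype(str).tolist()
        genes = pd.read_csv(features, header=None, sep="\t")[0].astype(str).tolist()
        if m.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {m.shape} does not match {len(genes)} features "
                f"x {len(cells)} barcodes"
            )
        return ExpressionMatrix(m.T, cells, genes, layer_tag="counts")
    if format == "csv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
        dups = sorted({h for h in header if header.count(h) > 1})
        if dups:
            raise ValueError(f"duplicate identifiers in CSV header: {dups}")
        df = pd.read_csv(path, index_col=0)
        if cells_as == "cols":
            df = df.T
        elif cells_as != "rows":
            raise ValueError("cells_as must be 'rows' or 'cols'")
        return ExpressionMatrix(
            sp.csr_matrix(df.to_numpy(dtype=float)),
            df.index.astype(str),
            df.columns.astype(str),
            layer_tag="counts",
        )
    raise ValueError(f"unknown format {format!r}")


def save_counts(m: ExpressionMatrix, path, format: str = "mtx_dir") -> None:
    """Write a counts matrix in the same formats :func:`load_counts` reads."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        vals = m.values if sp.issparse(m.values) else sp.csr_matrix(m.values)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(vals.T).astype(int), field="integer")
        pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", index=False, header=False)
        pd.Series(m.gene_ids).to_csv(path / "features.tsv", index=False, header=False)
    elif format == "csv":
        pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.gene_ids).to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gene_sets(path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then >=1 tab-separated genes."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 gene ({len(fields)} fields found)"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if len(set(genes)) != len(genes):
                _log.warning("gene set %r contains duplicate genes; deduplicated", name)
            sets.append(GeneSet(name, frozenset(genes)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter_cells(
    m: ExpressionMatrix,
    qc: QCConfig | None = None,
    mito_prefix: tuple[str, ...] = ("MT-", "mt-"),
) -> tuple[ExpressionMatrix, dict]:
    """Remove low-quality cells from a counts matrix.

    Returns the filtered matrix (gene set unchanged) and a report mapping
    each criterion to the number of cells it failed (a cell may fail
    several).  Cells with strictly fewer than ``min_genes_per_cell``
    detected genes are removed; all other thresholds are inclusive-keep.
    """
    qc = qc or QCConfig()
    if m.layer_tag != "counts":
        raise ValueError("qc_filter_cells expects the counts layer")
    vals = m.values if sp.issparse(m.values) else sp.csr_matrix(m.values)
    n_genes_detected = np.asarray((vals > 0).sum(axis=1)).ravel()
    total_counts = np.asarray(vals.sum(axis=1)).ravel()
    mito_mask = np.array(
        [any(g.startswith(p) for p in mito_prefix) for g in m.gene_ids], dtype=bool
    )
    mito_counts = (
        np.asarray(vals[:, mito_mask].sum(axis=1)).ravel()
        if mito_mask.any()
        else np.zeros(m.n_cells)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(total_counts > 0, mito_counts / np.maximum(total_counts, 1), 1.0)
        complexity = np.where(
            (total_counts > 1) & (n_genes_detected > 0),
            np.log10(np.maximum(n_genes_detected, 1)) / np.log10(np.maximum(total_counts, 2)),
            0.0,
        )

    fails: dict[str, np.ndarray] = {}
    fails["min_genes_per_cell"] = n_genes_detected < qc.min_genes_per_cell
    fails["max_mito_fraction"] = mito_frac > qc.max_mito_fraction
    if qc.min_counts is not None:
        fails["min_counts"] = total_counts < qc.min_counts
    if qc.max_counts is not None:
        fails["max_counts"] = total_counts > qc.max_counts
    if qc.complexity_min is not None:
        fails["complexity_min"] = complexity < qc.complexity_min

    any_fail = np.zeros(m.n_cells, dtype=bool)
    report: dict = {"n_cells_before": m.n_cells}
    for crit, mask in fails.items():
        report[f"removed_{crit}"] = int(mask.sum())
        any_fail |= mask
    keep = ~any_fail
    if not keep.any():
        raise ValueError("QC removed every cell; thresholds are inconsistent with the data")
    report["n_cells_removed"] = int(any_fail.sum())
    report["n_cells_after"] = int(keep.sum())
    _log.info("QC: kept %d / %d cells (%s)", keep.sum(), m.n_cells, report)
    return m.subset_cells(keep), report


def normalize_log1p(m: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size scale each cell to ``scale_factor`` total, then ln(1+x)."""
    if m.layer_tag != "counts":
        raise ValueError("normalize_log1p expects the counts layer")
    totals = np.asarray(m.values.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("cell with zero total counts; run qc_filter_cells first")
    if sp.issparse(m.values):
        vals = sp.csr_matrix(m.values, dtype=float)
        vals = sp.diags(scale_factor / totals) @ vals
        vals.data = np.log1p(vals.data)
    else:
        vals = np.log1p(m.values / totals[:, None] * scale_factor)
    return ExpressionMatrix(vals, m.cell_ids, m.gene_ids, layer_tag="lognorm")


def select_hvgs(m: ExpressionMatrix, n_hvgs: int = 2000, n_bins: int = 20) -> list[str]:
    """Rank genes by mean-binned standardized dispersion of log expression.

    Genes are binned by mean expression; within each bin the dispersion
    (variance/mean) is z-scored so highly expressed genes do not dominate.
    Ties broken by gene id for determinism.
    """
    if n_hvgs <= 0:
        raise ValueError("n_hvgs must be positive")
    if n_hvgs > m.n_genes:
        raise ValueError(f"n_hvgs={n_hvgs} exceeds gene count {m.n_genes}")
    X = m.dense()
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # keep >=5 genes per bin so within-bin z-scores stay meaningful
    n_bins = max(1, min(n_bins, m.n_genes // 5))
    order = np.argsort(mean, kind="stable")
    bins = np.empty(m.n_genes, dtype=int)
    bins[order] = np.arange(m.n_genes) * n_bins // m.n_genes
    z = np.zeros(m.n_genes)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = disp[sel].mean(), disp[sel].std()
        z[sel] = (disp[sel] - mu) / sd if sd > 0 else disp[sel] - mu
    ranked = sorted(range(m.n_genes), key=lambda i: (-z[i], m.gene_ids[i]))
    return [m.gene_ids[i] for i in ranked[:n_hvgs]]


def scale_genes(m: ExpressionMatrix, clip_negative: bool = False) -> ExpressionMatrix:
    """Z-score each gene across cells; optionally clip negatives to 0.

    Centering removes per-gene baseline expression, so downstream
    factorization components capture above-average co-expression rather
    than absolute abundance — standard practice before per-sample NMF
    program discovery.  Constant genes scale to 0.
    """
    X = m.dense()
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd_safe
    if clip_negative:
        Z = np.clip(Z, 0.0, None)
    return ExpressionMatrix(Z, m.cell_ids, m.gene_ids, layer_tag="scaled")


def normalize_and_select_hvgs(
    m: ExpressionMatrix, scale_factor: float = 1e4, n_hvgs: int = 2000
) -> tuple[ExpressionMatrix, list[str]]:
    """Log-normalize a counts matrix and restrict it to highly variable genes."""
    lognorm = normalize_log1p(m, scale_factor)
    hvgs = select_hvgs(lognorm, n_hvgs)
    return lognorm.subset_genes(np.array(hvgs)), hvgs
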