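"""Expression-matrix container, I/O and the preprocessing stage.

The pipeline operates on cells × genes matrices tagged with a ``layer``
(``counts`` → ``lognorm`` → ``scaled``; correction produces ``corrected``).
Normalization is the standard library-size + log1p transform
(``ln(1 + scale_factor * count / total)``), scaling is a per-gene z-score
applied within each batch, and the feature panel is a set of highly
variable genes shared by all batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

Layer = Literal["counts", "lognorm", "scaled", "corrected"]

_LAYERS = ("counts", "lognorm", "scaled", "corrected")


class FormatError(ValueError):
    """Raised when an on-disk matrix is malformed or incomplete."""


class ValidationError(ValueError):
    """Raised when a matrix violates an ExpressionMatrix invariant."""


@dataclass
class ExpressionMatrix:
    """A cells × genes expression matrix with identifiers and a layer tag.

    Parameters
    ----------
    values
        Dense ndarray or scipy sparse matrix, cells in rows.
    cell_ids, gene_ids
        Unique string identifiers for rows / columns.
    batch_ids
        Batch label per cell (one string per row).
    layer
        One of ``counts``, ``lognorm``, ``scaled``, ``corrected``.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    batch_ids: np.ndarray
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.batch_ids = np.asarray(self.batch_ids, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n, g = self.values.shape
        if self.layer not in _LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if len(self.cell_ids) != n:
            raise ValidationError("cell_ids length does not match row count")
        if len(self.gene_ids) != g:
            raise ValidationError("gene_ids length does not match column count")
        if len(self.batch_ids) != n:
            raise ValidationError("batch_ids length does not match row count")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene ids")
        data = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(data)):
            raise ValidationError("values contain NaN/Inf")
        if self.layer == "counts" and data.size and data.min() < 0:
            raise ValidationError("counts layer contains negative values")

    # -- conveniences -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Values as a dense float array (copy only if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.cell_ids.copy(), self.gene_ids.copy(),
            self.batch_ids.copy(), self.layer,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order."""
        idx = pd.Index(self.gene_ids).get_indexer(list(genes))
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise ValidationError(f"genes not present: {missing[:5]}...")
        vals = self.values[:, idx]
        return ExpressionMatrix(vals, self.cell_ids, np.asarray(list(genes), dtype=object),
                                self.batch_ids, self.layer)

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[index], self.cell_ids[index],
                                self.gene_ids, self.batch_ids[index], self.layer)

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (obs: batch; var: gene ids)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.values if sp.issparse(self.values) else np.asarray(self.values, float),
            obs=pd.DataFrame({"batch": pd.Categorical(self.batch_ids)},
                             index=self.cell_ids.astype(str)),
            var=pd.DataFrame(index=self.gene_ids.astype(str)),
        )
        adata.uns["layer"] = self.layer
        return adata


@dataclass(frozen=True)
class GeneSet:
    """An unordered set of gene identifiers (e.g. an HVG panel)."""

    genes: frozenset = field(default_factory=frozenset)

    def __init__(self, genes: Iterable[str] = ()):  # allow any iterable
        object.__setattr__(self, "genes", frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(sorted(self.genes))

    def __contains__(self, g: str) -> bool:
        return g in self.genes

    def intersection(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(self.genes & other.genes)

    def sorted(self) -> list:
        return sorted(self.genes)


def concat(batches: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Stack batches row-wise; all must share an identical gene panel."""
    genes = tuple(batches[0].gene_ids)
    for b in batches[1:]:
        if tuple(b.gene_ids) != genes:
            raise ValidationError("batches have differing gene panels")
    layer = batches[0].layer
    vals = [b.dense() for b in batches]
    return ExpressionMatrix(
        np.vstack(vals),
        np.concatenate([b.cell_ids for b in batches]),
        batches[0].gene_ids,
        np.concatenate([b.batch_ids for b in batches]),
        layer,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_matrix(path: str | Path, format: str = "mtx", *, batch_id: str | None = None,
                transposed: bool = False) -> ExpressionMatrix:
    """Load an expression matrix as a counts-layer :class:`ExpressionMatrix`.

    ``mtx`` expects ``<stem>.mtx`` plus ``genes.tsv`` / ``barcodes.tsv``
    companions in the same directory (barcodes may carry a second batch
    column). ``csv`` expects a dense table with a header row of gene ids and
    an index column of cell ids. ``h5`` expects datasets ``/X``,
    ``/obs/cell_id``, ``/obs/batch``, ``/var/gene_id``.

    Set ``transposed=True`` when the file stores genes × cells.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "mtx":
        m = _load_mtx(path)
    elif format == "csv":
        m = _load_csv(path, batch_id=batch_id)
    elif format == "h5":
        m = _load_h5(path)
    else:
        raise FormatError(f"unknown format {format!r}")
    if transposed:
        m = ExpressionMatrix(m.values.T, m.gene_ids, m.cell_ids,
                             np.repeat(batch_id or path.stem, m.values.shape[1]),
                             m.layer)
    if batch_id is not None:
        m.batch_ids = np.repeat(batch_id, m.n_cells).astype(object)
    return m


def _load_mtx(path: Path) -> ExpressionMatrix:
    genes_file = path.parent / "genes.tsv"
    barcodes_file = path.parent / "barcodes.tsv"
    for f in (genes_file, barcodes_file):
        if not f.exists():
            raise FormatError(f"missing companion file {f.name} next to {path.name}")
    values = sp.csr_matrix(scipy.io.mmread(path))
    genes = pd.read_csv(genes_file, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_file, sep="\t", header=None)
    gene_ids = genes.iloc[:, 0].astype(str).to_numpy()
    cell_ids = barcodes.iloc[:, 0].astype(str).to_numpy()
    if barcodes.shape[1] > 1:
        batch_ids = barcodes.iloc[:, 1].astype(str).to_numpy()
    else:
        batch_ids = np.repeat(path.stem, len(cell_ids))
    try:
        return ExpressionMatrix(values, cell_ids, gene_ids, batch_ids, "counts")
    except ValidationError:
        raise


def _load_csv(path: Path, batch_id: str | None) -> ExpressionMatrix:
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    header = pd.read_csv(path, sep=sep, header=None, nrows=1).iloc[0, 1:]
    if header.duplicated().any():   # pandas would silently mangle these
        raise ValidationError(f"duplicate gene ids in {path.name}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        raise ValidationError(f"duplicate cell ids in {path.name}")
    return ExpressionMatrix(df.to_numpy(dtype=float),
                            df.index.astype(str).to_numpy(),
                            df.columns.astype(str).to_numpy(),
                            np.repeat(batch_id or path.stem, len(df)),
                            "counts")


def _load_h5(path: Path) -> ExpressionMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        for key in ("X", "obs/cell_id", "obs/batch", "var/gene_id"):
            if key not in f:
                raise FormatError(f"dataset /{key} missing from {path.name}")
        X = f["X"][()]
        cell_ids = f["obs/cell_id"].asstr()[()]
        batch_ids = f["obs/batch"].asstr()[()]
        gene_ids = f["var/gene_id"].asstr()[()]
        layer = f.attrs.get("layer", "counts")
    return ExpressionMatrix(np.asarray(X, float), cell_ids, gene_ids, batch_ids,
                            str(layer))


def save_matrix(m: ExpressionMatrix, path: str | Path, format: str = "h5") -> None:
    """Write a matrix in one of the supported formats (see :func:`load_matrix`)."""
    path = Path(path)
    if format == "h5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=m.dense())
            f.create_dataset("obs/cell_id", data=np.asarray(m.cell_ids, dtype="S"))
            f.create_dataset("obs/batch", data=np.asarray(m.batch_ids, dtype="S"))
            f.create_dataset("var/gene_id", data=np.asarray(m.gene_ids, dtype="S"))
            f.attrs["layer"] = m.layer
    elif format == "mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(m.values))
        pd.DataFrame(m.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t",
                                        header=False, index=False)
        pd.DataFrame({"cell": m.cell_ids, "batch": m.batch_ids}).to_csv(
            path.parent / "barcodes.tsv", sep="\t", header=False, index=False)
    elif format == "csv":
        pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.gene_ids).to_csv(path)
    else:
        raise FormatError(f"unknown format {format!r}")


def load_labels(path: str | Path) -> dict:
    """Read a two-column TSV (cell_id, type) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "type"])
    return dict(zip(df["cell_id"].astype(str), df["type"].astype(str)))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def normalize_log(m: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Library-size normalize and log-transform counts.

    Each entry becomes ``ln(1 + scale_factor * count / total_count_of_cell)``,
    the standard log-normalization with a factor of 10,000.
    """
    if m.layer != "counts":
        raise ValidationError(f"normalize_log expects counts layer, got {m.layer!r}")
    X = m.dense()
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = m.cell_ids[totals <= 0]
        raise ValidationError(f"cells with zero total count: {list(bad[:5])}")
    out = np.log1p(scale_factor * X / totals[:, None])
    return ExpressionMatrix(out, m.cell_ids, m.gene_ids, m.batch_ids, "lognorm")


def scale_zscore(m: ExpressionMatrix, per_batch: bool = True) -> ExpressionMatrix:
    """Z-score each gene (population sd); constant genes map to zero columns.

    By default scaling is done within each batch so that per-batch location
    and scale differences do not leak into the embedding.
    """
    if m.layer != "lognorm":
        raise ValidationError(f"scale_zscore expects lognorm layer, got {m.layer!r}")
    X = m.dense().copy()
    groups = pd.unique(m.batch_ids) if per_batch else np.array(["__all__"])
    for b in groups:
        rows = slice(None) if b == "__all__" else np.flatnonzero(m.batch_ids == b)
        sub = X[rows]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)  # ddof=0
        sd_safe = np.where(sd > 0, sd, 1.0)
        Z = (sub - mu) / sd_safe
        Z[:, sd == 0] = 0.0
        X[rows] = Z
    return ExpressionMatrix(X, m.cell_ids, m.gene_ids, m.batch_ids, "scaled")


def _variance_ranks(m: ExpressionMatrix, genes: Sequence[str]) -> np.ndarray:
    """Rank (0 = most variable) of each of `genes` by lognorm variance."""
    sub = m.subset_genes(genes)
    var = sub.dense().var(axis=0)
    # sort by (-variance, gene id) for deterministic ties
    order = sorted(range(len(genes)), key=lambda i: (-var[i], genes[i]))
    ranks = np.empty(len(genes), dtype=int)
    ranks[order] = np.arange(len(genes))
    return ranks


def dispersion_scores(X: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-binned normalized dispersion per gene.

    Dispersion = variance / mean of the de-logged expression; genes are
    binned by mean into `n_bins` quantile bins and the dispersion is
    standardized within its bin (median/MAD-free z-score against bin mean and
    sd, degenerate bins fall back to the raw dispersion rank).
    """
    E = np.expm1(X)
    mean = E.mean(axis=0)
    var = E.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    # quantile bins on the mean
    n_bins = min(n_bins, max(1, len(mean) // 5))
    qs = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    bins = np.searchsorted(qs, mean, side="right") - 1
    out = np.zeros_like(disp)
    for b in np.unique(bins):
        idx = bins == b
        d = disp[idx]
        sd = d.std()
        out[idx] = (d - d.mean()) / sd if sd > 0 else 0.0
    return out


def select_hvg(batches: Sequence[ExpressionMatrix], n_genes: int = 3000,
               method: str = "variance") -> GeneSet:
    """Select highly variable genes shared by all batches.

    ``variance``: genes are ranked by lognorm variance within each batch,
    per-batch ranks are summed and the best ``n_genes`` kept (ties broken by
    gene id). ``dispersion``: ranked by mean-binned normalized dispersion,
    combined the same way.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for b in batches:
        if b.layer != "lognorm":
            raise ValidationError("select_hvg expects lognorm matrices")
    shared = set(batches[0].gene_ids)
    for b in batches[1:]:
        shared &= set(b.gene_ids)
    genes = sorted(shared)
    if n_genes > len(genes):
        warnings.warn(f"n_genes={n_genes} exceeds {len(genes)} shared genes; clamping")
        n_genes = len(genes)
    total_rank = np.zeros(len(genes), dtype=float)
    for b in batches:
        if method == "variance":
            total_rank += _variance_ranks(b, genes)
        elif method == "dispersion":
            scores = dispersion_scores(b.subset_genes(genes).dense())
            order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
            r = np.empty(len(genes), dtype=int)
            r[order] = np.arange(len(genes))
            total_rank += r
        else:
            raise ValueError(f"unknown method {method!r}")
    order = sorted(range(len(genes)), key=lambda i: (total_rank[i], genes[i]))
    return GeneSet(genes[i] for i in order[:n_genes])
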