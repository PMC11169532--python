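"""Domain containers, validation, normalization, and on-disk I/O.

The simulator's universal currency is a labeled expression matrix:
cells (or spots) x genes, non-negative, with one categorical population
label per cell. Three thin containers carry the data between stages:

- :class:`ExpressionDataset` — expression + gene names + population labels
- :class:`SpatialAssignment` — per-cell 2-D/3-D coordinates + labels
- :class:`SpatialReference`  — an annotated spatial dataset used as the
  mapping target in reference-based simulation

On disk, datasets are accepted as dense CSV/TSV matrices, MatrixMarket
triplets with sidecar gene/cell name files, or AnnData ``.h5ad``
containers (expression in ``X``, labels in ``obs["population"]``,
coordinates in ``obsm["spatial"]``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite


@dataclass
class ExpressionDataset:
    """A cells x genes non-negative expression matrix with population labels.

    Parameters
    ----------
    matrix
        Dense ``(n_cells, n_genes)`` float array of (normalized) expression.
    gene_names
        Ordered, unique gene identifiers, one per column.
    cell_ids
        Ordered, unique cell identifiers, one per row.
    population
        One categorical label per cell (stored as strings).
    """

    matrix: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    population: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.population = [str(p) for p in self.population]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def populations(self) -> list[str]:
        """Distinct population labels in lexicographic order."""
        return sorted(set(self.population))

    def subset_population(self, label: str) -> "ExpressionDataset":
        idx = [i for i, p in enumerate(self.population) if p == label]
        if not idx:
            raise KeyError(f"unknown population {label!r}")
        return ExpressionDataset(
            matrix=self.matrix[idx],
            gene_names=list(self.gene_names),
            cell_ids=[self.cell_ids[i] for i in idx],
            population=[label] * len(idx),
        )


@dataclass
class SpatialAssignment:
    """Per-cell spatial coordinates (2-D or 3-D) and population labels."""

    coordinates: np.ndarray
    population: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] not in (2, 3):
            raise ValueError("coordinates must be (n, 2) or (n, 3)")
        self.population = [str(p) for p in self.population]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n = self.coordinates.shape[0]
        if len(self.population) != n or len(self.cell_ids) != n:
            raise ValueError("coordinates, population and cell_ids must align")

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]

    @property
    def ndim(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class SpatialReference:
    """Spatial reference: positions, group annotation, and expression."""

    coordinates: np.ndarray
    group: list[str]
    expression: np.ndarray
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        self.group = [str(g) for g in self.group]
        n = self.coordinates.shape[0]
        if len(self.group) != n or self.expression.shape[0] != n:
            raise ValueError("coordinates, group and expression must have equal row counts")
        if not self.group:
            raise ValueError("reference must contain at least one position")

    def groups(self) -> list[str]:
        return sorted(set(self.group))


def validate_dataset(ds: ExpressionDataset) -> list[str]:
    """Check an :class:`ExpressionDataset` against its invariants.

    Returns a list of human-readable violations; an empty list means the
    dataset is valid. Never raises.
    """
    report: list[str] = []
    m = ds.matrix
    if m.ndim != 2:
        report.append(f"matrix must be 2-D, got ndim={m.ndim}")
        return report
    if m.shape[0] != len(ds.cell_ids):
        report.append(
            f"row count {m.shape[0]} != number of cell ids {len(ds.cell_ids)}"
        )
    if m.shape[1] != len(ds.gene_names):
        report.append(
            f"column count {m.shape[1]} != number of gene names {len(ds.gene_names)}"
        )
    if len(ds.population) != len(ds.cell_ids):
        report.append(
            f"{len(ds.population)} population labels for {len(ds.cell_ids)} cells"
        )
    if not np.all(np.isfinite(m)):
        bad = np.argwhere(~np.isfinite(m))
        i, j = bad[0]
        report.append(f"non-finite entry at cell {ds.cell_ids[i]!r}, gene index {j}")
    neg = np.argwhere(m < 0)
    if neg.size:
        i, j = neg[0]
        cell = ds.cell_ids[i] if i < len(ds.cell_ids) else str(i)
        gene = ds.gene_names[j] if j < len(ds.gene_names) else str(j)
        report.append(f"negative entry at cell {cell!r}, gene {gene!r}")
    dup_g = _duplicates(ds.gene_names)
    if dup_g:
        report.append(f"duplicated gene names: {sorted(dup_g)}")
    dup_c = _duplicates(ds.cell_ids)
    if dup_c:
        report.append(f"duplicated cell ids: {sorted(dup_c)}")
    return report


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for it in items:
        if it in seen:
            dups.add(it)
        seen.add(it)
    return dups


def _require_valid(ds: ExpressionDataset) -> ExpressionDataset:
    report = validate_dataset(ds)
    if report:
        raise ValueError("invalid dataset: " + "; ".join(report))
    return ds


def normalize_expression(
    raw: np.ndarray, target_sum: float | None = None
) -> np.ndarray:
    """Library-size normalize then log1p-transform a counts matrix.

    Each cell (row) is scaled so its total equals ``target_sum`` (the
    median of per-cell totals by default, computed over non-empty cells),
    then transformed with ``log(1 + x)``. All-zero cells are left all-zero.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("counts must be non-negative")
    totals = raw.sum(axis=1)
    nonzero = totals > 0
    if target_sum is None:
        target_sum = float(np.median(totals[nonzero])) if nonzero.any() else 1.0
    out = np.zeros_like(raw)
    out[nonzero] = raw[nonzero] * (target_sum / totals[nonzero, None])
    return np.log1p(out)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_POP_COL = "population"


def read_dataset(path: str, format: str | None = None) -> ExpressionDataset:
    """Read an :class:`ExpressionDataset` from ``csv``, ``mtx`` or ``h5ad``.

    CSV convention: cells are rows; the first column holds the cell id, the
    header row carries gene names, and a ``population`` column (if present)
    carries the labels. MTX convention: a genes-as-columns sparse matrix in
    ``<stem>.mtx`` with sidecar files ``<stem>.cells.txt`` (``cell_id<TAB>
    population`` per line) and ``<stem>.genes.txt``.
    """
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "mtx":
        return _read_mtx(path)
    if fmt == "h5ad":
        return _read_h5ad(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_dataset(ds: ExpressionDataset, path: str, format: str | None = None) -> None:
    """Write an :class:`ExpressionDataset` in the conventions of
    :func:`read_dataset`."""
    _require_valid(ds)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        df = pd.DataFrame(ds.matrix, index=ds.cell_ids, columns=ds.gene_names)
        df.insert(0, _POP_COL, ds.population)
        df.to_csv(path, index_label="cell_id")
    elif fmt == "mtx":
        stem = _mtx_stem(path)
        mmwrite(stem + ".mtx", sparse.csr_matrix(ds.matrix))
        with open(stem + ".cells.txt", "w") as fh:
            for cid, pop in zip(ds.cell_ids, ds.population):
                fh.write(f"{cid}\t{pop}\n")
        with open(stem + ".genes.txt", "w") as fh:
            fh.write("\n".join(ds.gene_names) + "\n")
    elif fmt == "h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=ds.matrix,
            obs=pd.DataFrame({_POP_COL: ds.population}, index=ds.cell_ids),
            var=pd.DataFrame(index=ds.gene_names),
        )
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: str) -> str:
    lower = path.lower()
    if lower.endswith((".csv", ".tsv")):
        return "csv"
    if lower.endswith(".mtx"):
        return "mtx"
    if lower.endswith(".h5ad"):
        return "h5ad"
    raise ValueError(f"cannot infer format from {path!r}")


def _mtx_stem(path: str) -> str:
    return path[:-4] if path.lower().endswith(".mtx") else path


def _read_csv(path: str) -> ExpressionDataset:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = "\t" if path.lower().endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if _POP_COL in df.columns:
        population = df[_POP_COL].astype(str).tolist()
        df = df.drop(columns=[_POP_COL])
    else:
        population = ["population_0"] * df.shape[0]
    return _require_valid(
        ExpressionDataset(
            matrix=df.to_numpy(dtype=float),
            gene_names=[str(c) for c in df.columns],
            cell_ids=[str(i) for i in df.index],
            population=population,
        )
    )


def _read_mtx(path: str) -> ExpressionDataset:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    stem = _mtx_stem(path)
    cells_file, genes_file = stem + ".cells.txt", stem + ".genes.txt"
    for side in (cells_file, genes_file):
        if not os.path.exists(side):
            raise FileNotFoundError(f"missing sidecar name file {side}")
    m = mmread(path)
    mat = np.asarray(m.todense() if sparse.issparse(m) else m, dtype=float)
    cell_ids, population = [], []
    with open(cells_file) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            cell_ids.append(parts[0])
            population.append(parts[1] if len(parts) > 1 else "population_0")
    with open(genes_file) as fh:
        gene_names = [ln.strip() for ln in fh if ln.strip()]
    if mat.shape != (len(cell_ids), len(gene_names)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match "
            f"{len(cell_ids)} cells x {len(gene_names)} genes from sidecar files"
        )
    return _require_valid(
        ExpressionDataset(mat, gene_names, cell_ids, population)
    )


def _read_h5ad(path: str) -> ExpressionDataset:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    import anndata as ad

    adata = ad.read_h5ad(path)
    X = adata.X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    if _POP_COL in adata.obs:
        population = adata.obs[_POP_COL].astype(str).tolist()
    else:
        population = ["population_0"] * adata.n_obs
    return _require_valid(
        ExpressionDataset(
            matrix=np.asarray(X, dtype=float),
            gene_names=[str(g) for g in adata.var_names],
            cell_ids=[str(c) for c in adata.obs_names],
            population=population,
        )
    )


def read_reference(path: str) -> SpatialReference:
    """Read a :class:`SpatialReference` from ``.h5ad`` (coordinates in
    ``obsm["spatial"]``, annotation in ``obs["group"]``) or from a CSV whose
    first columns are ``x``, ``y`` (optionally ``z``) and ``group``."""
    if path.lower().endswith(".h5ad"):
        import anndata as ad

        adata = ad.read_h5ad(path)
        if "spatial" not in adata.obsm:
            raise ValueError('reference h5ad must carry obsm["spatial"]')
        col = "group" if "group" in adata.obs else _POP_COL
        if col not in adata.obs:
            raise ValueError('reference h5ad must carry obs["group"]')
        X = adata.X
        if sparse.issparse(X):
            X = np.asarray(X.todense())
        return SpatialReference(
            coordinates=np.asarray(adata.obsm["spatial"], dtype=float),
            group=adata.obs[col].astype(str).tolist(),
            expression=np.asarray(X, dtype=float),
            gene_names=[str(g) for g in adata.var_names],
        )
    df = pd.read_csv(path, index_col=0)
    coord_cols = [c for c in ("x", "y", "z") if c in df.columns]
    if len(coord_cols) < 2 or "group" not in df.columns:
        raise ValueError("reference CSV needs x, y[, z] and group columns")
    expr_cols = [c for c in df.columns if c not in coord_cols + ["group"]]
    return SpatialReference(
        coordinates=df[coord_cols].to_numpy(dtype=float),
        group=df["group"].astype(str).tolist(),
        expression=df[expr_cols].to_numpy(dtype=float),
        gene_names=expr_cols,
    )


def write_assignment(
    assign: SpatialAssignment,
    path: str,
    expression: ExpressionDataset | None = None,
) -> None:
    """Write a :class:`SpatialAssignment` (optionally with expression) to
    ``.h5ad`` or CSV."""
    if path.lower().endswith(".h5ad"):
        import anndata as ad

        if expression is not None:
            X = expression.matrix
            var = pd.DataFrame(index=expression.gene_names)
        else:
            X = np.zeros((assign.n_cells, 0))
            var = pd.DataFrame(index=pd.Index([], dtype=str))
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame({_POP_COL: assign.population}, index=assign.cell_ids),
            var=var,
        )
        adata.obsm["spatial"] = assign.coordinates
        adata.write_h5ad(path)
        return
    cols = {"x": assign.coordinates[:, 0], "y": assign.coordinates[:, 1]}
    if assign.ndim == 3:
        cols["z"] = assign.coordinates[:, 2]
    cols[_POP_COL] = assign.population
    pd.DataFrame(cols, index=assign.cell_ids).to_csv(path, index_label="cell_id")


def read_assignment(path: str) -> SpatialAssignment:
    """Inverse of :func:`write_assignment` for the CSV and h5ad conventions."""
    if path.lower().endswith(".h5ad"):
        import anndata as ad

        adata = ad.read_h5ad(path)
        return SpatialAssignment(
            coordinates=np.asarray(adata.obsm["spatial"], dtype=float),
            population=adata.obs[_POP_COL].astype(str).tolist(),
            cell_ids=[str(c) for c in adata.obs_names],
        )
    df = pd.read_csv(path, index_col=0)
    coord_cols = [c for c in ("x", "y", "z") if c in df.columns]
    return SpatialAssignment(
        coordinates=df[coord_cols].to_numpy(dtype=float),
        population=df[_POP_COL].astype(str).tolist(),
        cell_ids=[str(i) for i in df.index],
    )
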