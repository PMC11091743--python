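"""Reading, validating and preprocessing count matrices.

The internal convention is cells x genes everywhere. Matrix Market inputs,
which are conventionally genes x cells, are auto-transposed by matching the
matrix dimensions against the sidecar name files.

Preprocessing follows the DCA/scDeepCluster lineage: per-cell size factors
(library size over median library size), a log1p + per-gene z-score encoder
input, and the untouched raw counts kept as the likelihood target.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


@dataclass
class CountMatrix:
    """Raw cells x genes integer counts with identifiers and optional labels."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError(
                f"identifier lengths ({len(self.cell_ids)}, {len(self.gene_ids)}) "
                f"do not match counts shape {self.counts.shape}"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene_ids")
        _validate_counts(self.counts)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels must have exactly one value per cell")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class PreprocessedData:
    """Model-ready view of a count matrix.

    x_input feeds the encoder; x_raw is the ZINB target on the count scale;
    size_factors scale the decoder mean back to library depth.
    """

    x_input: np.ndarray
    x_raw: np.ndarray
    size_factors: np.ndarray
    kept_gene_index: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.x_input.shape != self.x_raw.shape:
            raise ValueError("x_input and x_raw must have identical shape")
        if np.any(self.size_factors <= 0):
            raise ValueError("size_factors must be positive")


def _validate_counts(counts: np.ndarray) -> None:
    if np.any(counts < 0):
        bad = np.argwhere(counts < 0)[0]
        raise ValueError(
            f"negative count at cell {bad[0]}, gene {bad[1]}: counts must be >= 0"
        )
    if not np.allclose(counts, np.round(counts)):
        bad = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
        raise ValueError(
            f"non-integer count at cell {bad[0]}, gene {bad[1]}"
        )


def _read_names(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_counts(path: str, format: str | None = None, *,
                cell_file: str | None = None, gene_file: str | None = None,
                layer: str | None = None) -> CountMatrix:
    """Read a count matrix from CSV/TSV, Matrix Market, or AnnData h5ad.

    CSV: header row of gene names, first column of cell ids. MTX: a sidecar
    file of names per axis (defaults ``<stem>.cells.txt`` / ``<stem>.genes.txt``);
    orientation is resolved from the name-file lengths, so genes x cells files
    are transposed on read. h5ad: raw counts from `.X` or the named ``layer``.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".csv": "csv", ".tsv": "csv", ".txt": "csv",
                  ".mtx": "mtx", ".h5ad": "h5ad"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}")

    if format == "csv":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as err:  # surface the parser's line info
            raise ValueError(f"malformed delimited file {path!r}: {err}") from err
        counts = df.to_numpy(dtype=np.float64)
        _validate_counts(counts)
        return CountMatrix(counts.astype(np.int64),
                           [str(c) for c in df.index],
                           [str(g) for g in df.columns])

    if format == "mtx":
        stem = os.path.splitext(path)[0]
        cell_file = cell_file or stem + ".cells.txt"
        gene_file = gene_file or stem + ".genes.txt"
        try:
            mat = spio.mmread(path)
        except Exception as err:
            raise ValueError(f"malformed Matrix Market file {path!r}: {err}") from err
        mat = np.asarray(mat.todense() if sparse.issparse(mat) else mat,
                         dtype=np.float64)
        cells = _read_names(cell_file)
        genes = _read_names(gene_file)
        if mat.shape == (len(genes), len(cells)) and mat.shape[0] != mat.shape[1]:
            mat = mat.T  # genes x cells dialect
        elif mat.shape != (len(cells), len(genes)):
            if mat.shape == (len(genes), len(cells)):
                mat = mat.T
            else:
                raise ValueError(
                    f"MTX shape {mat.shape} matches neither "
                    f"(cells={len(cells)}, genes={len(genes)}) nor its transpose"
                )
        _validate_counts(mat)
        return CountMatrix(mat.astype(np.int64), cells, genes)

    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        x = adata.layers[layer] if layer else adata.X
        x = np.asarray(x.todense() if sparse.issparse(x) else x, dtype=np.float64)
        _validate_counts(x)
        return CountMatrix(x.astype(np.int64),
                           [str(c) for c in adata.obs_names],
                           [str(g) for g in adata.var_names])

    raise ValueError(f"unknown format {format!r}; expected csv, mtx, or h5ad")


def read_labels(path: str, cm: CountMatrix, sep: str | None = None) -> CountMatrix:
    """Attach per-cell labels from a two-column (cell id, type) file.

    Every cell of `cm` must appear exactly once; unknown or missing ids are
    errors (partial supervision is modeled downstream by the labeled-fraction
    mask, never by missing rows).
    """
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, header=None, names=["cell", "label"],
                     dtype={"cell": str})
    mapping = dict(zip(df["cell"], df["label"]))
    if len(mapping) != len(df):
        raise ValueError("duplicate cell ids in label file")
    ghosts = sorted(set(df["cell"]) - set(cm.cell_ids))
    if ghosts:
        raise ValueError(f"label file contains unknown cell ids: {ghosts}")
    missing = sorted(set(cm.cell_ids) - set(df["cell"]))
    if missing:
        raise ValueError(f"label file is missing cells: {missing}")
    labels = np.array([mapping[c] for c in cm.cell_ids])
    return CountMatrix(cm.counts, cm.cell_ids, cm.gene_ids, labels=labels)


def preprocess(cm: CountMatrix, min_gene_counts: int = 1,
               n_top_genes: int | None = None) -> PreprocessedData:
    """Filter genes, compute size factors, and standardize the encoder input.

    Genes with total count below ``min_gene_counts`` are dropped; optionally
    only the ``n_top_genes`` most variable (on the normalized log scale) are
    kept. size_factor_i = library_i / median(library); the encoder input is
    the per-gene z-score of log1p(count / size_factor). Zero-variance genes
    map to all-zero columns so the gene index stays stable.
    """
    if cm.n_cells == 0 or cm.n_genes == 0:
        raise ValueError("empty count matrix")
    counts = cm.counts.astype(np.float64)
    keep = counts.sum(axis=0) >= min_gene_counts
    if not keep.any():
        raise ValueError("all genes removed by min_gene_counts filter")
    kept_index = np.flatnonzero(keep)
    counts = counts[:, keep]

    lib = counts.sum(axis=1)
    if np.any(lib == 0):
        lib = np.maximum(lib, 1.0)  # all-zero cells get a unit library
    size_factors = lib / np.median(lib)

    norm = np.log1p(counts / size_factors[:, None])
    if n_top_genes is not None and n_top_genes < norm.shape[1]:
        var = norm.var(axis=0)
        order = np.argsort(-var, kind="stable")[:n_top_genes]
        order.sort()
        kept_index = kept_index[order]
        counts = counts[:, order]
        norm = norm[:, order]

    mu = norm.mean(axis=0)
    sd = norm.std(axis=0)
    x_input = np.where(sd > 0, (norm - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    return PreprocessedData(
        x_input=x_input,
        x_raw=counts,
        size_factors=size_factors,
        kept_gene_index=kept_index,
        cell_ids=list(cm.cell_ids),
        gene_ids=[cm.gene_ids[i] for i in kept_index],
    )


def write_results(labels: np.ndarray, embedding: np.ndarray,
                  path_prefix: str, cell_ids: list[str] | None = None) -> tuple[str, str]:
    """Write ``<prefix>.labels.csv`` (cell id, cluster) and
    ``<prefix>.embedding.csv`` (cell id + latent coordinates)."""
    labels = np.asarray(labels)
    embedding = np.asarray(embedding)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if len(labels) != embedding.shape[0]:
        raise ValueError("labels length must equal embedding rows")
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(len(labels))]
    lab_path = path_prefix + ".labels.csv"
    emb_path = path_prefix + ".embedding.csv"
    pd.DataFrame({"cell": cell_ids, "label": labels}).to_csv(
        lab_path, index=False, header=False)
    emb = pd.DataFrame(embedding, index=cell_ids)
    emb.to_csv(emb_path, header=False)
    return lab_path, emb_path


def write_counts_csv(cm: CountMatrix, path: str) -> None:
    """Write a CountMatrix in the CSV dialect ``read_counts`` accepts."""
    pd.DataFrame(cm.counts, index=cm.cell_ids, columns=cm.gene_ids).to_csv(path)


def write_counts_mtx(cm: CountMatrix, path: str) -> None:
    """Write cells x genes Matrix Market plus name sidecars."""
    stem = os.path.splitext(path)[0]
    spio.mmwrite(path, sparse.coo_matrix(cm.counts))
    with open(stem + ".cells.txt", "w") as fh:
        fh.write("\n".join(cm.cell_ids) + "\n")
    with open(stem + ".genes.txt", "w") as fh:
        fh.write("\n".join(cm.gene_ids) + "\n")
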