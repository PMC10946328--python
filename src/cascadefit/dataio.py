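"""Reading count matrices and pseudotime tables, and serializing fit results.

The on-disk dialects are deliberately plain: Matrix Market sparse counts with
one-gene-per-line / one-cell-per-line sidecar files (the format distributed by
most scRNA-seq pipelines), or a dense TSV with a header row of cell ids and a
first column of gene ids.  Pseudotime comes as a two-column TSV
(``cell_id``, ``pseudotime``).  Outputs are TSV summaries, per-gene posterior
sample tables, and a JSON run-metadata record.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "PseudotimeOrdering",
    "TrajectoryDataset",
    "read_count_matrix",
    "read_pseudotime",
    "build_trajectory",
    "filter_genes",
    "write_fit_results",
    "read_fit_results",
]


@dataclass
class CountMatrix:
    """Raw UMI counts, genes x cells."""

    gene_ids: list
    cell_ids: list
    counts: np.ndarray  # (n_genes, n_cells) nonnegative integers

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-d matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if np.any(self.counts < 0):
            raise ValueError("negative count entries")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-8):
                raise ValueError("non-integer count entries")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)

    @property
    def shape(self):
        return self.counts.shape


@dataclass
class PseudotimeOrdering:
    """Per-cell scalar pseudotime; only the induced ranks t = 1..N are used."""

    cell_ids: list
    pseudotime: np.ndarray

    def __post_init__(self):
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if len(self.cell_ids) != self.pseudotime.shape[0]:
            raise ValueError("cell_ids and pseudotime lengths differ")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids in pseudotime table")


@dataclass
class TrajectoryDataset:
    """Counts with columns in nondecreasing pseudotime order.

    ``umi_totals`` holds the per-cell totals M_t and ``size_factor`` the
    dataset median M-tilde used by the log-normalization mapping.
    """

    gene_ids: list
    cell_ids: list
    counts: np.ndarray
    pseudotime: np.ndarray
    umi_totals: np.ndarray = field(init=False)
    size_factor: float = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.umi_totals = self.counts.sum(axis=0)
        self.size_factor = float(np.median(self.umi_totals))

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def gene_counts(self, gene) -> np.ndarray:
        return self.counts[self.gene_index(gene)]


def _read_lines(path):
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_count_matrix(path_matrix, path_genes=None, path_cells=None,
                      transpose=False) -> CountMatrix:
    """Read a count matrix from Matrix Market (+ sidecars) or dense TSV.

    Matrix Market orientation is auto-detected by matching the gene sidecar
    length against the row count; ``transpose=True`` overrides the detection.
    Duplicate coordinate entries are summed.
    """
    if str(path_matrix).endswith((".mtx", ".mtx.gz")):
        if path_genes is None or path_cells is None:
            raise ValueError("Matrix Market input requires gene and cell sidecar files")
        try:
            mat = scipy.io.mmread(path_matrix)
        except Exception as exc:  # pragma: no cover - scipy error text varies
            raise ValueError(f"malformed Matrix Market file {path_matrix}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = np.asarray(mat.todense())  # tocsr inside sums duplicates
        genes = _read_lines(path_genes)
        cells = _read_lines(path_cells)
        if transpose:
            mat = mat.T
        elif len(genes) == mat.shape[0] and len(cells) == mat.shape[1]:
            pass
        elif len(genes) == mat.shape[1] and len(cells) == mat.shape[0]:
            mat = mat.T
        else:
            raise ValueError(
                f"sidecar lengths ({len(genes)} genes, {len(cells)} cells) match "
                f"neither orientation of matrix with shape {mat.shape}"
            )
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        return CountMatrix(genes, cells, mat)

    # dense TSV: header row of cell ids, first column of gene ids
    try:
        df = pd.read_csv(path_matrix, sep="\t", index_col=0)
    except Exception as exc:
        raise ValueError(f"malformed TSV count matrix {path_matrix}: {exc}") from exc
    values = df.to_numpy()
    if values.dtype == object:
        raise ValueError(f"non-numeric entries in count matrix {path_matrix}")
    if transpose:
        return CountMatrix(list(df.columns), list(df.index.astype(str)), values.T)
    return CountMatrix(list(df.index.astype(str)), list(df.columns), values)


def read_pseudotime(path) -> PseudotimeOrdering:
    """Read a TSV pseudotime table with columns cell_id, pseudotime."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if "cell_id" in cols and "pseudotime" in cols:
        cell_col = df.columns[cols.index("cell_id")]
        pt_col = df.columns[cols.index("pseudotime")]
    elif df.shape[1] >= 2:
        cell_col, pt_col = df.columns[0], df.columns[1]
    else:
        raise ValueError(f"pseudotime table {path} needs columns cell_id, pseudotime")
    return PseudotimeOrdering(list(df[cell_col].astype(str)), df[pt_col].to_numpy(float))


def build_trajectory(cm: CountMatrix, pt: PseudotimeOrdering) -> TrajectoryDataset:
    """Order counts by ascending pseudotime; ranks become t = 1..N.

    Ties in pseudotime are broken by lexicographic cell id so rank assignment
    is deterministic.  Cells in the count matrix without a pseudotime are
    dropped (logged); pseudotime entries naming unknown cells are an error, as
    are cells with zero total UMIs (the size-factor mapping is undefined).
    """
    cell_pos = {c: i for i, c in enumerate(cm.cell_ids)}
    unknown = [c for c in pt.cell_ids if c not in cell_pos]
    if unknown:
        raise ValueError(f"pseudotime references unknown cells: {unknown[:10]}")
    dropped = len(cm.cell_ids) - len(pt.cell_ids)
    if dropped:
        logger.info("dropping %d cells without pseudotime", dropped)
    # sort by (pseudotime, cell_id); np.lexsort uses the last key as primary
    order = np.lexsort((np.asarray(pt.cell_ids, dtype=object), pt.pseudotime))
    ordered_cells = [pt.cell_ids[i] for i in order]
    col_idx = np.array([cell_pos[c] for c in ordered_cells])
    counts = cm.counts[:, col_idx]
    totals = counts.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if zero.size:
        bad = [ordered_cells[i] for i in zero[:10]]
        raise ValueError(f"cells with zero total UMIs: {bad}")
    if len(ordered_cells) < 10:
        raise ValueError(f"too few cells to fit (N={len(ordered_cells)} < 10)")
    return TrajectoryDataset(
        gene_ids=list(cm.gene_ids),
        cell_ids=ordered_cells,
        counts=counts,
        pseudotime=pt.pseudotime[order],
    )


def filter_genes(td: TrajectoryDataset, min_expressed_frac: float) -> TrajectoryDataset:
    """Keep genes with nonzero counts in at least ``min_expressed_frac * N`` cells.

    The boundary is inclusive (a gene expressed in exactly 1% of cells passes
    at threshold 0.01).  Gene order is preserved; the filter is idempotent.
    """
    if not 0.0 <= min_expressed_frac <= 1.0:
        raise ValueError("min_expressed_frac must be in [0, 1]")
    n_nonzero = (td.counts > 0).sum(axis=1)
    keep = n_nonzero >= min_expressed_frac * td.n_cells
    if not keep.any():
        logger.warning("gene filter removed all genes")
    return TrajectoryDataset(
        gene_ids=[g for g, k in zip(td.gene_ids, keep) if k],
        cell_ids=list(td.cell_ids),
        counts=td.counts[keep],
        pseudotime=td.pseudotime.copy(),
    )


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.15g"  # >= 12 significant digits round-trip


def write_fit_results(results, out_dir, metadata=None):
    """Write a per-gene summary TSV, per-gene posterior sample TSVs, and
    a JSON run-metadata record.

    ``results`` is an iterable of :class:`cascadefit.model.GeneFitResult`.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for res in results:
        rows.append(res.summary_row())
        samples = res.sample_table()
        samples.to_csv(
            os.path.join(out_dir, f"{res.gene}_samples.tsv"),
            sep="\t", index=False, float_format=_FLOAT_FMT,
        )
    columns = list(rows[0].keys()) if rows else [
        "gene", "best_fit", "decision_branch", "dynamic_class"]
    summary = pd.DataFrame(rows, columns=columns)
    summary.to_csv(os.path.join(out_dir, "summary.tsv"), sep="\t",
                   index=False, float_format=_FLOAT_FMT)
    meta = dict(metadata or {})
    meta.setdefault("package", "cascadefit")
    with open(os.path.join(out_dir, "run_metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=float)
    return summary


def read_fit_results(out_dir):
    """Reload fit results written by :func:`write_fit_results`.

    Returns a list of :class:`cascadefit.model.GeneFitResult` rebuilt from the
    summary and per-gene sample tables (sufficient for all cascade and
    regulator operations).
    """
    from .model import GeneFitResult

    summary = pd.read_csv(os.path.join(out_dir, "summary.tsv"), sep="\t")
    results = []
    for _, row in summary.iterrows():
        gene = str(row["gene"])
        samples = pd.read_csv(os.path.join(out_dir, f"{gene}_samples.tsv"), sep="\t")
        results.append(GeneFitResult.from_tables(row, samples))
    return results
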