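"""Count-matrix construction, Matrix Market I/O, and protocol quality filters.

The in-memory container is an :class:`anndata.AnnData` with cells as rows
(``obs``) and genes as columns (``var``):

* ``X`` — sparse non-negative integer counts,
* ``obs["tissue"]`` — tissue label per cell,
* ``var["is_spikein"]`` — True for exogenous spike-in sequences,
* ``var["concentration"]`` — spike-in concentration in amol/ul (NaN for
  endogenous genes).

On disk a matrix is three text files: a Matrix Market ``.mtx`` (genes x
cells, the common convention for sparse expression matrices) plus two
tab-delimited sidecars for cell and gene metadata.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

SPIKEIN_PREFIX = "ERCC-"

CELL_COLUMNS = ["cell_id", "tissue", "is_real"]
GENE_COLUMNS = ["gene_id", "is_spikein", "concentration"]


def make_count_matrix(
    counts,
    gene_ids,
    cell_ids,
    tissues,
    is_spikein=None,
    concentration=None,
    *,
    seed: int | None = None,
) -> ad.AnnData:
    """Assemble a validated cells x genes count matrix.

    ``counts`` may be dense or sparse, cells as rows. ``tissues`` is one
    label per cell. Raises ``ValueError`` on negative or non-integral
    entries or inconsistent dimensions.
    """
    X = sp.csr_matrix(counts)
    n_cells, n_genes = X.shape
    if len(cell_ids) != n_cells or len(gene_ids) != n_genes:
        raise ValueError(
            f"metadata lengths ({len(cell_ids)} cells, {len(gene_ids)} genes) "
            f"do not match matrix shape {X.shape}"
        )
    if len(tissues) != n_cells:
        raise ValueError("one tissue label required per cell")
    _check_integral_nonnegative(X)
    X = X.astype(np.int64)

    if is_spikein is None:
        is_spikein = [str(g).startswith(SPIKEIN_PREFIX) for g in gene_ids]
    if concentration is None:
        concentration = np.full(n_genes, np.nan)

    obs = pd.DataFrame(
        {"tissue": pd.Categorical(tissues)},
        index=pd.Index([str(c) for c in cell_ids], name="cell_id"),
    )
    var = pd.DataFrame(
        {
            "is_spikein": np.asarray(is_spikein, dtype=bool),
            "concentration": np.asarray(concentration, dtype=float),
        },
        index=pd.Index([str(g) for g in gene_ids], name="gene_id"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    if seed is not None:
        adata.uns["seed"] = int(seed)
    return adata


def _check_integral_nonnegative(X: sp.spmatrix) -> None:
    data = X.data if sp.issparse(X) else np.asarray(X).ravel()
    if data.size and data.min() < 0:
        raise ValueError("counts must be non-negative")
    if not np.allclose(data, np.rint(data)):
        raise ValueError("counts must be integral")


def cell_totals(adata: ad.AnnData, include_spikeins: bool = True) -> np.ndarray:
    """Total count per cell, optionally restricted to endogenous genes."""
    if include_spikeins:
        X = adata.X
    else:
        X = adata.X[:, ~adata.var["is_spikein"].to_numpy()]
    return np.asarray(X.sum(axis=1)).ravel()


def genes_detected(adata: ad.AnnData, include_spikeins: bool = False) -> np.ndarray:
    """Number of genes with count > 0 per cell (endogenous by default)."""
    X = adata.X
    if not include_spikeins:
        X = X[:, ~adata.var["is_spikein"].to_numpy()]
    return np.asarray((X > 0).sum(axis=1)).ravel()


def cells_per_tissue(adata: ad.AnnData) -> pd.Series:
    """N_k: number of cells carrying each tissue label."""
    return adata.obs["tissue"].value_counts().sort_index()


# ---------------------------------------------------------------------------
# disk round trip
# ---------------------------------------------------------------------------

def write_counts(adata: ad.AnnData, matrix_path, cells_path, genes_path) -> None:
    """Write genes x cells .mtx plus TSV sidecars (UTF-8, header row)."""
    matrix_path, cells_path, genes_path = map(Path, (matrix_path, cells_path, genes_path))
    scipy.io.mmwrite(str(matrix_path), sp.csc_matrix(adata.X.T))
    cells = pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "tissue": adata.obs["tissue"].astype(str).to_numpy(),
            "is_real": np.ones(adata.n_obs, dtype=int),
        }
    )
    cells.to_csv(cells_path, sep="\t", index=False)
    genes = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "is_spikein": adata.var["is_spikein"].astype(int).to_numpy(),
            "concentration": adata.var["concentration"].to_numpy(),
        }
    )
    genes.to_csv(genes_path, sep="\t", index=False)


def read_counts(matrix_path, cells_path, genes_path,
                spikein_prefix: str = SPIKEIN_PREFIX) -> ad.AnnData:
    """Read a matrix written by :func:`write_counts`.

    Spike-ins are re-identified from the sidecar flag when present, else by
    gene-id prefix. Raises on dimension mismatch or invalid counts.
    """
    M = scipy.io.mmread(str(matrix_path))  # genes x cells
    cells = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str})
    genes = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str})
    if "tissue" not in cells.columns:
        raise ValueError("cells sidecar must contain a 'tissue' column")
    if M.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {M.shape} does not match sidecars "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    if "is_spikein" in genes.columns:
        is_spikein = genes["is_spikein"].astype(bool).to_numpy()
    else:
        is_spikein = genes["gene_id"].str.startswith(spikein_prefix).to_numpy()
    conc = genes["concentration"].to_numpy() if "concentration" in genes.columns else None
    return make_count_matrix(
        sp.csr_matrix(M.T),
        gene_ids=genes["gene_id"].tolist(),
        cell_ids=cells["cell_id"].tolist(),
        tissues=cells["tissue"].tolist(),
        is_spikein=is_spikein,
        concentration=conc,
    )


def read_counts_csv(path, tissue: str = "tissue0") -> ad.AnnData:
    """Dense CSV reader for toy fixtures: rows = cells, columns = genes."""
    df = pd.read_csv(path, index_col=0)
    return make_count_matrix(
        df.to_numpy(), gene_ids=df.columns, cell_ids=df.index,
        tissues=[tissue] * len(df),
    )


# ---------------------------------------------------------------------------
# protocol filters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FilterReport:
    """What a quality filter removed.

    For the plate/FACS filter, ``inclusion`` is a genes x tissues boolean
    frame saying in which tissues each surviving gene cleared the gene-total
    threshold (per-tissue scope); downstream per-tissue statistics should
    honour it.
    """

    protocol: str
    entries_zeroed: int = 0
    genes_dropped: list = dataclasses.field(default_factory=list)
    cells_dropped: list = dataclasses.field(default_factory=list)
    inclusion: pd.DataFrame | None = None


def filter_facs(
    adata: ad.AnnData,
    min_gene_total: int = 500,
    min_cell_count: int = 10,
    scope: str = "per_tissue",
) -> tuple[ad.AnnData, FilterReport]:
    """Plate-based (FACS) filter: zero small entries, drop low-total genes.

    Entries strictly below ``min_cell_count`` are set to zero first; genes
    whose post-zeroing total is not strictly greater than ``min_gene_total``
    are then dropped. Spike-ins are never dropped (kept for diagnostics).
    ``scope`` decides whether the gene total is evaluated within each tissue
    (``"per_tissue"``, the default — every downstream statistic is
    per-tissue) or over the whole matrix (``"global"``).
    """
    if min_gene_total < 0 or min_cell_count < 0:
        raise ValueError("thresholds must be non-negative")
    if scope not in ("per_tissue", "global"):
        raise ValueError(f"unknown scope {scope!r}")

    X = sp.csr_matrix(adata.X, copy=True)
    below = X.data < min_cell_count
    entries_zeroed = int(below.sum())
    X.data[below] = 0
    X.eliminate_zeros()

    is_spike = adata.var["is_spikein"].to_numpy()
    tissues = sorted(adata.obs["tissue"].astype(str).unique())
    per_tissue_total = {}
    for t in tissues:
        mask = (adata.obs["tissue"].astype(str) == t).to_numpy()
        per_tissue_total[t] = np.asarray(X[mask].sum(axis=0)).ravel()
    totals = pd.DataFrame(per_tissue_total, index=adata.var_names)

    if scope == "global":
        passed = totals.sum(axis=1) > min_gene_total
        inclusion = pd.DataFrame(
            {t: passed for t in tissues}, index=adata.var_names)
    else:
        inclusion = totals > min_gene_total

    keep = inclusion.any(axis=1).to_numpy() | is_spike
    dropped = [g for g, k in zip(adata.var_names, keep) if not k]

    out = ad.AnnData(X=X[:, keep], obs=adata.obs.copy(), var=adata.var[keep].copy())
    out.uns.update(adata.uns)
    report = FilterReport(
        protocol="facs",
        entries_zeroed=entries_zeroed,
        genes_dropped=dropped,
        inclusion=inclusion.loc[out.var_names],
    )
    return out, report


def filter_droplet(
    adata: ad.AnnData,
    min_total_reads: int = 1000,
    min_genes: int = 500,
) -> tuple[ad.AnnData, FilterReport]:
    """Droplet filter: keep cells with >= min_total_reads endogenous reads
    and >= min_genes endogenous genes detected (both inclusive). Counts of
    surviving cells are untouched.
    """
    if min_total_reads < 0 or min_genes < 0:
        raise ValueError("thresholds must be non-negative")
    totals = cell_totals(adata, include_spikeins=False)
    detected = genes_detected(adata, include_spikeins=False)
    keep = (totals >= min_total_reads) & (detected >= min_genes)
    dropped = [c for c, k in zip(adata.obs_names, keep) if not k]
    out = adata[keep].copy()
    report = FilterReport(protocol="droplet", cells_dropped=dropped)
    return out, report


def concat_genes(a: ad.AnnData, b: ad.AnnData) -> ad.AnnData:
    """Stack two matrices over the same cells (e.g. endogenous + spike-ins)."""
    if a.n_obs != b.n_obs:
        raise ValueError("matrices must describe the same cells")
    return make_count_matrix(
        sp.hstack([sp.csr_matrix(a.X), sp.csr_matrix(b.X)]),
        gene_ids=list(a.var_names) + list(b.var_names),
        cell_ids=a.obs_names,
        tissues=a.obs["tissue"].tolist(),
        is_spikein=np.concatenate([a.var["is_spikein"], b.var["is_spikein"]]),
        concentration=np.concatenate([a.var["concentration"], b.var["concentration"]]),
    )
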