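"""Spike-in diagnostics and normalization assessment.

ERCC-style spike-ins enter every cell at the same concentration, so their
counts should, ideally, be identical across cells: any spread measures
technical noise. Dividing each count by its cell's total ("normalizing")
only helps if the cell-to-cell variation of totals is technical. The test:
compare Var(ln M) of the raw spike-in counts to Var(ln M') of the
normalized ones. If totals vary for biological reasons, normalization
*injects* that variability into the constant-concentration sequences and
Var(ln M') comes out larger — the observed direction in full-length
plate data, where it is roughly five-fold and survives dropping the
lower quartile of cells by total count.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix_io import cell_totals


@dataclasses.dataclass
class NormalizedMatrix:
    """Per-cell count fractions M' = M / total, with provenance.

    ``fractions`` is cells x genes; the denominator is the cell's
    endogenous total unless ``spikeins_in_total`` was set, in which case
    spike-in reads are counted too. Endogenous entries of a cell sum to 1
    under the default.
    """

    fractions: sp.csr_matrix
    source: object
    spikeins_in_total: bool


def normalize_counts(adata, include_spikeins_in_total: bool = False) -> NormalizedMatrix:
    """Replace each count by the fraction of its cell's total.

    Every cell must have a positive total (zero-total cells are excluded
    upstream by the protocol filters).
    """
    totals = cell_totals(adata, include_spikeins=include_spikeins_in_total)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total count must be removed before normalizing")
    X = sp.csr_matrix(adata.X, dtype=float)
    inv = sp.diags(1.0 / totals)
    return NormalizedMatrix(fractions=inv @ X, source=adata,
                            spikeins_in_total=include_spikeins_in_total)


def _log_variance(col: np.ndarray) -> tuple[float, int]:
    """Population variance of ln(x) over strictly positive entries."""
    pos = col[col > 0]
    if pos.size == 0:
        return np.nan, 0
    return float(np.var(np.log(pos))), int(pos.size)


@dataclasses.dataclass
class SpikeinVariabilityReport:
    per_spikein: pd.DataFrame     # sequence, concentration, var_ln_raw, var_ln_norm, n_cells
    mean_var_ln_raw: float
    mean_var_ln_norm: float
    ratio: float                  # mean_var_ln_norm / mean_var_ln_raw
    excluded_lower_quartile: bool
    n_cells_used: int


def spikein_log_variability(
    adata,
    normalized: NormalizedMatrix | None = None,
    exclude_lower_quartile: bool = False,
) -> SpikeinVariabilityReport:
    """Compare log-count variability of spike-ins before and after
    normalization.

    For each spike-in sequence: Var(ln M) over cells where M > 0, and
    Var(ln M') for the normalized fractions. ``exclude_lower_quartile``
    drops the quarter of cells with the smallest total count (raw totals,
    computed before normalization) before either variance.
    """
    spike_mask = adata.var["is_spikein"].to_numpy()
    if not spike_mask.any():
        raise ValueError("matrix contains no spike-ins")
    if normalized is None:
        normalized = normalize_counts(adata)

    totals = cell_totals(adata, include_spikeins=normalized.spikeins_in_total)
    cells = np.ones(adata.n_obs, dtype=bool)
    if exclude_lower_quartile:
        cells = totals > np.quantile(totals, 0.25)

    raw = np.asarray(sp.csr_matrix(adata.X)[cells][:, spike_mask].todense(), dtype=float)
    norm = np.asarray(normalized.fractions[cells][:, spike_mask].todense())

    rows = []
    names = adata.var_names[spike_mask]
    conc = adata.var["concentration"].to_numpy()[spike_mask]
    for j, (name, c) in enumerate(zip(names, conc)):
        v_raw, n = _log_variance(raw[:, j])
        v_norm, _ = _log_variance(norm[:, j])
        rows.append((name, c, v_raw, v_norm, n))
    per = pd.DataFrame(
        rows, columns=["sequence", "concentration", "var_ln_raw", "var_ln_norm", "n_cells"]
    )
    mraw = float(per["var_ln_raw"].mean())
    mnorm = float(per["var_ln_norm"].mean())
    return SpikeinVariabilityReport(
        per_spikein=per,
        mean_var_ln_raw=mraw,
        mean_var_ln_norm=mnorm,
        ratio=mnorm / mraw if mraw > 0 else np.inf,
        excluded_lower_quartile=exclude_lower_quartile,
        n_cells_used=int(cells.sum()),
    )


def equalize_tissue_activity(stats: pd.DataFrame) -> pd.DataFrame:
    """Shift activities so every tissue's mean A equals the overall mean.

    The shift is additive in A (multiplicative on alpha), so within-tissue
    variances are untouched. The overall mean is the unweighted mean of the
    per-tissue means, matching the simple-average convention used for
    tissue summaries. Returns a copy with adjusted ``A`` and ``alpha``.
    """
    out = stats.copy()
    tissue_mean = out.groupby("tissue", observed=True)["A"].transform("mean")
    grand = out.groupby("tissue", observed=True)["A"].mean().mean()
    shift = grand - tissue_mean
    out["A"] = out["A"] + shift
    out["alpha"] = np.exp(out["A"])
    return out
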