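"""Per-gene, per-tissue transcription parameters.

For every gene *i* in tissue *k* the count vector over the N_k cells gives
the population mean mu and variance sigma^2, from which the two headline
parameters follow:

    p     = mu^2 / sigma^2     activation probability (valid for p << 1),
    alpha = sigma^2 / mu       peak transcript level when active,

with logarithmic companions A = ln(alpha) (*activity*) and I = -ln(p)
(*intermittency*). Under an on/off model where a cell carries alpha
transcripts with probability p and none otherwise, mu = alpha*p and
sigma^2 = p(1-p)*alpha^2, so the estimators recover p/(1-p) and
alpha*(1-p) — i.e. p and alpha themselves when p is small.

A gene is called *intermittent* when I > ln(5), i.e. when it appears
active in fewer than one cell in five; spike-in sequences, present in
every cell, calibrate the I ≈ 0 ideal.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

INTERMITTENCY_CUTOFF = math.log(5.0)


def moments(counts, ddof: int = 0) -> tuple[float, float]:
    """Population mean and variance of a count vector.

    The population (1/N) convention is the default; ``ddof=1`` gives the
    unbiased sample variance.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty count vector")
    return float(x.mean()), float(x.var(ddof=ddof))


def estimate_p(mu: float, sigma2: float) -> float:
    """Activation-probability estimate p = mu^2 / sigma^2, clipped to [0, 1].

    Degenerate cases: mu = 0 gives p = 0; sigma^2 = 0 with mu > 0 (constant
    nonzero expression, the ideal spike-in) gives p = 1. Ratios above 1
    (sub-Poissonian counts) are clipped to 1 so that I = -ln(p) stays
    non-negative. Use :func:`is_degenerate` to flag these cases.
    """
    if mu < 0 or sigma2 < 0:
        raise ValueError("moments must be non-negative")
    if mu == 0:
        return 0.0
    if sigma2 == 0:
        return 1.0
    return min(mu * mu / sigma2, 1.0)


def estimate_alpha(mu: float, sigma2: float) -> float:
    """Peak-activity estimate alpha = sigma^2 / mu.

    For sigma^2 = 0 (constant expression) alpha falls back to mu, the
    constant level itself. mu must be positive.
    """
    if mu <= 0:
        raise ValueError("alpha is undefined for a gene with zero mean")
    if sigma2 < 0:
        raise ValueError("variance must be non-negative")
    if sigma2 == 0:
        return mu
    return sigma2 / mu


def is_degenerate(mu: float, sigma2: float) -> bool:
    """True when (p, alpha) required clipping or a fallback."""
    return mu == 0 or sigma2 == 0 or mu * mu > sigma2


def to_log(p: float, alpha: float) -> tuple[float, float]:
    """Logarithmic variables (I, A) = (-ln p, ln alpha); I >= 0 for p <= 1."""
    if p <= 0 or p > 1:
        raise ValueError("p must lie in (0, 1]")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return -math.log(p), math.log(alpha)


def classify_intermittent(I: float, cutoff: float = INTERMITTENCY_CUTOFF) -> bool:
    """True iff I strictly exceeds the cutoff (default ln 5, i.e. p < 0.2)."""
    if I < 0:
        raise ValueError("intermittency must be non-negative")
    return I > cutoff


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def gene_tissue_stats(
    adata,
    inclusion: pd.DataFrame | None = None,
    ddof: int = 0,
    intermittency_cutoff: float = INTERMITTENCY_CUTOFF,
    include_spikeins: bool = False,
) -> pd.DataFrame:
    """Per-(gene, tissue) statistics table.

    One row per gene per tissue with columns ``gene, tissue, n_cells, mu,
    sigma2, p, alpha, A, I, intermittent, degenerate``. Genes absent
    (all-zero) in a tissue are excluded from that tissue rather than
    assigned infinite intermittency. ``inclusion`` is an optional genes x
    tissues boolean frame (from the FACS filter) restricting which
    (gene, tissue) pairs are evaluated.
    """
    import scipy.sparse as sp

    tissues = sorted(adata.obs["tissue"].astype(str).unique())
    gene_mask = np.ones(adata.n_vars, dtype=bool)
    if not include_spikeins:
        gene_mask &= ~adata.var["is_spikein"].to_numpy()
    genes = adata.var_names[gene_mask]

    rows = []
    X = sp.csr_matrix(adata.X)
    for t in tissues:
        cmask = (adata.obs["tissue"].astype(str) == t).to_numpy()
        n_k = int(cmask.sum())
        sub = X[cmask][:, gene_mask]
        mu = np.asarray(sub.mean(axis=0)).ravel()
        ex2 = np.asarray(sub.power(2).mean(axis=0)).ravel()
        sigma2 = ex2 - mu * mu
        if ddof:
            sigma2 = sigma2 * n_k / max(n_k - ddof, 1)
        sigma2 = np.maximum(sigma2, 0.0)
        for g, m, s2 in zip(genes, mu, sigma2):
            if m == 0:
                continue
            if inclusion is not None and (
                g not in inclusion.index or not bool(inclusion.loc[g, t])
            ):
                continue
            p = estimate_p(m, s2)
            alpha = estimate_alpha(m, s2)
            I, A = to_log(p, alpha)
            rows.append(
                (g, t, n_k, m, s2, p, alpha, A, I,
                 classify_intermittent(I, intermittency_cutoff),
                 is_degenerate(m, s2))
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "tissue", "n_cells", "mu", "sigma2", "p", "alpha",
                 "A", "I", "intermittent", "degenerate"],
    )


def tissue_summary(stats: pd.DataFrame, drop_degenerate: bool = True) -> pd.DataFrame:
    """Per-gene tissue averages and deviations.

    Averages are simple (unweighted by cell numbers). Returns one row per
    (gene, tissue) with ``A_bar, I_bar, dA, dI, n_tissues``; per gene the
    deviations sum to zero by construction. Degenerate entries are dropped
    before averaging by default.
    """
    df = stats[~stats["degenerate"]] if drop_degenerate else stats
    if df.empty:
        raise ValueError("no usable (gene, tissue) entries")
    g = df.groupby("gene", observed=True)
    out = df[["gene", "tissue", "A", "I"]].copy()
    out["A_bar"] = g["A"].transform("mean")
    out["I_bar"] = g["I"].transform("mean")
    out["dA"] = out["A"] - out["A_bar"]
    out["dI"] = out["I"] - out["I_bar"]
    out["n_tissues"] = g["A"].transform("size")
    return out.reset_index(drop=True)


def gene_summary(stats: pd.DataFrame, drop_degenerate: bool = True) -> pd.DataFrame:
    """One row per gene: tissue-averaged activity and intermittency."""
    per = tissue_summary(stats, drop_degenerate=drop_degenerate)
    return (
        per.groupby("gene", observed=True)
        .agg(A_bar=("A_bar", "first"), I_bar=("I_bar", "first"),
             n_tissues=("n_tissues", "first"))
        .reset_index()
    )


@dataclasses.dataclass
class DispersionResult:
    """Pooled cross-tissue dispersion of activity and intermittency."""

    var_dA: float
    var_dI: float
    hist: np.ndarray        # 20 x 20 counts, rows = dI bins, cols = dA bins
    dI_edges: np.ndarray
    dA_edges: np.ndarray
    n_points: int


def dispersion_variances(per_tissue: pd.DataFrame, bins: int = 20) -> DispersionResult:
    """Population variances of the pooled (dA, dI) deviations plus the
    2-D histogram of (dI, dA) pairs on a ``bins x bins`` lattice."""
    dA = per_tissue["dA"].to_numpy(dtype=float)
    dI = per_tissue["dI"].to_numpy(dtype=float)
    hist, ie, ae = np.histogram2d(dI, dA, bins=bins)
    return DispersionResult(
        var_dA=float(np.var(dA)),
        var_dI=float(np.var(dI)),
        hist=hist,
        dI_edges=ie,
        dA_edges=ae,
        n_points=len(dA),
    )
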