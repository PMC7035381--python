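"""Gene-gene correlation statistics and the exclusivity test.

Two statistics per gene pair within a tissue, both on raw counts with
population moments:

    C = (<M_i M_j> - mu_i mu_j) / (sigma_i sigma_j)      (Pearson-type)
    K = C * sigma_i sigma_j / (mu_i mu_j)
      = <M_i M_j> / (mu_i mu_j) - 1

K is the discriminator between the two explanations of rarely observed
genes: if two genes are never expressed in the same cell (continuous
expression in disjoint rare cell types), <M_i M_j> = 0 and K = -1
*exactly*. Temporally intermittent genes co-occur by chance or share
activation programs, so K stays away from -1 and the larger correlation
coefficients are predominantly positive.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclasses.dataclass
class PairCorrelation:
    gene_i: str
    gene_j: str
    tissue: str | None
    C: float
    K: float


def pair_correlation(counts_i, counts_j, gene_i: str = "i", gene_j: str = "j",
                     tissue: str | None = None) -> PairCorrelation:
    """C and K for one aligned pair of count vectors (population moments).

    Both genes must be non-degenerate in the tissue: positive mean and
    positive variance.
    """
    x = np.asarray(counts_i, dtype=float)
    y = np.asarray(counts_j, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("count vectors must be aligned and of length >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    if mx == 0 or my == 0:
        raise ValueError("zero-mean gene: correlation undefined")
    if vx == 0 or vy == 0:
        raise ValueError("zero-variance gene: correlation undefined")
    cross = float(np.mean(x * y))
    C = (cross - mx * my) / np.sqrt(vx * vy)
    K = cross / (mx * my) - 1.0
    return PairCorrelation(gene_i, gene_j, tissue, float(C), float(K))


def correlation_survey(
    adata,
    tissue: str,
    genes=None,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """All-pairs C and K over the eligible genes of one tissue.

    Eligible genes are endogenous, restricted to ``genes`` when given, and
    non-degenerate (positive mean and variance) within the tissue. When the
    pair count exceeds ``max_pairs`` a seeded uniform subsample of pairs is
    returned; subsampling preserves the sign-split distributions.
    """
    cmask = (adata.obs["tissue"].astype(str) == tissue).to_numpy()
    if cmask.sum() < 2:
        raise ValueError(f"fewer than 2 cells in tissue {tissue!r}")
    gmask = ~adata.var["is_spikein"].to_numpy()
    if genes is not None:
        wanted = set(genes)
        gmask &= np.array([g in wanted for g in adata.var_names])

    X = np.asarray(sp.csr_matrix(adata.X)[cmask][:, gmask].todense(), dtype=float)
    names = adata.var_names[gmask]
    mu = X.mean(axis=0)
    var = X.var(axis=0)
    ok = (mu > 0) & (var > 0)
    X, names, mu, var = X[:, ok], names[ok], mu[ok], var[ok]
    m = len(names)
    if m < 2:
        raise ValueError("fewer than 2 eligible genes")

    n = X.shape[0]
    cross = (X.T @ X) / n                       # <M_i M_j>
    iu, ju = np.triu_indices(m, k=1)
    if max_pairs is not None and iu.size > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(iu.size, size=max_pairs, replace=False)
        iu, ju = iu[pick], ju[pick]
    cr = cross[iu, ju]
    C = (cr - mu[iu] * mu[ju]) / np.sqrt(var[iu] * var[ju])
    K = cr / (mu[iu] * mu[ju]) - 1.0
    return pd.DataFrame(
        {
            "gene_i": names[iu],
            "gene_j": names[ju],
            "tissue": tissue,
            "C": C,
            "K": K,
        }
    )


def sign_split_histogram(values, n_bins: int = 40, floor: float = 1e-4) -> pd.DataFrame:
    """Log-binned histograms of |values|, positive and negative branches
    separately (the layout of the survey figures)."""
    v = np.asarray(values, dtype=float)
    out = []
    top = max(np.abs(v).max(), floor * 10) if v.size else floor * 10
    edges = np.geomspace(floor, top, n_bins + 1)
    for branch, sel in (("positive", v > 0), ("negative", v < 0)):
        h, _ = np.histogram(np.abs(v[sel]), bins=edges)
        out.append(pd.DataFrame({
            "branch": branch,
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": h,
        }))
    return pd.concat(out, ignore_index=True)


@dataclasses.dataclass
class ExclusivityReport:
    """Summary of the case A vs case B discrimination statistics."""

    fraction_K_near_minus1: float
    n_pairs: int
    epsilon: float
    c_threshold: float
    n_significant: int           # pairs with |C| > c_threshold
    n_significant_positive: int
    positive_fraction: float     # among significant pairs


def exclusivity_fraction(
    pairs: pd.DataFrame,
    epsilon: float = 0.05,
    c_threshold: float = 0.1,
) -> ExclusivityReport:
    """Fraction of pairs with K within ``epsilon`` of -1, plus the sign
    split of the pairs whose |C| exceeds ``c_threshold``."""
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    K = pairs["K"].to_numpy(dtype=float)
    C = pairs["C"].to_numpy(dtype=float)
    near = np.abs(K + 1.0) <= epsilon
    sig = np.abs(C) > c_threshold
    n_sig = int(sig.sum())
    n_sig_pos = int((sig & (C > 0)).sum())
    return ExclusivityReport(
        fraction_K_near_minus1=float(near.mean()),
        n_pairs=len(K),
        epsilon=epsilon,
        c_threshold=c_threshold,
        n_significant=n_sig,
        n_significant_positive=n_sig_pos,
        positive_fraction=n_sig_pos / n_sig if n_sig else np.nan,
    )
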