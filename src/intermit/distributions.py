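"""Distributional analyses of the gene parameters.

Covers the probability density functions of activity A and intermittency I
by tissue, the tail of the tissue-averaged activity A-bar, and the
correlation between a gene's average activity and average intermittency.

An exponential tail exp(-m * A_bar) in the log variable is the same thing
as a power-law tail P(alpha) ~ alpha^-(m+1) in alpha = exp(A): the tail
slope in A-space plus one is the power-law exponent, exactly, by change of
variables. The slope is estimated by maximum likelihood on the excesses
over a lower cutoff (the Hill estimator, viewed in log space), which is
scale-equivariant in alpha: rescaling all alpha shifts A-bar and the
cutoff together and leaves the estimate unchanged.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats


def pdf_by_tissue(values: pd.DataFrame, column: str = "A", bins: int = 50) -> pd.DataFrame:
    """Normalized (area 1) histograms of one statistic per tissue.

    ``values`` needs columns ``tissue`` and ``column``. Common bin edges
    are taken over the pooled range so tissues are directly comparable.
    """
    if values.empty:
        raise ValueError("no values to histogram")
    x = values[column].to_numpy(dtype=float)
    edges = np.histogram_bin_edges(x, bins=bins)
    out = []
    for t, sub in values.groupby("tissue", observed=True):
        if sub.empty:
            continue
        dens, _ = np.histogram(sub[column], bins=edges, density=True)
        out.append(pd.DataFrame({
            "tissue": t, "bin_left": edges[:-1], "bin_right": edges[1:],
            "density": dens,
        }))
    return pd.concat(out, ignore_index=True)


@dataclasses.dataclass
class TailFit:
    """Exponential tail fit of A-bar, equivalently a power law in alpha."""

    tail_slope: float            # rate m of exp(-m * A_bar)
    implied_alpha_exponent: float  # m + 1, the power-law exponent of alpha
    stderr: float
    lower_cutoff: float
    n_tail: int
    method: str


def fit_tail_exponent(
    a_bar,
    lower_cutoff: float,
    method: str = "mle",
    min_tail: int = 50,
    n_bins: int = 30,
) -> TailFit:
    """Estimate the exponential tail rate of A-bar above a cutoff.

    ``method="mle"``: rate = 1 / mean(A_bar - cutoff) over the tail points
    (the exponential MLE; equivalently the Hill estimator on alpha), with
    stderr = rate / sqrt(n). ``method="regression"``: least-squares slope
    of the log-histogram of the tail, the figure-replication mode.
    """
    x = np.asarray(a_bar, dtype=float)
    tail = x[x > lower_cutoff] - lower_cutoff
    if tail.size < min_tail:
        raise ValueError(
            f"only {tail.size} points above cutoff {lower_cutoff}; need >= {min_tail}")
    if np.all(tail == tail[0]):
        raise ValueError("degenerate (constant) tail")
    if method == "mle":
        rate = 1.0 / float(tail.mean())
        se = rate / np.sqrt(tail.size)
    elif method == "regression":
        hist, edges = np.histogram(tail, bins=n_bins, density=True)
        mids = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        if keep.sum() < 3:
            raise ValueError("too few occupied bins for regression fit")
        res = scipy.stats.linregress(mids[keep], np.log(hist[keep]))
        rate, se = -float(res.slope), float(res.stderr)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TailFit(
        tail_slope=rate,
        implied_alpha_exponent=rate + 1.0,
        stderr=float(se),
        lower_cutoff=float(lower_cutoff),
        n_tail=int(tail.size),
        method=method,
    )


def activity_intermittency_correlation(summary: pd.DataFrame) -> float:
    """Pearson correlation of A-bar against I-bar across genes.

    Weakly negative values say that highly intermittent genes tend,
    slightly, to have lower peak activity.
    """
    a = summary["A_bar"].to_numpy(dtype=float)
    i = summary["I_bar"].to_numpy(dtype=float)
    if len(a) < 3:
        raise ValueError("need at least 3 genes")
    if np.var(a) == 0 or np.var(i) == 0:
        raise ValueError("degenerate variance")
    r, _ = scipy.stats.pearsonr(a, i)
    return float(r)
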