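import math

import numpy as np
import pytest

from intermit import matrix_io, synthetic


def two_point_se(p: float, a: float, n: int) -> tuple[float, float]:
    """Delta-method standard errors of the moment-ratio estimators on
    fixed-count two-point data (count = a with probability p, else 0).

    Exact sampling covariances of (mean, mean-of-squares) follow from the
    Bernoulli moments; the gradients of p_hat = m1^2/(m2 - m1^2) and
    alpha_hat = m2/m1 - m1 are evaluated at the true moments.
    """
    q = 1.0 - p
    m1, m2 = a * p, a * a * p
    s2 = a * a * p * q
    V11, V22, V12 = a * a * p * q / n, a ** 4 * p * q / n, a ** 3 * p * q / n
    df1, df2 = 2 * m1 * m2 / s2 ** 2, -m1 * m1 / s2 ** 2
    dg1, dg2 = -m2 / m1 ** 2 - 1.0, 1.0 / m1
    se_p = math.sqrt(df1 * df1 * V11 + 2 * df1 * df2 * V12 + df2 * df2 * V22)
    se_a = math.sqrt(dg1 * dg1 * V11 + 2 * dg1 * dg2 * V12 + dg2 * dg2 * V22)
    return se_p, se_a


@pytest.fixture
def toy_matrix():
    """3 genes x 4 cells, one spike-in, two tissues."""
    counts = np.array([
        [5, 0, 12],
        [0, 3, 12],
        [2, 0, 11],
        [0, 0, 13],
    ])
    return matrix_io.make_count_matrix(
        counts,
        gene_ids=["geneA", "geneB", "ERCC-00042"],
        cell_ids=["c1", "c2", "c3", "c4"],
        tissues=["heart", "heart", "liver", "liver"],
        concentration=[np.nan, np.nan, 150.0],
    )


@pytest.fixture
def exclusive_matrix():
    """Two genes expressed in disjoint rare cell types (case A)."""
    spec = synthetic.DifferentiationSpec(
        type_frequencies={"t1": 0.5, "t2": 0.5},
        gene_assignments={"g1": "t1", "g2": "t2"},
        active_level={"g1": 20.0, "g2": 20.0},
    )
    adata, truth = synthetic.gen_differentiated_counts(spec, 400, seed=7)
    return adata, truth
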