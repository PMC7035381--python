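import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intermit import params, synthetic


class TestMoments:
    @pytest.mark.parametrize(
        "counts,mu,sigma2",
        [
            ((0, 0, 10, 10), 5.0, 25.0),
            ((0, 0, 0), 0.0, 0.0),
            ((2, 4, 6), 4.0, 8.0 / 3.0),
        ],
    )
    def test_population_convention(self, counts, mu, sigma2):
        m, s2 = params.moments(counts)
        assert m == pytest.approx(mu)
        assert s2 == pytest.approx(sigma2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            params.moments([])

    def test_sample_convention_flag(self):
        _, s2 = params.moments((2, 4, 6), ddof=1)
        assert s2 == pytest.approx(4.0)


class TestEstimators:
    def test_rare_gene(self):
        # one cell at 10 among ten: the two-point model with true p = 0.1
        counts = [10] + [0] * 9
        mu, s2 = params.moments(counts)
        assert params.estimate_p(mu, s2) == pytest.approx(1 / 9)
        assert params.estimate_alpha(mu, s2) == pytest.approx(9.0)

    def test_constant_expression_is_degenerate(self):
        mu, s2 = params.moments([7, 7, 7])
        assert params.estimate_p(mu, s2) == 1.0
        assert params.estimate_alpha(mu, s2) == 7.0
        assert params.is_degenerate(mu, s2)
        I, _ = params.to_log(1.0, 7.0)
        assert I == 0.0

    def test_zero_mean(self):
        assert params.estimate_p(0.0, 0.0) == 0.0
        assert params.is_degenerate(0.0, 0.0)
        with pytest.raises(ValueError):
            params.estimate_alpha(0.0, 0.0)

    def test_super_poissonian_clipped(self):
        # mu^2 > sigma^2: ratio above 1 is clipped so I stays non-negative
        assert params.estimate_p(10.0, 50.0) == 1.0
        assert params.is_degenerate(10.0, 50.0)

    def test_poisson_boundary_alpha_one(self):
        assert params.estimate_alpha(5.0, 5.0) == pytest.approx(1.0)
        _, A = params.to_log(1.0, 1.0)
        assert A == 0.0

    @given(
        mu=st.floats(0.01, 1e4),
        ratio=st.floats(0.01, 100.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identity_p_alpha_mu(self, mu, ratio):
        """p * alpha == mu whenever no clipping was needed."""
        sigma2 = mu * mu / ratio if ratio <= 1 else mu * mu * ratio
        sigma2 = max(sigma2, mu * mu)  # keep p = mu^2/sigma2 <= 1
        p = params.estimate_p(mu, sigma2)
        alpha = params.estimate_alpha(mu, sigma2)
        assert p * alpha == pytest.approx(mu, rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        x = rng.poisson(3, 100)
        a, b = params.moments(x), params.moments(rng.permutation(x))
        assert a == pytest.approx(b, rel=1e-12)


class TestLogVariables:
    def test_p_fifth_gives_ln5(self):
        I, _ = params.to_log(0.2, 1.0)
        assert I == pytest.approx(math.log(5))

    def test_trivial_points(self):
        assert params.to_log(1.0, 1.0) == (0.0, 0.0)
        _, A = params.to_log(0.5, math.e ** 3)
        assert A == pytest.approx(3.0)

    def test_domain_errors(self):
        for bad in [(0.0, 1.0), (1.5, 1.0), (0.5, 0.0)]:
            with pytest.raises(ValueError):
                params.to_log(*bad)

    @pytest.mark.parametrize(
        "I,expected",
        [(1.7, True), (math.log(5), False), (0.0, False)],
    )
    def test_intermittency_cutoff_strict(self, I, expected):
        assert params.classify_intermittent(I) is expected


class TestTwoPointRecovery:
    def test_estimators_converge_to_mixture_values(self):
        """On fixed-count on/off data, p_hat -> p/(1-p), alpha_hat -> alpha(1-p)."""
        from conftest import two_point_se

        p, a, n = 0.1, 100.0, 100_000
        spec = synthetic.IntermittentGeneSpec("g", p, a)
        adata, _ = synthetic.gen_intermittent_counts([spec], n, seed=21, mode="fixed")
        stats = params.gene_tissue_stats(adata)
        se_p, se_a = two_point_se(p, a, n)
        assert abs(stats["p"].iloc[0] - p / (1 - p)) < 3 * se_p
        assert abs(stats["alpha"].iloc[0] - a * (1 - p)) < 3 * se_a


class TestTissueSummary:
    def _stats(self, A_by_tissue, I_by_tissue=None):
        tissues = [f"t{j}" for j in range(len(A_by_tissue))]
        I_by_tissue = I_by_tissue or [0.5] * len(tissues)
        return pd.DataFrame({
            "gene": "g", "tissue": tissues, "n_cells": 10,
            "mu": 1.0, "sigma2": 2.0, "p": 0.5, "alpha": 2.0,
            "A": A_by_tissue, "I": I_by_tissue,
            "intermittent": False, "degenerate": False,
        })

    def test_simple_average_and_deltas(self):
        out = params.tissue_summary(self._stats([1.0, 2.0, 3.0]))
        assert out["A_bar"].unique() == pytest.approx([2.0])
        assert sorted(out["dA"]) == pytest.approx([-1.0, 0.0, 1.0])
        assert out["dA"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_single_tissue_zero_delta(self):
        out = params.tissue_summary(self._stats([2.5]))
        assert out["dA"].tolist() == [0.0]

    def test_constant_gene_no_dispersion(self):
        out = params.tissue_summary(self._stats([2.0, 2.0, 2.0]))
        disp = params.dispersion_variances(out)
        assert disp.var_dA == 0.0

    def test_degenerate_entries_excluded(self):
        df = self._stats([1.0, 2.0, 9.0])
        df.loc[2, "degenerate"] = True
        out = params.tissue_summary(df)
        assert out["A_bar"].unique() == pytest.approx([1.5])

    def test_no_usable_tissues(self):
        df = self._stats([1.0])
        df["degenerate"] = True
        with pytest.raises(ValueError):
            params.tissue_summary(df)


class TestDispersion:
    def test_one_gene_three_tissues(self):
        df = pd.DataFrame({
            "gene": "g", "tissue": ["a", "b", "c"],
            "A": [1.0, 2.0, 3.0], "I": [0.0, 0.0, 0.0],
            "degenerate": False,
        })
        per = params.tissue_summary(df)
        disp = params.dispersion_variances(per)
        assert disp.var_dA == pytest.approx(2.0 / 3.0)
        assert disp.var_dI == 0.0
        assert disp.hist.shape == (20, 20)
        assert disp.hist.sum() == disp.n_points == 3

    def test_shared_alpha_varying_p_makes_dA_small(self):
        """Persistent activity + tissue-modulated intermittency: the pooled
        activity dispersion is far below the intermittency dispersion."""
        tissues = ["t0", "t1", "t2"]
        specs = synthetic.random_intermittent_specs(
            60, tissues, seed=31, p_low=0.05, p_high=0.5)
        adata, _ = synthetic.gen_intermittent_counts(
            specs, {t: 600 for t in tissues}, seed=31)
        per = params.tissue_summary(params.gene_tissue_stats(adata))
        disp = params.dispersion_variances(per)
        assert disp.var_dA < disp.var_dI
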