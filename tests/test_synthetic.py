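import numpy as np
import pytest

from intermit import params, synthetic
from intermit.telegraph import TelegraphParams, stationary_moments


def _dense(adata):
    return np.asarray(adata.X.todense())


class TestSpecs:
    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            synthetic.IntermittentGeneSpec("g", 0.0, 10.0)
        with pytest.raises(ValueError):
            synthetic.IntermittentGeneSpec("g", 0.5, 10.0, tissue_p={"t": 1.5})

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            synthetic.DifferentiationSpec({"a": 0.6, "b": 0.6}, {}, {})

    def test_spikein_validation(self):
        with pytest.raises(ValueError):
            synthetic.Spikein("ERCC-00001", -1.0)
        with pytest.raises(ValueError):
            synthetic.Spikein("ERCC-00001", 1.0, noise_scale=-0.1)


class TestIntermittent:
    def test_always_on_fixed_gene_has_zero_intermittency(self):
        spec = synthetic.IntermittentGeneSpec("g", 1.0, 42.0)
        adata, _ = synthetic.gen_intermittent_counts([spec], 50, seed=0, mode="fixed")
        col = _dense(adata).ravel()
        assert (col == 42).all()
        stats = params.gene_tissue_stats(adata)
        assert stats["I"].iloc[0] == 0.0

    def test_counts_nonnegative_integers_and_truth_complete(self):
        specs = synthetic.random_intermittent_specs(10, ["a", "b"], seed=1)
        adata, truth = synthetic.gen_intermittent_counts(
            specs, {"a": 30, "b": 30}, cell_size_dispersion=0.4, seed=1)
        X = _dense(adata)
        assert (X >= 0).all() and X.dtype.kind == "i"
        assert set(truth["gene"]) == set(adata.var_names)
        assert set(truth["tissue"]) == {"a", "b"}

    def test_activation_frequency_concentrates_on_p_true(self):
        spec = synthetic.IntermittentGeneSpec("g", 0.3, 500.0)
        adata, _ = synthetic.gen_intermittent_counts([spec], 50_000, seed=2)
        frac_on = (_dense(adata).ravel() > 0).mean()
        # binomial 3-sigma band around p (alpha large: active cells never draw 0)
        assert abs(frac_on - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 50_000)

    def test_shared_program_correlates_genes(self):
        specs = [
            synthetic.IntermittentGeneSpec("g1", 0.2, 50.0, program="pr"),
            synthetic.IntermittentGeneSpec("g2", 0.2, 80.0, program="pr"),
        ]
        adata, _ = synthetic.gen_intermittent_counts([*specs], 5000, seed=3)
        X = _dense(adata)
        C = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        assert C > 0.9

    def test_tissue_override_changes_p(self):
        spec = synthetic.IntermittentGeneSpec(
            "g", 0.5, 100.0, tissue_p={"rare": 0.05})
        adata, truth = synthetic.gen_intermittent_counts(
            [spec], {"common": 4000, "rare": 4000}, seed=4)
        X = _dense(adata).ravel()
        labels = adata.obs["tissue"].astype(str).to_numpy()
        assert (X[labels == "common"] > 0).mean() > 5 * (X[labels == "rare"] > 0).mean()
        assert truth.set_index("tissue").loc["rare", "p_true"] == 0.05

    def test_errors(self):
        with pytest.raises(ValueError):
            synthetic.gen_intermittent_counts([], 10)
        spec = synthetic.IntermittentGeneSpec("g", 0.5, 10.0)
        with pytest.raises(ValueError):
            synthetic.gen_intermittent_counts([spec], {"t": 0})


class TestDifferentiated:
    def test_disjoint_supports_and_cross_moment_zero(self, exclusive_matrix):
        adata, truth = exclusive_matrix
        X = _dense(adata)
        assert float((X[:, 0] * X[:, 1]).sum()) == 0.0

    def test_cell_assignment_matches_truth(self, exclusive_matrix):
        adata, truth = exclusive_matrix
        X = _dense(adata)
        types = adata.obs["cell_type"].astype(str).to_numpy()
        for j, gene in enumerate(adata.var_names):
            own = truth.set_index("gene").loc[gene, "cell_type"]
            assert (X[types != own, j] == 0).all()

    def test_single_type_reduces_to_always_on(self):
        spec = synthetic.DifferentiationSpec(
            {"only": 1.0}, {"g": "only"}, {"g": 9.0})
        adata, _ = synthetic.gen_differentiated_counts(spec, 30, seed=5, mode="fixed")
        assert (_dense(adata).ravel() == 9).all()


class TestTelegraphCounts:
    def test_k_tr_zero_all_zero(self):
        adata, _ = synthetic.gen_telegraph_counts(
            [TelegraphParams(1.0, 1.0, 0.0, 1.0)], 100, seed=6)
        assert _dense(adata).sum() == 0

    def test_k_off_zero_is_poisson(self):
        par = TelegraphParams(1.0, 0.0, 50.0, 1.0)
        adata, _ = synthetic.gen_telegraph_counts([par], 50_000, seed=7)
        x = _dense(adata).ravel()
        assert x.mean() == pytest.approx(50.0, rel=0.02)
        assert x.var() == pytest.approx(x.mean(), rel=0.05)

    def test_moments_match_closed_form(self):
        par = TelegraphParams(0.1, 0.9, 100.0, 1.0)
        mean_th, var_th = stationary_moments(par)
        adata, _ = synthetic.gen_telegraph_counts([par], 100_000, seed=8)
        x = _dense(adata).ravel().astype(float)
        se_mean = x.std() / np.sqrt(len(x))
        m2 = x.var()
        se_var = np.sqrt((np.mean((x - x.mean()) ** 4) - m2 ** 2) / len(x))
        assert abs(x.mean() - mean_th) < 3 * se_mean
        assert abs(m2 - var_th) < 3 * se_var


class TestSpikeins:
    def test_ideal_panel_identical_counts(self):
        panel = [synthetic.Spikein("ERCC-00001", 100.0, capture_efficiency=0.5)]
        adata, _ = synthetic.gen_spikein_counts(panel, 20, seed=9)
        col = _dense(adata).ravel()
        assert (col == 50).all()
        stats = params.gene_tissue_stats(adata, include_spikeins=True)
        assert stats["I"].iloc[0] == 0.0

    def test_concentration_linearity(self):
        panel = [
            synthetic.Spikein("ERCC-00001", 100.0),
            synthetic.Spikein("ERCC-00002", 200.0),
        ]
        adata, _ = synthetic.gen_spikein_counts(panel, 5, seed=10)
        X = _dense(adata)
        assert (X[:, 1] == 2 * X[:, 0]).all()

    def test_panel_metadata(self):
        panel = synthetic.ercc_panel(n=8, seed=11)
        adata, truth = synthetic.gen_spikein_counts(panel, 3, seed=11)
        assert adata.var["is_spikein"].all()
        assert (adata.var["concentration"] > 0).all()
        assert len(truth) == 8
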