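"""Preprocessing semantics: log-CPM closed forms, strict filtering,
connectivity outliers, quantile normalization, PCA factors and
residualization."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cascadeqtl import preprocess, simulate
from cascadeqtl.datatypes import FactorSet, OmicsMatrix


def mk(values, layer="mrna", stage="raw_counts", samples=None, genes=None):
    v = np.asarray(values, float)
    return OmicsMatrix(
        layer=layer,
        stage=stage,
        values=pd.DataFrame(
            v,
            index=samples or [f"S{i}" for i in range(v.shape[0])],
            columns=genes or [f"g{j}" for j in range(v.shape[1])],
        ),
    )


class TestLogCpm:
    def test_single_gene_full_library_closed_form(self):
        m = mk([[1e6]])
        out = preprocess.counts_to_log_cpm(m)
        expect = np.log2(1e6 * (1e6 + 0.5) / (1e6 + 1))
        assert abs(out.values.iloc[0, 0] - expect) < 1e-9

    def test_all_zero_gene_constant_minimum(self):
        m = mk([[0, 10, 30], [0, 20, 60]])
        out = preprocess.counts_to_log_cpm(m).values
        assert (out["g0"] == out.min(axis=1)).all()

    def test_doubling_counts_leaves_cpm_unchanged(self):
        # scale invariance is exact up to the pseudocount, so large counts
        base = np.array([[4e5, 1e6, 6e5]])
        a = preprocess.counts_to_log_cpm(mk(base)).values.to_numpy()
        b = preprocess.counts_to_log_cpm(mk(2 * base)).values.to_numpy()
        assert np.abs(a - b).max() < 1e-6

    def test_zero_total_sample_names_sample(self):
        with pytest.raises(ValueError, match="S1"):
            preprocess.counts_to_log_cpm(mk([[1, 2], [0, 0]]))


class TestFilter:
    def test_exactly_75_percent_low_is_kept(self):
        # below threshold in 3 of 4 samples = 75%, not "more than" -> kept
        m = mk([[5], [-1], [-1], [-1]], stage="log_cpm")
        out = preprocess.filter_low_expression(m, threshold=0.0, max_fraction=0.75)
        assert list(out.values.columns) == ["g0"]

    def test_all_low_removed(self):
        m = mk([[-1], [-1], [-1], [-1]], stage="log_cpm")
        out = preprocess.filter_low_expression(m, threshold=0.0, max_fraction=0.75)
        assert out.values.shape[1] == 0

    def test_minus_inf_threshold_keeps_all(self):
        m = mk(np.random.default_rng(0).normal(size=(5, 7)), stage="log_cpm")
        out = preprocess.filter_low_expression(m, threshold=-np.inf)
        assert out.values.shape == m.values.shape

    def test_survivor_order_preserved(self):
        rng = np.random.default_rng(1)
        m = mk(rng.normal(size=(8, 20)), stage="log_cpm")
        out = preprocess.filter_low_expression(m, threshold=-0.5, max_fraction=0.4)
        survivors = list(out.values.columns)
        assert survivors == [g for g in m.values.columns if g in survivors]


class TestOutliers:
    def test_iid_samples_produce_no_flags(self):
        rng = np.random.default_rng(3)
        m = mk(rng.normal(size=(100, 300)), stage="log_cpm")
        assert preprocess.flag_outlier_samples(m, z_cutoff=-5.0) == []

    def test_noise_sample_has_minimal_connectivity(self):
        rng = np.random.default_rng(4)
        shared = rng.normal(size=300)
        data = shared + 0.3 * rng.normal(size=(50, 300))
        data[17] = rng.normal(size=300)  # independent of everyone
        m = mk(data, stage="log_cpm")
        flagged = preprocess.flag_outlier_samples(m, z_cutoff=-2.0)
        assert "S17" in flagged

    def test_two_samples_rejected(self):
        with pytest.raises(ValueError):
            preprocess.flag_outlier_samples(mk([[1, 2], [3, 4]], stage="log_cpm"))

    def test_constant_sample_flagged_with_warning(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(12, 50))
        data[3] = 7.0
        with pytest.warns(UserWarning):
            flagged = preprocess.flag_outlier_samples(mk(data, stage="log_cpm"), -5.0)
        assert "S3" in flagged


class TestQuantileNormalize:
    def test_hand_computed_two_samples(self):
        m = mk([[1, 2, 3], [4, 5, 6]], stage="log_cpm")
        out = preprocess.quantile_normalize(m).values.to_numpy()
        assert np.allclose(out, [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    def test_identical_multisets_unchanged(self):
        m = mk([[3, 1, 2], [1, 2, 3]], stage="log_cpm")
        out = preprocess.quantile_normalize(m).values.to_numpy()
        assert np.allclose(out, [[3, 1, 2], [1, 2, 3]])

    def test_per_sample_means_equalized(self):
        rng = np.random.default_rng(6)
        m = mk(rng.normal(size=(10, 40)) * rng.uniform(1, 5, size=(10, 1)), stage="log_cpm")
        out = preprocess.quantile_normalize(m).values.to_numpy()
        assert np.ptp(out.mean(axis=1)) < 1e-9

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        m = mk(rng.normal(size=(6, 15)), stage="log_cpm")
        once = preprocess.quantile_normalize(m)
        twice = preprocess.quantile_normalize(
            OmicsMatrix(layer="mrna", stage="log_cpm", values=once.values)
        )
        assert np.abs(once.values.to_numpy() - twice.values.to_numpy()).max() < 1e-9

    def test_tie_handling_averages_reference(self):
        m = mk([[1, 1, 5], [2, 4, 6]], stage="log_cpm")
        out = preprocess.quantile_normalize(m).values.to_numpy()
        # sample 0 ties at rank 0/1: both get mean of reference[0:2]
        ref = np.array([(1 + 2) / 2, (1 + 4) / 2, (5 + 6) / 2])
        assert np.allclose(out[0], [ref[:2].mean(), ref[:2].mean(), ref[2]])


class TestFactors:
    def test_rank_one_signal_dominates(self):
        rng = np.random.default_rng(7)
        u, v = rng.normal(size=(80, 1)), rng.normal(size=(1, 60))
        m = mk(u @ v + 0.01 * rng.normal(size=(80, 60)), stage="quantile_normalized")
        fs = preprocess.estimate_hidden_factors(m, 3)
        assert fs.variance_explained[0] > 0.95

    def test_iid_noise_elbow_small(self):
        rng = np.random.default_rng(5)
        m = mk(rng.normal(size=(100, 500)), stage="quantile_normalized")
        assert preprocess.select_n_factors(m) <= 3

    def test_factors_orthogonal(self):
        rng = np.random.default_rng(8)
        m = mk(rng.normal(size=(50, 100)), stage="quantile_normalized")
        fs = preprocess.estimate_hidden_factors(m, 10)
        c = np.corrcoef(fs.factors.to_numpy(), rowvar=False)
        assert np.abs(c - np.eye(10)).max() < 1e-8

    def test_too_many_factors_rejected(self):
        m = mk(np.random.default_rng(9).normal(size=(10, 5)), stage="quantile_normalized")
        with pytest.raises(ValueError):
            preprocess.estimate_hidden_factors(m, 5)


class TestResidualize:
    def _factors(self, arr, samples):
        return FactorSet(
            factors=pd.DataFrame(
                np.asarray(arr, float), index=samples,
                columns=[f"PC{i}" for i in range(np.asarray(arr).shape[1])],
            ),
            variance_explained=np.zeros(np.asarray(arr).shape[1]),
        )

    def test_orthogonal_factor_gives_standardized_original(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=40)
        f = rng.normal(size=40)
        f -= f @ (y - y.mean()) / ((y - y.mean()) @ (y - y.mean())) * (y - y.mean())
        m = mk(y[:, None], stage="quantile_normalized")
        out = preprocess.residualize(m, self._factors(f[:, None], m.sample_ids))
        expect = (y - y.mean()) / (y - y.mean()).std()
        # residualizing an orthogonal factor changes nothing beyond scaling
        assert np.abs(out.values.to_numpy().ravel() - expect).max() < 0.15

    def test_output_standardized(self):
        rng = np.random.default_rng(11)
        m = mk(rng.normal(size=(60, 20)), stage="quantile_normalized")
        fs = self._factors(rng.normal(size=(60, 3)), m.sample_ids)
        out = preprocess.residualize(m, fs).values.to_numpy()
        assert np.abs(out.mean(axis=0)).max() < 1e-8
        assert np.abs(out.std(axis=0) - 1).max() < 1e-8

    def test_gene_equal_to_factor_dropped(self):
        rng = np.random.default_rng(12)
        f = rng.normal(size=30)
        data = np.column_stack([f, rng.normal(size=30)])
        m = mk(data, stage="quantile_normalized")
        with pytest.warns(UserWarning, match="zero residual variance"):
            out = preprocess.residualize(m, self._factors(f[:, None], m.sample_ids))
        assert list(out.values.columns) == ["g1"]

    def test_collinear_factors_rejected(self):
        rng = np.random.default_rng(13)
        f = rng.normal(size=30)
        m = mk(rng.normal(size=(30, 4)), stage="quantile_normalized")
        fs = self._factors(np.column_stack([f, 2 * f]), m.sample_ids)
        with pytest.raises(ValueError, match="collinear"):
            preprocess.residualize(m, fs)

    def test_removes_hidden_confounding(self):
        # cascade with 5 hidden factors: residuals decorrelate from truth
        g = simulate.simulate_genotypes(200, 120, ld_block_size=3, seed=14)
        truth = simulate.make_cascade_truth(g, 40, seed=14, factor_sd=0.6)
        rng = np.random.default_rng(14)
        latent, F = simulate._latent_layers(g, truth, rng)
        m = OmicsMatrix(
            layer="protein", stage="quantile_normalized",
            values=pd.DataFrame(latent["protein"], index=g.sample_ids,
                                columns=truth.gene_ids),
        )
        fs = preprocess.estimate_hidden_factors(m, 5)
        out = preprocess.residualize(m, fs).values.to_numpy()
        cors = np.abs(np.corrcoef(out.T, F.T)[:40, 40:])
        assert cors.mean() < 0.05


class TestIsoforms:
    def test_highest_median_chosen(self):
        m = mk([[3.0, 5.0], [3.2, 5.0]], stage="log_cpm", genes=["iso1", "iso2"])
        out = preprocess.select_representative_isoform(
            m, {"iso1": "geneA", "iso2": "geneA"}
        )
        assert list(out.values.columns) == ["geneA"]
        assert np.allclose(out.values["geneA"], [5.0, 5.0])

    def test_single_isoform_passthrough(self):
        m = mk([[1.0], [2.0]], stage="log_cpm", genes=["iso1"])
        out = preprocess.select_representative_isoform(m, {"iso1": "geneA"})
        assert np.allclose(out.values["geneA"], [1.0, 2.0])

    def test_median_tie_lexicographic(self):
        m = mk([[4.0, 4.0], [6.0, 6.0]], stage="log_cpm", genes=["isoB", "isoA"])
        out = preprocess.select_representative_isoform(
            m, {"isoA": "geneA", "isoB": "geneA"}
        )
        # equal medians: lexicographically first isoform id wins
        assert np.allclose(out.values["geneA"], m.values["isoA"])

    def test_unmapped_isoform_dropped_with_warning(self):
        m = mk([[1.0, 2.0]], stage="log_cpm", genes=["iso1", "isoX"])
        with pytest.warns(UserWarning, match="isoX"):
            out = preprocess.select_representative_isoform(m, {"iso1": "geneA"})
        assert list(out.values.columns) == ["geneA"]


def test_stage_transitions_only_forward():
    m = mk([[1.0]], stage="quantile_normalized")
    with pytest.raises(ValueError, match="backward"):
        m.advance("log_cpm", m.values)


def test_missing_value_imputation_uses_gene_minimum():
    m = mk([[1.0, np.nan], [3.0, 5.0]], layer="protein", stage="log_cpm")
    out = preprocess.impute_missing_min(m)
    assert out.values.iloc[0, 1] == 5.0
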