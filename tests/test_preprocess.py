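"""Normalization, ΔΔCt and significance-gate behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

import rarobust as rr
from rarobust.preprocess import anova_two_way

from conftest import make_matrix


def _meta(sample_ids, **overrides):
    rows = []
    for s in sample_ids:
        row = {"sample_id": s, "clutch": "X", "treatment": "Control",
               "time_h": 0.0, "assay": "rnaseq"}
        row.update({k: v[s] if isinstance(v, dict) else v for k, v in overrides.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


class TestFilterMinExpression:
    def test_below_threshold_everywhere_removed(self):
        m = make_matrix({"s1": [4, 10], "s2": [4, 0]},
                        _meta(["s1", "s2"]).reset_index().to_dict("records"),
                        scale="counts")
        out = rr.filter_min_expression(m, 5)
        assert out.gene_ids == [1]

    def test_single_sample_at_threshold_retained(self):
        values = pd.DataFrame([np.r_[np.zeros(71), 5.0]], index=["g"])
        meta = _meta(values.columns)
        m = rr.ExpressionMatrix(values, meta, "counts")
        assert rr.filter_min_expression(m, 5).gene_ids == ["g"]

    def test_planted_zero_genes_counted(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.uniform(5, 100, size=(90, 6)))
        values = pd.concat([values, pd.DataFrame(np.zeros((10, 6)))], ignore_index=True)
        m = rr.ExpressionMatrix(values, _meta(values.columns), "counts")
        assert rr.filter_min_expression(m, 5).n_genes == 90

    def test_wrong_scale_flagged(self):
        m = make_matrix({"s1": [1.0], "s2": [2.0]},
                        _meta(["s1", "s2"]).reset_index().to_dict("records"),
                        scale="log2")
        with pytest.raises(ValueError, match="counts-scale"):
            rr.filter_min_expression(m, 5)


class TestLog2Transform:
    @pytest.mark.parametrize("count,expected", [(0, 0.0), (7, 3.0), (1023, 10.0)])
    def test_pseudocount_one(self, count, expected):
        m = make_matrix({"s1": [count], "s2": [count]},
                        _meta(["s1", "s2"]).reset_index().to_dict("records"),
                        scale="counts")
        out = rr.log2_transform(m, pseudocount=1)
        assert out.scale == "log2"
        assert out.values.iloc[0, 0] == pytest.approx(expected)

    def test_negative_input_rejected(self):
        m = make_matrix({"s1": [-1.0], "s2": [1.0]},
                        _meta(["s1", "s2"]).reset_index().to_dict("records"),
                        scale="counts")
        with pytest.raises(ValueError, match="negative"):
            rr.log2_transform(m)


class TestQuantileNormalize:
    def test_two_sample_hand_example(self):
        m = make_matrix({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
                        _meta(["s1", "s2"]).reset_index().to_dict("records"))
        out = rr.quantile_normalize(m)
        np.testing.assert_allclose(out.values["s1"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.values["s2"], [2.5, 3.5, 4.5])

    def test_identical_samples_fixed_point(self):
        m = make_matrix({"s1": [3.0, 1.0, 2.0], "s2": [3.0, 1.0, 2.0]},
                        _meta(["s1", "s2"]).reset_index().to_dict("records"))
        out = rr.quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_ties_get_mean_of_tied_order_statistic_means(self):
        m = make_matrix({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 4.0, 6.0]},
                        _meta(["s1", "s2"]).reset_index().to_dict("records"))
        out = rr.quantile_normalize(m)
        sorted_means = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)  # 1.5, 2.5, 5.5
        np.testing.assert_allclose(
            out.values["s1"], [sorted_means[:2].mean()] * 2 + [sorted_means[2]]
        )

    def test_single_sample_rejected(self):
        values = pd.DataFrame({"s1": [1.0, 2.0]})
        m = rr.ExpressionMatrix(values, _meta(["s1"]), "log2")
        with pytest.raises(ValueError, match="at least 2 samples"):
            rr.quantile_normalize(m)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_sorted_columns_identical_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(rng.normal(size=(30, 5)))  # continuous: no ties
        m = rr.ExpressionMatrix(values, _meta(values.columns), "log2")
        out = rr.quantile_normalize(m).values.to_numpy()
        ref = np.sort(out, axis=0)
        assert np.abs(ref - ref[:, [0]]).max() < 1e-9

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_ranks_preserved_even_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(rng.normal(size=(30, 5)).round(1))  # rounding forces ties
        m = rr.ExpressionMatrix(values, _meta(values.columns), "log2")
        out = rr.quantile_normalize(m).values.to_numpy()
        for j in range(out.shape[1]):
            orig = rankdata(values.iloc[:, j], method="average")
            new = rankdata(out[:, j], method="average")
            np.testing.assert_allclose(orig, new)


class TestZscoreGenes:
    def test_rows_standardized(self):
        m = make_matrix({"s1": [1.0], "s2": [2.0], "s3": [3.0]},
                        _meta(["s1", "s2", "s3"]).reset_index().to_dict("records"))
        out = rr.zscore_genes(m)
        assert out.scale == "zscore"
        assert out.values.iloc[0].mean() == pytest.approx(0.0, abs=1e-12)
        assert out.values.iloc[0].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_gene_dropped_with_warning(self):
        m = make_matrix({"s1": [5.0, 1.0], "s2": [5.0, 2.0], "s3": [5.0, 4.0]},
                        _meta(["s1", "s2", "s3"]).reset_index().to_dict("records"))
        with pytest.warns(UserWarning, match="constant"):
            out = rr.zscore_genes(m)
        assert out.gene_ids == [1]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(size=(10, 6)))
        m = rr.ExpressionMatrix(values, _meta(values.columns), "log2")
        once = rr.zscore_genes(m)
        twice = rr.zscore_genes(once)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)


class TestDeltaDeltaCt:
    def _table(self, records):
        frame = pd.DataFrame(
            records, columns=["gene_id", "sample_id", "preamp_group", "tech_replicate", "ct"]
        )
        samples = _meta(sorted(frame["sample_id"].unique()),
                        treatment={"ref": "Control", "trt": "RA"},
                        time_h=0.0)
        return rr.CtTable(records=frame, samples=samples, housekeeping="gapdh")

    def test_one_cycle_lower_is_plus_one_log2(self):
        records = []
        for s, ct_target in (("ref", 20.0), ("trt", 19.0)):
            records.append(("tbx", s, 1, 1, ct_target))
            records.append(("gapdh", s, 1, 1, 15.0))
        out = rr.delta_delta_ct(self._table(records))
        assert out.values.at["tbx", "trt"] == pytest.approx(1.0)
        assert out.values.at["tbx", "ref"] == pytest.approx(0.0)

    def test_preamp_group_median(self):
        records = [("tbx", "ref", g, 1, ct) for g, ct in ((1, 20.0), (2, 21.0), (3, 30.0))]
        records += [("gapdh", "ref", 1, 1, 15.0), ("gapdh", "trt", 1, 1, 15.0)]
        records += [("tbx", "trt", 1, 1, 21.0)]
        from rarobust.preprocess import collapse_ct

        collapsed = collapse_ct(self._table(records))
        assert collapsed.at["tbx", "ref"] == pytest.approx(21.0)

    def test_round_trip_recovers_simulated_expression(self, small_noise_free):
        _, matrix, ct, _ = small_noise_free
        out = rr.delta_delta_ct(ct)
        meta = matrix.samples
        for s in out.sample_ids[:10]:
            ref = f"{meta.loc[s, 'clutch']}_Control_0h"
            expected = matrix.values.loc[out.gene_ids, s] - matrix.values.loc[out.gene_ids, ref]
            np.testing.assert_allclose(out.values[s], expected, atol=1e-9)

    def test_missing_reference_clutch_rejected(self):
        records = [("tbx", "trt", 1, 1, 20.0), ("gapdh", "trt", 1, 1, 15.0)]
        frame = pd.DataFrame(
            records, columns=["gene_id", "sample_id", "preamp_group", "tech_replicate", "ct"]
        )
        samples = _meta(["trt"], treatment="RA")
        table = rr.CtTable(records=frame, samples=samples, housekeeping="gapdh")
        with pytest.raises(ValueError, match="reference"):
            rr.delta_delta_ct(table)


class TestCombineAssays:
    def test_study_grid_combines_to_144(self, small_noisy):
        _, matrix, ct, _ = small_noisy
        rnaseq = matrix.subset_samples((matrix.samples["assay"] == "rnaseq").to_numpy())
        z_r = rr.zscore_genes(rnaseq)
        z_q = rr.zscore_genes(rr.delta_delta_ct(ct))
        combined = rr.combine_assays(z_r, z_q)
        assert combined.n_samples == 144
        assert set(combined.gene_ids) == set(z_q.gene_ids) & set(z_r.gene_ids)

    def test_disjoint_panels_rejected(self):
        a = make_matrix({"s1": [0.5], "s2": [-0.5]},
                        _meta(["s1", "s2"]).reset_index().to_dict("records"), "zscore")
        b = make_matrix({"s3": [0.5], "s4": [-0.5]},
                        _meta(["s3", "s4"]).reset_index().to_dict("records"), "zscore")
        b.values.index = ["other_gene"]
        with pytest.raises(ValueError, match="intersect"):
            rr.combine_assays(a, b)

    def test_self_combination_doubles_columns(self):
        a = make_matrix({"s1": [0.5, 1.0], "s2": [-0.5, -1.0]},
                        _meta(["s1", "s2"]).reset_index().to_dict("records"), "zscore")
        b = rr.ExpressionMatrix(
            a.values.rename(columns={"s1": "t1", "s2": "t2"}),
            a.samples.rename(index={"s1": "t1", "s2": "t2"}),
            "zscore",
        )
        out = rr.combine_assays(a, b)
        assert out.n_samples == 4
        np.testing.assert_allclose(out.values["t1"], out.values["s1"])


class TestSignificanceFilter:
    @staticmethod
    def _design_matrix(seed=0, n_genes=40, effect_genes=0, effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for clutch in "ABC":
            for trt in ("Control", "RA", "DEAB"):
                for t in (0.0, 1.5, 3.0, 4.5):
                    rows.append({"sample_id": f"{clutch}_{trt}_{t:g}",
                                 "clutch": clutch, "treatment": trt,
                                 "time_h": t, "assay": "rnaseq"})
        meta = pd.DataFrame(rows).set_index("sample_id")
        values = rng.normal(size=(n_genes, len(meta)))
        for g in range(effect_genes):
            bump = np.where(meta["treatment"] == "RA", effect, 0.0)
            values[g] += bump
        frame = pd.DataFrame(values, columns=meta.index)
        return rr.ExpressionMatrix(frame, meta, "log2")

    def test_anova_matches_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        matrix = self._design_matrix(seed=3, n_genes=5)
        table = anova_two_way(matrix)
        for gene in matrix.gene_ids:
            data = matrix.samples.assign(y=matrix.values.loc[gene].to_numpy())
            fit = smf.ols("y ~ C(time_h) * C(treatment)", data=data).fit()
            ref = sm.stats.anova_lm(fit, typ=2)
            assert table.at[gene, "p_time"] == pytest.approx(ref.loc["C(time_h)", "PR(>F)"], rel=1e-6)
            assert table.at[gene, "p_treatment"] == pytest.approx(
                ref.loc["C(treatment)", "PR(>F)"], rel=1e-6)
            assert table.at[gene, "p_interaction"] == pytest.approx(
                ref.loc["C(time_h):C(treatment)", "PR(>F)"], rel=1e-6)

    def test_planted_strong_effects_all_recovered(self):
        matrix = self._design_matrix(seed=4, n_genes=100, effect_genes=50, effect=4.0)
        hits = rr.significance_filter(matrix, 0.05)
        assert set(matrix.gene_ids[:50]).issubset(hits)

    def test_zero_threshold_returns_nothing(self):
        matrix = self._design_matrix(seed=5, n_genes=30)
        assert rr.significance_filter(matrix, 0.0) == []

    def test_unreplicated_cells_rejected(self):
        matrix = self._design_matrix(seed=6, n_genes=5)
        one_clutch = matrix.subset_samples((matrix.samples["clutch"] == "A").to_numpy())
        with pytest.raises(ValueError, match="unreplicated"):
            rr.significance_filter(one_clutch)

    def test_null_false_positive_fraction_controlled(self):
        rates = []
        for seed in range(20):
            matrix = self._design_matrix(seed=100 + seed, n_genes=60)
            hits = rr.significance_filter(matrix, 0.05)
            rates.append(len(hits) / matrix.n_genes)
        assert float(np.mean(rates)) <= 0.05
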