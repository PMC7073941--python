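"""Prevalence filtering, imputation, scaling, PCA and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ccmquant.errors import ValidationError
from ccmquant.stats import (
    autoscale,
    class_composition,
    group_means,
    impute_min,
    log2_fold_change,
    magnitude_heatmap,
    pca,
    prevalence_filter,
    ttest_fdr,
)


def make_matrix(data, groups):
    """samples x metabolites matrix with a (group_id, sample_id) index."""
    index = pd.MultiIndex.from_tuples(
        [(g, f"{g}_r{i}") for i, g in enumerate(groups)], names=["group_id", "sample_id"]
    )
    df = pd.DataFrame(data, index=index)
    if not isinstance(data, dict):
        df.columns = [f"m{j}" for j in range(df.shape[1])]
    df.columns.name = "metabolite_id"
    return df


class TestPrevalenceFilter:
    def build(self, n_groups_present):
        groups = [f"g{k}" for k in range(8)]
        col = [1.0 if int(g[1]) < n_groups_present else np.nan for g in groups]
        return make_matrix({"a": col, "b": [1.0] * 8}, groups)

    def test_majority_retained(self):
        out = prevalence_filter(self.build(5).rename(columns={"a": "m", "b": "k"}))
        assert set(out.columns) == {"m", "k"}

    def test_half_dropped_strict_inequality(self):
        mat = self.build(4)
        out = prevalence_filter(mat)
        assert list(out.columns) == [mat.columns[1]]

    def test_all_present_unchanged(self):
        mat = make_matrix(np.ones((8, 3)), [f"g{k}" for k in range(8)])
        assert prevalence_filter(mat).equals(mat)


class TestImputeMin:
    def test_minimum_rule(self):
        mat = make_matrix({"a": [1.0, 2.0, np.nan]}, ["g1", "g1", "g2"])
        assert list(impute_min(mat)["a"]) == [1.0, 2.0, 1.0]

    def test_multiple_missing_same_minimum(self):
        mat = make_matrix({"a": [5.0, np.nan, np.nan]}, ["g1", "g1", "g2"])
        assert list(impute_min(mat)["a"]) == [5.0, 5.0, 5.0]

    def test_identity_without_missing(self):
        mat = make_matrix(np.arange(6.0).reshape(3, 2), ["g1", "g1", "g2"])
        assert impute_min(mat).equals(mat)


class TestAutoscale:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(5)
        mat = make_matrix(rng.lognormal(size=(10, 4)), [f"g{k % 2}" for k in range(10)])
        z = autoscale(mat)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_two_point_closed_form(self):
        mat = make_matrix({"a": [1.0, 3.0]}, ["g1", "g2"])
        assert np.allclose(autoscale(mat)["a"], [-0.70710678, 0.70710678])

    def test_constant_column_named_in_error(self):
        mat = make_matrix({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}, ["g1", "g1", "g2"])
        with pytest.raises(ValidationError, match="a"):
            autoscale(mat)


class TestPca:
    def test_rank_one_matrix(self):
        v = np.array([1.0, -2.0, 0.5])
        scores = np.array([[1.0], [2.0], [-1.0], [-2.0]])
        mat = make_matrix(scores @ v[None, :], ["g1", "g1", "g2", "g2"])
        res = pca(mat, n_components=1)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(11)
        mat = make_matrix(rng.normal(size=(6, 4)), [f"g{k % 3}" for k in range(6)])
        z = autoscale(mat)
        res = pca(z, n_components=4)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + z.to_numpy().mean(0)
        assert np.abs(recon - z.to_numpy()).max() < 1e-8
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(res.explained_variance_fraction) <= 1e-12).all()

    def test_groups_cluster_in_scores(self, default_bundle):
        """Group-structured ground truth should produce group-separated
        PC1/PC2 scores (positive mean silhouette)."""
        from sklearn.metrics import silhouette_score

        scores = default_bundle["pca"].scores
        labels = scores.index.get_level_values("group_id")
        assert silhouette_score(scores.to_numpy(), labels) > 0

    def test_ellipses_cover_groups(self, default_bundle):
        ell = default_bundle["pca"].ellipses
        assert set(ell["group_id"]) == set(
            default_bundle["matrix"].index.get_level_values("group_id")
        )
        assert (ell["semi_axis_major"] >= ell["semi_axis_minor"]).all()


def bh_oracle(p):
    """Brute-force Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestTtestFdr:
    def test_worked_pair_matches_pooled_formula(self):
        a, b = [1.0, 2, 3, 4, 5], [2.0, 3, 4, 5, 6]
        mat = make_matrix({"a": a + b}, ["ga"] * 5 + ["gb"] * 5)
        res = ttest_fdr(mat, "ga", "gb")
        na = nb = 5
        sp2 = (np.var(a, ddof=1) * (na - 1) + np.var(b, ddof=1) * (nb - 1)) / (na + nb - 2)
        t_expect = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_expect = 2 * sps.t.sf(abs(t_expect), na + nb - 2)
        assert res["t_statistic"].iloc[0] == pytest.approx(t_expect)
        assert res["p_value"].iloc[0] == pytest.approx(p_expect)

    def test_identical_groups_not_significant(self):
        col = [1.0, 2, 3, 4, 5]
        mat = make_matrix({"a": col + col}, ["ga"] * 5 + ["gb"] * 5)
        res = ttest_fdr(mat, "ga", "gb")
        assert res["p_value"].iloc[0] > 0.99
        assert not res["significant"].any()

    def test_bh_qvalues_match_brute_force(self):
        pvec = [0.01, 0.02, 0.03, 0.5]
        rng = np.random.default_rng(3)
        mats = []
        # embed the p-vector via statsmodels directly against the oracle
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 30))
            _, q, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(q, bh_oracle(p), atol=1e-12)
        _, q, _, _ = multipletests(pvec, method="fdr_bh")
        assert np.allclose(q, bh_oracle(pvec))

    def test_small_group_rejected(self):
        mat = make_matrix({"a": [1.0, 2.0, 3.0]}, ["ga", "gb", "gb"])
        with pytest.raises(ValidationError):
            ttest_fdr(mat, "ga", "gb")


class TestLog2FoldChange:
    def test_four_fold(self):
        assert log2_fold_change(4e-3, 1e-3) == pytest.approx(2.0)

    def test_identity_and_antisymmetry(self):
        assert log2_fold_change(5.0, 5.0) == 0.0
        assert log2_fold_change(1.0, 2.0) == pytest.approx(-log2_fold_change(2.0, 1.0))

    def test_nonpositive_mean_absent(self):
        assert np.isnan(log2_fold_change(0.0, 1.0))


class TestClassComposition:
    def test_single_class_is_hundred_percent(self, panel):
        aa = [m.metabolite_id for m in panel.by_class("amino_acid")]
        means = pd.DataFrame([[1.0] * len(aa)], index=["g1"], columns=aa)
        comp = class_composition(means, panel)
        assert comp.loc[comp["met_class"] == "amino_acid", "percent"].iloc[0] == pytest.approx(100.0)

    def test_percentages_sum_to_hundred(self, default_bundle, panel):
        comp = default_bundle["compositions"]
        sums = comp.groupby("group_id")["percent"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_dominant_osmolyte_share(self, panel):
        """A single metabolite holding 34% of the total pool reports a 34%
        contribution (the microalgal proline situation)."""
        mids = panel.metabolite_ids
        means = pd.DataFrame([[1.0] * len(mids)], index=["alga"], columns=mids, dtype=float)
        others_total = len(mids) - 1
        means.loc["alga", "pro"] = 0.34 / 0.66 * others_total
        comp = class_composition(means, panel)
        total = means.loc["alga"].sum()
        assert means.loc["alga", "pro"] / total == pytest.approx(0.34)
        aa_share = comp.loc[comp["met_class"] == "amino_acid", "percent"].iloc[0]
        assert aa_share > 34.0  # class share includes the osmolyte


class TestMagnitudeHeatmap:
    def test_floor_convention(self):
        means = pd.DataFrame({"a": [2.3e-4], "b": [1e-3], "c": [9.99e-3]}, index=["g"])
        heat = magnitude_heatmap(means)
        assert list(heat.loc["g"]) == [-4, -3, -3]

    def test_absent_for_nonpositive(self):
        means = pd.DataFrame({"a": [0.0], "b": [np.nan]}, index=["g"])
        heat = magnitude_heatmap(means)
        assert heat.isna().all().all()

    def test_recovered_study_spans(self, default_bundle):
        heat = magnitude_heatmap(group_means(default_bundle["matrix"]))
        per_group = heat.max(axis=1) - heat.min(axis=1)
        assert (per_group >= 3).all()
        panel_span = int(heat.max().max() - heat.min().min())
        assert 6 <= panel_span <= 8
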