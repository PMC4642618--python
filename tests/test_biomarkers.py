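import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ipf
from ipf.biomarkers import anova_select, group_summary, heatmap_export, module_discovery
from ipf.datasets import OmicsDataset


def _labels(groups):
    out = []
    for g, n in enumerate(groups, start=1):
        out += [g] * n
    return pd.Series(out, index=[f"s{i}" for i in range(sum(groups))])


class TestAnovaSelect:
    def test_f_matches_textbook_arithmetic(self):
        # 3 groups of 4, hand-checkable values
        vals = [3.0, 4.0, 5.0, 4.0, 6.0, 7.0, 8.0, 7.0, 10.0, 11.0, 12.0, 11.0]
        labels = _labels([4, 4, 4])
        ds = OmicsDataset(
            "e",
            pd.DataFrame({"f": vals, "g": np.arange(12.0)}, index=labels.index),
        )
        res = anova_select([ds], labels, alpha=0.05)
        row = res[res.feature_id == "f"].iloc[0]
        # oracle: between/within mean squares computed directly
        F_ref, p_ref = stats.f_oneway(vals[:4], vals[4:8], vals[8:])
        assert row.f_stat == pytest.approx(F_ref, rel=1e-12)
        assert row.p_value == pytest.approx(p_ref, rel=1e-10)
        # group means 4/7/11, grand mean 22/3: between MS = 148/3,
        # within MS = 2/3 -> F = 74
        assert row.f_stat == pytest.approx(74.0, rel=1e-10)

    def test_constant_feature_null(self):
        labels = _labels([3, 3])
        ds = OmicsDataset(
            "e", pd.DataFrame({"f": [5.0] * 6, "g": np.arange(6.0)}, index=labels.index)
        )
        res = anova_select([ds], labels, alpha=0.05)
        row = res[res.feature_id == "f"].iloc[0]
        assert row.f_stat == 0.0 and row.p_value == 1.0

    def test_perfect_group_indicator_significant(self):
        labels = _labels([5, 5, 5])
        ds = OmicsDataset(
            "e",
            pd.DataFrame(
                {"ind": labels.to_numpy().astype(float), "g": np.arange(15.0)},
                index=labels.index,
            ),
        )
        res = anova_select([ds], labels, alpha=1e-10)
        assert bool(res[res.feature_id == "ind"].iloc[0].significant)

    def test_bonferroni_is_monotone_and_capped(self):
        rng = np.random.default_rng(0)
        labels = _labels([10, 10, 10])
        ds = OmicsDataset(
            "e",
            pd.DataFrame(
                rng.normal(size=(30, 20)), index=labels.index,
                columns=[f"f{j}" for j in range(20)],
            ),
        )
        res = anova_select([ds], labels, alpha=0.05)
        assert (res.p_adjusted <= 1.0).all()
        by_raw = res.sort_values("p_value")
        # adjusted p is a monotone transform of raw p (ties at the 1.0 cap)
        assert (np.diff(by_raw.p_adjusted.to_numpy()) >= -1e-15).all()
        uncapped = res[res.p_adjusted < 1.0]
        np.testing.assert_allclose(
            uncapped.p_adjusted, uncapped.p_value * 20, rtol=1e-12
        )

    def test_cluster_subset_restriction(self):
        labels = _labels([4, 4, 4])
        rng = np.random.default_rng(1)
        ds = OmicsDataset(
            "e",
            pd.DataFrame(rng.normal(size=(12, 3)), index=labels.index,
                         columns=["a", "b", "c"]),
        )
        res = anova_select([ds], labels, alpha=0.05, clusters=[1, 3])
        assert len(res) == 3  # still all features, but on 2 groups

    def test_sensitivity_and_fdr_on_planted_signal(self):
        spec = ipf.SimSpec(
            n_samples=90,
            k_true=3,
            effect_size=2.0,
            noise_fraction=0.5,
            omics_specs=[ipf.OmicsSpec(n_features=60)],
            seed=4,
        )
        res = ipf.simulate(spec)
        ds, mask = res.datasets[0], res.informative_mask[0]
        table = anova_select([ds], res.true_labels, alpha=0.05 / ds.n_features)
        sel = table[table.significant].feature_id
        informative = set(np.array(ds.feature_ids)[mask])
        sens = len(set(sel) & informative) / len(informative)
        fdr = len(set(sel) - informative) / max(len(sel), 1)
        assert sens >= 0.9
        assert fdr <= 0.1


class TestModuleDiscovery:
    def test_flip_restores_anticorrelated_pair(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        vals = pd.DataFrame(
            [base + 0.1 * rng.normal(size=30), -base + 0.1 * rng.normal(size=30),
             rng.normal(size=30), rng.normal(size=30)],
            index=["mrna1", "mir1", "n1", "n2"],
        )
        out = module_discovery(vals, flip_set=["mir1"], g_max=3, B=10, seed=0)
        mods = out.assignments.set_index("feature_id")["module"]
        assert mods["mrna1"] == mods["mir1"]
        assert out.assignments.set_index("feature_id")["sign_flipped"]["mir1"]

    def test_empty_flip_set_identity(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(6, 25)),
                            index=[f"f{i}" for i in range(6)])
        a = module_discovery(vals, flip_set=[], g_max=3, B=10, seed=0)
        b = module_discovery(vals, flip_set=None, g_max=3, B=10, seed=0)
        pd.testing.assert_frame_equal(a.assignments, b.assignments)
        pd.testing.assert_frame_equal(a.flipped_values, vals)

    def test_planted_modules_recovered_with_flip(self):
        hits = 0
        runs = 10
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            lat = rng.normal(size=(4, 60))
            mod = np.repeat(np.arange(4), 12)
            F = lat[mod] + 0.4 * rng.normal(size=(48, 60))
            flip = [f"f{i}" for i in range(0, 48, 7)]  # scattered "miRNAs"
            ids = [f"f{i}" for i in range(48)]
            vals = pd.DataFrame(F, index=ids)
            vals.loc[flip] = -vals.loc[flip]  # inhibitory species observed inverted
            out = module_discovery(vals, flip_set=flip, g_max=8, B=10, seed=seed)
            hits += out.G == 4
            # flip restores positive within-module correlation
            R = np.corrcoef(out.flipped_values.to_numpy())
            within = [R[i, j] for i in range(48) for j in range(i + 1, 48)
                      if mod[i] == mod[j]]
            between = [R[i, j] for i in range(48) for j in range(i + 1, 48)
                       if mod[i] != mod[j]]
            assert np.mean(within) > np.mean(between)
        assert hits > runs / 2

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            module_discovery(pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"]))


class TestGroupSummary:
    def test_kruskal_matches_scipy_oracle(self):
        labels = _labels([4, 4, 4])
        vals = np.array([1.0, 2, 3, 4, 10, 11, 12, 13, 20, 21, 22, 23])
        ds = OmicsDataset("c", pd.DataFrame({"v": vals}, index=labels.index))
        out = group_summary(ds, labels).set_index("variable")
        ref = stats.kruskal(vals[:4], vals[4:8], vals[8:]).pvalue
        assert out.loc["v", "kw_p"] == pytest.approx(ref, rel=1e-12)
        ref12 = stats.kruskal(vals[:4], vals[4:8]).pvalue
        assert out.loc["v", "p_1_vs_2"] == pytest.approx(ref12, rel=1e-12)

    def test_constant_variable_null_p(self):
        labels = _labels([3, 3])
        ds = OmicsDataset("c", pd.DataFrame({"v": [2.0] * 6}, index=labels.index))
        out = group_summary(ds, labels).set_index("variable")
        assert out.loc["v", "kw_p"] == 1.0

    def test_binary_reported_as_percent(self):
        labels = _labels([4, 4])
        ds = OmicsDataset(
            "c",
            pd.DataFrame({"b": [1.0, 1, 1, 1, 0, 0, 0, 0]}, index=labels.index),
            pd.Series(["binary"], index=["b"]),
        )
        out = group_summary(ds, labels).set_index("variable")
        assert out.loc["b", "cluster_1"] == 100.0
        assert out.loc["b", "cluster_2"] == 0.0
        assert out.loc["b", "p_1_vs_2"] < 0.05


class TestHeatmapExport:
    def test_exported_matrix_is_flipped_and_reordered(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            rng.normal(size=(4, 6)),
            index=["a", "b", "c", "d"],
            columns=[f"s{i}" for i in range(6)],
        )
        out = module_discovery(vals, flip_set=["b"], g_max=2, B=10, seed=0)
        labels = pd.Series([1, 1, 2, 2, 1, 2], index=vals.columns)
        tsv = tmp_path / "hm.tsv"
        mat = heatmap_export(out, labels, path_img=tmp_path / "hm.png", path_tsv=tsv)
        back = pd.read_csv(tsv, sep="\t", index_col=0)
        np.testing.assert_allclose(back.to_numpy(), mat.to_numpy())
        # flipped row holds the negated input values
        np.testing.assert_allclose(
            np.sort(np.abs(mat.loc["b"].to_numpy())),
            np.sort(np.abs(vals.loc["b"].to_numpy())),
        )
        assert (tmp_path / "hm.png").exists()
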