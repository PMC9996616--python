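import numpy as np
import pandas as pd
import pytest

from sortmet.detection import detect_per_celltype
from sortmet.differential import (
    buffer_effect,
    cross_study_correlation,
    median_log_ratio,
    pca_profiles,
    volcano,
)
from sortmet.preprocess import preprocess_pipeline
from sortmet.synth import (
    SyntheticConfig,
    default_celltype_config,
    default_treatment_config,
    generate_celltype_panel,
    generate_treatment_pair,
    metabolite_ids,
)
from tests.conftest import build_table


def treatment_table(seed=1, **overrides):
    cfg = default_treatment_config(seed=seed, **overrides)
    table, truth = generate_treatment_pair(cfg)
    return table, truth


class TestVolcano:
    def test_identical_groups_no_hits(self):
        cfg = default_treatment_config(
            seed=2,
            lognormal_sigma_metabolite=0.0,
            lognormal_sigma_technical=0.0,
            outlier_rate=0.0,
            lod_quantile=0.0,
        )
        cfg.treatment_log2fc = {m: 0.0 for m in cfg.treatment_log2fc}
        table, _ = generate_treatment_pair(cfg)
        res = volcano(table, "treated", "control")
        included = res.frame[res.frame["included"]]
        np.testing.assert_allclose(included["log2_fold_change"], 0.0, atol=1e-12)
        assert not res.frame["hit"].any()

    def test_injected_fold_changes_are_extreme_hits(self):
        table, truth = treatment_table(seed=31, outlier_rate=0.0)
        processed, _ = preprocess_pipeline(table)
        res = volcano(processed, "treated", "control")
        frame = res.frame
        up = frame["log2_fold_change"].idxmax()
        down = frame["log2_fold_change"].idxmin()
        designated = truth.log2_fold_change
        assert {up, down} == set(designated)
        assert frame.loc[up, "hit"] and frame.loc[down, "hit"]
        for m, lfc in designated.items():
            assert frame.loc[m, "log2_fold_change"] == pytest.approx(lfc, abs=0.5)

    def test_below_blank_excluded_regardless_of_fold_change(self):
        rng = np.random.default_rng(0)
        n = 6
        # m1: huge fold change but at blank level in group A
        values, roles, groups, events = [], [], [], []
        for grp, m1 in (("A", 1.0), ("B", 100.0)):
            for _ in range(n):
                values.append([m1 * rng.uniform(0.9, 1.1), 500 * rng.uniform(0.9, 1.1)])
                roles.append("cell")
                groups.append(grp)
                events.append(5000)
        for _ in range(n):
            values.append([1.0 * rng.uniform(0.9, 1.1), 1.0 * rng.uniform(0.9, 1.1)])
            roles.append("debris")
            groups.append(None)
            events.append(5000)
        table = build_table(
            np.array(values), roles=roles, groups=groups, event_counts=events
        )
        res = volcano(table, "A", "B")
        assert not res.frame.loc["m1", "included"]
        assert not res.frame.loc["m1", "hit"]
        assert res.frame.loc["m2", "included"]

    def test_swap_symmetry(self):
        table, _ = treatment_table(seed=9)
        res_ab = volcano(table, "treated", "control")
        res_ba = volcano(table, "control", "treated")
        np.testing.assert_allclose(
            res_ab.frame["log2_fold_change"],
            -res_ba.frame["log2_fold_change"],
            rtol=1e-10,
        )
        np.testing.assert_allclose(
            res_ab.frame["p_value"], res_ba.frame["p_value"], rtol=1e-10
        )
        assert (res_ab.frame["included"] == res_ba.frame["included"]).all()

    def test_hit_implies_included(self):
        table, _ = treatment_table(seed=13)
        frame = volcano(table, "treated", "control").frame
        assert (~frame["hit"] | frame["included"]).all()

    def test_gate_matches_per_celltype_rule(self):
        table, _ = treatment_table(seed=5, outlier_rate=0.0)
        res = volcano(table, "treated", "control")
        smeta = table.samples
        sets = {}
        for grp in ("treated", "control"):
            keep = list(smeta.index[(smeta["group"] == grp) | (smeta["role"] == "debris")])
            sub = detect_per_celltype(table.subset(sample_ids=keep))
            sets[grp] = sub.detected["Jurkat"]
        included = set(res.frame.index[res.frame["included"]])
        assert included == sets["treated"] & sets["control"]

    def test_missing_group_rejected(self):
        table, _ = treatment_table(seed=1)
        with pytest.raises(ValueError, match="nope"):
            volcano(table, "nope", "control")


class TestBufferEffect:
    def make_condition(self, rt, intensity, mets=None):
        mets = mets or [f"m{i}" for i in range(len(rt))]
        return pd.DataFrame(
            {"rt": rt, "intensity": intensity}, index=pd.Index(mets, name="metabolite")
        )

    def test_reference_vs_itself_all_zero(self):
        ref = self.make_condition([5.0, 7.0], [100.0, 300.0])
        res = buffer_effect(ref, ref.copy())
        np.testing.assert_allclose(res.frame["delta_rt"], 0.0)
        np.testing.assert_allclose(res.frame["log2_intensity_ratio"], 0.0)

    def test_uniform_halving(self):
        ref = self.make_condition([5.0, 7.0, 9.0], [100.0, 300.0, 50.0])
        trt = ref.copy()
        trt["intensity"] /= 2
        res = buffer_effect(ref, trt)
        np.testing.assert_allclose(res.frame["log2_intensity_ratio"], -1.0)
        assert res.median_log2_ratio == pytest.approx(-1.0)

    def test_positive_rt_shifts_recovered(self):
        rng = np.random.default_rng(3)
        n = 40
        rt = rng.uniform(2, 15, n)
        shift = rng.uniform(0.05, 0.3, n)  # all positive
        ref = self.make_condition(rt, np.full(n, 100.0))
        trt = self.make_condition(rt + shift, np.full(n, 100.0))
        res = buffer_effect(ref, trt)
        assert (res.frame["delta_rt"] > 0).all()
        assert res.median_abs_delta_rt == pytest.approx(np.median(shift))

    def test_unmatched_metabolite_dropped_with_warning(self):
        ref = self.make_condition([5.0, 7.0], [100.0, 300.0], mets=["a", "b"])
        trt = self.make_condition([5.1], [90.0], mets=["a"])
        with pytest.warns(UserWarning, match="dropped"):
            res = buffer_effect(ref, trt)
        assert list(res.frame.index) == ["a"]


class TestPCA:
    def celltype_table(self):
        # two types with disjoint content profiles so the type contrast is
        # guaranteed to live in the leading components
        cfg = SyntheticConfig(
            seed=11,
            lognormal_sigma_metabolite=0.05,
            lognormal_sigma_technical=0.02,
            outlier_rate=0.0,
            celltype_profiles={
                "A": [2.0] * 15 + [0.05] * 15,
                "B": [0.05] * 15 + [2.0] * 15,
            },
        )
        table, truth = generate_celltype_panel(cfg)
        processed, _ = preprocess_pipeline(table, normalize=False)
        return processed, truth

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(3, 0.5, size=(5, 4))
        values = np.vstack([values, values[0]])  # duplicate first sample
        table = build_table(values, roles=["blank"] * 6)
        scores, _, _ = pca_profiles(table, table.metabolite_ids)
        np.testing.assert_allclose(
            scores.iloc[0].to_numpy(), scores.iloc[5].to_numpy(), atol=1e-10
        )

    def test_variance_fractions(self):
        table, _ = self.celltype_table()
        _, _, var_frac = pca_profiles(table, table.metabolite_ids)
        assert var_frac.sum() == pytest.approx(1.0)
        assert (np.diff(var_frac) <= 1e-12).all()

    def test_metabolite_scaling_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(3, 0.5, size=(6, 4))
        t1 = build_table(values, roles=["blank"] * 6)
        scaled = values.copy()
        scaled[:, 1] *= 1000.0
        t2 = build_table(scaled, roles=["blank"] * 6)
        s1, _, _ = pca_profiles(t1, t1.metabolite_ids)
        s2, _, _ = pca_profiles(t2, t2.metabolite_ids)
        np.testing.assert_allclose(np.abs(s1), np.abs(s2), atol=1e-8)

    def test_celltypes_separate_debris_central(self):
        from sklearn.metrics import silhouette_score

        table, truth = self.celltype_table()
        subset = [m for m, c in truth.class_label.items() if c != "internal_standard"]
        scores, _, _ = pca_profiles(table, subset)
        smeta = table.samples
        cells = smeta.index[smeta["role"] == "cell"]
        labels = smeta.loc[cells, "cell_type"]
        assert silhouette_score(scores.loc[cells, ["PC1", "PC2"]], labels) > 0
        debris = smeta.index[smeta["role"] == "debris"]
        debris_centroid = scores.loc[debris, ["PC1", "PC2"]].mean()
        assert np.linalg.norm(debris_centroid) < min(
            np.linalg.norm(scores.loc[labels[labels == t].index, ["PC1", "PC2"]].mean())
            for t in labels.unique()
        )

    def test_zero_variance_metabolite_dropped(self):
        values = np.column_stack([np.full(5, 3.0), np.linspace(1, 2, 5)])
        table = build_table(values, roles=["blank"] * 5)
        with pytest.warns(UserWarning, match="zero-variance"):
            scores, loadings, _ = pca_profiles(table, table.metabolite_ids)
        assert list(loadings.index) == ["m2"]

    def test_empty_subset_rejected(self):
        table = build_table(np.ones((3, 2)), roles=["blank"] * 3)
        with pytest.raises(ValueError, match="empty"):
            pca_profiles(table, [])

    def test_missing_values_rejected(self):
        table = build_table(
            [[1.0, np.nan], [2.0, 3.0], [1.0, 2.0]], roles=["blank"] * 3
        )
        with pytest.raises(ValueError, match="impute"):
            pca_profiles(table, table.metabolite_ids)


class TestCrossStudy:
    def test_identical_maps(self):
        ratios = {f"m{i}": float(np.sin(i)) for i in range(10)}
        res = cross_study_correlation(ratios, dict(ratios))
        assert res.r == pytest.approx(1.0)
        assert res.n_common == 10

    def test_negated_maps(self):
        ratios = {f"m{i}": float(np.sin(i)) for i in range(10)}
        res = cross_study_correlation(ratios, {k: -v for k, v in ratios.items()})
        assert res.r == pytest.approx(-1.0)

    def test_known_latent_correlation_recovered(self):
        rho, n = 0.6, 30
        rng = np.random.default_rng(42)
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        a = {f"m{i}": xy[i, 0] for i in range(n)}
        b = {f"m{i}": xy[i, 1] for i in range(n)}
        res = cross_study_correlation(a, b)
        # Fisher z 95% sampling interval around the latent correlation
        assert abs(np.arctanh(res.r) - np.arctanh(rho)) <= 1.96 / np.sqrt(n - 3)
        assert res.n_common == n

    def test_too_few_common_rejected(self):
        with pytest.raises(ValueError, match="common"):
            cross_study_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0, "c": 0.0})

    def test_intersection_only(self):
        a = {"x": 1.0, "y": 2.0, "z": 3.0, "w": 4.0}
        b = {"y": 2.0, "z": 2.5, "w": 4.5, "v": 0.0}
        res = cross_study_correlation(a, b)
        assert res.n_common == 3
        assert res.common_metabolites == ["w", "y", "z"]


class TestMedianLogRatio:
    def test_log_ratio_of_medians(self):
        cfg = default_celltype_config(("A", "B"), seed=20, outlier_rate=0.0)
        table, _ = generate_celltype_panel(cfg)
        processed, _ = preprocess_pipeline(table, normalize=False)
        ratios = median_log_ratio(processed, "A", "B")
        smeta = processed.samples
        a_ids = smeta.index[(smeta["role"] == "cell") & (smeta["cell_type"] == "A")]
        b_ids = smeta.index[(smeta["role"] == "cell") & (smeta["cell_type"] == "B")]
        m = next(iter(ratios))
        expected = np.log10(
            processed.intensities.loc[a_ids, m].median()
            / processed.intensities.loc[b_ids, m].median()
        )
        assert ratios[m] == pytest.approx(expected)
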