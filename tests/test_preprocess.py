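"""Symbol updating, MAF collapsing, harmonization, filtering, normalization."""

import numpy as np
import pandas as pd
import pytest

import clinomics as cg


def _pm(tag, values: dict, samples=None) -> cg.PlatformMatrix:
    frame = pd.DataFrame(values).T
    if samples is not None:
        frame.columns = samples
    return cg.PlatformMatrix(tag=tag, values=frame)


class TestUpdateSymbols:
    def test_identity_mapping_is_identity(self):
        m = _pm("RNASEQ", {"A": [1.0, 2.0], "B": [3.0, 4.0]})
        out, removed = cg.update_symbols(m, {})
        assert list(out.features) == ["A", "B"]
        assert removed == []

    def test_rename_and_obsolete_drop(self):
        m = _pm("RNASEQ", {"OLD1": [1.0, 2.0], "OLD2": [3.0, 4.0], "KEEP": [5.0, 6.0]})
        out, removed = cg.update_symbols(m, {"OLD1": "NEW1", "OLD2": None})
        assert set(out.features) == {"NEW1", "KEEP"}
        assert removed == ["OLD2"]
        assert list(out.values.loc["NEW1"]) == [1.0, 2.0]

    def test_collision_keeps_fewer_missing(self):
        frame = pd.DataFrame(
            {"X1": [1.0, np.nan, 3.0], "X2": [4.0, 5.0, 6.0]}
        ).T
        m = cg.PlatformMatrix(tag="RNASEQ", values=frame)
        out, removed = cg.update_symbols(m, {"X1": "G", "X2": "G"})
        assert list(out.features) == ["G"]
        assert list(out.values.loc["G"]) == [4.0, 5.0, 6.0]  # X2 wins
        assert removed == ["X1"]

    def test_collision_tie_breaks_lexicographically(self):
        m = _pm("RNASEQ", {"B": [1.0, 2.0], "A": [3.0, 4.0]})
        out, removed = cg.update_symbols(m, {"A": "G", "B": "G"})
        assert list(out.values.loc["G"]) == [3.0, 4.0]  # A wins the tie
        assert removed == ["B"]


class TestMutationMatrixFromMaf:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
        )

    def test_non_silent_sets_one(self):
        records = self._records([("G", "S1", "Missense_Mutation")])
        mat, rejected = cg.mutation_matrix_from_maf(records, ["S1", "S2"])
        assert mat.values.loc["G", "S1"] == 1.0
        assert mat.values.loc["G", "S2"] == 0.0
        assert rejected.empty

    @pytest.mark.parametrize(
        "classification", ["Silent", "Intron", "3'UTR", "5'UTR", "IGR", "RNA"]
    )
    def test_silent_classes_do_not_count(self, classification):
        records = self._records([("G", "S1", classification)])
        mat, _ = cg.mutation_matrix_from_maf(records, ["S1"])
        assert mat.values.loc["G", "S1"] == 0.0

    def test_unknown_sample_rejected_and_logged(self):
        records = self._records(
            [("G", "S1", "Nonsense_Mutation"), ("G", "S9", "Missense_Mutation")]
        )
        mat, rejected = cg.mutation_matrix_from_maf(records, ["S1"])
        assert len(rejected) == 1
        assert mat.values.loc["G", "S1"] == 1.0

    def test_sample_without_records_is_all_zero(self):
        records = self._records([("G", "S1", "Frame_Shift_Del")])
        mat, _ = cg.mutation_matrix_from_maf(records, ["S1", "S2", "S3"])
        assert (mat.values[["S2", "S3"]] == 0).all().all()


class TestHarmonizeMethylation:
    def test_common_probes_hm450_wins_shared_samples(self):
        hm27 = _pm("METH", {"p1": [0.1, 0.2], "p2": [0.3, 0.4]}, samples=["A", "B"])
        hm450 = _pm("METH", {"p2": [0.5, 0.6], "p3": [0.7, 0.8]}, samples=["B", "C"])
        out = cg.harmonize_methylation(hm27, hm450, mode="common-probes")
        assert list(out.features) == ["p2"]
        assert set(out.samples) == {"A", "B", "C"}
        assert out.values.loc["p2", "B"] == 0.5  # HM450 value, not HM27's 0.4
        assert out.values.loc["p2", "A"] == 0.3  # HM27-only sample retained

    def test_hm450_only_mode_passthrough(self):
        hm27 = _pm("METH", {"p1": [0.1]}, samples=["A"])
        hm450 = _pm("METH", {"p9": [0.9]}, samples=["B"])
        out = cg.harmonize_methylation(hm27, hm450, mode="hm450-only")
        assert out is hm450

    def test_disjoint_probes_rejected(self):
        hm27 = _pm("METH", {"p1": [0.1]}, samples=["A"])
        hm450 = _pm("METH", {"p2": [0.2]}, samples=["A"])
        with pytest.raises(ValueError, match="common"):
            cg.harmonize_methylation(hm27, hm450, mode="common-probes")


class TestIntersectSamples:
    def test_intersection_and_order(self):
        a = _pm("RNASEQ", {"f": [1.0, 2.0, 3.0]}, samples=["A", "B", "C"])
        b = _pm("CNV", {"g": [0.0, 1.0, -1.0]}, samples=["B", "C", "D"])
        out = cg.intersect_samples([a, b])
        for m in out:
            assert list(m.samples) == ["B", "C"]

    def test_identical_sets_unchanged(self):
        a = _pm("RNASEQ", {"f": [1.0, 2.0]}, samples=["A", "B"])
        out = cg.intersect_samples([a])
        assert list(out[0].samples) == ["A", "B"]

    def test_disjoint_sets_rejected(self):
        a = _pm("RNASEQ", {"f": [1.0]}, samples=["A"])
        b = _pm("CNV", {"g": [1.0]}, samples=["B"])
        with pytest.raises(ValueError, match="shared"):
            cg.intersect_samples([a, b])


class TestFilterAndImpute:
    def test_three_percent_boundary_drops(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(2, 100)), index=["drop3", "keep2"])
        vals.iloc[0, :3] = np.nan  # 3/100 >= 0.03 -> dropped
        vals.iloc[1, :2] = np.nan  # 2/100 < 0.03 -> imputed
        m = cg.PlatformMatrix(tag="RNASEQ", values=vals)
        out, dropped = cg.filter_and_impute(m)
        assert dropped == ["drop3"]
        assert list(out.features) == ["keep2"]
        assert not out.values.isna().to_numpy().any()
        median = np.nanmedian(vals.iloc[1].to_numpy())
        assert (out.values.loc["keep2"].iloc[:2] == median).all()

    def test_imputation_preserves_feature_median(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(5, 200)))
        vals[vals.abs() > 2.2] = np.nan
        m = cg.PlatformMatrix(tag="RNASEQ", values=vals.set_axis([f"f{i}" for i in range(5)]))
        before = np.nanmedian(m.values.to_numpy(), axis=1)
        out, _ = cg.filter_and_impute(m, max_missing=0.5)
        after = np.median(out.values.to_numpy(), axis=1)
        np.testing.assert_allclose(before, after)

    def test_no_missing_is_identity(self):
        m = _pm("RNASEQ", {"f": [1.0, 2.0, 3.0]})
        out, dropped = cg.filter_and_impute(m)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert dropped == []

    def test_all_features_dropped_rejected(self):
        vals = pd.DataFrame({"f": [np.nan, 1.0]}).T
        m = cg.PlatformMatrix(tag="RNASEQ", values=vals)
        with pytest.raises(ValueError, match="all features"):
            cg.filter_and_impute(m, max_missing=0.1)


class TestNormalizeFeatures:
    def test_homogeneous_scale_divides_by_twice_sd(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=40)
        vals = pd.DataFrame([base, base * -1 + 5], index=["a", "b"])
        s = float(vals.std(axis=1, ddof=1).iloc[0])
        m = cg.PlatformMatrix(tag="RNASEQ", values=vals)
        out = cg.normalize_features(m)
        assert out.sd10 == pytest.approx(s)
        np.testing.assert_allclose(
            out.values.to_numpy(), vals.to_numpy() / (2 * s), rtol=1e-12
        )

    def test_two_feature_percentile_example(self):
        """sds {2, 20} -> 10th percentile 3.8 by linear interpolation;
        feature 1 is divided by 2 + 3.8 = 5.8."""
        rng = np.random.default_rng(3)
        z = rng.normal(size=500)
        z = (z - z.mean()) / z.std(ddof=1)
        vals = pd.DataFrame([2 * z, 20 * z], index=["a", "b"])
        out = cg.normalize_features(cg.PlatformMatrix(tag="RNASEQ", values=vals))
        assert out.sd10 == pytest.approx(3.8, abs=1e-9)
        np.testing.assert_allclose(
            out.values.loc["a"].to_numpy(), vals.loc["a"].to_numpy() / 5.8, rtol=1e-12
        )

    def test_sd_identity_on_random_matrices(self):
        """sd of normalized feature equals sd / (sd + sd10) exactly."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            vals = pd.DataFrame(
                rng.normal(size=(20, 50)) * rng.uniform(0.5, 20, size=(20, 1))
            ).set_axis([f"f{i}" for i in range(20)])
            out = cg.normalize_features(cg.PlatformMatrix(tag="RNASEQ", values=vals))
            sds = vals.std(axis=1, ddof=1).to_numpy()
            sd10 = np.percentile(sds, 10)
            got = out.values.std(axis=1, ddof=1).to_numpy()
            np.testing.assert_allclose(got, sds / (sds + sd10), atol=1e-12)
            assert (got < 1).all()

    def test_all_constant_matrix_rejected(self):
        vals = pd.DataFrame({"f": [1.0, 1.0, 1.0]}).T
        with pytest.raises(ValueError, match="denominator"):
            cg.normalize_features(cg.PlatformMatrix(tag="RNASEQ", values=vals))


class TestIntegratePlatforms:
    def _normed(self, tag, n_feat, n_samp, seed):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(
            rng.normal(size=(n_feat, n_samp)),
            index=[f"{tag}_f{i}" for i in range(n_feat)],
            columns=[f"S{i}" for i in range(n_samp)],
        )
        return cg.normalize_features(cg.PlatformMatrix(tag=tag, values=vals))

    def test_target_filter_applies_to_gene_group(self):
        m = self._normed("RNASEQ", 5, 10, 0)
        targets = cg.TargetList.from_sources({"COSMIC": ["RNASEQ_f0", "RNASEQ_f1"]})
        out = cg.integrate_platforms([m], "gene", targets)
        assert set(out.values.index.get_level_values("entity")) == {
            "RNASEQ_f0",
            "RNASEQ_f1",
        }

    def test_concatenation_and_tags(self):
        a = self._normed("RNASEQ", 5, 10, 0)
        b = self._normed("METH", 7, 10, 1)
        out = cg.integrate_platforms([a, b], "miR")
        assert out.n_features == 12
        assert set(out.values.index.get_level_values("platform")) == {"RNASEQ", "METH"}

    def test_platform_scale_recoverable(self):
        a = self._normed("RNASEQ", 6, 30, 2)
        out = cg.integrate_platforms([a], "protein")
        scale = out.platform_scale["RNASEQ"]
        block = out.values.xs("RNASEQ", level="platform")
        np.testing.assert_allclose(
            block.to_numpy() / scale,
            a.values.to_numpy(),
            rtol=1e-12,
        )
        # the scalar sets the mean per-feature sd to 1
        assert block.std(axis=1, ddof=1).mean() == pytest.approx(1.0)

    def test_unit_scale_matrix_gets_scale_one(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(rng.normal(size=(4, 200)))
        vals = vals.div(vals.std(axis=1, ddof=1), axis=0)  # unit sd per feature
        vals = vals.set_axis([f"f{i}" for i in range(4)])
        m = cg.PlatformMatrix(tag="RNASEQ", values=vals)
        out = cg.integrate_platforms([m], "protein")
        assert out.platform_scale["RNASEQ"] == pytest.approx(1.0)

    def test_sample_order_mismatch_rejected(self):
        a = self._normed("RNASEQ", 3, 5, 0)
        b = self._normed("METH", 3, 5, 1)
        b = cg.PlatformMatrix(
            tag="METH",
            values=b.values[list(b.values.columns[::-1])],
        )
        with pytest.raises(ValueError, match="sample order"):
            cg.integrate_platforms([a, b], "miR")

    def test_gene_group_requires_targets(self):
        a = self._normed("RNASEQ", 3, 5, 0)
        with pytest.raises(ValueError, match="target"):
            cg.integrate_platforms([a], "gene")


def test_pipeline_single_platform_no_missing_reduces_to_normalize(small_cohort):
    m = small_cohort.platform("RNASEQ")
    integrated, dropped = cg.preprocess_group([m], "protein", scale_platforms=False)
    assert dropped == {"RNASEQ": []}
    expected = cg.normalize_features(m)
    np.testing.assert_allclose(
        integrated.values.to_numpy(), expected.values.to_numpy(), rtol=1e-12
    )
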