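import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenoscreen import (
    FeatureTable,
    MAD_CONSISTENCY,
    PlateFormatError,
    ProcessingConfig,
    aggregate_fields,
    normalize_to_controls,
    qc_flag_images,
    remove_redundant_features,
    robust_z_scale,
    transform_skewed,
)
from phenoscreen.io_plate import PipelineStateError


def _well_table(values: np.ndarray, names=None, roles=None, plates=None,
                stage="aggregated") -> FeatureTable:
    n = len(values)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    df = pd.DataFrame({
        "plate": plates if plates is not None else ["P01"] * n,
        "well": [f"{chr(65 + i // 24)}{i % 24 + 1:02d}" for i in range(n)],
        "role": roles if roles is not None else ["dmso"] * n,
    })
    df[names] = values
    return FeatureTable(df, names, level="well", stage=stage)


class TestAggregateFields:
    def test_identical_fields_pass_through(self, small_screen):
        _, table, _ = small_screen
        agg = aggregate_fields(table)
        assert agg.level == "well"
        assert len(agg) == table.data.groupby(["plate", "well"]).ngroups

    def test_median_of_fields(self):
        rows = []
        for f, v in enumerate([1, 2, 3, 4, 5, 100], start=1):
            rows.append(("P01", "A01", f, "dmso", float(v)))
        df = pd.DataFrame(rows, columns=["plate", "well", "field", "role", "f0"])
        table = FeatureTable(df, ["f0"], level="field", stage="raw")
        agg = aggregate_fields(table)
        assert agg.data["f0"].iloc[0] == 3.5

    def test_flagged_field_excluded_from_median(self):
        rows = [("P01", "A01", f, "dmso", float(v))
                for f, v in enumerate([1, 1, 1, 1, 1, 1000], start=1)]
        df = pd.DataFrame(rows, columns=["plate", "well", "field", "role", "f0"])
        table = FeatureTable(df, ["f0"], level="field", stage="raw")
        agg = aggregate_fields(table, exclude={("P01", "A01", 6)})
        assert agg.data["f0"].iloc[0] == 1.0

    def test_well_level_input_rejected(self):
        table = _well_table(np.ones((8, 2)), stage="raw")
        with pytest.raises(PipelineStateError):
            aggregate_fields(table)


class TestQCFlagging:
    @staticmethod
    def _qc_table(values):
        n = len(values)
        df = pd.DataFrame({
            "plate": ["P01"] * n,
            "well": [f"A{i % 24 + 1:02d}" for i in range(n)],
            "field": [(i // 24) % 6 + 1 for i in range(n)],
        })
        names = [f"qc{j}" for j in range(values.shape[1])]
        df[names] = values
        return FeatureTable(df, names, level="field", stage="raw")

    def test_clean_table_flags_under_one_percent(self):
        rng = np.random.default_rng(0)
        table = self._qc_table(rng.normal(size=(120, 4)))
        _, frac = qc_flag_images(table)
        assert frac < 0.01 + 1e-9  # 0.995 chi-square quantile, clean data

    def test_planted_outliers_recovered(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(144, 4))
        bad = rng.choice(144, size=4, replace=False)  # ~3% of fields
        vals[bad] += 25.0  # extreme blur-proxy shift
        table = self._qc_table(vals)
        flagged, _ = qc_flag_images(table)
        df = table.data
        bad_keys = {(df["plate"].iat[i], df["well"].iat[i], df["field"].iat[i])
                    for i in bad}
        assert len(bad_keys & flagged) >= 0.9 * len(bad_keys)

    def test_constant_features_no_crash(self):
        table = self._qc_table(np.ones((48, 3)))
        flagged, frac = qc_flag_images(table)
        assert flagged == set() and frac == 0.0


class TestRedundancyFilter:
    def test_duplicate_column_dropped_once(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        vals = np.column_stack([x, x, rng.normal(size=100)])
        table = _well_table(vals, names=["a", "b", "c"])
        out, dropped = remove_redundant_features(table, 0.99)
        assert dropped == ["b"]
        assert out.feature_names == ["a", "c"]

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(1)
        table = _well_table(rng.normal(size=(200, 5)))
        out, dropped = remove_redundant_features(table, 0.99)
        assert dropped == []

    def test_near_duplicate_above_cutoff_dropped(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y = x + rng.normal(scale=0.05, size=500)
        r = np.corrcoef(x, y)[0, 1]
        assert r > 0.99  # construction check for the oracle
        out, dropped = remove_redundant_features(
            _well_table(np.column_stack([x, y]), names=["x", "y"]), 0.99)
        assert dropped == ["y"]

    def test_surviving_set_below_cutoff(self, scaled_screen):
        scaled, _, _ = scaled_screen
        corr = np.corrcoef(scaled.matrix, rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        assert np.nanmax(np.abs(corr[iu])) <= 0.995  # scaled is corr-filtered upstream

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(60, 6))
        vals[:, 3] = vals[:, 1] * 1.0000001
        t1 = _well_table(vals)
        perm = rng.permutation(60)
        t2 = _well_table(vals[perm])
        _, d1 = remove_redundant_features(t1, 0.99)
        _, d2 = remove_redundant_features(t2, 0.99)
        assert d1 == d2

    def test_all_constant_rejected(self):
        table = _well_table(np.ones((20, 3)))
        with pytest.raises(PlateFormatError, match="informative"):
            remove_redundant_features(table, 0.99)


class TestNormalizeAndScale:
    @staticmethod
    def _two_plate_table(offset=10.0, n_per_plate=24, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(2 * n_per_plate, 3))
        vals[n_per_plate:] += offset
        roles = (["dmso"] * 12 + ["sample"] * (n_per_plate - 12)) * 2
        plates = ["P01"] * n_per_plate + ["P02"] * n_per_plate
        return _well_table(vals, roles=roles, plates=plates, stage="filtered")

    def test_dmso_median_zero_after_normalization(self):
        table = self._two_plate_table()
        normed = normalize_to_controls(table)
        df = normed.data
        for plate, sub in df.groupby("plate"):
            med = sub.loc[sub["role"] == "dmso", normed.feature_names].median()
            np.testing.assert_allclose(med, 0.0, atol=1e-12)

    def test_plate_offset_removed(self):
        normed = normalize_to_controls(self._two_plate_table(offset=10.0))
        means = normed.data.groupby("plate")[normed.feature_names].mean()
        assert np.abs(means.loc["P01"] - means.loc["P02"]).max() < 1.0

    def test_missing_reference_plate_named(self):
        table = self._two_plate_table()
        df = table.data.copy()
        df.loc[df["plate"] == "P02", "role"] = "sample"
        bad = FeatureTable(df, table.feature_names, level="well", stage="filtered")
        with pytest.raises(PlateFormatError, match="P02"):
            normalize_to_controls(bad)

    def test_robust_z_definition(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(40, 1))
        table = _well_table(vals, names=["f0"], stage="transformed")
        scaled, _ = robust_z_scale(table)
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        x = vals[7, 0]
        expect = (x - med) / (MAD_CONSISTENCY * mad)
        assert scaled.data["f0"].iloc[7] == pytest.approx(expect, rel=1e-12)

    def test_scaled_gaussian_sd_near_one(self):
        """1.4826 x MAD is a consistent Gaussian sd estimator: z has sd ~ 1."""
        n = 5000
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(n, 1))
        df = pd.DataFrame({"plate": "P01",
                           "well": [f"{chr(65 + i % 16)}{i % 24 + 1:02d}" for i in range(n)],
                           "role": ["dmso"] * n, "f0": vals[:, 0]})
        table = FeatureTable(df, ["f0"], level="well", stage="transformed")
        scaled, _ = robust_z_scale(table)
        assert scaled.data["f0"].std() == pytest.approx(1.0, rel=0.05)

    def test_zero_mad_feature_zeroed_and_flagged(self):
        vals = np.column_stack([np.ones(20), np.random.default_rng(7).normal(size=20)])
        table = _well_table(vals, names=["const", "ok"], stage="transformed")
        scaled, degenerate = robust_z_scale(table)
        assert ("P01", "const") in degenerate
        assert (scaled.data["const"] == 0).all()

    def test_scaling_idempotent_on_dmso_medians(self, scaled_screen):
        scaled, _, _ = scaled_screen
        rescaled, _ = robust_z_scale(scaled)
        dmso = rescaled.data[rescaled.data["role"] == "dmso"]
        meds = dmso.groupby("plate")[rescaled.feature_names].median()
        assert np.abs(meds.to_numpy()).max() < 1e-9

    def test_out_of_order_stage_raises(self):
        table = self._two_plate_table()  # stage: filtered
        with pytest.raises(PipelineStateError):
            robust_z_scale(table)  # scaling before normalize/transform


class TestTransformSkewed:
    @staticmethod
    def _table_with(values, roles=None, stage="normalized"):
        return _well_table(values, roles=roles, stage=stage)

    def test_gaussian_feature_untransformed(self):
        rng = np.random.default_rng(0)
        table = self._table_with(rng.normal(size=(500, 1)))
        _, transformed = transform_skewed(table)
        assert transformed == []

    def test_exponential_feature_transformed_and_improved(self):
        rng = np.random.default_rng(1)
        vals = rng.exponential(size=(500, 1)) - 1.0
        table = self._table_with(vals)
        out, transformed = transform_skewed(table)
        assert transformed == ["f0"]
        before = abs(stats.skew(vals[:, 0]))
        after = abs(stats.skew(out.data["f0"]))
        assert after < before

    def test_constant_feature_no_crash(self):
        vals = np.column_stack([np.zeros(100),
                                np.random.default_rng(2).normal(size=100)])
        table = self._table_with(vals)
        _, transformed = transform_skewed(table)
        assert "f0" not in transformed

    def test_too_few_reference_wells_passes_through(self):
        rng = np.random.default_rng(3)
        vals = rng.exponential(size=(30, 1))
        roles = ["dmso"] * 5 + ["sample"] * 25
        table = self._table_with(vals, roles=roles)
        _, transformed = transform_skewed(table)
        assert transformed == []
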