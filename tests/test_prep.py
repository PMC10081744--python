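"""Filtering, stratified splitting, median-cap balancing and feature encoding."""

import math

import numpy as np
import pandas as pd
import pytest

from mfisplit.cohort import CohortSpec, DESTINATIONS, generate_cohort
from mfisplit.frailty import INDICATORS
from mfisplit.prep import (
    COMPOSITE,
    FeatureEncoder,
    SpecialtyDataset,
    VARIANTS,
    encode_features,
    filter_records,
    partial_balance,
    stratified_split,
)

from _helpers import make_records


class TestFilterRecords:
    def test_missing_indicator_excluded(self):
        df = make_records({"home": 4})
        df.loc[1, "diabetes"] = pd.NA
        ds = filter_records(df)["general"]
        assert len(ds.records) == 3
        assert "R000001" not in set(ds.records["record_id"])

    def test_rare_destination_dropped(self):
        df = make_records({"home": 5, "hospice": 1})
        ds = filter_records(df)["general"]
        assert ds.present_destinations == ("home",)
        assert len(ds.records) == 5

    def test_complete_records_all_kept(self):
        df = make_records({"home": 6, "rehab": 4})
        out = filter_records(df)
        assert len(out["general"].records) == 10
        assert len(out[COMPOSITE].records) == 10

    def test_empty_specialty_is_marker_not_crash(self):
        df = make_records({"home": 4}, specialty="general")
        ds = filter_records(df)["cardiac"]
        assert ds.empty
        assert ds.present_destinations == ()

    def test_composite_filtered_independently(self):
        # one record per specialty: every specialty drops it (<2 per dest),
        # but pooled they form a viable composite class
        frames = [make_records({"rehab": 1}, specialty=s) for s in ("general", "cardiac")]
        df = pd.concat(frames).reset_index(drop=True)
        df["record_id"] = [f"R{i:06d}" for i in range(len(df))]
        out = filter_records(df)
        assert out["general"].present_destinations == ()
        assert out[COMPOSITE].present_destinations == ("rehab",)


class TestStratifiedSplit:
    def test_even_destination_halved(self):
        ds = filter_records(make_records({"home": 10}))["general"]
        split = stratified_split(ds, seed=1)
        assert len(split.train) == len(split.test) == 5

    def test_two_record_destination_gives_one_each(self):
        ds = filter_records(make_records({"home": 10, "death": 2}))["general"]
        split = stratified_split(ds, seed=1)
        assert (split.train["destination"] == "death").sum() == 1
        assert (split.test["destination"] == "death").sum() == 1

    def test_counts_differ_by_at_most_one(self):
        ds = filter_records(
            make_records({"home": 7, "rehab": 9, "skilled_facility": 4, "death": 3})
        )["general"]
        split = stratified_split(ds, seed=5)
        for dest in ds.present_destinations:
            tr = (split.train["destination"] == dest).sum()
            te = (split.test["destination"] == dest).sum()
            assert abs(tr - te) <= 1

    def test_partition_is_exact(self):
        ds = filter_records(make_records({"home": 9, "rehab": 6}))["general"]
        split = stratified_split(ds, seed=2)
        ids_train = set(split.train["record_id"])
        ids_test = set(split.test["record_id"])
        assert not ids_train & ids_test
        assert ids_train | ids_test == set(ds.records["record_id"])

    def test_seed_contract(self):
        ds = filter_records(make_records({"home": 20, "rehab": 10}))["general"]
        a = stratified_split(ds, seed=3)
        b = stratified_split(ds, seed=3)
        c = stratified_split(ds, seed=4)
        pd.testing.assert_frame_equal(a.train, b.train)
        assert set(a.train["record_id"]) != set(c.train["record_id"])
        assert len(a.train) == len(c.train)

    def test_unfiltered_rare_destination_rejected(self):
        df = make_records({"home": 4, "death": 1})
        ds = SpecialtyDataset("general", df, ("home", "death"))
        with pytest.raises(ValueError, match="filter_records"):
            stratified_split(ds, seed=1)


class TestPartialBalance:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"home": 10, "rehab": 4, "death": 2}, {"home": 4, "rehab": 4, "death": 2}),
            ({"home": 8, "death": 2}, {"home": 5, "death": 2}),  # even case: m=5
            ({"home": 4, "rehab": 4, "death": 4}, {"home": 4, "rehab": 4, "death": 4}),
        ],
    )
    def test_median_cap(self, counts, expected):
        out = partial_balance(make_records(counts), seed=0)
        got = out["destination"].value_counts().to_dict()
        assert got == expected

    def test_oracle_recount_on_random_count_vectors(self, rng):
        """Post-balance counts equal min(count, ceil(median)) for every
        destination, on 100 random count vectors."""
        for _ in range(100):
            k = rng.integers(2, 10)
            dests = list(rng.choice(DESTINATIONS, size=k, replace=False))
            counts = {d: int(rng.integers(2, 40)) for d in dests}
            out = partial_balance(make_records(counts), seed=int(rng.integers(1 << 30)))
            got = out["destination"].value_counts().to_dict()
            m = float(np.median(list(counts.values())))
            cap = math.ceil(m)
            expected = {d: (cap if c > m else c) for d, c in counts.items()}
            assert got == expected
            assert len(out) == sum(expected.values())

    def test_never_increases_or_removes(self, rng):
        counts = {"home": 30, "rehab": 3, "death": 2}
        out = partial_balance(make_records(counts), seed=1)
        got = out["destination"].value_counts().to_dict()
        assert set(got) == set(counts)
        assert all(got[d] <= counts[d] for d in counts)

    def test_subsample_is_seeded(self):
        df = make_records({"home": 30, "rehab": 3, "death": 2})
        a = partial_balance(df, seed=1)
        b = partial_balance(df, seed=1)
        c = partial_balance(df, seed=2)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["record_id"]) != set(c["record_id"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            partial_balance(make_records({"home": 2}).iloc[:0], seed=0)


class TestEncodeFeatures:
    @pytest.mark.parametrize(
        "variant, n_cols",
        [("single_mfi", 5), ("split_mfi", 6), ("high_only", 5),
         ("low_only", 5), ("mfi_hat", 5)],
    )
    def test_column_counts(self, variant, n_cols):
        df = make_records({"home": 6, "rehab": 4})
        fm = encode_features(df, variant)
        assert fm.X.shape == (10, n_cols)
        assert len(fm.columns) == n_cols

    def test_values_scaled_to_unit_interval(self):
        df = make_records({"home": 6, "rehab": 4})
        fm = encode_features(df, "split_mfi")
        assert np.all(fm.X >= 0) and np.all(fm.X <= 1)
        assert not np.isnan(fm.X).any()

    def test_one_hot_labels(self):
        df = make_records({"home": 6, "rehab": 4})
        fm = encode_features(df, "single_mfi")
        assert fm.classes == ("home", "rehab")
        np.testing.assert_array_equal(fm.y.sum(axis=1), np.ones(10))
        assert fm.y[:, 0].sum() == 6

    def test_constant_covariate_scales_to_zero(self):
        df = make_records({"home": 6, "rehab": 4})
        df["asa_class"] = 3
        fm = encode_features(df, "single_mfi")
        j = fm.columns.index("asa_class")
        assert np.all(fm.X[:, j] == 0.0)

    def test_test_matrix_reuses_training_bounds(self):
        train = make_records({"home": 6, "rehab": 4})
        test = make_records({"home": 4, "rehab": 2})
        test["age"] = 90  # outside training range -> clipped by train bounds
        enc = FeatureEncoder(VARIANTS["single_mfi"], classes=("home", "rehab"))
        fm_train = enc.fit_transform(train)
        fm_test = enc.transform(test)
        assert fm_train.columns == fm_test.columns
        j = fm_test.columns.index("age")
        assert np.all(fm_test.X[:, j] <= 1.0)

    def test_unseen_destination_rejected(self):
        enc = FeatureEncoder(VARIANTS["single_mfi"], classes=("home",))
        enc.fit(make_records({"home": 4}))
        with pytest.raises(ValueError, match="rehab"):
            enc.transform(make_records({"rehab": 2}))

    def test_mfi_hat_scaled_by_theoretical_max(self):
        df = make_records({"home": 6, "rehab": 4})
        df[list(INDICATORS)] = 1  # all deficits present
        fm = encode_features(df, "mfi_hat")
        j = fm.columns.index("mfi_hat")
        np.testing.assert_allclose(fm.X[:, j], 1.0)
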