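"""Encoding, scaling, discretization and split schemes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icisurv.cohort import CohortSpec, generate_cohort
from icisurv.preprocess import (
    FeatureMatrix,
    apply_scaler,
    discretize,
    encode_features,
    enumerate_folds,
    fit_scaler,
    make_time_grid,
    split_cohort,
)


@pytest.fixture(scope="module")
def cohort():
    c, _, _ = generate_cohort(CohortSpec(n_patients=60, seed=3))
    return c


class TestEncodeFeatures:
    def test_feature_counts_per_set(self, cohort):
        assert encode_features(cohort, "hybrid").X.shape[1] == 31
        assert encode_features(cohort, "clinical_only").X.shape[1] == 28
        assert encode_features(cohort, "mb_only").X.shape[1] == 3

    def test_hybrid_is_disjoint_union_of_arms(self, cohort):
        hy = set(encode_features(cohort, "hybrid").columns)
        cl = set(encode_features(cohort, "clinical_only").columns)
        mb = set(encode_features(cohort, "mb_only").columns)
        assert cl & mb == set()
        assert hy == cl | mb

    def test_race_onehot_declared_order(self, cohort):
        fm = encode_features(cohort, "hybrid")
        cols = [c for c in fm.columns if c.startswith("race=")]
        assert cols == ["race=African American", "race=Asian", "race=White", "race=Hispanic"]
        i = next(k for k, row in cohort.iterrows() if row["race"] == "White")
        idx = [fm.columns.index(c) for c in cols]
        assert fm.X[i, idx].tolist() == [0.0, 0.0, 1.0, 0.0]

    def test_absent_levels_keep_their_columns(self, cohort):
        sub = cohort[cohort["histology"] != "Neuroendocrine"]
        fm = encode_features(sub.reset_index(drop=True), "hybrid")
        col = fm.columns.index("histology=Neuroendocrine")
        assert np.all(fm.X[:, col] == 0)
        assert "histology=Small Cell" in fm.columns  # zero-count coding level

    def test_onehot_groups_sum_to_one(self, cohort):
        fm = encode_features(cohort, "hybrid")
        for g in ("race", "histology", "treatment_arm", "max_ae_grade"):
            idx = fm.group_indices()[g]
            assert np.allclose(fm.X[:, idx].sum(axis=1), 1.0)

    def test_nlr_never_constructed(self, cohort):
        cols = encode_features(cohort, "hybrid").columns
        assert not any("ratio" in c.lower() or "nlr" in c.lower() for c in cols)

    def test_unknown_level_rejected_by_name(self, cohort):
        bad = cohort.copy()
        bad.loc[0, "histology"] = "Sarcomatoid"
        with pytest.raises(ValueError, match="Sarcomatoid"):
            encode_features(bad, "hybrid")


class TestScaler:
    def test_standardization_arithmetic(self):
        fm = FeatureMatrix(
            X=np.array([[1.0], [2.0], [3.0]]), columns=["x"],
            kinds=["continuous"], groups=["x"],
        )
        out = apply_scaler(fit_scaler(fm), fm)
        assert np.allclose(out.X[:, 0], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_train_transform_centers_train(self, cohort):
        fm = encode_features(cohort, "hybrid")
        out = apply_scaler(fit_scaler(fm), fm)
        cont = [i for i, k in enumerate(fm.kinds) if k == "continuous"]
        assert np.max(np.abs(out.X[:, cont].mean(axis=0))) < 1e-12
        onehot = [i for i, k in enumerate(fm.kinds) if k == "one-hot"]
        assert np.array_equal(out.X[:, onehot], fm.X[:, onehot])

    def test_fold_refit_changes_transform(self, cohort):
        fm = encode_features(cohort, "hybrid")
        a = fit_scaler(FeatureMatrix(fm.X[:30], fm.columns, fm.kinds, fm.groups))
        b = fit_scaler(FeatureMatrix(fm.X[30:], fm.columns, fm.kinds, fm.groups))
        assert not np.allclose(a.mean, b.mean)

    def test_no_leakage_from_test_rows(self, cohort):
        # perturbing a held-out row must not change the transform of training rows
        fm = encode_features(cohort, "hybrid")
        train = FeatureMatrix(fm.X[:40], fm.columns, fm.kinds, fm.groups)
        state = fit_scaler(train)
        before = apply_scaler(state, train).X.copy()
        perturbed = fm.copy()
        perturbed.X[50, 0] += 1e6
        train_after = FeatureMatrix(perturbed.X[:40], fm.columns, fm.kinds, fm.groups)
        after = apply_scaler(fit_scaler(train_after), train_after).X
        assert np.array_equal(before, after)

    def test_zero_variance_column_warns_and_scales_by_one(self):
        fm = FeatureMatrix(
            X=np.array([[2.0, 1.0], [2.0, 3.0]]), columns=["c", "d"],
            kinds=["continuous", "continuous"], groups=["c", "d"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            state = fit_scaler(fm)
        assert state.scale[0] == 1.0


class TestTimeGrid:
    def test_equidistant_construction(self):
        grid = make_time_grid(np.array([40.0, 100.0]), n_bins=20)
        assert np.allclose(grid.edges, np.arange(0, 101, 5))
        assert grid.n_bins == 20

    def test_degenerate_durations_still_valid(self):
        grid = make_time_grid(np.array([50.0, 50.0]), n_bins=4)
        assert grid.edges[-1] == 50.0

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            make_time_grid(np.array([10.0]), n_bins=1)

    @pytest.mark.parametrize(
        "duration,expected_bin",
        [(5.0, 0), (5.0001, 1), (12.0, 2), (100.0, 19)],
    )
    def test_interval_convention_left_open_right_closed(self, duration, expected_bin):
        grid = make_time_grid(np.array([100.0]), n_bins=20)
        assert discretize(duration, 1, grid).bin_index == expected_bin

    def test_beyond_grid_clamps_with_warning(self):
        grid = make_time_grid(np.array([100.0]), n_bins=20)
        with pytest.warns(UserWarning, match="clamp"):
            lab = discretize(999.0, 0, grid)
        assert lab.bin_index == 19

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(d1=st.floats(0.01, 200.0), d2=st.floats(0.01, 200.0))
    def test_discretization_monotone(self, d1, d2):
        import warnings

        grid = make_time_grid(np.array([100.0]), n_bins=20)
        lo, hi = sorted((d1, d2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert discretize(lo, 1, grid).bin_index <= discretize(hi, 1, grid).bin_index


class TestSplits:
    def test_trial_geometry(self):
        ids = np.arange(93)
        s = split_cohort(ids, seed=0)
        assert len(s.test) == 19 and len(s.val) == 15 and len(s.train) == 59
        union = np.concatenate([s.train, s.val, s.test])
        assert sorted(union.tolist()) == ids.tolist()

    def test_explicit_fractions(self):
        s = split_cohort(np.arange(10), seed=0, fractions=(0.6, 0.2, 0.2))
        assert (len(s.train), len(s.val), len(s.test)) == (6, 2, 2)

    def test_seed_determinism(self):
        a = split_cohort(np.arange(50), seed=9)
        b = split_cohort(np.arange(50), seed=9)
        assert np.array_equal(a.test, b.test) and np.array_equal(a.train, b.train)

    def test_fold_count_and_coverage(self):
        ids = np.arange(93)
        folds = enumerate_folds(ids, n_groups=5, seed=4)
        assert len(folds) == 20
        test_appearances = {i: 0 for i in ids}
        for f in folds:
            assert set(f.train) | set(f.val) | set(f.test) == set(ids)
            assert not set(f.val) & set(f.test)
            for i in f.test:
                test_appearances[i] += 1
        # each patient's group is the test group in n_groups - 1 folds
        assert set(test_appearances.values()) == {4}

    def test_three_groups_give_six_folds(self):
        assert len(enumerate_folds(np.arange(30), n_groups=3, seed=0)) == 6
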