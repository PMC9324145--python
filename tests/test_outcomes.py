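"""Outcome stage: mRS regrouping, mRSRF selection, the seven feature
groups and the held-out evaluation grid."""

import numpy as np
import pandas as pd
import pytest

from strokepwi.benchmark import model_registry
from strokepwi.outcomes import (GROUP_NAMES, assemble_feature_groups,
                                evaluate_outcomes, regroup_mrs, select_mrsrf)
from strokepwi.selection import SelectorParams
from strokepwi.survival import SurvivalConfig
from strokepwi.synth import generate_cti_table

TABLE4_COUNTS = [25, 11, 9, 4, 8, 9, 14]


def _labels_from_counts(counts):
    return np.repeat(np.arange(len(counts)), counts)


class TestRegroup:
    def test_table4_worked_example(self):
        y7 = _labels_from_counts(TABLE4_COUNTS)
        np.testing.assert_array_equal(
            np.bincount(regroup_mrs(y7, 2)), [45, 35])
        np.testing.assert_array_equal(
            np.bincount(regroup_mrs(y7, 4)), [25, 20, 12, 23])

    def test_identity_for_seven(self):
        y7 = _labels_from_counts(TABLE4_COUNTS)
        np.testing.assert_array_equal(regroup_mrs(y7, 7), y7)

    def test_counts_conserved_and_deterministic(self):
        y7 = _labels_from_counts(TABLE4_COUNTS)
        for scheme in (2, 4, 7):
            y = regroup_mrs(y7, scheme)
            assert len(y) == len(y7)
            assert np.bincount(y).sum() == len(y7)
            np.testing.assert_array_equal(y, regroup_mrs(y7, scheme))

    def test_degenerate_all_zero(self):
        z = np.zeros(10, dtype=int)
        for scheme in (2, 4, 7):
            assert set(regroup_mrs(z, scheme)) == {0}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0..6"):
            regroup_mrs([0, 7], 2)
        with pytest.raises(ValueError, match="scheme"):
            regroup_mrs([0, 1], 3)


class TestMrsrf:
    def test_selection_is_subset_of_input(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 6)),
                          columns=[f"f{i}" for i in range(6)])
        y = rng.integers(0, 2, 60)
        fs = select_mrsrf(df, y, "Lasso")
        assert set(fs.features) <= set(df.columns)

    def test_full_shrinkage_gives_empty_set(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, 40)
        fs = select_mrsrf(df, y, "Lasso",
                          SelectorParams(lasso_lambda=1e6))
        assert fs.features == []

    def test_planted_feature_recovered(self):
        hits = 0
        for rep in range(40):
            r = np.random.default_rng(100 + rep)
            X = r.normal(size=(120, 8))
            y = (X[:, 5] > 0).astype(int)
            df = pd.DataFrame(X, columns=[f"f{i}" for i in range(8)])
            fs = select_mrsrf(df, y, "Lasso")
            hits += "f5" in fs.features
        assert hits >= 38

    def test_two_class_scorer_falls_back_on_multiclass(self, rng):
        df = pd.DataFrame(rng.normal(size=(140, 4)), columns=list("abcd"))
        df["a"] += np.repeat(np.arange(7), 20)      # monotone in mRS
        y7 = np.repeat(np.arange(7), 20)
        fs = select_mrsrf(df, y7, "TS")
        assert "a" in fs.features


class TestFeatureGroups:
    @pytest.fixture()
    def blocks(self, rng):
        cti = generate_cti_table(30, seed=1)
        mrsrf = pd.DataFrame(rng.normal(size=(30, 4)),
                             columns=[f"r{i}" for i in range(4)])
        survf = rng.normal(size=30)
        return cti, mrsrf, survf

    def test_group_schema_and_column_counts(self, blocks):
        cti, mrsrf, survf = blocks
        groups = assemble_feature_groups(cti, mrsrf, survf)
        assert set(groups) == set(GROUP_NAMES)
        assert groups["ALL"].shape[1] == (cti.shape[1] + mrsrf.shape[1] + 1)
        assert set(cti.columns) <= set(groups["CTI+SurvF"].columns)
        assert "SurvF" in groups["mRSRF+SurvF"].columns

    def test_columns_are_range_normalized(self, blocks):
        cti, mrsrf, survf = blocks
        groups = assemble_feature_groups(cti, mrsrf, survf)
        arr = groups["ALL"].to_numpy()
        assert np.abs(arr.mean(axis=0)).max() < 1e-9
        assert np.nanmax(np.abs(arr)) <= 1.0 + 1e-12

    def test_empty_mrsrf_degenerate_groups(self, blocks, caplog):
        cti, _, survf = blocks
        empty = pd.DataFrame(index=cti.index)
        groups = assemble_feature_groups(cti, empty, survf)
        assert groups["mRSRF"].shape[1] == 0
        assert groups["CTI+mRSRF"].shape[1] == cti.shape[1]

    def test_misaligned_blocks_rejected(self, blocks):
        cti, mrsrf, survf = blocks
        with pytest.raises(ValueError, match="misaligned"):
            assemble_feature_groups(cti, mrsrf.iloc[:-1], survf)


class TestEvaluate:
    FAST3 = {k: v for k, v in model_registry("fast", 0).items()
             if k in ("LR", "DA", "NB")}

    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(8)
        n = 80
        cti = generate_cti_table(n, seed=8)
        mrs7 = np.repeat(np.arange(7), [25, 11, 9, 4, 8, 9, 14])
        rng.shuffle(mrs7)
        outstanding = pd.DataFrame(
            rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)])
        outstanding["f0"] += mrs7          # informative imaging feature
        return cti, outstanding, mrs7

    def test_grid_complete_across_situations(self, cohort):
        cti, outstanding, mrs7 = cohort
        rep = evaluate_outcomes(
            cti, outstanding, mrs7, best_method="Lasso", models=self.FAST3,
            survival_config=SurvivalConfig(epochs=30, seed=0), seed=0)
        assert len(rep.cells) == 3 * 7 * 3
        assert rep.grid_complete(n_models=3)
        assert set(rep.cells["situation"]) == {"mRS_2", "mRS_4", "mRS_7"}
        assert set(rep.cells["group"]) == set(GROUP_NAMES)
        assert len(rep.group_means) == 21
        vals = rep.cells[["Pre", "Acc", "Auc", "F1", "Recall"]].to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1

    def test_leaked_label_feature_scores_near_one(self, cohort):
        cti, outstanding, mrs7 = cohort
        leak = outstanding.copy()
        leak["f1"] = regroup_mrs(mrs7, 2).astype(float)
        rep = evaluate_outcomes(
            cti, leak, mrs7, best_method="Lasso", models=self.FAST3,
            survival_config=SurvivalConfig(epochs=10, seed=0), seed=0,
            situations=(2,))
        mrsrf_rows = rep.cells[rep.cells["group"] == "mRSRF"]
        assert (mrsrf_rows["Auc"] > 0.9).all()

    def test_single_sample_class_fails_loudly(self, cohort):
        cti, outstanding, _ = cohort
        mrs7 = np.zeros(80, dtype=int)
        mrs7[0] = 6                        # lone severe case
        with pytest.raises(ValueError, match="single sample"):
            evaluate_outcomes(cti, outstanding, mrs7, models=self.FAST3,
                              situations=(7,))

    def test_deterministic_given_seed(self, cohort):
        cti, outstanding, mrs7 = cohort
        kw = dict(best_method="Lasso", models=self.FAST3,
                  survival_config=SurvivalConfig(epochs=10, seed=0),
                  seed=1, situations=(2,))
        r1 = evaluate_outcomes(cti, outstanding, mrs7, **kw)
        r2 = evaluate_outcomes(cti, outstanding, mrs7, **kw)
        pd.testing.assert_frame_equal(r1.cells, r2.cells)
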