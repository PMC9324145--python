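"""The 13 selectors: mutual-information oracles, greedy-vs-exhaustive
equivalence, hand-arithmetic score checks and the selection-threshold
rules."""

import collections
import math

import numpy as np
import pandas as pd
import pytest

from strokepwi.selection import (ALL_METHODS, SelectorParams,
                                 apply_selection_rule,
                                 conditional_mutual_information,
                                 mutual_information, score_features_sif,
                                 score_features_ssl, score_features_stf,
                                 score_features_ti, select_features)

PARAMS = SelectorParams()


# ---------------------------------------------------------------------------
# independent oracles (plain-python, Counter-based)

def mi_oracle(x, y):
    """Brute-force sum p log(p/(px py)) from the contingency table."""
    n = len(x)
    cxy = collections.Counter(zip(x, y))
    cx, cy = collections.Counter(x), collections.Counter(y)
    total = 0.0
    for (a, b), c in cxy.items():
        p = c / n
        total += p * math.log(p / ((cx[a] / n) * (cy[b] / n)))
    return total


def cmi_oracle(x, y, z):
    n = len(z)
    out = 0.0
    for zv, cz in collections.Counter(z).items():
        sel = [i for i in range(n) if z[i] == zv]
        out += cz / n * mi_oracle([x[i] for i in sel], [y[i] for i in sel])
    return out


def greedy_oracle(method, cols, y, beta, steps):
    """Exhaustive per-step evaluation of the printed greedy criteria."""
    selected, remaining = [], list(cols)
    rel = {c: mi_oracle(cols[c], y) for c in cols}
    while remaining and len(selected) < steps:
        best, best_v = None, -np.inf
        for c in remaining:
            if not selected:
                v = rel[c]
            elif method == "MIFS":
                v = rel[c] - beta * sum(mi_oracle(cols[c], cols[s])
                                        for s in selected)
            elif method == "MRMR":
                v = rel[c] - np.mean([mi_oracle(cols[c], cols[s])
                                      for s in selected])
            elif method == "JMI":
                v = rel[c] - np.mean([rel[c] - cmi_oracle(cols[c], y, cols[s])
                                      for s in selected])
            elif method == "CMIM":
                v = min(cmi_oracle(cols[c], y, cols[s]) for s in selected)
            if v > best_v:
                best, best_v = c, v
        selected.append(best)
        remaining.remove(best)
    return selected


# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_identity_gives_label_entropy(self):
        y = np.array([0] * 30 + [1] * 10)
        h = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert mutual_information(y, y) == pytest.approx(h)

    def test_constant_is_independent(self):
        y = np.array([0, 1] * 20)
        assert mutual_information(np.zeros(40), y) == pytest.approx(0.0)

    def test_contingency_table_worked_example(self):
        # joint counts (30,10;10,30)
        x = np.array([0] * 40 + [1] * 40)
        y = np.array([0] * 30 + [1] * 10 + [0] * 10 + [1] * 30)
        assert mutual_information(x, y) == pytest.approx(mi_oracle(x, y))
        # explicit closed form for the symmetric 2x2 table
        expected = 2 * (0.375 * math.log(0.375 / 0.25)
                        + 0.125 * math.log(0.125 / 0.25))
        assert mutual_information(x, y) == pytest.approx(expected)

    def test_conditional_mi_against_oracle(self, rng):
        x = rng.integers(0, 3, 60)
        y = rng.integers(0, 2, 60)
        z = rng.integers(0, 2, 60)
        assert conditional_mutual_information(x, y, z) == pytest.approx(
            cmi_oracle(list(x), list(y), list(z)))


class TestGreedySelectors:
    @pytest.fixture()
    def toy(self, rng):
        y = rng.integers(0, 2, 40)
        cols = {
            "a": (y + rng.integers(0, 2, 40) * (rng.random(40) < 0.2)) % 2,
            "b": rng.integers(0, 2, 40),
            "c": (1 - y + (rng.random(40) < 0.3)) % 2,
            "d": rng.integers(0, 3, 40),
            "e": (y + rng.integers(0, 3, 40)) % 3,
        }
        return pd.DataFrame({k: v.astype(float) for k, v in cols.items()}), y

    @pytest.mark.parametrize("method", ["MIFS", "MRMR", "JMI", "CMIM"])
    def test_greedy_matches_exhaustive_oracle(self, method, toy):
        df, y = toy
        params = SelectorParams(mi_bins=3, max_features=4)
        scores = score_features_ti(method, df, y, params)
        cols = {c: [int(v) for v in df[c]] for c in df.columns}
        expected = greedy_oracle(method, cols, list(y), params.mifs_beta, 4)
        assert list(scores.index) == expected

    def test_single_candidate_reduces_to_mim(self, toy):
        df, y = toy
        single = df[["a"]]
        mim = score_features_ti("MIM", single, y, PARAMS)
        for method in ("MIFS", "MRMR", "JMI", "CMIM"):
            s = score_features_ti(method, single, y, PARAMS)
            assert s["a"] == pytest.approx(mim["a"])

    def test_duplicate_feature_penalized(self, toy):
        df, y = toy
        dup = pd.DataFrame({"a": df["a"], "a2": df["a"]})
        mim = score_features_ti("MIM", dup, y, PARAMS)
        for method in ("MIFS", "MRMR"):
            s = score_features_ti(method, dup, y,
                                  SelectorParams(max_features=2))
            second = s.index[1]
            assert s[second] < mim[second]

    def test_needs_two_classes(self, toy):
        df, _ = toy
        with pytest.raises(ValueError, match="2 classes"):
            score_features_ti("MIM", df, np.zeros(40), PARAMS)


class TestSimilaritySelectors:
    def test_fisher_population_worked_example(self):
        # two classes, means 0 and 2, within-class variance exactly 1:
        # between = 1, within = 1, ratio = 1
        df = pd.DataFrame({"f": [-1.0, 1.0] * 10 + [1.0, 3.0] * 10})
        y = np.array([0] * 20 + [1] * 20)
        s = score_features_sif("Fisher", df, y, PARAMS)
        assert s["f"] == pytest.approx(1.0)

    def test_fisher_indicator_dominates_noise(self, rng):
        y = np.array([0] * 30 + [1] * 30)
        df = pd.DataFrame({
            "ind": y + rng.normal(0, 0.01, 60),
            "noise": rng.normal(size=60),
        })
        s = score_features_sif("Fisher", df, y, PARAMS)
        assert s["ind"] > 100 * s["noise"]

    def test_laplacian_score_prefers_smooth_cluster_feature(self, rng):
        # two well-separated clusters: a feature aligned with them varies
        # little across graph edges, a white-noise feature varies a lot
        cluster = np.array([0.0] * 20 + [5.0] * 20)
        df = pd.DataFrame({
            "smooth": cluster + rng.normal(0, 0.1, 40),
            "noise": rng.normal(0, 1, 40),
        })
        s = score_features_sif("LS", df, None, PARAMS)
        assert s["smooth"] > s["noise"]

    def test_relieff_separating_feature_is_maximal(self, rng):
        y = np.array([0] * 25 + [1] * 25)
        df = pd.DataFrame({
            "sep": y.astype(float),          # perfectly separating
            "n1": rng.normal(size=50),
            "n2": rng.normal(size=50),
        })
        s = score_features_sif("ReliefF", df, y, PARAMS)
        assert s.idxmax() == "sep"
        # hits never differ, misses always differ by the full range
        assert s["sep"] == pytest.approx(1.0)


class TestStatisticalSelectors:
    @pytest.fixture()
    def tiny(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0, 6.0, 7.0, 8.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        return df, y

    def test_fs_matches_hand_arithmetic(self, tiny):
        df, y = tiny
        # means: overall 4.5, neg 2, pos 7; variances (ddof=1): 1 and 1
        expected = ((7 - 4.5) ** 2 + (2 - 4.5) ** 2) / (1.0 + 1.0)
        s = score_features_stf("FS", df, y)
        assert s["f"] == pytest.approx(expected)

    def test_ts_matches_hand_arithmetic(self, tiny):
        df, y = tiny
        expected = (7 - 2) / math.sqrt(1.0 + 1.0)
        s = score_features_stf("TS", df, y)
        assert s["f"] == pytest.approx(expected)

    def test_ts_zero_for_equal_means_and_scale_invariant(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"f": np.concatenate([x, x])})
        y = np.array([0] * 30 + [1] * 30)
        assert score_features_stf("TS", df, y)["f"] == pytest.approx(0.0)
        df2 = pd.DataFrame({"f": rng.normal(size=60) + y})
        s1 = score_features_stf("TS", df2, y)["f"]
        s2 = score_features_stf("TS", 7.3 * df2, y)["f"]
        assert s1 == pytest.approx(s2)

    def test_requires_exactly_two_classes(self, tiny):
        df, _ = tiny
        with pytest.raises(ValueError, match="2 classes"):
            score_features_stf("FS", df, np.array([0, 1, 2, 0, 1, 2]))


class TestSparseStreamingSelectors:
    def test_lasso_full_shrinkage_empty_selection(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 5)),
                          columns=list("abcde"))
        y = rng.integers(0, 2, 60)
        fs = select_features("Lasso", df, y,
                             SelectorParams(lasso_lambda=1e6))
        assert fs.features == []

    def test_lasso_recovers_planted_feature(self, rng):
        hits = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            X = r.normal(size=(200, 10))
            y = (X[:, 3] + 0.3 * r.normal(size=200) > 0).astype(int)
            df = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)])
            scores = score_features_ssl("Lasso", df, y, PARAMS)
            hits += scores.idxmax() == "f3"
        assert hits >= 95

    def test_alpha_zero_wealth_admits_nothing(self, rng):
        df = pd.DataFrame(rng.normal(size=(80, 6)),
                          columns=[f"f{i}" for i in range(6)])
        y = (df["f0"] > 0).astype(int)
        scores = score_features_ssl("Alpha", df, y,
                                    SelectorParams(alpha_wealth=0.0))
        assert len(scores) == 0

    def test_alpha_admits_strong_first_feature(self, rng):
        y = rng.integers(0, 2, 100)
        df = pd.DataFrame({"good": y + rng.normal(0, 0.1, 100),
                           "noise": rng.normal(size=100)})
        scores = score_features_ssl("Alpha", df, y, PARAMS)
        assert "good" in scores.index

    def test_mcfs_scores_cluster_feature_highest(self, rng):
        cluster = np.array([0.0] * 25 + [4.0] * 25)
        df = pd.DataFrame({
            "clust": cluster + rng.normal(0, 0.2, 50),
            "n1": rng.normal(size=50),
            "n2": rng.normal(size=50),
        })
        scores = score_features_ssl("MCFS", df, None, PARAMS)
        assert scores.idxmax() == "clust"


class TestSelectionRule:
    def test_lasso_coefficient_boundary(self):
        scores = pd.Series({"lo": 0.019, "hi": 0.021})
        fs = apply_selection_rule("Lasso", scores, PARAMS)
        assert fs.features == ["hi"]

    def test_top20_truncation(self):
        # 25 features passing the normalized-score cut: keep the top 20
        scores = pd.Series({f"f{i:02d}": 1000.0 - i for i in range(25)}
                           | {f"junk{i}": 0.0 for i in range(50)})
        fs = apply_selection_rule("MIM", scores, PARAMS)
        assert len(fs.features) == 20
        assert fs.features == [f"f{i:02d}" for i in range(20)]

    def test_constant_scores_select_nothing(self):
        scores = pd.Series({"a": 0.5, "b": 0.5, "c": 0.5})
        fs = apply_selection_rule("Fisher", scores, PARAMS)
        assert fs.features == []

    def test_ties_broken_by_input_order(self):
        scores = pd.Series({"z_first": 5.0, "a_second": 5.0, "low": 0.0})
        fs = apply_selection_rule("MIM", scores, PARAMS)
        assert fs.features == ["z_first", "a_second"]


class TestDispatcher:
    def test_all_methods_run_and_are_deterministic(self, rng):
        y = rng.integers(0, 2, 60)
        X = rng.normal(size=(60, 8))
        X[:, 0] += 2.5 * y
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(8)])
        for method in ALL_METHODS:
            fs1 = select_features(method, df, y, PARAMS)
            fs2 = select_features(method, df, y, PARAMS)
            assert fs1.features == fs2.features
            assert fs1.scores == pytest.approx(fs2.scores)
            assert set(fs1.features) <= set(df.columns)

    def test_unknown_method_rejected(self, rng):
        df = pd.DataFrame({"f": rng.normal(size=10)})
        with pytest.raises(ValueError, match="unknown"):
            select_features("PCA", df, np.zeros(10))
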