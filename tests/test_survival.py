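"""Cox partial likelihood, concordance index and the survival-feature
network: hand-evaluated toys, brute-force pair oracles, an external
concordance oracle, null behavior and planted-hazard recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from strokepwi.survival import (CoxRiskNet, SurvivalConfig, compute_survf,
                                concordance_index, cox_loss_gradient,
                                cox_partial_likelihood_loss,
                                default_event_rule, train_survival_net)


def cindex_oracle(risks, times, events):
    """Brute-force pair enumeration."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i]:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den


class TestCoxLoss:
    def test_single_event_sample_has_zero_loss(self):
        assert cox_partial_likelihood_loss([1.7], [5.0], [1]) == pytest.approx(0.0)

    def test_two_sample_equal_risk_loss_is_log2(self):
        # the event sample's risk set contains both samples
        loss = cox_partial_likelihood_loss([0.3, 0.3], [1.0, 2.0], [1, 0])
        assert loss == pytest.approx(np.log(2.0))

    def test_shift_invariance(self, rng):
        r = rng.normal(size=30)
        t = rng.exponential(size=30)
        e = rng.integers(0, 2, 30)
        e[0] = 1
        l1 = cox_partial_likelihood_loss(r, t, e)
        l2 = cox_partial_likelihood_loss(r + 123.4, t, e)
        assert l1 == pytest.approx(l2)

    def test_breslow_ties_share_risk_set(self):
        # two events at the same time: both see the full 3-sample risk set
        r = np.array([0.0, 0.0, 0.0])
        loss = cox_partial_likelihood_loss(r, [1.0, 1.0, 2.0], [1, 1, 0])
        assert loss == pytest.approx(np.log(3.0))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_partial_likelihood_loss([0.1], [1.0], [0])

    def test_gradient_matches_finite_differences(self, rng):
        r = rng.normal(size=12)
        t = rng.exponential(size=12)
        e = rng.integers(0, 2, 12)
        e[:3] = 1
        g = cox_loss_gradient(r, t, e)
        eps = 1e-6
        for k in range(12):
            rp, rm = r.copy(), r.copy()
            rp[k] += eps
            rm[k] -= eps
            fd = (cox_partial_likelihood_loss(rp, t, e)
                  - cox_partial_likelihood_loss(rm, t, e)) / (2 * eps)
            assert g[k] == pytest.approx(fd, abs=1e-5)


class TestConcordance:
    def test_perfect_anti_ordering(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        r = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance_index(r, t, [1, 1, 1, 1]) == pytest.approx(1.0)

    def test_four_sample_toy_five_of_six(self):
        # all events, one discordant pair out of six comparable
        t = np.array([1.0, 2.0, 3.0, 4.0])
        r = np.array([4.0, 2.0, 3.0, 1.0])    # (2,3) discordant
        e = np.array([1, 1, 1, 1])
        assert concordance_index(r, t, e) == pytest.approx(5 / 6)
        assert cindex_oracle(r, t, e) == pytest.approx(5 / 6)

    def test_matches_bruteforce_and_lifelines(self, rng):
        from lifelines.utils import concordance_index as ll_cindex
        r = rng.normal(size=40)
        t = rng.exponential(size=40)          # continuous: no time ties
        e = rng.integers(0, 2, 40)
        e[:5] = 1
        ours = concordance_index(r, t, e)
        assert ours == pytest.approx(cindex_oracle(r, t, e))
        # lifelines counts concordance of *low* risk with *long* time
        assert ours == pytest.approx(ll_cindex(t, -r, e))

    def test_random_risks_near_half(self, rng):
        t = rng.exponential(size=400)
        r = rng.normal(size=400)
        assert abs(concordance_index(r, t, np.ones(400)) - 0.5) < 0.06

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1.0, 2.0], [1.0, 1.0], [0, 0])


class TestTraining:
    def test_planted_hazard_recovery(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        risk = 2.0 * X[:, 0]
        T = rng.exponential(1.0 / np.exp(risk))
        E = np.ones(200, dtype=int)
        net, hist = train_survival_net(
            X, T, E, SurvivalConfig(epochs=200, seed=0))
        r = net.forward(X)
        assert abs(spearmanr(r, X[:, 0]).statistic) > 0.8
        assert hist["c_index"].iloc[-1] > hist["c_index"].iloc[0]

    def test_permuted_events_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 3))
        T = rng.permutation(rng.exponential(size=200))
        net, _ = train_survival_net(
            X, T, np.ones(200, int),
            SurvivalConfig(epochs=100, hidden_layout=(), seed=1))
        c = concordance_index(net.forward(X), T, np.ones(200, int))
        assert abs(c - 0.5) < 0.1

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(50, 2))
        T = rng.exponential(size=50)
        E = np.ones(50, int)
        cfg = SurvivalConfig(epochs=20, seed=4)
        n1, _ = train_survival_net(X, T, E, cfg)
        n2, _ = train_survival_net(X, T, E, cfg)
        np.testing.assert_array_equal(n1.forward(X), n2.forward(X))

    def test_all_censored_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="event"):
            train_survival_net(X, np.arange(10.0), np.zeros(10, int),
                               SurvivalConfig(epochs=1))


class TestSurvF:
    def test_constant_output_maps_to_zeros(self):
        net = CoxRiskNet(3, hidden_layout=(4,), seed=0)
        for W in net.W:
            W[:] = 0.0
        X = np.ones((5, 3))
        np.testing.assert_array_equal(compute_survf(net, X), np.zeros(5))

    def test_normalization_preserves_ranking(self, rng):
        net = CoxRiskNet(3, seed=2)
        X = rng.normal(size=(20, 3))
        survf = compute_survf(net, X)
        raw = net.forward(X)
        assert (np.argsort(survf) == np.argsort(raw)).all()
        assert abs(survf.mean()) < 1e-9

    def test_saved_model_round_trips(self, tmp_path, rng):
        net = CoxRiskNet(4, seed=7)
        X = rng.normal(size=(15, 4))
        p = tmp_path / "coxnet.npz"
        net.save(p)
        back = CoxRiskNet.load(p)
        np.testing.assert_array_equal(compute_survf(net, X),
                                      compute_survf(back, X))

    def test_default_event_rule_is_poor_outcome(self):
        np.testing.assert_array_equal(
            default_event_rule([0, 1, 2, 3, 4, 5, 6]),
            [0, 0, 0, 1, 1, 1, 1])
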