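import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milsurv.datatypes import RiskPrediction
from milsurv.errors import (DegenerateGroupsError, HorizonError,
                            NoComparablePairsError, ParameterError)
from milsurv.evaluate import (bootstrap_delta_c, cox_hr_binary, harrell_c,
                              ipcw_auc, km_estimate, stratify_quantile,
                              timepoint_auc_panel, zscore_by_fold)
from milsurv.synthetic import make_cohort, strong_signal_config


def _preds(fold_risks: dict[int, list[float]]) -> list[RiskPrediction]:
    out = []
    for fold, risks in fold_risks.items():
        for i, r in enumerate(risks):
            out.append(RiskPrediction(slide_id=f"f{fold}s{i}", fold_id=fold,
                                      risk_raw=float(r)))
    return out


class TestZScoreByFold:
    def test_analytic_three_values(self):
        out, stats = zscore_by_fold(_preds({0: [1, 2, 3]}))
        np.testing.assert_allclose([p.risk_std for p in out],
                                   [-1.224744871, 0.0, 1.224744871], atol=1e-8)
        assert stats[0].std == pytest.approx(0.816496580927726)

    def test_mean_zero_unit_sigma_per_fold(self):
        rng = np.random.default_rng(0)
        out, _ = zscore_by_fold(_preds({0: rng.normal(5, 3, 20).tolist(),
                                        1: rng.normal(-2, 0.5, 15).tolist()}))
        for f in (0, 1):
            z = np.array([p.risk_std for p in out if p.fold_id == f])
            assert z.mean() == pytest.approx(0.0, abs=1e-9)
            assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_rank_preserved_within_fold(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(1)
        raw = rng.normal(size=30)
        out, _ = zscore_by_fold(_preds({0: raw.tolist()}))
        z = np.array([p.risk_std for p in out])
        assert spearmanr(raw, z).statistic == pytest.approx(1.0)

    def test_zero_spread_fold_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out, _ = zscore_by_fold(_preds({0: [2.0, 2.0, 2.0]}))
        assert all(p.risk_std == 0.0 for p in out)

    def test_single_prediction_fold_rejected(self):
        with pytest.raises(ParameterError):
            zscore_by_fold(_preds({0: [1.0]}))

    def test_standardization_repairs_fold_scale_distortion(self):
        # two folds carry the same signal but wildly different calibration:
        # pooling raw risks scrambles cross-fold order, z-scoring restores it
        rng = np.random.default_rng(2)
        n = 40
        times = rng.exponential(20, 2 * n) + 0.1
        events = np.ones(2 * n, dtype=int)
        signal = -times  # perfect risk
        raw = signal.copy()
        raw[:n] = 0.05 * signal[:n] + 40.0   # fold 0 squashed and offset
        raw[n:] = 3.0 * signal[n:] - 7.0     # fold 1 stretched
        preds = [RiskPrediction(slide_id=f"s{i}", fold_id=int(i >= n),
                                risk_raw=float(raw[i])) for i in range(2 * n)]
        c_before = harrell_c(raw, times, events)
        out, _ = zscore_by_fold(preds)
        c_after = harrell_c([p.risk_std for p in out], times, events)
        assert c_after >= c_before


def oracle_harrell_c(risks, times, events):
    """Independent O(n^2) pair-enumeration oracle."""
    conc = ties = comp = 0
    for i in range(len(risks)):
        if events[i] != 1:
            continue
        for j in range(len(risks)):
            if times[i] < times[j]:
                comp += 1
                if risks[i] > risks[j]:
                    conc += 1
                elif risks[i] == risks[j]:
                    ties += 1
    if comp == 0:
        raise ZeroDivisionError
    return (conc + 0.5 * ties) / comp


class TestHarrellC:
    def test_perfect_ordering(self):
        assert harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_anti_ordering(self):
        assert harrell_c([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 0.0

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = 60
            risks = rng.normal(size=n)
            risks[rng.uniform(size=n) < 0.2] = 0.0  # force risk ties
            times = rng.exponential(10, n) + 0.1
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            assert harrell_c(risks, times, events) == \
                oracle_harrell_c(risks, times, events)

    def test_reversal_symmetry_without_ties(self):
        rng = np.random.default_rng(4)
        risks = rng.normal(size=50)
        times = rng.exponential(10, 50) + 0.1
        events = rng.integers(0, 2, 50)
        events[0] = 1
        assert harrell_c(risks, times, events) + \
            harrell_c(-risks, times, events) == pytest.approx(1.0)

    @given(st.integers(min_value=0, max_value=2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        risks = rng.normal(size=30)
        times = rng.exponential(10, 30) + 0.1
        events = np.ones(30, dtype=int)
        c1 = harrell_c(risks, times, events)
        c2 = harrell_c(np.exp(2.0 * risks) + 5.0, times, events)
        assert c1 == pytest.approx(c2)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(NoComparablePairsError):
            harrell_c([1, 2], [5.0, 5.0], [1, 1])  # tied times, no order

    def test_agrees_with_scikit_survival(self):
        from sksurv.metrics import concordance_index_censored
        rng = np.random.default_rng(5)
        n = 120
        times = rng.exponential(30, n) + rng.uniform(0, 1e-9, n)
        events = rng.integers(0, 2, n).astype(bool)
        events[:3] = True
        risks = -times + rng.normal(0, 15, n)
        ours = harrell_c(risks, times, events.astype(int))
        theirs = concordance_index_censored(events, times, risks)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_censored_middle_subject(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(3.0) == pytest.approx(0.0)

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.survival_at(100.0) == 1.0
        assert len(curve.times) == 0

    def test_probabilities_non_increasing_start_at_one(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(5, 200) + 0.01
        e = rng.integers(0, 2, 200)
        curve = km_estimate(t, e)
        assert curve.survival_at(0.0) == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_empirical_survival_random_uncensored(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(5, 100) + 0.01
        curve = km_estimate(t, np.ones(100, dtype=int))
        for q in (1.0, 3.0, 8.0):
            assert curve.survival_at(q) == pytest.approx((t > q).mean())

    def test_left_limit(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert curve.survival_at(2.0, side="left") == pytest.approx(2 / 3)
        assert curve.survival_at(2.0, side="right") == pytest.approx(1 / 3)

    def test_agrees_with_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(8)
        t = rng.exponential(10, 150) + 0.01
        e = rng.integers(0, 2, 150)
        e[0] = 1
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for u in curve.times:
            assert curve.survival_at(u) == \
                pytest.approx(float(kmf.predict(u)), abs=1e-10)


class TestStratifyQuantile:
    def test_median_split(self):
        g = stratify_quantile(np.arange(1.0, 9.0), 0.5)
        assert len(g.low_idx) == 4 and len(g.high_idx) == 4

    def test_upper_quartile_split(self):
        g = stratify_quantile(np.arange(1.0, 9.0), 0.75)
        assert len(g.low_idx) == 6 and len(g.high_idx) == 2

    def test_subset_partition(self):
        risks = np.arange(20.0)
        subset = risks[risks >= 12]  # a grade-like subgroup
        g = stratify_quantile(subset, 0.75)
        assert len(g.low_idx) + len(g.high_idx) == len(subset)
        assert len(g.high_idx) == 2

    def test_partition_is_complete_and_disjoint(self):
        rng = np.random.default_rng(9)
        risks = rng.normal(size=33)
        g = stratify_quantile(risks, 0.25)
        both = np.concatenate([g.low_idx, g.high_idx])
        assert sorted(both) == list(range(33))

    def test_identical_risks_rejected(self):
        with pytest.raises(DegenerateGroupsError):
            stratify_quantile(np.ones(10), 0.5)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.5])
    def test_invalid_quantile(self, q):
        with pytest.raises(ParameterError):
            stratify_quantile(np.arange(5.0), q)


class TestCoxHRBinary:
    def test_identical_groups_give_unit_hr(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        events = np.ones(8, dtype=int)
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = cox_hr_binary(group, times, events)
        assert not res.diverged
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=int)
        group = np.array([1, 0, 1, 0])
        # independent vectorized grid over the Breslow partial likelihood
        betas = np.linspace(-3, 3, 600001)
        eb = np.exp(betas)
        # risk sets: t=1 {1,0,1,0}, t=2 {0,1,0}, t=3 {1,0}, t=4 {0}
        ll = (betas - np.log(2 * eb + 2)
              + 0.0 - np.log(eb + 2)
              + betas - np.log(eb + 1)
              + 0.0 - np.log(np.ones_like(eb)))
        beta_grid = betas[np.argmax(ll)]
        res = cox_hr_binary(group, times, events)
        assert res.log_hr == pytest.approx(beta_grid, abs=1e-4)

    def test_monotone_likelihood_flagged(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=int)
        group = np.array([1, 1, 0, 0])  # all early deaths in one group
        res = cox_hr_binary(group, times, events)
        assert res.diverged
        assert np.isinf(res.hazard_ratio)

    def test_agrees_with_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(10)
        n = 80
        group = rng.integers(0, 2, n)
        times = rng.exponential(10 / (1 + group), n) + rng.uniform(0, 1e-9, n)
        events = rng.integers(0, 2, n)
        events[:4] = 1
        res = cox_hr_binary(group, times, events)
        df = pd.DataFrame({"t": times, "e": events, "x": group})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        # both optimizers converge to the same maximum within solver tolerance
        assert res.log_hr == pytest.approx(float(cph.params_["x"]), abs=1e-4)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            cox_hr_binary(np.zeros(4, dtype=int), np.arange(1.0, 5.0),
                          np.ones(4, dtype=int))


class TestIPCWAUC:
    def test_perfect_separation(self):
        auc = ipcw_auc([4, 3, 2, 1], [1, 2, 3, 4], [1, 1, 1, 1], 2.5)
        assert auc == 1.0

    def test_all_risks_equal(self):
        assert ipcw_auc([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1], 2.5) == 0.5

    def test_reduces_to_rank_sum_auc_without_censoring(self):
        rng = np.random.default_rng(11)
        n = 100
        times = rng.exponential(10, n) + 0.01
        risks = -times + rng.normal(0, 5, n)
        events = np.ones(n, dtype=int)
        horizon = float(np.median(times))
        label = (times <= horizon).astype(int)
        # plain Mann-Whitney oracle
        pos, neg = risks[label == 1], risks[label == 0]
        auc_oracle = ((pos[:, None] > neg[None, :]).sum()
                      + 0.5 * (pos[:, None] == neg[None, :]).sum()) \
            / (len(pos) * len(neg))
        assert ipcw_auc(risks, times, events, horizon) == pytest.approx(auc_oracle)

    def test_agrees_with_scikit_survival(self):
        from sksurv.metrics import cumulative_dynamic_auc
        rng = np.random.default_rng(12)
        n = 150
        times = rng.exponential(30, n) + rng.uniform(0, 1e-6, n)
        events = rng.integers(0, 2, n).astype(bool)
        events[:3] = True
        risks = -times + rng.normal(0, 20, n)
        y = np.array(list(zip(events, times)), dtype=[("e", "?"), ("t", "<f8")])
        for h in (10.0, 25.0):
            theirs = cumulative_dynamic_auc(y, y, risks, [h])[0][0]
            assert ipcw_auc(risks, times, events.astype(int), h) == \
                pytest.approx(theirs, abs=1e-10)

    def test_no_cases_rejected(self):
        with pytest.raises(HorizonError):
            ipcw_auc([1, 2], [5.0, 6.0], [1, 1], 1.0)

    def test_no_controls_rejected(self):
        with pytest.raises(HorizonError):
            ipcw_auc([1, 2], [1.0, 2.0], [1, 1], 10.0)


class TestAUCPanel:
    def test_three_horizons(self):
        rng = np.random.default_rng(13)
        n = 200
        times = rng.exponential(40, n) + 0.01
        events = rng.integers(0, 2, n)
        risks = -times + rng.normal(0, 20, n)
        panel = timepoint_auc_panel(risks, times, events)
        assert set(panel) == {12.0, 36.0, 60.0}
        assert all(0.0 <= v <= 1.0 for v in panel.values())

    def test_horizon_beyond_followup_raises_with_id(self):
        rng = np.random.default_rng(14)
        times = rng.uniform(1, 30, 50)
        with pytest.raises(HorizonError) as exc:
            timepoint_auc_panel(-times, times, np.ones(50, dtype=int),
                                horizons=(12.0, 500.0))
        assert exc.value.horizon == 500.0

    def test_oracle_risk_auc_decreases_from_1y_to_5y(self):
        # tendency check, frozen seeds: early discrimination is at least as
        # good as late discrimination in >= 4 of 5 cohorts
        wins = 0
        for seed in range(5):
            cohort = make_cohort(strong_signal_config(
                n_slides=600, seed=seed, baseline_rate=5e-3))
            eta = cohort.truth["eta"].to_numpy()
            panel = timepoint_auc_panel(eta, cohort.times(), cohort.events(),
                                        horizons=(12.0, 60.0))
            wins += panel[12.0] >= panel[60.0]
        assert wins >= 4


class TestBootstrapDeltaC:
    def _data(self, n=60, seed=15):
        rng = np.random.default_rng(seed)
        times = rng.exponential(10, n) + 0.01
        events = rng.integers(0, 2, n)
        events[:3] = 1
        return times, events

    def test_identical_models(self):
        times, events = self._data()
        risks = -times + np.random.default_rng(0).normal(0, 3, len(times))
        res = bootstrap_delta_c(risks, risks, times, events, n_iter=200, seed=0)
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)
        assert res.p_value == 1.0
        assert res.delta_c == 0.0

    def test_deterministic_extremes(self):
        times = np.arange(1.0, 31.0)
        events = np.ones(30, dtype=int)
        res = bootstrap_delta_c(-times, times, times, events, n_iter=100, seed=1)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        times, events = self._data()
        rng = np.random.default_rng(1)
        ra, rb = rng.normal(size=60), rng.normal(size=60)
        r1 = bootstrap_delta_c(ra, rb, times, events, n_iter=100, seed=9)
        r2 = bootstrap_delta_c(ra, rb, times, events, n_iter=100, seed=9)
        np.testing.assert_array_equal(r1.deltas, r2.deltas)
        assert (r1.ci_low, r1.ci_high, r1.p_value) == \
            (r2.ci_low, r2.ci_high, r2.p_value)

    def test_ci_contains_point_estimate_typically(self):
        times, events = self._data(n=100, seed=16)
        rng = np.random.default_rng(2)
        ra = -times + rng.normal(0, 5, 100)
        rb = rng.normal(size=100)
        res = bootstrap_delta_c(ra, rb, times, events, n_iter=300, seed=3)
        assert res.ci_low <= res.delta_c <= res.ci_high
        assert res.p_value < 0.05  # a real signal difference
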