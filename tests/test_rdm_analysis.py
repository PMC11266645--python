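import numpy as np
import pandas as pd
import pytest

from fishrdm import InvalidArgumentError, economics
from fishrdm import population_model as pm
from fishrdm import rdm_analysis as ra
from fishrdm import synthetic_data as sd


def toy_ensemble(records):
    """Build an EnsembleResults-like object from hand-written run records.

    Each record: (run_id, policy_type, level, [(year, ssb, fbar, profit)]).
    """
    long_rows, sum_rows = [], []
    for run_id, ptype, level, years in records:
        ok_all = True
        for year, ssb, fbar, profit in years:
            long_rows.append({"run_id": run_id, "sr_form": "env_ricker",
                              "scenario": "moderate", "scheme_id": run_id,
                              "policy_type": ptype, "level": level,
                              "year": year, "ssb": ssb, "fbar": fbar,
                              "catch": 0.0, "recruits": 1.0,
                              "profit": profit, "collapsed": False})
            ok_all &= (ssb >= 97_800.0) and (fbar <= 0.28)
        sum_rows.append({"run_id": run_id, "sr_form": "env_ricker",
                         "scenario": "moderate", "scheme_id": run_id,
                         "policy_type": ptype, "level": level,
                         "log_alpha": 10.0, "dd_log": 12.0, "gamma": 0.8,
                         "sustainable_years": sum(
                             1 for y in years
                             if y[1] >= 97_800.0 and y[2] <= 0.28),
                         "success": ok_all, "collapsed": False,
                         "infeasible_years": 0})

    class Toy:
        long = pd.DataFrame(long_rows)
        summary = pd.DataFrame(sum_rows)

    return Toy()


class TestSustainableYears:
    def test_all_pass_and_all_fail(self, refpts):
        years = np.arange(2030, 2101)
        run = pm.RunResult(years=years, ssb=np.full(71, 2e5),
                           fbar=np.zeros(71), catch=np.zeros(71),
                           recruits=np.ones(71), profit=np.zeros(71),
                           collapsed=False, collapse_year=None,
                           catch_infeasible_years=[])
        assert ra.sustainable_years(run, refpts) == 71
        bad = pm.RunResult(years=years, ssb=np.full(71, 5e4),
                           fbar=np.zeros(71), catch=np.zeros(71),
                           recruits=np.ones(71), profit=np.zeros(71),
                           collapsed=False, collapse_year=None,
                           catch_infeasible_years=[])
        assert ra.sustainable_years(bad, refpts) == 0

    def test_manual_enumeration(self, refpts):
        years = np.arange(2030, 2035)
        ssb = np.array([2e5, 5e4, 2e5, 2e5, 2e5])
        fbar = np.array([0.1, 0.1, 0.2, 0.1, 0.5])  # pattern 1,0,1,1,0
        run = pm.RunResult(years=years, ssb=ssb, fbar=fbar,
                           catch=np.zeros(5), recruits=np.ones(5),
                           profit=np.zeros(5), collapsed=False,
                           collapse_year=None, catch_infeasible_years=[])
        assert ra.sustainable_years(run, refpts) == 3

    def test_post_collapse_years_excluded(self, refpts):
        years = np.arange(2030, 2035)
        run = pm.RunResult(years=years, ssb=np.full(5, 2e5),
                           fbar=np.zeros(5), catch=np.zeros(5),
                           recruits=np.ones(5), profit=np.zeros(5),
                           collapsed=True, collapse_year=2033,
                           catch_infeasible_years=[])
        assert ra.sustainable_years(run, refpts) == 3


class TestRisks:
    def test_all_violate_and_fraction(self, refpts):
        ens = toy_ensemble([
            (0, "constant_catch", 10.0, [(2030, 5e4, 0.1, 0.0)]),
            (1, "constant_catch", 10.0, [(2030, 5e4, 0.1, 0.0)]),
        ])
        assert ra.sustainability_risk(ens, refpts, [0, 1], "full") == 100.0
        ens2 = toy_ensemble([
            (i, "constant_catch", 10.0,
             [(2030, 5e4 if i == 0 else 2e5, 0.1, 0.0)])
            for i in range(4)])
        assert ra.sustainability_risk(ens2, refpts, range(4), "full") == 25.0

    def test_brute_force_recount(self, refpts, econ):
        rng = np.random.default_rng(7)
        records = []
        for run_id in range(20):
            years = [(int(y), float(rng.uniform(5e4, 3e5)),
                      float(rng.uniform(0, 0.6)),
                      float(rng.uniform(-1e7, 2e8)))
                     for y in range(2030, 2101)]
            records.append((run_id, "constant_catch",
                            float(rng.uniform(1, 100)), years))
        ens = toy_ensemble(records)
        for period, (lo, hi) in ra.PERIODS.items():
            # independent brute-force filter over the raw records
            n_sus = n_prof = 0
            for run_id, _, _, years in records:
                sus = any(lo <= y <= hi and (ssb < 97_800.0 or fbar > 0.28)
                          for y, ssb, fbar, _ in years)
                prof = any(lo <= y <= hi and p < econ.reference_profit
                           for y, _, _, p in years)
                n_sus += sus
                n_prof += prof
            assert ra.sustainability_risk(ens, refpts, range(20), period) \
                == pytest.approx(100.0 * n_sus / 20)
            assert ra.profitability_risk(ens, econ, range(20), period) \
                == pytest.approx(100.0 * n_prof / 20)

    def test_zero_catch_profitability_risk_is_total(self, biology,
                                                    ricker_truth, sst_bank,
                                                    refpts, econ):
        """With a positive profitability reference, never fishing means the
        profit objective fails in every projection."""
        params, _ = ricker_truth
        assert econ.reference_profit > 0
        run = pm.project(biology, params, pm.PolicySpec("constant_catch", 0.0),
                         sst_bank["moderate"], refpts, econ=econ)
        assert np.all(run.profit < econ.reference_profit)

    def test_empty_bin_rejected(self, refpts):
        ens = toy_ensemble([(0, "constant_catch", 1.0,
                             [(2030, 2e5, 0.0, 0.0)])])
        with pytest.raises(InvalidArgumentError):
            ra.sustainability_risk(ens, refpts, [], "full")


class TestFeatureScores:
    def test_planted_policy_signal_dominates(self, refpts):
        """When sustainable_years depends only on policy level, the policy
        predictor takes essentially all the importance and a zero-variance
        predictor none."""
        rng = np.random.default_rng(0)
        sum_rows = []
        for i in range(600):
            level = rng.uniform(0, 100)
            sum_rows.append({"run_id": i, "sr_form": "env_ricker",
                             "scenario": "moderate", "scheme_id": i,
                             "policy_type": "constant_catch", "level": level,
                             "log_alpha": rng.uniform(8.67, 12.02),
                             "dd_log": 12.27,  # zero variance
                             "gamma": rng.uniform(0.64, 0.95),
                             "sustainable_years": int(71 * np.exp(-level / 30)),
                             "success": False, "collapsed": False,
                             "infeasible_years": 0})

        class Toy:
            summary = pd.DataFrame(sum_rows)
            long = pd.DataFrame()

        scores = ra.feature_scores(Toy(), "env_ricker", "constant_catch")
        assert scores.importances["level"] > 0.9
        assert scores.importances["dd_log"] <= 0.01
        assert scores.importances.sum() == pytest.approx(1.0, abs=1e-9)
        surface = scores.partial_dependence[("level", "log_alpha")]
        assert surface["values"].shape == (20, 20)

    def test_empty_stratum_rejected(self, small_ensemble):
        with pytest.raises(InvalidArgumentError):
            ra.feature_scores(small_ensemble, "env_ricker", "nope")


class TestDiscoverSuccessful:
    def test_no_success_and_single_success(self, refpts):
        ens = toy_ensemble([
            (0, "constant_catch", 1.0, [(2030, 2e5, 0.0, 0.0),
                                        (2031, 5e4, 0.0, 0.0)]),
            (1, "constant_catch", 2.0, [(2030, 2e5, 0.0, 0.0),
                                        (2031, 2e5, 0.0, 0.0)]),
        ])
        subset, _ = ra.discover_successful(ens, refpts)
        assert list(subset["run_id"]) == [1]

    def test_planted_threshold_recovered(self, refpts):
        """Success iff level < 40; the recovered boundary between all-success
        and no-success bins lies within one grid bin of 40."""
        rng = np.random.default_rng(1)
        records = []
        for i in range(400):
            level = float(rng.uniform(0, 100))
            good = level < 40.0
            records.append((i, "constant_catch", level,
                            [(2030, 2e5 if good else 5e4, 0.0, 0.0)]))
        ens = toy_ensemble(records)
        _, char = ra.discover_successful(ens, refpts, n_bins=25)
        char = char.sort_values("level")
        full = char[char["success_pct"] == 100.0]["bin_right"].max()
        empty = char[char["success_pct"] == 0.0]["bin_left"].min()
        width = (char["bin_right"] - char["bin_left"]).iloc[0]
        assert abs(full - 40.0) <= width and abs(empty - 40.0) <= width

    def test_success_subset_consistent_with_zero_risk(self, small_ensemble,
                                                      refpts):
        subset, _ = ra.discover_successful(small_ensemble, refpts)
        for run_id in subset["run_id"]:
            assert ra.sustainability_risk(small_ensemble, refpts, [run_id],
                                          "full") == 0.0


class TestTradeoff:
    def test_direct_three_level_example(self, refpts, econ):
        # risks (10,90), (40,42), (80,15): middle level has ratio nearest 1
        curve = pd.DataFrame({
            "level": [1.0, 2.0, 3.0],
            "sustainability_risk": [10.0, 40.0, 80.0],
            "profitability_risk": [90.0, 42.0, 15.0]})
        s = curve["sustainability_risk"].to_numpy()
        p = curve["profitability_risk"].to_numpy()
        ratio = np.abs(np.log(s / p))
        assert curve["level"][np.argmin(ratio)] == 2.0
        assert curve["level"][np.argmin(s + p)] == 2.0

    def test_selections_match_exhaustive_search(self, small_ensemble, refpts,
                                                econ):
        curve, sel = ra.tradeoff(small_ensemble, refpts, econ,
                                 "harvest_rate", "full", n_bins=6)
        t = curve.table.dropna(subset=["sustainability_risk",
                                       "profitability_risk"])
        best_sum, best_ratio, best_sum_lvl, best_ratio_lvl = (
            np.inf, np.inf, None, None)
        for _, row in t.iterrows():
            s, p = row["sustainability_risk"], row["profitability_risk"]
            if s + p < best_sum:
                best_sum, best_sum_lvl = s + p, row["level"]
            r = abs(np.log((s + 1e-12) / (p + 1e-12)))
            if r < best_ratio:
                best_ratio, best_ratio_lvl = r, row["level"]
        assert sel["min_sum_level"] == pytest.approx(best_sum_lvl)
        assert sel["ratio_one_level"] == pytest.approx(best_ratio_lvl)

    def test_double_zero_wins_min_sum(self, refpts, econ):
        ens = toy_ensemble([
            (0, "constant_catch", 1.0, [(2030, 2e5, 0.0, 1e9)]),
            (1, "constant_catch", 50.0, [(2030, 5e4, 0.5, -1e9)]),
            (2, "constant_catch", 99.0, [(2030, 5e4, 0.5, -1e9)]),
        ])
        _, sel = ra.tradeoff(ens, refpts, econ, "constant_catch", "full",
                             n_bins=3)
        assert sel["min_sum_level"] < 20.0
        assert sel["min_sum_risks"] == (0.0, 0.0)
        assert sel["ratio_one_level"] < 20.0  # both-zero ratio is exactly 1


class TestTemporalRisk:
    def test_never_violating_policy_is_flat_zero(self, refpts, econ):
        ens = toy_ensemble([
            (0, "constant_catch", 1.0, [(y, 2e5, 0.0, 1e9)
                                        for y in range(2030, 2040)])])
        per_policy, env = ra.temporal_risk(ens, refpts, econ,
                                           "constant_catch")
        assert np.all(per_policy["risk_pct"] == 0.0)
        assert np.all(env["median"] == 0.0)

    def test_envelopes_match_direct_sorting(self, refpts, econ):
        rng = np.random.default_rng(3)
        records = []
        for i, level in enumerate([1.0, 2.0, 3.0]):
            for rep in range(4):
                years = [(int(y), float(rng.choice([5e4, 2e5])), 0.0, 0.0)
                         for y in range(2030, 2034)]
                records.append((i * 4 + rep, "constant_catch", level, years))
        ens = toy_ensemble(records)
        per_policy, env = ra.temporal_risk(ens, refpts, econ,
                                           "constant_catch")
        for year in range(2030, 2034):
            series = per_policy[per_policy["year"] == year].sort_values(
                "level")["risk_pct"].to_numpy()
            row = env[env["year"] == year].iloc[0]
            assert row["median"] == pytest.approx(np.percentile(series, 50))
            assert row["q25"] == pytest.approx(np.percentile(series, 25))
            assert row["q75"] == pytest.approx(np.percentile(series, 75))

    def test_single_policy_median_is_its_series(self, refpts, econ):
        ens = toy_ensemble([
            (0, "harvest_rate", 0.1, [(2030, 5e4, 0.0, 0.0),
                                      (2031, 2e5, 0.0, 0.0)])])
        per_policy, env = ra.temporal_risk(ens, refpts, econ, "harvest_rate")
        np.testing.assert_allclose(env["median"].to_numpy(),
                                   per_policy["risk_pct"].to_numpy())
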