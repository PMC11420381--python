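"""KM, Cox and time-dependent Cox baselines against exact oracles."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, CoxTimeVaryingFitter

from ttcjoint import survival as sv


# ---------------------------------------------------------------------------
# brute-force Efron partial likelihood (independent of the package implementation)

def brute_force_efron_loglik(start, stop, event, X, beta):
    """Direct evaluation of the Efron partial likelihood via explicit risk sets."""
    start, stop = np.asarray(start, float), np.asarray(stop, float)
    event = np.asarray(event, int)
    X = np.asarray(X, float)
    eta = X @ np.asarray(beta, float)
    ll = 0.0
    for t in sorted(set(stop[event == 1])):
        risk = [i for i in range(len(stop)) if start[i] < t <= stop[i]]
        ties = [i for i in risk if stop[i] == t and event[i] == 1]
        d = len(ties)
        sum_risk = sum(np.exp(eta[i]) for i in risk)
        sum_ties = sum(np.exp(eta[i]) for i in ties)
        ll += sum(eta[i] for i in ties)
        for j in range(d):
            ll -= np.log(sum_risk - (j / d) * sum_ties)
    return ll


def random_small_dataset(rng, n, time_dependent=False):
    """Random counting-process data with ties, n <= 6 subjects."""
    rows = []
    for i in range(n):
        x = rng.integers(0, 2)
        z = rng.normal()
        if time_dependent and rng.random() < 0.5:
            t_switch = float(rng.integers(1, 4))
            t_end = t_switch + float(rng.integers(1, 4))
            rows.append((f"S{i}", 0.0, t_switch, 0, x, z))
            rows.append((f"S{i}", t_switch, t_end, int(rng.random() < 0.7), 1 - x, z + 1))
        else:
            t_end = float(rng.integers(1, 6))
            rows.append((f"S{i}", 0.0, t_end, int(rng.random() < 0.7), x, z))
    df = pd.DataFrame(rows, columns=["patient_id", "start", "stop", "event", "x", "z"])
    if df["event"].sum() < 2:
        df.loc[df.index[-1], "event"] = 1
        df.loc[df.index[0], "event"] = 1
    return df


class TestPartialLikelihoodOracle:
    @pytest.mark.parametrize("td", [False, True])
    def test_matches_brute_force_on_small_data(self, td):
        rng = np.random.default_rng(17)
        grid = [np.array([0.0, 0.0]), np.array([0.5, -0.3]),
                np.array([-1.0, 0.7]), np.array([2.0, 0.1])]
        for n in (3, 4, 5, 6):
            for rep in range(5):
                df = random_small_dataset(rng, n, time_dependent=td)
                X = df[["x", "z"]].to_numpy(float)
                for beta in grid:
                    mine, _, _ = sv._partial_loglik(
                        beta, df["start"].to_numpy(float), df["stop"].to_numpy(float),
                        df["event"].to_numpy(int), X)
                    oracle = brute_force_efron_loglik(
                        df["start"], df["stop"], df["event"], X, beta)
                    assert mine == pytest.approx(oracle, abs=1e-6)

    def test_two_event_score_root_solved_by_hand(self):
        # subjects A (x=1, event t=1), B (x=0, event t=2), C (x=1, censored t=3).
        # With u = e^b the score is 1 - 2u/(2u+1) - u/(1+u) = 0 whose root is
        # u^2 = 1/2, i.e. b = -log(2)/2.
        df = pd.DataFrame({
            "patient_id": ["A", "B", "C"],
            "time_months": [1.0, 2.0, 3.0],
            "event": [1, 1, 0],
            "x": [1.0, 0.0, 1.0],
        })
        fit = sv.cox_fit(df, ["x"])
        assert fit.coef["x"] == pytest.approx(-0.5 * np.log(2.0), abs=1e-8)

    def test_constant_covariate_pinned_at_zero(self):
        df = pd.DataFrame({
            "patient_id": list("ABCD"), "time_months": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 0], "c": [1.0, 1.0, 1.0, 1.0],
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sv.cox_fit(df, ["c"])
        assert fit.coef["c"] == 0.0
        assert fit.loglik == pytest.approx(fit.loglik_null)
        assert "c" in fit.constant

    def test_duplicated_dataset_halves_variance(self):
        df = pd.DataFrame({
            "patient_id": list("ABCDEF"),
            "time_months": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 0, 1],
            "x": [1.0, 0.0, 1.0, 0.0, 0.0, 1.0],
            "z": [0.2, -0.5, 1.0, 0.3, -1.2, 0.7],
        })
        dup = pd.concat([df, df.assign(patient_id=df["patient_id"] + "dup")],
                        ignore_index=True)
        # under Breslow ties the duplicated partial likelihood is exactly the
        # original doubled, so estimates coincide and information doubles
        # (Efron's within-tie correction would couple the two copies)
        f1 = sv.cox_fit(df, ["x", "z"], ties="breslow")
        f2 = sv.cox_fit(dup, ["x", "z"], ties="breslow")
        np.testing.assert_allclose(f2.coef, f1.coef, rtol=1e-6)
        np.testing.assert_allclose(f2.se, f1.se / np.sqrt(2.0), rtol=1e-6)

    def test_collinear_covariates_rejected(self):
        df = pd.DataFrame({
            "patient_id": list("ABCD"), "time_months": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 0], "x": [0.0, 1.0, 0.0, 1.0],
        })
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(ValueError, match="collinear"):
            sv.cox_fit(df, ["x", "x2"])

    def test_separation_flagged(self):
        df = pd.DataFrame({
            "patient_id": list("ABCDEF"), "time_months": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 0, 0, 0], "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        })
        with pytest.warns(UserWarning, match="monotone"):
            fit = sv.cox_fit(df, ["x"])
        assert fit.diverged


class TestAgainstLifelines:
    def test_baseline_cox_cross_check(self, raw_cohort):
        _, surv_df, _ = raw_cohort
        df = surv_df.copy()
        fit = sv.cox_fit(df, ["prior_alki", "weight_kg"])
        cph = CoxPHFitter()
        cph.fit(df[["time_months", "event", "prior_alki", "weight_kg"]],
                "time_months", "event")
        np.testing.assert_allclose(fit.coef, cph.params_.values, rtol=1e-3, atol=5e-4)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, rtol=1e-3)

    def test_time_varying_cross_check(self, raw_cohort):
        long_df, surv_df, _ = raw_cohort
        rec = long_df.rename(columns={"t_obs_months": "t", "conc_ng_ml": "val"})
        cp = sv.expand_lvcf(surv_df, rec, value_col="val")
        cp = cp.merge(surv_df[["patient_id", "prior_alki"]], on="patient_id")
        fit = sv.td_cox_fit(cp, ["val", "prior_alki"])
        ctv = CoxTimeVaryingFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(cp, id_col="patient_id", start_col="start", stop_col="stop",
                    event_col="event")
        np.testing.assert_allclose(fit.coef, ctv.params_.values, rtol=1e-4)


class TestTdReducesToBaseline:
    def test_single_interval_bitwise_equality(self):
        df = pd.DataFrame({
            "patient_id": list("ABCDEF"), "start": 0.0,
            "stop": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 0, 1],
            "x": [1.0, 0.0, 1.0, 0.0, 0.0, 1.0],
            "z": [0.2, -0.5, 1.0, 0.3, -1.2, 0.7],
        })
        base = df.rename(columns={"stop": "time_months"}).drop(columns=["start"])
        f_base = sv.cox_fit(base, ["x", "z"])
        f_td = sv.td_cox_fit(df, ["x", "z"])
        assert (f_base.coef == f_td.coef).all()
        assert (f_base.se == f_td.se).all()
        assert f_base.loglik == f_td.loglik

    def test_switch_after_last_event_is_invisible(self):
        base = pd.DataFrame({
            "patient_id": list("ABC"), "start": [0.0, 0.0, 0.0],
            "stop": [2.0, 4.0, 9.0], "event": [1, 1, 0], "x": [1.0, 0.0, 0.0],
        })
        switched = pd.concat([
            base.iloc[:2],
            pd.DataFrame({"patient_id": ["C", "C"], "start": [0.0, 5.0],
                          "stop": [5.0, 9.0], "event": [0, 0], "x": [0.0, 7.0]}),
        ], ignore_index=True)
        f1 = sv.td_cox_fit(base, ["x"])
        f2 = sv.td_cox_fit(switched, ["x"])
        assert f1.coef["x"] == pytest.approx(f2.coef["x"], abs=1e-10)

    def test_overlapping_intervals_rejected(self):
        rows = pd.DataFrame({
            "patient_id": ["A", "A", "B"], "start": [0.0, 1.0, 0.0],
            "stop": [2.0, 3.0, 4.0], "event": [0, 1, 1], "x": [0.0, 1.0, 0.5],
        })
        with pytest.raises(ValueError, match="overlap"):
            sv.td_cox_fit(rows, ["x"])


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        df = pd.DataFrame({"patient_id": list("ABC"),
                           "time_months": [1.0, 2.0, 3.0], "event": [1, 1, 1]})
        km = sv.km_fit(df)
        surv_at = dict(zip(km.times, km.survival))
        assert surv_at[1.0] == pytest.approx(2 / 3)
        assert surv_at[2.0] == pytest.approx(1 / 3)
        assert surv_at[3.0] == pytest.approx(0.0)
        assert km.median == pytest.approx(2.0)

    def test_hand_computed_with_censoring(self):
        # times 1+, 2, 3+, 4: the subject censored at 1 has left the risk set
        # by t=2, so S(2) = 1 - 1/3 = 2/3; at t=4 only one remains, S(4) = 0
        df = pd.DataFrame({"patient_id": list("ABCD"),
                           "time_months": [1.0, 2.0, 3.0, 4.0],
                           "event": [0, 1, 0, 1]})
        km = sv.km_fit(df)
        surv_at = dict(zip(km.times, km.survival))
        assert surv_at[2.0] == pytest.approx(2.0 / 3.0)
        assert surv_at[4.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, size=50).round(1) + 0.1
        df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(50)],
                           "time_months": t, "event": 1})
        km = sv.km_fit(df)
        for ti, si in zip(km.times, km.survival):
            assert si == pytest.approx(np.mean(t > ti))

    def test_all_censored_flat_at_one(self):
        df = pd.DataFrame({"patient_id": list("ABC"),
                           "time_months": [5.0, 6.0, 7.0], "event": [0, 0, 0]})
        with pytest.warns(UserWarning, match="no events"):
            km = sv.km_fit(df)
        assert np.all(km.survival == 1.0)
        assert not km.median_defined


class TestReverseKm:
    def test_all_censored_at_ten(self):
        df = pd.DataFrame({"patient_id": list("ABC"),
                           "time_months": [10.0, 10.0, 10.0], "event": [0, 0, 0]})
        assert sv.reverse_km_followup(df) == pytest.approx(10.0)

    def test_identity_with_flipped_km(self):
        df = pd.DataFrame({"patient_id": list("ABCDE"),
                           "time_months": [3.0, 8.0, 12.0, 20.0, 25.0],
                           "event": [1, 0, 1, 0, 0]})
        flipped = df.assign(event=1 - df["event"])
        assert sv.reverse_km_followup(df) == sv.km_fit(flipped).median

    def test_no_censoring_undefined(self):
        df = pd.DataFrame({"patient_id": ["A", "B"], "time_months": [1.0, 2.0],
                           "event": [1, 1]})
        with pytest.warns(UserWarning, match="undefined"):
            out = sv.reverse_km_followup(df)
        assert np.isnan(out)


class TestExpandLvcf:
    def _surv(self):
        return pd.DataFrame({"patient_id": ["A"], "time_months": [5.0], "event": [1]})

    def test_single_measurement_reduces_to_baseline(self):
        long = pd.DataFrame({"patient_id": ["A"], "t": [0.0], "ttc": [30.0]})
        cp = sv.expand_lvcf(self._surv(), long, value_col="ttc")
        assert len(cp) == 1
        row = cp.iloc[0]
        assert (row["start"], row["stop"], row["event"], row["ttc"]) == (0.0, 5.0, 1, 30.0)

    def test_two_measurements_rowwise(self):
        long = pd.DataFrame({"patient_id": ["A", "A"], "t": [0.0, 3.0],
                             "ttc": [30.0, 40.0]})
        cp = sv.expand_lvcf(self._surv(), long, value_col="ttc")
        assert cp[["start", "stop", "event", "ttc"]].values.tolist() == [
            [0.0, 3.0, 0, 30.0], [3.0, 5.0, 1, 40.0]]

    def test_exposure_time_preserved(self, raw_cohort):
        long_df, surv_df, _ = raw_cohort
        rec = long_df.rename(columns={"t_obs_months": "t"})
        cp = sv.expand_lvcf(surv_df, rec, value_col="conc_ng_ml")
        total = cp.groupby("patient_id").apply(
            lambda g: (g["stop"] - g["start"]).sum(), include_groups=False)
        surv_idx = surv_df.set_index("patient_id")["time_months"]
        for pid, tot in total.items():
            assert tot == pytest.approx(surv_idx[pid])

    def test_first_value_carried_back_vs_excluded(self):
        long = pd.DataFrame({"patient_id": ["A"], "t": [2.0], "ttc": [25.0]})
        carry = sv.expand_lvcf(self._surv(), long, value_col="ttc")
        assert carry[["start", "stop"]].values.tolist() == [[0.0, 5.0]]
        excl = sv.expand_lvcf(self._surv(), long, value_col="ttc", pre_first="exclude")
        assert excl[["start", "stop"]].values.tolist() == [[2.0, 5.0]]

    def test_measurement_after_event_dropped(self):
        long = pd.DataFrame({"patient_id": ["A", "A"], "t": [1.0, 6.0],
                             "ttc": [30.0, 40.0]})
        with pytest.warns(UserWarning, match="dropped"):
            cp = sv.expand_lvcf(self._surv(), long, value_col="ttc")
        assert len(cp) == 1 and cp.iloc[0]["ttc"] == 30.0

    def test_patient_without_usable_measurements_excluded(self):
        long = pd.DataFrame({"patient_id": ["A"], "t": [9.0], "ttc": [30.0]})
        with pytest.warns(UserWarning):
            cp = sv.expand_lvcf(self._surv(), long, value_col="ttc")
        assert len(cp) == 0

    def test_orphan_patient_rejected(self):
        long = pd.DataFrame({"patient_id": ["Z"], "t": [1.0], "ttc": [30.0]})
        with pytest.raises(ValueError, match="missing from survival"):
            sv.expand_lvcf(self._surv(), long, value_col="ttc")


class TestDichotomize:
    def test_boundary_counts_as_adequate(self):
        med = pd.Series([435.0, 434.9, 500.0, 100.0])
        out = sv.dichotomize_exposure(med)
        assert out.tolist() == [1, 0, 1, 0]

    def test_sensitivity_thresholds_relabel(self):
        med = pd.Series([450.0, 550.0, 650.0, 750.0])
        assert sv.dichotomize_exposure(med, 500.0).tolist() == [0, 1, 1, 1]
        assert sv.dichotomize_exposure(med, 700.0).tolist() == [0, 0, 0, 1]


class TestBackwardElimination:
    def _simulated(self, seed=6, n=150):
        rng = np.random.default_rng(seed)
        x_strong = rng.integers(0, 2, n).astype(float)
        x_null = rng.normal(size=n)
        expo = rng.normal(size=n)
        tt = rng.exponential(1.0 / np.exp(1.2 * x_strong - 0.3 * expo), size=n) * 10
        cens = rng.uniform(5, 30, n)
        return pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "time_months": np.minimum(tt, cens).round(2) + 0.01,
            "event": (tt <= cens).astype(int),
            "exposure": expo, "strong": x_strong, "nullcov": x_null,
        })

    def test_null_covariate_removed_strong_kept(self):
        df = self._simulated()
        fit, kept = sv.backward_eliminate(df, ["strong", "nullcov"], forced=("exposure",))
        assert kept == ["strong"]
        assert "nullcov" not in fit.coef.index

    def test_all_null_leaves_exposure_only(self):
        df = self._simulated()
        rng = np.random.default_rng(10)
        df["n1"] = rng.normal(size=len(df))
        df["n2"] = rng.normal(size=len(df))
        fit, kept = sv.backward_eliminate(df, ["n1", "n2"], forced=("exposure",))
        assert kept == []
        assert list(fit.coef.index) == ["exposure"]

    def test_alpha_one_retains_full_model(self):
        df = self._simulated()
        fit, kept = sv.backward_eliminate(df, ["strong", "nullcov"],
                                          forced=("exposure",), alpha=1.0000001)
        assert set(kept) == {"strong", "nullcov"}
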