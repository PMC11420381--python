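"""Joint-model building blocks: likelihood oracles, WAIC/LPML, summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tests.conftest import make_cohort
from ttcjoint import joint, survival as sv
from ttcjoint.hazard import HazardSpec, hazard
from ttcjoint.trajectory import Trajectory


def small_joint_inputs(seed=3, n=25):
    rec, surv_df, truth = make_cohort(seed=seed, n_patients=n)
    return rec, surv_df


def tiny_spec(**kw):
    mcmc = joint.McmcSettings(chains=kw.pop("chains", 2),
                              warmup=kw.pop("warmup", 50),
                              draws=kw.pop("draws", 100),
                              seed=kw.pop("seed", 0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return joint.JointModelSpec(mcmc=mcmc, **kw)


class TestAverageExposure:
    def test_constant_trajectory(self):
        tr = Trajectory(33.0, 0.0)
        for t in (0.0, 1.0, 12.0):
            assert joint.average_exposure(tr, t) == pytest.approx(33.0)

    def test_linear_closed_form(self):
        tr = Trajectory(10.0, 3.0)
        assert joint.average_exposure(tr, 8.0) == pytest.approx(10.0 + 3.0 * 8.0 / 2.0)

    def test_dose_step_matches_64_node_quadrature(self):
        t_end = 9.0
        tr = Trajectory(40.0, 0.2, seg_times=[0.0, t_end / 2.0], seg_offsets=[0.0, -8.0])
        gx, gw = np.polynomial.legendre.leggauss(64)
        total = 0.0
        for lo, hi in ((0.0, t_end / 2.0), (t_end / 2.0, t_end)):
            half, mid = 0.5 * (hi - lo), 0.5 * (hi + lo)
            total += np.sum(half * gw * tr(mid + half * gx))
        assert joint.average_exposure(tr, t_end) == pytest.approx(total / t_end, rel=1e-8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            joint.average_exposure(Trajectory(1.0, 0.0), -1.0)


class TestHazardDefinition:
    def test_one_unit_higher_trajectory_gives_hr_0891(self):
        spec = HazardSpec(log_rates=[-2.0], alpha_current=float(np.log(0.891)))
        h_lo = hazard(3.0, Trajectory(50.0, 0.0), spec)
        h_hi = hazard(3.0, Trajectory(51.0, 0.0), spec)
        assert h_hi / h_lo == pytest.approx(0.891, rel=1e-12)

    def test_piecewise_log_linear_in_time(self):
        # piecewise-constant h0 with linear m and alpha_current: log h is
        # linear in t within a baseline piece
        spec = HazardSpec(knots=[10.0], log_rates=[-2.0, -1.5], alpha_current=-0.05)
        tr = Trajectory(30.0, 1.2)
        ts = np.array([1.0, 2.0, 3.0])
        slopes = np.diff(np.log(hazard(ts, tr, spec)))
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-12)
        assert slopes[0] == pytest.approx(-0.05 * 1.2, rel=1e-12)


class TestLogLikelihood:
    """Vectorized per-subject conditional density vs independent scalar oracles."""

    def _data_state(self, association="current_plus_average", seed=3):
        rec, surv_df = small_joint_inputs(seed=seed)
        spec = tiny_spec(association=association)
        data = joint.JointData(rec, surv_df, spec)
        rng = np.random.default_rng(1)
        state = {
            "beta": np.array([44.0, 0.06] + [-7.0] * (data.p - 2)),
            "b": rng.normal(0, [8.0, 0.2], size=(data.n, 2)),
            "sigma": 6.5,
            "log_lam": rng.normal(-3.5, 0.3, size=data.n_pieces),
            "phi": np.array([0.6]),
            "alpha_current": -0.03,
            "alpha_average": -0.05,
        }
        return data, state, spec

    def test_survival_term_matches_scalar_quadrature_path(self):
        data, state, spec = self._data_state()
        per = joint._ll_surv_subj(data, spec.association, state["beta"], state["b"],
                                  state["log_lam"], state["phi"],
                                  state["alpha_current"], state["alpha_average"])
        for i in (0, 5, 11, 20):
            traj = data.trajectory(state, i)
            # fold the TTC centering into the covariate linear predictor
            lin = float(data.W[i] @ state["phi"]) - (
                state["alpha_current"] + state["alpha_average"]) * data.ttc_center
            hz = HazardSpec(knots=data.knots, log_rates=state["log_lam"],
                            lin_pred=lin, alpha_current=state["alpha_current"],
                            alpha_average=state["alpha_average"])
            T = data.T[i]
            grid_breaks = np.concatenate((data.knots, traj.change_points(), [T]))
            edges = np.unique(np.concatenate(([0.0], grid_breaks[grid_breaks <= T])))
            dense = 0.0
            for lo, hi in zip(edges[:-1], edges[1:]):
                g = np.linspace(lo + 1e-10 * (hi - lo), hi, 40001)
                dense += np.trapezoid(hazard(g, traj, hz), g)
            expected = data.delta[i] * np.log(hazard(T, traj, hz)) - dense
            assert per[i] == pytest.approx(expected, rel=1e-6, abs=1e-6)

    def test_single_subject_constant_hazard_closed_form(self):
        # alpha = 0 reduces the survival term to log(lam) - lam * T
        data, state, spec = self._data_state(association="none")
        state["alpha_current"] = 0.0
        state["alpha_average"] = 0.0
        state["phi"] = np.zeros(1)
        lam = 0.04
        state["log_lam"] = np.full(data.n_pieces, np.log(lam))
        per = joint._ll_surv_subj(data, spec.association, state["beta"], state["b"],
                                  state["log_lam"], state["phi"], 0.0, 0.0)
        expected = data.delta * np.log(lam) - lam * data.T
        np.testing.assert_allclose(per, expected, rtol=1e-10)

    def test_total_combines_longitudinal_and_survival(self):
        data, state, spec = self._data_state()
        total, per = joint.log_likelihood(data, state, spec)
        assert total == pytest.approx(per.sum())
        # longitudinal part alone matches a direct normal density evaluation
        long_part = per - joint._ll_surv_subj(
            data, spec.association, state["beta"], state["b"], state["log_lam"],
            state["phi"], state["alpha_current"], state["alpha_average"])
        from scipy.stats import norm
        mu = data.X_long @ state["beta"] + state["b"][data.subj_long, 0] \
            + state["b"][data.subj_long, 1] * data.t_long
        direct = norm.logpdf(data.y, mu, state["sigma"])
        np.testing.assert_allclose(long_part.sum(), direct.sum(), rtol=1e-10)


class TestInformationCriteria:
    def _fake_fit(self, ll_matrix):
        pw = np.asarray(ll_matrix)[None, ...]  # one chain
        return joint.JointModelFit(
            spec=tiny_spec(), draws={}, pointwise=pw, accept_rates={},
            patients=[f"P{i}" for i in range(pw.shape[-1])], fixed_names=[],
            n_events=0)

    def test_duplicated_draws_have_zero_penalty(self):
        row = np.array([-3.0, -1.5, -2.2])
        fit = self._fake_fit(np.tile(row, (400, 1)))
        assert joint.waic(fit) == pytest.approx(-2.0 * row.sum())
        assert joint.lpml(fit) == pytest.approx(row.sum())

    def test_single_subject_constant_density(self):
        fit = self._fake_fit(np.full((250, 1), np.log(0.2)))
        assert joint.lpml(fit) == pytest.approx(np.log(0.2))

    def test_invariant_to_draw_order(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-2.0, 0.4, size=(600, 8))
        fit = self._fake_fit(ll)
        fit_perm = self._fake_fit(ll[rng.permutation(600)])
        assert joint.waic(fit) == pytest.approx(joint.waic(fit_perm), rel=1e-12)
        assert joint.lpml(fit) == pytest.approx(joint.lpml(fit_perm), rel=1e-12)

    def test_waic_penalty_is_positive_for_varying_draws(self):
        rng = np.random.default_rng(1)
        ll = rng.normal(-2.0, 0.5, size=(500, 5))
        fit = self._fake_fit(ll)
        lppd_only = -2.0 * (np.logaddexp.reduce(ll, axis=0) - np.log(500)).sum()
        assert joint.waic(fit) > lppd_only


class TestSummarizeHr:
    def _fit_with_alpha(self, alpha_draws, kind="average_exposure"):
        arr = np.asarray(alpha_draws)[None, :]
        draws = {"alpha_average": arr, "alpha_current": np.zeros_like(arr),
                 "phi": np.zeros((1, arr.shape[1], 1))}
        return joint.JointModelFit(
            spec=tiny_spec(association=kind), draws=draws,
            pointwise=np.zeros((1, arr.shape[1], 1)), accept_rates={},
            patients=["P1"], fixed_names=[], n_events=0)

    def test_point_mass_at_log_0891_reports_11_percent(self):
        fit = self._fit_with_alpha(np.full(500, np.log(0.891)))
        row = joint.summarize_hr(fit).iloc[0]
        assert row["HR"] == pytest.approx(0.891)
        assert row["pct_reduction"] == 11

    def test_null_draws_report_hr_one(self):
        fit = self._fit_with_alpha(np.zeros(500))
        row = joint.summarize_hr(fit).iloc[0]
        assert row["HR"] == 1.0 and row["pct_reduction"] == 0

    def test_per_unit_scaling_law(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(-0.1, 0.02, 501)  # odd count: the median is an order stat
        f = self._fit_with_alpha(draws)
        hr1 = joint.summarize_hr(f, per_unit=1.0).iloc[0]["HR"]
        hr10 = joint.summarize_hr(f, per_unit=10.0).iloc[0]["HR"]
        assert hr10 == pytest.approx(hr1**10, rel=1e-9)


class TestFitJoint:
    def test_smoke_single_chain_few_draws(self):
        rec, surv_df = small_joint_inputs()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = joint.JointModelSpec(
                mcmc=joint.McmcSettings(chains=1, warmup=10, draws=10, seed=0))
            fit = joint.fit_joint(rec, surv_df, spec)
        assert fit.pointwise.shape == (1, 10, len(fit.patients))
        assert np.isfinite(joint.waic(fit))
        assert np.isfinite(joint.lpml(fit))

    def test_submodel_consistency_phi_matches_cox(self):
        # with the association switched off, the survival sub-model's phi
        # posterior should sit near the partial-likelihood estimate
        rec, surv_df, _ = make_cohort(seed=19, n_patients=100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = joint.JointModelSpec(
                association="none",
                mcmc=joint.McmcSettings(chains=2, warmup=400, draws=800, seed=4))
            fit = joint.fit_joint(rec, surv_df, spec)
        cox = sv.cox_fit(surv_df, ["prior_alki"])
        phi_draws = fit.stacked("phi")[:, 0]
        assert abs(phi_draws.mean() - cox.coef["prior_alki"]) < 0.5 * cox.se["prior_alki"]

    def test_deterministic_given_seed(self):
        rec, surv_df = small_joint_inputs()
        spec_kw = dict(chains=1, warmup=20, draws=20, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = joint.fit_joint(rec, surv_df, joint.JointModelSpec(
                mcmc=joint.McmcSettings(**spec_kw)))
            f2 = joint.fit_joint(rec, surv_df, joint.JointModelSpec(
                mcmc=joint.McmcSettings(**spec_kw)))
        for k in f1.draws:
            np.testing.assert_array_equal(f1.draws[k], f2.draws[k])


class TestAssociationStructure:
    def test_kinds_and_flags(self):
        a = joint.AssociationStructure("current_value")
        assert a.has_current and not a.has_average
        b = joint.AssociationStructure("current_plus_average")
        assert b.has_current and b.has_average
        with pytest.raises(ValueError):
            joint.AssociationStructure("slope")
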