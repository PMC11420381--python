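"""Bayesian joint model of the TTC trajectory and progression-free survival.

The longitudinal sub-model is the random-intercept/slope LMM of
:mod:`ttcjoint.lmm`; the event sub-model is a proportional-hazards model with
a piecewise-constant baseline (knots at event-time quintiles).  The two are
linked through the subject-specific trajectory

    m_i(t) = x(t)'beta + b0_i + b1_i t

entering the log-hazard via an association structure: the current value
m_i(t), the running average (1/t) int_0^t m_i, or both ("combined"), each
with its own coefficient:

    h_i(t) = h0(t) exp( phi' w_i + a_curr m_i(t) + a_avg avg m_i(t) ).

Estimation is by Metropolis-within-Gibbs: adaptive random-walk blocks for the
fixed effects, per-subject random effects, variance components, baseline
log-rates and the hazard coefficients, initialized from the standalone LMM
and Cox fits.  Cumulative hazards use Gauss-Legendre quadrature within the
pieces on which the integrand is smooth.  Fitted models are compared by WAIC
and LPML, both computed from per-subject conditional (given b_i) joint
densities of the longitudinal and survival data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import lmm as lmm_mod
from . import survival as surv_mod
from .trajectory import Trajectory

__all__ = [
    "AssociationStructure",
    "Priors",
    "McmcSettings",
    "JointModelSpec",
    "JointModelFit",
    "average_exposure",
    "fit_joint",
    "log_likelihood",
    "waic",
    "lpml",
    "summarize_hr",
]

_ASSOC_KINDS = ("current_value", "average_exposure", "current_plus_average", "none")


@dataclass(frozen=True)
class AssociationStructure:
    """Which functionals of the trajectory enter the hazard.

    ``none`` (no association term) is supported for sub-model consistency
    diagnostics; the slope functional is intentionally not offered.
    """

    kind: str = "current_plus_average"

    def __post_init__(self) -> None:
        if self.kind not in _ASSOC_KINDS:
            raise ValueError(f"association kind must be one of {_ASSOC_KINDS}")

    @property
    def has_current(self) -> bool:
        return self.kind in ("current_value", "current_plus_average")

    @property
    def has_average(self) -> bool:
        return self.kind in ("average_exposure", "current_plus_average")


@dataclass(frozen=True)
class Priors:
    """Weakly-informative prior scales.

    Longitudinal fixed effects live on the TTC (0-100) scale and get
    N(0, beta_sd^2); hazard-scale coefficients (phi, alpha) get
    N(0, loghr_sd^2); random-effect and residual SDs get half-t(3) priors;
    the random-effects correlation is uniform on (-1, 1); baseline log-rates
    are N(log crude rate, lam_sd^2).
    """

    beta_sd: float = 100.0
    loghr_sd: float = 10.0
    sd_scale: float = 25.0        # half-t(3) scale: intercept SD, residual SD
    slope_sd_scale: float = 2.5   # half-t(3) scale: slope SD (TTC/month)
    lam_sd: float = 5.0


@dataclass(frozen=True)
class McmcSettings:
    """Chain geometry and adaptation for the random-walk sampler."""

    chains: int = 3
    warmup: int = 1000
    draws: int = 2000
    seed: int = 0
    adapt_window: int = 50
    target_accept: float = 0.3

    def __post_init__(self) -> None:
        if self.chains < 2 or self.draws < 500:
            warnings.warn("fewer than 2 chains or 500 draws: diagnostics and "
                          "WAIC/LPML will be unreliable", stacklevel=2)


@dataclass(frozen=True)
class JointModelSpec:
    association: AssociationStructure = AssociationStructure()
    n_baseline_pieces: int = 5
    priors: Priors = Priors()
    mcmc: McmcSettings = McmcSettings()
    quad_nodes: int = 7
    covariates: tuple[str, ...] = ("prior_alki",)

    def __post_init__(self) -> None:
        if isinstance(self.association, str):
            object.__setattr__(self, "association", AssociationStructure(self.association))
        if self.quad_nodes < 7:
            warnings.warn("fewer than 7 quadrature nodes: cumulative-hazard "
                          "integration may be inaccurate", stacklevel=2)


def average_exposure(traj: Trajectory, t) -> float | np.ndarray:
    """Running average (1/t) int_0^t m(s) ds of a trajectory, m(0) at t=0."""
    return traj.average(t)


# ---------------------------------------------------------------------------
# precomputed data arrays

class JointData:
    """Design matrices and quadrature grids shared by all likelihood calls.

    Dose histories are reconstructed from each subject's sampled dose levels
    by last-value-carried-forward (first value carried back to t=0), exactly
    the information a real analysis has.
    """

    def __init__(self, records: pd.DataFrame, survival: pd.DataFrame,
                 spec: JointModelSpec):
        surv = survival.set_index("patient_id")
        orphans = set(records["patient_id"]) - set(surv.index)
        if orphans:
            raise ValueError(f"longitudinal patients missing from survival table: {sorted(orphans)[:5]}")
        # subjects with no longitudinal data cannot contribute a trajectory
        have_long = surv.index.isin(records["patient_id"])
        if not have_long.all():
            warnings.warn(f"{int((~have_long).sum())} patient(s) without samples excluded",
                          stacklevel=3)
            surv = surv[have_long]
        self.patients = list(surv.index)
        self.n = len(self.patients)
        pid_to_idx = {p: i for i, p in enumerate(self.patients)}

        self.T = surv["time_months"].to_numpy(float)
        self.delta = surv["event"].to_numpy(int)
        self.W = surv[list(spec.covariates)].to_numpy(float)
        self.covariate_names = list(spec.covariates)

        # baseline knots: interior quantiles of observed event times
        ev_times = self.T[self.delta == 1]
        if len(ev_times) < 2:
            raise ValueError("need >= 2 events to place baseline knots")
        qs = np.linspace(0, 1, spec.n_baseline_pieces + 1)[1:-1]
        knots = np.unique(np.quantile(ev_times, qs))
        knots = knots[(knots > 0) & (knots < self.T.max())]
        self.knots = knots
        self.n_pieces = len(knots) + 1

        records = records.sort_values(["patient_id", "t"], kind="mergesort")
        self.dose_levels = tuple(sorted(records["dose_level"].unique()))
        self.fixed_names = ["intercept", "time"] + [f"dose_level[{l}]" for l in self.dose_levels[1:]]
        self.p = len(self.fixed_names)

        # longitudinal arrays
        self.y = records["ttc_value"].to_numpy(float)
        # association terms enter the hazard centred at the mean observed TTC
        # (pure reparameterization of the baseline; decorrelates alpha from
        # the baseline log-rates, which otherwise cripples the sampler)
        self.ttc_center = float(self.y.mean())
        self.t_long = records["t"].to_numpy(float)
        self.subj_long = records["patient_id"].map(pid_to_idx).to_numpy(int)
        self.X_long = self._fixed_design(self.t_long, records["dose_level"].to_numpy(int))
        self.N = len(self.y)
        self.n_long = np.bincount(self.subj_long, minlength=self.n).astype(float)

        # per-subject dose histories (LVCF from the sampled dose levels)
        self.dose_hist = {}
        for pid, grp in records.groupby("patient_id", sort=False):
            tt = grp["t"].to_numpy(float)
            ll = grp["dose_level"].to_numpy(int)
            seg_t = [0.0]
            seg_l = [int(ll[0])]
            for tj, lj in zip(tt[1:], ll[1:]):
                if lj != seg_l[-1] and tj > seg_t[-1]:
                    seg_t.append(float(tj))
                    seg_l.append(int(lj))
            self.dose_hist[pid] = (np.asarray(seg_t), np.asarray(seg_l, dtype=int))

        # quadrature nodes and event-time designs
        gx, gw = np.polynomial.legendre.leggauss(spec.quad_nodes)
        node_t, node_w, node_subj = [], [], []
        Xe_rows, Xa_e_rows = [], []
        for i, pid in enumerate(self.patients):
            seg_t, seg_l = self.dose_hist[pid]
            Ti = self.T[i]
            bp = np.unique(np.concatenate(([0.0, Ti], self.knots[self.knots < Ti],
                                           seg_t[(seg_t > 0) & (seg_t < Ti)])))
            lo, hi = bp[:-1], bp[1:]
            half, mid = 0.5 * (hi - lo), 0.5 * (hi + lo)
            tq = (mid[:, None] + half[:, None] * gx[None, :]).ravel()
            wq = (half[:, None] * gw[None, :]).ravel()
            node_t.append(tq)
            node_w.append(wq)
            node_subj.append(np.full(len(tq), i))
            Xe_rows.append(self._fixed_design(np.array([Ti]), None, (seg_t, seg_l)))
            Xa_e_rows.append(self._avg_design(np.array([Ti]), (seg_t, seg_l)))
        self.t_node = np.concatenate(node_t)
        self.w_node = np.concatenate(node_w)
        self.subj_node = np.concatenate(node_subj)
        self.piece_node = np.searchsorted(self.knots, self.t_node, side="left")
        self.X_node = np.vstack([self._fixed_design(
            self.t_node[self.subj_node == i], None, self.dose_hist[p])
            for i, p in enumerate(self.patients)])
        self.Xa_node = np.vstack([self._avg_design(
            self.t_node[self.subj_node == i], self.dose_hist[p])
            for i, p in enumerate(self.patients)])
        self.X_event = np.vstack(Xe_rows)
        self.Xa_event = np.vstack(Xa_e_rows)
        self.piece_event = np.searchsorted(self.knots, self.T, side="left")
        # time spent in each baseline piece (for crude-rate initialization)
        edges = np.concatenate(([0.0], self.knots, [np.inf]))
        self.exposure_piece = np.array([
            np.sum(np.clip(self.T, None, edges[k + 1]) - np.minimum(self.T, edges[k]))
            for k in range(self.n_pieces)])
        self.events_piece = np.bincount(self.piece_event, weights=self.delta,
                                        minlength=self.n_pieces)

    def _fixed_design(self, t: np.ndarray, levels, dose_hist=None) -> np.ndarray:
        """Rows [1, t, 1{level=l}] with the level either given or read off a history."""
        if levels is None:
            seg_t, seg_l = dose_hist
            idx = np.clip(np.searchsorted(seg_t, t, side="left") - 1, 0, len(seg_l) - 1)
            levels = seg_l[idx]
        X = np.zeros((len(t), self.p))
        X[:, 0] = 1.0
        X[:, 1] = t
        for j, lev in enumerate(self.dose_levels[1:], start=2):
            X[:, j] = (levels == lev).astype(float)
        return X

    def _avg_design(self, t: np.ndarray, dose_hist) -> np.ndarray:
        """Design of the running average: [1, t/2, occupancy fraction per level]."""
        seg_t, seg_l = dose_hist
        X = np.zeros((len(t), self.p))
        X[:, 0] = 1.0
        X[:, 1] = 0.5 * t
        if self.p > 2:
            bounds = np.concatenate((seg_t, [np.inf]))
            for j, lev in enumerate(self.dose_levels[1:], start=2):
                occ = np.zeros(len(t))
                for k in range(len(seg_l)):
                    if seg_l[k] != lev:
                        continue
                    lo, hi = bounds[k], bounds[k + 1]
                    occ += np.clip(t, None, hi) - np.minimum(t, lo)
                with np.errstate(invalid="ignore", divide="ignore"):
                    frac = np.where(t > 0, occ / np.where(t > 0, t, 1.0),
                                    (seg_l[0] == lev).astype(float))
                X[:, j] = frac
        return X

    def trajectory(self, state: dict, i: int) -> Trajectory:
        """Subject i's trajectory at the given parameter state."""
        seg_t, seg_l = self.dose_hist[self.patients[i]]
        beta = state["beta"]
        offsets = np.zeros(len(seg_l))
        for j, lev in enumerate(self.dose_levels[1:], start=2):
            offsets[seg_l == lev] = beta[j]
        return Trajectory(intercept=beta[0] + state["b"][i, 0],
                          slope=beta[1] + state["b"][i, 1],
                          seg_times=seg_t, seg_offsets=offsets)


# ---------------------------------------------------------------------------
# log-likelihood pieces (all per-subject, vectorized)

_LOG2PI = float(np.log(2.0 * np.pi))

#: extra sweeps of the survival block per iteration (its conditional posterior
#: carries the ill-conditioned association ridge but is cheap to evaluate)
_SURV_BLOCK_REPS = 10


def _ll_long_subj(data: JointData, beta, b, sigma) -> np.ndarray:
    resid = data.y - data.X_long @ beta - b[data.subj_long, 0] - b[data.subj_long, 1] * data.t_long
    sse = np.bincount(data.subj_long, weights=resid * resid, minlength=data.n)
    return -0.5 * (sse / sigma**2 + data.n_long * (_LOG2PI + 2.0 * np.log(sigma)))


def _ll_surv_subj(data: JointData, assoc: AssociationStructure,
                  beta, b, log_lam, phi, a_curr, a_avg) -> np.ndarray:
    c0 = data.ttc_center
    eta_node = data.W[data.subj_node] @ phi
    eta_event = data.W @ phi
    if assoc.has_current:
        m_node = data.X_node @ beta + b[data.subj_node, 0] + b[data.subj_node, 1] * data.t_node
        m_event = (data.X_event * beta).sum(axis=1) + b[:, 0] + b[:, 1] * data.T
        eta_node = eta_node + a_curr * (m_node - c0)
        eta_event = eta_event + a_curr * (m_event - c0)
    if assoc.has_average:
        a_node = data.Xa_node @ beta + b[data.subj_node, 0] + 0.5 * b[data.subj_node, 1] * data.t_node
        a_event = (data.Xa_event * beta).sum(axis=1) + b[:, 0] + 0.5 * b[:, 1] * data.T
        eta_node = eta_node + a_avg * (a_node - c0)
        eta_event = eta_event + a_avg * (a_event - c0)
    cumhaz = np.bincount(data.subj_node,
                         weights=data.w_node * np.exp(log_lam[data.piece_node] + eta_node),
                         minlength=data.n)
    return data.delta * (log_lam[data.piece_event] + eta_event) - cumhaz


def _ll_b_subj(b: np.ndarray, sd0, sd1, corr) -> np.ndarray:
    det = (sd0 * sd1) ** 2 * (1.0 - corr**2)
    z0 = b[:, 0] / sd0
    z1 = b[:, 1] / sd1
    quad = (z0**2 - 2.0 * corr * z0 * z1 + z1**2) / (1.0 - corr**2)
    return -0.5 * (quad + np.log(det) + 2.0 * _LOG2PI)


def _half_t3_logpdf(s: float, scale: float) -> float:
    # t with 3 df truncated to s > 0; normalization constant irrelevant to MCMC
    return -2.0 * np.log1p((s / scale) ** 2 / 3.0) - np.log(scale)


def log_likelihood(data: JointData, state: dict, spec: JointModelSpec):
    """Conditional (given b) joint data log-density, total and per subject.

    Sums the Gaussian longitudinal density and the survival term
    ``delta * log h(T) - int_0^T h``; excludes the random-effects density and
    all priors.
    """
    per_subj = (_ll_long_subj(data, state["beta"], state["b"], state["sigma"])
                + _ll_surv_subj(data, spec.association, state["beta"], state["b"],
                                state["log_lam"], state["phi"],
                                state.get("alpha_current", 0.0),
                                state.get("alpha_average", 0.0)))
    return float(per_subj.sum()), per_subj


# ---------------------------------------------------------------------------
# sampler

class _AdaptiveBlock:
    """Random-walk Metropolis block with Robbins-Monro scale adaptation and
    (for dim > 1) empirical proposal covariance learned during warmup."""

    def __init__(self, dim: int, init_scale: float, target: float = 0.3):
        self.dim = dim
        self.log_scale = np.log(init_scale)
        self.target = target
        self.chol = np.eye(dim)
        self.history: list[np.ndarray] = []
        self.k = 0

    def propose(self, rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
        return x + np.exp(self.log_scale) * (self.chol @ rng.standard_normal(self.dim))

    def update(self, x: np.ndarray, accepted: bool, warmup: bool) -> None:
        if not warmup:
            return
        self.k += 1
        self.log_scale += (float(accepted) - self.target) / np.sqrt(self.k)
        self.history.append(np.array(x))
        if self.dim > 1 and self.k >= 200 and self.k % 100 == 0:
            # discard the first third as burn-in of the adaptation itself
            hist = np.asarray(self.history[len(self.history) // 3:])
            emp = np.cov(hist.T)
            try:
                self.chol = np.linalg.cholesky(emp + 1e-10 * np.eye(self.dim))
            except np.linalg.LinAlgError:
                pass


def _fd_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = len(x)
    H = np.zeros((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            ei, ej = np.zeros(d), np.zeros(d)
            ei[i], ej[j] = h, h
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                     - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * h**2)
    return H


def _proposal_chol_from_hessian(f, x: np.ndarray) -> np.ndarray:
    """Cholesky of the inverse negative Hessian, regularized; identity fallback."""
    try:
        H = _fd_hessian(f, x)
        cov = np.linalg.inv(-H + 1e-8 * np.eye(len(x)))
        # guard against negative curvature directions at a non-optimum
        ev, U = np.linalg.eigh(cov)
        ev = np.clip(ev, 1e-10, None)
        return np.linalg.cholesky((U * ev) @ U.T)
    except np.linalg.LinAlgError:
        return np.eye(len(x))


def _init_state(data: JointData, spec: JointModelSpec, lmm_fit, cox_fit_res,
                rng: np.random.Generator) -> dict:
    beta = np.zeros(data.p)
    for j, name in enumerate(data.fixed_names):
        if name in lmm_fit.fixed.index:
            beta[j] = lmm_fit.fixed[name]
    b = np.zeros((data.n, 2))
    for i, pid in enumerate(data.patients):
        if pid in lmm_fit.re_modes:
            b[i] = lmm_fit.re_modes[pid]
    D = lmm_fit.random_cov
    sd0 = max(np.sqrt(D[0, 0]), 1e-2)
    sd1 = max(np.sqrt(D[1, 1]), 1e-3)
    corr = float(np.clip(D[0, 1] / (sd0 * sd1) if D[0, 0] > 0 and D[1, 1] > 0 else 0.0,
                         -0.95, 0.95))
    crude = np.log(np.maximum(data.events_piece, 0.5) / np.maximum(data.exposure_piece, 1e-8))
    phi = np.zeros(len(spec.covariates))
    if cox_fit_res is not None:
        for j, name in enumerate(spec.covariates):
            if name in cox_fit_res.coef.index and np.isfinite(cox_fit_res.coef[name]):
                phi[j] = cox_fit_res.coef[name]
    state = {
        "beta": beta + 0.1 * rng.standard_normal(data.p),
        "b": b + 0.1 * rng.standard_normal((data.n, 2)) * [1.0, 0.05],
        "log_sd0": np.log(sd0) + 0.05 * rng.standard_normal(),
        "log_sd1": np.log(sd1) + 0.05 * rng.standard_normal(),
        "zcorr": np.arctanh(corr) + 0.05 * rng.standard_normal(),
        "log_sigma": 0.5 * np.log(max(lmm_fit.resid_var, 1e-2)) + 0.05 * rng.standard_normal(),
        "log_lam": crude + 0.1 * rng.standard_normal(data.n_pieces),
        "phi": phi + 0.05 * rng.standard_normal(len(phi)),
        "alpha_current": 0.0,
        "alpha_average": 0.0,
    }
    return state


@dataclass
class JointModelFit:
    """Posterior draws and per-subject conditional log-densities.

    ``draws`` maps parameter name -> array of shape (chains, draws) or
    (chains, draws, dim); ``pointwise`` has shape (chains, draws, n_subjects)
    and feeds WAIC/LPML.  Hazard-ratio summaries, R-hat and effective sample
    sizes are derived lazily.
    """

    spec: JointModelSpec
    draws: dict
    pointwise: np.ndarray
    accept_rates: dict
    patients: list
    fixed_names: list
    n_events: int

    def stacked(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def association(self) -> AssociationStructure:
        return self.spec.association

    def convergence(self, params=("alpha_current", "alpha_average", "phi")) -> pd.DataFrame:
        import arviz as az
        rows = []
        for name in params:
            if name not in self.draws:
                continue
            arr = self.draws[name]
            if arr.ndim == 2:
                arr = arr[..., None]
            for j in range(arr.shape[2]):
                if np.allclose(arr[..., j], arr[0, 0, j]):
                    continue  # fixed-at-zero coefficients
                ds = az.convert_to_dataset(arr[..., j])
                rows.append({"param": f"{name}[{j}]",
                             "rhat": float(az.rhat(ds)["x"].values),
                             "ess_bulk": float(az.ess(ds)["x"].values)})
        return pd.DataFrame(rows)

    def check_convergence(self, threshold: float = 1.05) -> bool:
        conv = self.convergence()
        bad = conv[conv["rhat"] > threshold]
        if len(bad):
            warnings.warn(f"split-Rhat above {threshold} for: "
                          + ", ".join(f"{r.param}={r.rhat:.3f}" for r in bad.itertuples()),
                          stacklevel=2)
        return len(bad) == 0

    @property
    def posterior_table(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            flat = self.stacked(name)
            if flat.ndim == 1:
                flat = flat[:, None]
            labels = ([f"{name}[{j}]" for j in range(flat.shape[1])]
                      if flat.shape[1] > 1 else [name])
            for j, lab in enumerate(labels):
                q = np.quantile(flat[:, j], [0.025, 0.5, 0.975])
                rows.append({"param": lab, "mean": flat[:, j].mean(),
                             "q2.5": q[0], "median": q[1], "q97.5": q[2]})
        return pd.DataFrame(rows)

    def draw_table(self) -> pd.DataFrame:
        """Long-format (chain, draw, parameter, value) table of all draws."""
        recs = []
        for name, arr in self.draws.items():
            a = arr if arr.ndim == 3 else arr[..., None]
            for j in range(a.shape[2]):
                lab = f"{name}[{j}]" if a.shape[2] > 1 else name
                for c in range(a.shape[0]):
                    recs.append(pd.DataFrame({
                        "chain": c, "draw": np.arange(a.shape[1]),
                        "parameter": lab, "value": a[c, :, j]}))
        return pd.concat(recs, ignore_index=True)


def waic(fit: JointModelFit) -> float:
    """Watanabe-Akaike information criterion, -2(lppd - p_waic); smaller is better.

    Pointwise unit is the subject: the conditional (given b_i) joint density
    of that subject's longitudinal and survival data.
    """
    ll = fit.pointwise.reshape(-1, fit.pointwise.shape[-1])  # (S, n)
    S = ll.shape[0]
    lppd = logsumexp(ll, axis=0) - np.log(S)
    p_waic = ll.var(axis=0, ddof=0)
    return float(-2.0 * (lppd.sum() - p_waic.sum()))


def lpml(fit: JointModelFit) -> float:
    """Log pseudo-marginal likelihood, sum of log conditional predictive
    ordinates (harmonic-mean estimator, stabilized); larger is better."""
    ll = fit.pointwise.reshape(-1, fit.pointwise.shape[-1])
    S = ll.shape[0]
    log_cpo = np.log(S) - logsumexp(-ll, axis=0)
    return float(log_cpo.sum())


def summarize_hr(fit: JointModelFit, per_unit: float = 1.0) -> pd.DataFrame:
    """Posterior hazard-ratio table per ``per_unit`` TTC units.

    Reports exp of the posterior quantiles, a two-sided posterior tail
    probability, and the percent risk reduction (1 - median HR) rounded to
    the nearest integer.
    """
    rows = []
    entries = []
    if fit.association.has_current:
        entries.append(("alpha_current", "current value (TTC)", fit.stacked("alpha_current")))
    if fit.association.has_average:
        entries.append(("alpha_average", "average exposure (TTC)", fit.stacked("alpha_average")))
    phi = fit.stacked("phi")
    for j, name in enumerate(fit.spec.covariates):
        entries.append((f"phi[{name}]", name, phi[:, j]))  # covariates per their own unit
    for key, label, draws in entries:
        scaled = per_unit * draws if key.startswith("alpha") else draws
        hr = np.exp(scaled)
        med, lo, hi = np.quantile(hr, [0.5, 0.025, 0.975])
        p_tail = 2.0 * min(np.mean(scaled > 0), np.mean(scaled < 0))
        rows.append({
            "variable": label, "HR": med, "ci_low": lo, "ci_high": hi,
            "p": p_tail, "pct_reduction": int(round((1.0 - med) * 100.0)),
        })
    return pd.DataFrame(rows)


def fit_joint(records: pd.DataFrame, survival: pd.DataFrame,
              spec: JointModelSpec) -> JointModelFit:
    """Fit the joint model by adaptive Metropolis-within-Gibbs.

    ``records`` is the longitudinal table (patient_id, t, ttc_value,
    dose_level); ``survival`` the per-patient table.  Initialization comes
    from the standalone LMM and Cox fits; every stochastic step is governed
    by ``spec.mcmc.seed``.  A convergence warning is issued when split-Rhat
    of any association coefficient exceeds 1.05.
    """
    data = JointData(records, survival, spec)
    assoc = spec.association
    priors = spec.priors
    mc = spec.mcmc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lmm_fit = lmm_mod.fit_lmm(records)
        try:
            cox_res = surv_mod.cox_fit(
                survival[survival["patient_id"].isin(data.patients)],
                list(spec.covariates))
        except ValueError:
            cox_res = None

    crude = np.log(np.maximum(data.events_piece, 0.5) / np.maximum(data.exposure_piece, 1e-8))

    def log_prior(state) -> float:
        lp = -0.5 * np.sum((state["beta"] / priors.beta_sd) ** 2)
        lp += -0.5 * np.sum((state["phi"] / priors.loghr_sd) ** 2)
        if assoc.has_current:
            lp += -0.5 * (state["alpha_current"] / priors.loghr_sd) ** 2
        if assoc.has_average:
            lp += -0.5 * (state["alpha_average"] / priors.loghr_sd) ** 2
        sd0, sd1 = np.exp(state["log_sd0"]), np.exp(state["log_sd1"])
        sigma = np.exp(state["log_sigma"])
        # half-t densities plus log-Jacobians of the log transforms
        lp += _half_t3_logpdf(sd0, priors.sd_scale) + state["log_sd0"]
        lp += _half_t3_logpdf(sd1, priors.slope_sd_scale) + state["log_sd1"]
        lp += _half_t3_logpdf(sigma, priors.sd_scale) + state["log_sigma"]
        # uniform correlation via Fisher-z: Jacobian 1 - r^2
        lp += np.log1p(-np.tanh(state["zcorr"]) ** 2)
        lp += -0.5 * np.sum(((state["log_lam"] - crude) / priors.lam_sd) ** 2)
        return float(lp)

    def unpack(state):
        return (np.exp(state["log_sd0"]), np.exp(state["log_sd1"]),
                np.tanh(state["zcorr"]), np.exp(state["log_sigma"]))

    def ll_long(state):
        return _ll_long_subj(data, state["beta"], state["b"], np.exp(state["log_sigma"]))

    def ll_surv(state):
        return _ll_surv_subj(data, assoc, state["beta"], state["b"], state["log_lam"],
                             state["phi"], state["alpha_current"], state["alpha_average"])

    def ll_b(state):
        sd0, sd1, corr, _ = unpack(state)
        return _ll_b_subj(state["b"], sd0, sd1, corr)

    n_chains = max(mc.chains, 1)
    n_alpha = int(assoc.has_current) + int(assoc.has_average)
    surv_dim = data.n_pieces + len(spec.covariates) + n_alpha

    # curvature-matched initial proposal covariance for the survival block:
    # finite-difference Hessian of its conditional log-posterior at the
    # (deterministic) initialization point
    state0 = _init_state(data, spec, lmm_fit, cox_res, np.random.default_rng(0))

    def _surv_vec_logpost(vec: np.ndarray) -> float:
        st = dict(state0)
        k = data.n_pieces
        st["log_lam"] = vec[:k]
        st["phi"] = vec[k:k + len(spec.covariates)]
        j = k + len(spec.covariates)
        if assoc.has_current:
            st["alpha_current"] = float(vec[j]); j += 1
        if assoc.has_average:
            st["alpha_average"] = float(vec[j])
        ll = _ll_surv_subj(data, assoc, st["beta"], st["b"], st["log_lam"],
                           st["phi"], st["alpha_current"], st["alpha_average"]).sum()
        lp = -0.5 * np.sum(((st["log_lam"] - crude) / priors.lam_sd) ** 2)
        lp += -0.5 * np.sum((st["phi"] / priors.loghr_sd) ** 2)
        lp += -0.5 * (st["alpha_current"] / priors.loghr_sd) ** 2
        lp += -0.5 * (st["alpha_average"] / priors.loghr_sd) ** 2
        return float(ll + lp)

    vec0 = np.concatenate([state0["log_lam"], state0["phi"], np.zeros(n_alpha)])
    surv_chol0 = _proposal_chol_from_hessian(_surv_vec_logpost, vec0)

    chain_draws: list[dict] = []
    chain_pointwise: list[np.ndarray] = []
    accept_tally = {"beta": 0.0, "b": 0.0, "var": 0.0, "surv": 0.0, "total": 0.0}
    seeds = np.random.SeedSequence(mc.seed).spawn(n_chains)

    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        state = _init_state(data, spec, lmm_fit, cox_res, rng)

        beta_blk = _AdaptiveBlock(data.p, 1.0)
        beta_se = np.array([lmm_fit.se.get(name, 0.5) for name in data.fixed_names])
        beta_blk.chol = np.diag(np.where(np.isfinite(beta_se) & (beta_se > 0), beta_se, 0.5))
        var_blk = _AdaptiveBlock(4, 0.05)
        surv_blk = _AdaptiveBlock(surv_dim, 2.38 / np.sqrt(surv_dim))
        surv_blk.chol = surv_chol0.copy()
        shift0_blk = _AdaptiveBlock(1, 1.0)
        shift1_blk = _AdaptiveBlock(1, 0.05)
        b_scale = np.array([2.0, 0.1])
        b_k = 0

        kept = {k: [] for k in ("beta", "sd_b0", "sd_b1", "corr_b", "sigma",
                                "log_lam", "phi", "alpha_current", "alpha_average")}
        ptw = []

        cur_long = ll_long(state)
        cur_surv = ll_surv(state)
        cur_b = ll_b(state)
        cur_prior = log_prior(state)

        total_iter = mc.warmup + mc.draws
        for it in range(total_iter):
            warm = it < mc.warmup

            # --- beta block (longitudinal + survival + prior)
            prop = dict(state)
            prop["beta"] = beta_blk.propose(rng, state["beta"])
            p_long, p_surv = ll_long(prop), ll_surv(prop)
            p_prior = log_prior(prop)
            log_r = (p_long.sum() + p_surv.sum() + p_prior
                     - cur_long.sum() - cur_surv.sum() - cur_prior)
            acc = np.log(rng.uniform()) < log_r
            if acc:
                state, cur_long, cur_surv, cur_prior = prop, p_long, p_surv, p_prior
            beta_blk.update(state["beta"], acc, warm)
            accept_tally["beta"] += acc / total_iter / n_chains

            # --- translation moves: shift mass between beta and the b columns
            for col, blk in ((0, shift0_blk), (1, shift1_blk)):
                delta = float(blk.propose(rng, np.zeros(1))[0])
                prop = dict(state)
                beta_new = state["beta"].copy()
                beta_new[col] += delta
                prop["beta"] = beta_new
                prop["b"] = state["b"].copy()
                prop["b"][:, col] -= delta
                # m_i(t) unchanged: only the RE density and beta prior move
                p_b = ll_b(prop)
                p_prior = log_prior(prop)
                log_r = p_b.sum() + p_prior - cur_b.sum() - cur_prior
                acc = np.log(rng.uniform()) < log_r
                if acc:
                    state, cur_b, cur_prior = prop, p_b, p_prior
                blk.update(np.zeros(1), acc, warm)

            # --- per-subject random effects (parallel RWM)
            prop_b = state["b"] + b_scale * rng.standard_normal((data.n, 2))
            prop = dict(state)
            prop["b"] = prop_b
            p_long, p_surv, p_b = ll_long(prop), ll_surv(prop), ll_b(prop)
            log_r_i = (p_long + p_surv + p_b) - (cur_long + cur_surv + cur_b)
            acc_i = np.log(rng.uniform(size=data.n)) < log_r_i
            new_b = np.where(acc_i[:, None], prop_b, state["b"])
            state = dict(state)
            state["b"] = new_b
            cur_long = np.where(acc_i, p_long, cur_long)
            cur_surv = np.where(acc_i, p_surv, cur_surv)
            cur_b = np.where(acc_i, p_b, cur_b)
            if not acc_i.all():
                # mixed acceptance: recompute nothing (per-subject terms exact)
                pass
            rate = acc_i.mean()
            accept_tally["b"] += rate / total_iter / n_chains
            if warm:
                b_k += 1
                b_scale *= np.exp((rate - 0.35) / np.sqrt(b_k))

            # --- variance components (affect longitudinal sigma + RE density)
            vec = np.array([state["log_sd0"], state["log_sd1"], state["zcorr"], state["log_sigma"]])
            pvec = var_blk.propose(rng, vec)
            prop = dict(state)
            prop["log_sd0"], prop["log_sd1"], prop["zcorr"], prop["log_sigma"] = pvec
            p_long, p_b = ll_long(prop), ll_b(prop)
            p_prior = log_prior(prop)
            log_r = (p_long.sum() + p_b.sum() + p_prior
                     - cur_long.sum() - cur_b.sum() - cur_prior)
            acc = np.log(rng.uniform()) < log_r
            if acc:
                state, cur_long, cur_b, cur_prior = prop, p_long, p_b, p_prior
            var_blk.update(pvec if acc else vec, acc, warm)
            accept_tally["var"] += acc / total_iter / n_chains

            # --- survival block: baseline log-rates, phi, active alphas.
            # Cheapest block (survival likelihood only) and the worst
            # conditioned (current/average association ridge): repeat it.
            for _rep in range(_SURV_BLOCK_REPS):
                vec = np.concatenate([state["log_lam"], state["phi"],
                                      [state["alpha_current"]] if assoc.has_current else [],
                                      [state["alpha_average"]] if assoc.has_average else []])
                pvec = surv_blk.propose(rng, vec)
                prop = dict(state)
                k = data.n_pieces
                prop["log_lam"] = pvec[:k]
                prop["phi"] = pvec[k:k + len(spec.covariates)]
                j = k + len(spec.covariates)
                if assoc.has_current:
                    prop["alpha_current"] = float(pvec[j]); j += 1
                if assoc.has_average:
                    prop["alpha_average"] = float(pvec[j])
                p_surv = ll_surv(prop)
                p_prior = log_prior(prop)
                log_r = p_surv.sum() + p_prior - cur_surv.sum() - cur_prior
                acc = np.log(rng.uniform()) < log_r
                if acc:
                    state, cur_surv, cur_prior = prop, p_surv, p_prior
                surv_blk.update(pvec if acc else vec, acc, warm)
                accept_tally["surv"] += acc / total_iter / n_chains / _SURV_BLOCK_REPS

            if not warm:
                sd0, sd1, corr, sigma = unpack(state)
                kept["beta"].append(state["beta"].copy())
                kept["sd_b0"].append(sd0)
                kept["sd_b1"].append(sd1)
                kept["corr_b"].append(corr)
                kept["sigma"].append(sigma)
                kept["log_lam"].append(state["log_lam"].copy())
                kept["phi"].append(state["phi"].copy())
                kept["alpha_current"].append(state["alpha_current"])
                kept["alpha_average"].append(state["alpha_average"])
                ptw.append(cur_long + cur_surv)

        chain_draws.append({k: np.asarray(v) for k, v in kept.items()})
        chain_pointwise.append(np.asarray(ptw))

    draws = {k: np.stack([cd[k] for cd in chain_draws]) for k in chain_draws[0]}
    pointwise = np.stack(chain_pointwise)
    fit = JointModelFit(
        spec=spec, draws=draws, pointwise=pointwise, accept_rates=accept_tally,
        patients=data.patients, fixed_names=data.fixed_names,
        n_events=int(data.delta.sum()),
    )
    if n_chains >= 2 and mc.draws >= 100:
        fit.check_convergence()
    return fit
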