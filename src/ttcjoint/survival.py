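"""Kaplan-Meier and (time-dependent) Cox proportional-hazards baselines.

These are the conventional exposure-response analyses the joint model is
compared against: per-patient median exposure entered into a standard Cox
model (continuous TTC, or dichotomized at the 435 ng/mL trough target), and
last-value-carried-forward (LVCF) expansion of the repeated measurements into
counting-process rows for a time-dependent Cox model.

The partial likelihood (Efron tie handling) and its Newton-Raphson maximizer
are implemented here on counting-process data; the standard Cox model is the
single-interval special case, so both fits share one optimizer path exactly.
Kaplan-Meier estimation delegates to lifelines (Greenwood variance, log-log
confidence intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

__all__ = [
    "CoxFit",
    "KmCurve",
    "km_fit",
    "reverse_km_followup",
    "cox_fit",
    "td_cox_fit",
    "expand_lvcf",
    "dichotomize_exposure",
    "backward_eliminate",
    "build_design",
]

#: survival-table categorical covariates expanded to treatment dummies
CATEGORICAL_COVARIATES = ("ecog", "prior_lines")


# ---------------------------------------------------------------------------
# partial likelihood engine (counting-process format, Efron/Breslow ties)

def _partial_loglik(beta: np.ndarray, start: np.ndarray, stop: np.ndarray,
                    event: np.ndarray, X: np.ndarray, ties: str = "efron"):
    """Log partial likelihood with gradient and Hessian.

    Risk set at an event time t contains rows with ``start < t <= stop``.
    Efron's correction down-weights tied failures within the risk set;
    ``ties='breslow'`` omits the correction.
    """
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    eta = X @ beta
    w = np.exp(eta)
    wX = w[:, None] * X
    event_times = np.unique(stop[event == 1])
    for t in event_times:
        at_risk = (start < t) & (stop >= t)
        tied = (stop == t) & (event == 1)
        d = int(tied.sum())
        S0 = w[at_risk].sum()
        S1 = wX[at_risk].sum(axis=0)
        S2 = (wX[at_risk].T @ X[at_risk])
        s0d = w[tied].sum()
        s1d = wX[tied].sum(axis=0)
        s2d = (wX[tied].T @ X[tied])
        ll += eta[tied].sum()
        grad += X[tied].sum(axis=0)
        for j in range(d):
            f = j / d if ties == "efron" else 0.0
            denom = S0 - f * s0d
            num1 = S1 - f * s1d
            num2 = S2 - f * s2d
            ll -= np.log(denom)
            grad -= num1 / denom
            hess -= num2 / denom - np.outer(num1, num1) / denom**2
    return ll, grad, hess


@dataclass
class CoxFit:
    """Proportional-hazards fit: log-HRs with Wald inference.

    ``ci_low``/``ci_high`` are exp(coef -/+ 1.96 se); ``diverged`` flags a
    monotone partial likelihood (separation); ``constant`` lists covariates
    that were constant in the data (coefficient pinned at 0, no inference).
    """

    coef: pd.Series
    se: pd.Series
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str = "efron"
    diverged: bool = False
    constant: tuple = ()

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.coef)

    @property
    def zvalues(self) -> pd.Series:
        return self.coef / self.se

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.coef.index)

    @property
    def ci_low(self) -> pd.Series:
        return np.exp(self.coef - 1.959963984540054 * self.se)

    @property
    def ci_high(self) -> pd.Series:
        return np.exp(self.coef + 1.959963984540054 * self.se)

    @property
    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "HR": self.hr,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.pvalues,
        })

    def wald_block_p(self, columns) -> float:
        """Multivariate Wald p-value for a block of coefficients."""
        cols = [c for c in columns if c in self.coef.index and c not in self.constant]
        if not cols:
            return 1.0
        idx = [self.coef.index.get_loc(c) for c in cols]
        V = self._vcov[np.ix_(idx, idx)]
        b = self.coef.iloc[idx].to_numpy()
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            return 1.0
        return float(stats.chi2.sf(chi2, df=len(cols)))


def _cox_engine(start, stop, event, X: pd.DataFrame, ties: str = "efron",
                tol: float = 1e-9, max_iter: int = 100) -> CoxFit:
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event, dtype=int)
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    if np.any(start >= stop):
        raise ValueError("need start < stop on every interval")
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events, got {n_events}")

    # constant covariates cancel from the partial likelihood: pin at zero
    const_mask = np.array([np.ptp(Xm[:, j]) == 0 for j in range(Xm.shape[1])])
    active = ~const_mask
    Xa = Xm[:, active]
    if Xa.shape[1]:
        centered = Xa - Xa.mean(axis=0)
        if np.linalg.matrix_rank(centered) < Xa.shape[1]:
            raise ValueError("collinear covariates")

    ll_null, _, _ = _partial_loglik(np.zeros(Xa.shape[1]), start, stop, event, Xa, ties)
    beta = np.zeros(Xa.shape[1])
    ll = ll_null
    diverged = False
    for _ in range(max_iter):
        if not Xa.shape[1]:
            break
        ll, gradient, hessian = _partial_loglik(beta, start, stop, event, Xa, ties)
        if np.max(np.abs(gradient)) < tol:
            break
        try:
            step = np.linalg.solve(hessian, -gradient)
        except np.linalg.LinAlgError:
            diverged = True
            break
        # step-halving to guarantee ascent
        for _ in range(30):
            ll_new, _, _ = _partial_loglik(beta + step, start, stop, event, Xa, ties)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(beta)) > 25:
            diverged = True
            break
    # a monotone likelihood can also "converge" at an absurd coefficient
    if Xa.shape[1] and np.max(np.abs(beta)) > 10:
        diverged = True
    if diverged:
        warnings.warn("partial likelihood appears monotone (separation); "
                      "estimates are unreliable", stacklevel=3)

    se_a = np.full(Xa.shape[1], np.nan)
    vcov = np.full((len(names), len(names)), np.nan)
    if Xa.shape[1] and not diverged:
        _, _, hessian = _partial_loglik(beta, start, stop, event, Xa, ties)
        cov_a = np.linalg.inv(-hessian)
        se_a = np.sqrt(np.diag(cov_a))
        vcov[np.ix_(active, active)] = cov_a

    coef = np.zeros(len(names))
    se = np.full(len(names), np.nan)
    coef[active] = beta
    se[active] = se_a
    ll_full = ll if Xa.shape[1] else ll_null
    fit = CoxFit(
        coef=pd.Series(coef, index=names), se=pd.Series(se, index=names),
        loglik=float(ll_full), loglik_null=float(ll_null),
        n=len(stop), n_events=n_events, ties=ties, diverged=diverged,
        constant=tuple(np.asarray(names)[const_mask]),
    )
    fit._vcov = vcov
    return fit


def cox_fit(records: pd.DataFrame, covariates, ties: str = "efron",
            time_col: str = "time_months", event_col: str = "event") -> CoxFit:
    """Standard Cox model on one row per subject (time-fixed covariates)."""
    X = records[list(covariates)]
    start = np.zeros(len(records))
    return _cox_engine(start, records[time_col], records[event_col], X, ties)


def td_cox_fit(rows: pd.DataFrame, covariates, ties: str = "efron") -> CoxFit:
    """Time-dependent Cox model on counting-process (start, stop] rows.

    Intervals within a patient must be disjoint and ordered, with the event
    (if any) on the final row; reduces exactly to :func:`cox_fit` when every
    patient contributes a single row starting at 0.
    """
    for pid, grp in rows.groupby("patient_id", sort=False):
        s = grp.sort_values("start")
        if np.any(s["start"].to_numpy() >= s["stop"].to_numpy()):
            raise ValueError(f"patient {pid}: empty or inverted interval")
        if np.any(s["stop"].to_numpy()[:-1] > s["start"].to_numpy()[1:]):
            raise ValueError(f"patient {pid}: overlapping intervals")
        ev = s["event"].to_numpy()
        if ev[:-1].any():
            raise ValueError(f"patient {pid}: event on a non-final interval")
    X = rows[list(covariates)]
    return _cox_engine(rows["start"], rows["stop"], rows["event"], X, ties)


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KmCurve:
    """Product-limit estimate with Greenwood log-log confidence band."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float
    median_ci: tuple
    n: int
    n_events: int

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)


def km_fit(records: pd.DataFrame, time_col: str = "time_months",
           event_col: str = "event", label: str = "KM") -> KmCurve:
    """Kaplan-Meier curve; median = first time the estimate drops to <= 0.5.

    With no events the curve is flat at 1 and the median is undefined
    (returned as ``inf`` and flagged via :attr:`KmCurve.median_defined`).
    """
    if len(records) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(records[time_col], records[event_col])
    n_events = int(records[event_col].sum())
    if n_events == 0:
        warnings.warn("no events: KM median undefined", stacklevel=2)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    median = float(kmf.median_survival_time_)
    med_ci_df = median_survival_times(ci)
    med_ci = (float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1]))
    return KmCurve(
        times=sf.index.to_numpy(float), survival=sf.iloc[:, 0].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(), ci_upper=ci.iloc[:, 1].to_numpy(),
        median=median, median_ci=med_ci, n=len(records), n_events=n_events,
    )


def reverse_km_followup(records: pd.DataFrame, time_col: str = "time_months",
                        event_col: str = "event") -> float:
    """Median follow-up by reverse Kaplan-Meier (censoring as the event)."""
    flipped = records.copy()
    flipped[event_col] = 1 - flipped[event_col]
    if flipped[event_col].sum() == 0:
        warnings.warn("no censored subjects: reverse-KM follow-up undefined", stacklevel=2)
        return float("nan")
    return km_fit(flipped, time_col, event_col, label="reverse-KM").median


# ---------------------------------------------------------------------------
# LVCF expansion and exposure dichotomization

def expand_lvcf(survival: pd.DataFrame, longitudinal: pd.DataFrame,
                value_col: str = "ttc", time_col: str = "t",
                pre_first: str = "carry_back") -> pd.DataFrame:
    """Expand repeated measurements into counting-process rows (LVCF).

    A measurement at t_j supplies the covariate value on [t_j, t_{j+1}); the
    period before the first measurement either carries the first value
    backward (``pre_first='carry_back'``, default) or is excluded from the
    risk set (``pre_first='exclude'``, delayed entry at t_1).  Measurements at
    or after the event/censoring time are dropped with a warning; a patient
    with no usable measurement is excluded and logged.
    """
    if pre_first not in ("carry_back", "exclude"):
        raise ValueError("pre_first must be 'carry_back' or 'exclude'")
    surv = survival.set_index("patient_id")
    orphans = set(longitudinal["patient_id"]) - set(surv.index)
    if orphans:
        raise ValueError(f"longitudinal patients missing from survival table: {sorted(orphans)[:5]}")
    out = []
    for pid, grp in longitudinal.groupby("patient_id", sort=True):
        T = float(surv.loc[pid, "time_months"])
        delta = int(surv.loc[pid, "event"])
        grp = grp.sort_values(time_col, kind="mergesort")
        keep = grp[time_col].to_numpy(float) < T
        if not keep.all():
            warnings.warn(f"patient {pid}: {int((~keep).sum())} measurement(s) at/after "
                          "the event time dropped", stacklevel=2)
        times = grp[time_col].to_numpy(float)[keep]
        values = grp[value_col].to_numpy(float)[keep]
        if len(times) == 0:
            warnings.warn(f"patient {pid}: no usable measurements; excluded", stacklevel=2)
            continue
        # deduplicate equal times, keeping the last value
        uniq_t, idx = np.unique(times, return_index=True)
        last_idx = np.r_[idx[1:], len(times)] - 1
        times, values = uniq_t, values[last_idx]
        if pre_first == "carry_back":
            starts = np.r_[0.0, times[1:]]
        else:
            starts = times.copy()
        stops = np.r_[starts[1:], T]
        ok = stops > starts
        for s, e, v in zip(starts[ok], stops[ok], values[ok]):
            out.append((pid, s, e, 0, v))
        if out and out[-1][0] == pid:
            last = out[-1]
            out[-1] = (pid, last[1], last[2], delta, last[4])
    cp = pd.DataFrame(out, columns=["patient_id", "start", "stop", "event", value_col])
    return cp


def dichotomize_exposure(per_patient_median: pd.Series, threshold: float = 435.0) -> pd.Series:
    """Label per-patient median troughs adequate (1) vs inadequate (0, reference).

    The boundary counts as adequate (median >= threshold).
    """
    return (per_patient_median >= threshold).astype(int).rename("adequate")


# ---------------------------------------------------------------------------
# covariate handling and backward elimination

def build_design(survival: pd.DataFrame, covariates) -> tuple[pd.DataFrame, dict]:
    """Expand a covariate list into design columns.

    Categorical covariates (ECOG, prior treatment lines) become unordered
    treatment dummies against their lowest observed level; returns the design
    and a mapping candidate-name -> list of design columns (a block).
    """
    cols = {}
    blocks = {}
    for cov in covariates:
        if cov in CATEGORICAL_COVARIATES:
            levels = sorted(survival[cov].unique())
            block = []
            for lev in levels[1:]:
                name = f"{cov}[{lev}]"
                cols[name] = (survival[cov] == lev).astype(float)
                block.append(name)
            blocks[cov] = block
        else:
            cols[cov] = survival[cov].astype(float)
            blocks[cov] = [cov]
    return pd.DataFrame(cols, index=survival.index), blocks


def backward_eliminate(records: pd.DataFrame, candidates, forced,
                       alpha: float = 0.05, ties: str = "efron",
                       time_col: str = "time_months", event_col: str = "event"):
    """Backward elimination of baseline covariates at Wald level ``alpha``.

    ``forced`` covariates (the exposure variable, at minimum) are never
    removed.  At each step the candidate (block, for categoricals) with the
    largest Wald p >= alpha is dropped and the model refitted, until all
    remaining candidates are significant.  Deterministic given the input.
    """
    design, blocks = build_design(records, list(candidates) + [c for c in forced if c in records.columns])
    # forced columns may already be design columns rather than raw covariates
    forced_cols = []
    for c in forced:
        forced_cols.extend(blocks.get(c, [c]))
    data = pd.concat([records[[time_col, event_col]], design], axis=1)
    for c in forced_cols:
        if c not in data.columns:
            data[c] = records[c].astype(float)
    remaining = [c for c in candidates]
    while True:
        model_cols = forced_cols + [col for cand in remaining for col in blocks[cand]]
        fit = cox_fit(data, model_cols, ties, time_col, event_col)
        if not remaining:
            return fit, remaining
        pvals = {cand: fit.wald_block_p(blocks[cand]) for cand in remaining}
        worst = max(sorted(pvals), key=lambda c: pvals[c])
        if pvals[worst] >= alpha:
            remaining = [c for c in remaining if c != worst]
        else:
            return fit, remaining
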