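"""Linear mixed-effects sub-model for the TTC trajectory.

The longitudinal outcome is the transformed trough concentration (TTC),
modelled as

    y_ij = beta0 + beta1 * t_ij + beta_dose[level_ij] + b0_i + b1_i * t_ij + e_ij

with a subject-level random intercept and slope (covariance D) clustering the
repeated measurements, dose entering as an unordered categorical covariate
(reference = standard dose), and i.i.d. Gaussian residuals.  Fitting is by
maximum likelihood; per-subject empirical-Bayes modes of (b0, b1) turn the
fit into evaluable subject trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trajectory import Trajectory

__all__ = ["LmmFit", "fit_lmm", "subject_trajectory", "add_dose_level"]

#: expected longitudinal-record columns
RECORD_COLUMNS = ("patient_id", "t", "ttc_value", "dose_level")


def add_dose_level(long_df: pd.DataFrame, dose_levels_mg=None) -> pd.DataFrame:
    """Derive the categorical ``dose_level`` (0 = standard dose) from ``dose_mg``.

    Levels are indexed by descending dose; unseen doses are rejected.  If
    ``dose_levels_mg`` is None the observed doses define the levels.
    """
    if dose_levels_mg is None:
        dose_levels_mg = sorted(long_df["dose_mg"].unique(), reverse=True)
    mapping = {d: i for i, d in enumerate(dose_levels_mg)}
    unknown = set(long_df["dose_mg"].unique()) - set(mapping)
    if unknown:
        raise ValueError(f"doses {sorted(unknown)} not in dose_levels_mg {list(dose_levels_mg)}")
    out = long_df.copy()
    out["dose_level"] = long_df["dose_mg"].map(mapping).astype(int)
    return out


@dataclass
class LmmFit:
    """ML fit of the random-intercept/slope model.

    ``fixed`` holds the fixed effects keyed ``intercept``, ``time`` and
    ``dose_level[k]`` for each non-reference level present; ``random_cov`` is
    the 2x2 covariance of (b0, b1) (slope row/col zero if the fit degenerated
    to a random intercept only); ``re_modes`` maps patient id -> (b0, b1)
    empirical-Bayes modes.
    """

    fixed: pd.Series
    se: pd.Series
    random_cov: np.ndarray
    resid_var: float
    loglik: float
    re_modes: dict = field(default_factory=dict)
    dose_levels: tuple = ()
    converged: bool = True
    slope_dropped: bool = False

    @property
    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.fixed, "se": self.se})


def _design(records: pd.DataFrame, dose_levels):
    """Fixed-effect design: intercept, time, dummies for non-reference levels."""
    n = len(records)
    cols = {"intercept": np.ones(n), "time": records["t"].to_numpy(float)}
    for lev in dose_levels[1:]:
        cols[f"dose_level[{lev}]"] = (records["dose_level"].to_numpy() == lev).astype(float)
    return pd.DataFrame(cols, index=records.index)


def fit_lmm(records: pd.DataFrame, reml: bool = False) -> LmmFit:
    """Fit the random-intercept/slope LMM by (restricted) maximum likelihood.

    ``records`` needs columns ``patient_id, t, ttc_value, dose_level``; at
    least two patients, each with at least one record.  Patients with a
    single observation are retained (their random effects shrink toward 0).
    A singular random-effects covariance triggers a flagged refit with a
    random intercept only.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"longitudinal records missing columns {missing}")
    if records["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients")
    bad = records.index[(records["ttc_value"] < 0) | (records["ttc_value"] >= 100)]
    if len(bad):
        raise ValueError(f"ttc_value out of [0, 100) at rows {list(bad[:5])}")

    records = records.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)
    dose_levels = tuple(sorted(records["dose_level"].unique()))
    exog = _design(records, dose_levels)
    endog = records["ttc_value"].to_numpy(float)
    groups = records["patient_id"].to_numpy()
    exog_re = exog[["intercept", "time"]]

    def _fit(exog_re_):
        # lbfgs is fast but fragile on near-flat variance profiles; Powell is
        # slower and robust.  Keep the best-likelihood converged fit.
        model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re_)
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell"):
                try:
                    res = model.fit(reml=reml, method=method, maxiter=1000)
                except Exception:
                    continue
                if best is None or (res.converged and not best.converged) or (
                    res.converged == best.converged and res.llf > best.llf
                ):
                    best = res
                if best.converged and method == "lbfgs" and best.llf > -np.inf:
                    # still try powell; lbfgs "converged" can sit on a plateau
                    continue
        if best is None:
            raise RuntimeError("mixed-model optimization failed outright")
        return best

    res = _fit(exog_re)
    slope_dropped = False
    # near-singular D (or failed convergence): fall back to random intercept only
    cov = np.asarray(res.cov_re)
    eigvals = np.linalg.eigvalsh(cov)
    if (not res.converged) or eigvals.min() < 1e-8 * max(eigvals.max(), 1.0):
        res_ri = _fit(exog_re[["intercept"]])
        if res_ri.converged or not res.converged:
            res, slope_dropped = res_ri, True
            warnings.warn("random-effects covariance singular or fit non-converged; "
                          "refitted with random intercept only", stacklevel=2)
    if not res.converged:
        warnings.warn("MixedLM did not converge; estimates may be unreliable", stacklevel=2)

    k = exog.shape[1]
    fixed = pd.Series(np.asarray(res.fe_params)[:k], index=exog.columns)
    se = pd.Series(np.asarray(res.bse)[:k], index=exog.columns)
    sigma2 = float(res.scale)
    cov = np.asarray(res.cov_re)  # statsmodels reports cov_re on the data scale
    if slope_dropped:
        D = np.zeros((2, 2))
        D[0, 0] = float(cov[0, 0])
    else:
        D = np.asarray(cov, dtype=float)

    re_modes = {}
    for pid, re in res.random_effects.items():
        vals = np.asarray(re, dtype=float)
        re_modes[pid] = (float(vals[0]), float(vals[1]) if not slope_dropped else 0.0)

    return LmmFit(
        fixed=fixed, se=se, random_cov=D, resid_var=sigma2,
        loglik=float(res.llf), re_modes=re_modes, dose_levels=dose_levels,
        converged=bool(res.converged), slope_dropped=slope_dropped,
    )


def dose_offsets(fit: LmmFit, levels: np.ndarray) -> np.ndarray:
    """Fixed-effect offset contributed by each dose level (0 for the reference)."""
    out = np.zeros(len(levels))
    for j, lev in enumerate(levels):
        key = f"dose_level[{lev}]"
        if key in fit.fixed.index:
            out[j] = fit.fixed[key]
        elif lev != fit.dose_levels[0]:
            raise ValueError(f"dose level {lev} unknown to the fit")
    return out


def subject_trajectory(fit: LmmFit, patient_id, dose_history) -> Trajectory:
    """Estimated trajectory m_i(t) for one fitted patient.

    ``dose_history`` is a sequence of (time, dose_level) pairs, first at t=0;
    the trajectory is linear in time between dose changes and steps by the
    fitted dose coefficient at each change (left-continuous at change points).
    """
    if patient_id not in fit.re_modes:
        raise KeyError(f"patient {patient_id!r} not in fit")
    b0, b1 = fit.re_modes[patient_id]
    times = np.asarray([h[0] for h in dose_history], dtype=float)
    levels = np.asarray([h[1] for h in dose_history])
    return Trajectory(
        intercept=fit.fixed["intercept"] + b0,
        slope=fit.fixed["time"] + b1,
        seg_times=times,
        seg_offsets=dose_offsets(fit, levels),
    )
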