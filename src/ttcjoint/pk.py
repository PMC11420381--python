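"""Trough extrapolation and sigmoid (Emax/Hill) normalization of drug concentrations.

Plasma samples drawn at routine clinic visits are rarely true troughs.  With a
drug whose elimination half-life is long relative to the dosing interval
(alectinib: t1/2 = 32 h, dosed every 12 h), the concentration immediately
before the next intake can be recovered by log-linear extrapolation of the
measured concentration forward to the next scheduled trough.

Troughs are then mapped onto a bounded 0-100 scale -- the transformed trough
concentration (TTC) -- through a Hill sigmoid

    TTC(C) = C**gamma / (EC50**gamma + C**gamma) * 100

which both normalizes the right-skewed concentration distribution and encodes
the pharmacological saturation of effect at high exposure.  EC50 centres the
curve (TTC(EC50) = 50); gamma sets its steepness and is calibrated so the
transformed sample is as close to Gaussian as possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SigmoidParams",
    "PkConstants",
    "PkSample",
    "extrapolate_trough",
    "ttc",
    "inverse_ttc",
    "calibrate_gamma",
    "gamma_from_unit_pair",
    "unit_increase_equivalent",
    "transform_table",
    "DAYS_PER_MONTH",
    "HOURS_PER_MONTH",
]

#: All longitudinal and survival times in this package are in months.
DAYS_PER_MONTH = 30.4375
HOURS_PER_MONTH = 24.0 * DAYS_PER_MONTH

#: Default gamma calibration grid (dimensionless steepness candidates).
DEFAULT_GAMMA_GRID = tuple(np.arange(0.5, 4.0 + 1e-9, 0.25))


@dataclass(frozen=True)
class SigmoidParams:
    """Hill-sigmoid parameters for the trough -> TTC transformation.

    ec50
        Concentration (ng/mL) at the curve centre, TTC(ec50) = scale / 2.
        Default 600 ng/mL, slightly above the 435 ng/mL efficacy target so
        the transformation is still informative around the target.
    gamma
        Steepness exponent (> 0).  Default 1.5, which reproduces the
        one-TTC-unit concentration pairs (350 -> 361, 600 -> 617 ng/mL)
        used for interpretation.
    scale
        Output ceiling; TTC takes values in [0, scale).  Fixed at 100.
    """

    ec50: float = 600.0
    gamma: float = 1.5
    scale: float = 100.0

    def __post_init__(self) -> None:
        if not self.ec50 > 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")


#: Sensitivity-analysis presets: EC50 shifted to 500 / 700 ng/mL with gamma 2.
SENSITIVITY_PRESETS = (
    SigmoidParams(ec50=500.0, gamma=2.0),
    SigmoidParams(ec50=700.0, gamma=2.0),
)


@dataclass(frozen=True)
class PkConstants:
    """Elimination and dosing constants used for trough extrapolation."""

    half_life_h: float = 32.0
    dosing_interval_h: float = 12.0

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise ValueError("half_life_h must be > 0")
        if not self.dosing_interval_h > 0:
            raise ValueError("dosing_interval_h must be > 0")


@dataclass(frozen=True)
class PkSample:
    """One measured plasma concentration with its dosing context."""

    patient_id: str
    t_obs: float  # months since treatment start
    conc_obs: float  # ng/mL
    t_since_dose: float  # hours since last intake
    dose: float  # mg per intake at sampling

    def __post_init__(self) -> None:
        if not self.conc_obs > 0:
            raise ValueError(f"conc_obs must be > 0, got {self.conc_obs}")
        if self.t_since_dose < 0:
            raise ValueError(f"t_since_dose must be >= 0, got {self.t_since_dose}")
        if self.t_obs < 0:
            raise ValueError(f"t_obs must be >= 0, got {self.t_obs}")
        if not self.dose > 0:
            raise ValueError(f"dose must be > 0, got {self.dose}")


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def extrapolate_trough(conc_obs, t_since_dose_h, constants: PkConstants = PkConstants()):
    """Log-linearly decay a measured concentration forward to the next trough.

    The remaining time to the next scheduled intake is
    ``delta = (interval - t_since_dose mod interval) mod interval``; the trough
    estimate is ``conc_obs * 2**(-delta / half_life)``.  A sample drawn exactly
    at a scheduled trough (``delta = 0``) is returned unchanged.  Times since
    dose beyond one interval (late or missed intake) are reduced modulo the
    interval rather than treated as non-adherence.

    Accepts scalars or arrays; a :class:`PkSample` may be passed as the first
    argument with ``t_since_dose_h=None``.
    """
    if isinstance(conc_obs, PkSample):
        sample = conc_obs
        conc_obs, t_since_dose_h = sample.conc_obs, sample.t_since_dose
    conc = _as_array(conc_obs)
    tsd = _as_array(t_since_dose_h)
    if np.any(~(conc > 0)):
        bad = np.nonzero(np.atleast_1d(~(conc > 0)))[0]
        raise ValueError(f"non-positive concentration(s) at positions {bad[:5]}")
    if np.any(tsd < 0):
        bad = np.nonzero(np.atleast_1d(tsd < 0))[0]
        raise ValueError(f"negative t_since_dose at positions {bad[:5]}")
    tau = constants.dosing_interval_h
    delta = np.mod(tau - np.mod(tsd, tau), tau)
    out = conc * np.exp2(-delta / constants.half_life_h)
    return out if out.ndim else float(out)


def ttc(conc, params: SigmoidParams = SigmoidParams()):
    """Map trough concentration(s) (ng/mL) to the TTC scale [0, scale)."""
    c = _as_array(conc)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    ratio = (c / params.ec50) ** params.gamma
    out = params.scale * ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def inverse_ttc(value, params: SigmoidParams = SigmoidParams()):
    """Invert :func:`ttc`: the concentration whose TTC equals ``value``.

    ``value`` must lie in [0, scale); the ceiling itself is unreachable.
    """
    v = _as_array(value)
    if np.any((v < 0) | (v >= params.scale)):
        raise ValueError(f"TTC values must lie in [0, {params.scale})")
    frac = v / params.scale
    out = params.ec50 * (frac / (1.0 - frac)) ** (1.0 / params.gamma)
    return out if out.ndim else float(out)


def calibrate_gamma(concentrations, ec50: float, grid=DEFAULT_GAMMA_GRID) -> float:
    """Pick the grid gamma whose TTC sample is closest to Gaussian.

    The normality score is the Shapiro-Wilk W statistic of the transformed
    sample; ties break toward the smaller gamma.  Requires at least 10
    non-degenerate concentrations (W is unstable below that).
    """
    conc = _as_array(concentrations)
    if conc.size < 10:
        raise ValueError(f"need >= 10 concentrations to calibrate gamma, got {conc.size}")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    if np.ptp(conc) == 0:
        raise ValueError("degenerate (constant) sample: normality score undefined")
    grid = [float(g) for g in grid]
    if not grid or any(g <= 0 for g in grid):
        raise ValueError("gamma grid must be non-empty and positive")
    if len(grid) == 1:
        return grid[0]
    best_g, best_w = None, -np.inf
    for g in sorted(grid):
        w = stats.shapiro(ttc(conc, SigmoidParams(ec50=ec50, gamma=g))).statistic
        if w > best_w:  # strict: first (smallest) gamma wins ties
            best_g, best_w = g, w
    return best_g


def gamma_from_unit_pair(conc_low: float, conc_high: float, ec50: float,
                         scale: float = 100.0) -> float:
    """Solve for the gamma at which ``conc_low`` and ``conc_high`` are one TTC unit apart.

    Used to recover the steepness implied by a printed interpretation pair
    such as "one TTC unit separates troughs of 600 and 617 ng/mL".
    """
    if not 0 < conc_low < conc_high:
        raise ValueError("need 0 < conc_low < conc_high")

    def gap(g: float) -> float:
        p = SigmoidParams(ec50=ec50, gamma=g, scale=scale)
        return ttc(conc_high, p) - ttc(conc_low, p) - 1.0

    return float(optimize.brentq(gap, 1e-3, 50.0, xtol=1e-12, rtol=1e-14))


def unit_increase_equivalent(conc: float, params: SigmoidParams = SigmoidParams()) -> float:
    """Concentration whose TTC is exactly one unit above that of ``conc``."""
    base = ttc(conc, params)
    if base + 1.0 >= params.scale:
        raise ValueError("TTC + 1 exceeds the transformation ceiling")
    return float(inverse_ttc(base + 1.0, params))


LONGITUDINAL_COLUMNS = ("patient_id", "t_obs_months", "conc_ng_ml", "t_since_dose_h", "dose_mg")


def transform_table(df: pd.DataFrame,
                    params: SigmoidParams = SigmoidParams(),
                    constants: PkConstants = PkConstants()) -> pd.DataFrame:
    """Augment a long-format sample table with ``trough_ng_ml`` and ``ttc`` columns.

    Expects columns ``patient_id, t_obs_months, conc_ng_ml, t_since_dose_h,
    dose_mg``; rejects rows violating the sample invariants, reporting row
    labels in the error.
    """
    missing = [c for c in LONGITUDINAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"longitudinal table missing columns {missing}")
    bad_conc = df.index[~(df["conc_ng_ml"] > 0)]
    if len(bad_conc):
        raise ValueError(f"non-positive conc_ng_ml at rows {list(bad_conc[:5])}")
    bad_tsd = df.index[df["t_since_dose_h"] < 0]
    if len(bad_tsd):
        raise ValueError(f"negative t_since_dose_h at rows {list(bad_tsd[:5])}")
    bad_t = df.index[df["t_obs_months"] < 0]
    if len(bad_t):
        raise ValueError(f"negative t_obs_months at rows {list(bad_t[:5])}")
    out = df.copy()
    out["trough_ng_ml"] = extrapolate_trough(
        out["conc_ng_ml"].to_numpy(), out["t_since_dose_h"].to_numpy(), constants
    )
    out["ttc"] = ttc(out["trough_ng_ml"].to_numpy(), params)
    return out
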