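"""Von Bertalanffy growth: fitting, curves, derived ages, performance index.

Length-at-age follows L_t = L_inf (1 - e^(-k (t - t0))); weight-at-age is
obtained through the allometric relationship, W_t = W_inf (1 - e^(-k (t -
t0)))^b with W_inf = a L_inf^b.  Two biologically meaningful ages derive
from these curves:

* the inflection age t_i = ln(b)/k + t0, where the weight growth *rate*
  peaks (the zero of the weight growth acceleration), and
* the critical age t_c = [k t0 - ln M + ln(b k + M)]/k, where the biomass
  of an unfished cohort subject to natural mortality M peaks.

The growth performance index phi = log10(k) + 2 log10(L_inf) standardises
growth rate by asymptotic size for cross-population comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import DegenerateInputError, FitError, InsufficientDataError
from .length_weight import LengthWeightFit
from .samples import IntervalEstimate

#: Convergence policy for the nonlinear fit: relative objective change.
FTOL = 1e-9
MAX_ITER = 500


@dataclass(frozen=True)
class VBGFParams:
    """Von Bertalanffy parameters, each with an interval estimate.

    ``L_inf`` in mm, ``k`` in 1/year, ``t0`` in years.
    """

    L_inf: IntervalEstimate
    k: IntervalEstimate
    t0: IntervalEstimate

    def __post_init__(self):
        if not self.L_inf.value > 0:
            raise ValueError("L_inf must be > 0")
        if not self.k.value > 0:
            raise ValueError("k must be > 0")

    @classmethod
    def from_points(cls, L_inf: float, k: float, t0: float) -> "VBGFParams":
        return cls(
            L_inf=IntervalEstimate(L_inf, L_inf, point=L_inf),
            k=IntervalEstimate(k, k, point=k),
            t0=IntervalEstimate(t0, t0, point=t0),
        )


@dataclass(frozen=True)
class GrowthDerived:
    """Derived growth quantities for reporting."""

    W_inf: float  # g
    t_inflection: float  # year
    t_critical: float  # year
    phi: float  # log10 scale

    def __post_init__(self):
        if not math.isfinite(self.phi):
            raise ValueError("phi must be finite")


def _vbgf(t, L_inf, k, t0):
    return L_inf * (1.0 - np.exp(-k * (np.asarray(t, dtype=float) - t0)))


def _ford_walford_k0(ages: np.ndarray, lengths: np.ndarray) -> float:
    """Initial k from a Ford-Walford-style regression on mean length-at-age.

    Regressing mean L at age t+1 on mean L at age t gives slope e^-k for
    unit age steps; the result is clipped to a sane range so a poor
    initialisation cannot derail the solver.
    """
    uniq = np.unique(ages)
    means = {int(a): lengths[ages == a].mean() for a in uniq}
    pairs = [(means[a], means[a + 1]) for a in means if a + 1 in means]
    if len(pairs) >= 3:
        x, y = np.array(pairs).T
        if np.ptp(x) > 0:
            slope = np.polyfit(x, y, 1)[0]
            if 0 < slope < 1:
                return float(np.clip(-np.log(slope), 0.01, 1.0))
    return 0.2


def fit_vbgf(
    ages: Sequence[float],
    lengths: Sequence[float],
    *,
    confidence: float = 0.95,
) -> VBGFParams:
    """Fit the VBGF to individual (age, length) pairs by nonlinear least squares.

    Initialisation: L_inf0 = max(L)/0.95, k0 from a Ford-Walford-style
    regression, t00 = 0.  CIs come from the estimated parameter covariance
    (Gauss-Newton approximation) and the t distribution with n - 3 df.
    Deterministic: same data always yields bit-identical parameters.
    """
    ages = np.asarray(ages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if ages.shape != lengths.shape or ages.ndim != 1:
        raise ValueError("ages and lengths must be 1-D and equal length")
    if np.unique(ages).size < 5:
        raise InsufficientDataError(
            f"need >= 5 distinct ages, got {np.unique(ages).size}"
        )
    if np.any(lengths <= 0):
        raise DegenerateInputError("all lengths must be positive")

    x0 = np.array([lengths.max() / 0.95, _ford_walford_k0(ages, lengths), 0.0])

    def resid(p):
        return _vbgf(ages, *p) - lengths

    sol = least_squares(
        resid, x0, ftol=FTOL, xtol=1e-12, gtol=1e-12, max_nfev=MAX_ITER * 4,
        bounds=([1e-6, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
    )
    if not sol.success:
        raise FitError(
            f"VBGF fit did not converge: {sol.message}",
            best_params=tuple(sol.x),
            diagnostics={"cost": sol.cost, "nfev": sol.nfev, "status": sol.status},
        )

    n, p = ages.size, 3
    dof = max(n - p, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    tq = stats.t.ppf(0.5 + confidence / 2, dof) if n > p else np.inf

    def iv(i):
        return IntervalEstimate(
            lower=float(sol.x[i] - tq * se[i]),
            upper=float(sol.x[i] + tq * se[i]),
            point=float(sol.x[i]),
            confidence=confidence,
        )

    return VBGFParams(L_inf=iv(0), k=iv(1), t0=iv(2))


# ---------------------------------------------------------------- curves


def length_at_age(p: VBGFParams, t) -> float | np.ndarray:
    """Mean body length (mm) at age t."""
    out = _vbgf(t, p.L_inf.value, p.k.value, p.t0.value)
    return float(out) if np.isscalar(t) else out


def asymptotic_weight(p: VBGFParams, lw: LengthWeightFit) -> float:
    """W_inf = a L_inf^b."""
    return lw.a * p.L_inf.value ** lw.b


def weight_at_age(p: VBGFParams, lw: LengthWeightFit, t) -> float | np.ndarray:
    """Mean body weight (g) at age t; zero at and below t0."""
    frac = 1.0 - np.exp(-p.k.value * (np.asarray(t, dtype=float) - p.t0.value))
    out = asymptotic_weight(p, lw) * np.maximum(frac, 0.0) ** lw.b
    return float(out) if np.isscalar(t) else out


def growth_rate(p: VBGFParams, lw: LengthWeightFit, t):
    """(dL/dt in mm/yr, dW/dt in g/yr) at age t, in closed form."""
    L_inf, k, t0 = p.L_inf.value, p.k.value, p.t0.value
    b = lw.b
    e = np.exp(-k * (np.asarray(t, dtype=float) - t0))
    dl = L_inf * k * e
    w_inf = asymptotic_weight(p, lw)
    dw = b * w_inf * k * e * np.maximum(1.0 - e, 0.0) ** (b - 1.0)
    if np.isscalar(t):
        return float(dl), float(dw)
    return dl, dw


def growth_acceleration(p: VBGFParams, lw: LengthWeightFit, t):
    """(d2L/dt2 in mm/yr^2, d2W/dt2 in g/yr^2) at age t, in closed form.

    The length acceleration is negative everywhere; the weight
    acceleration changes sign exactly once, at the inflection age.
    """
    L_inf, k, t0 = p.L_inf.value, p.k.value, p.t0.value
    b = lw.b
    e = np.exp(-k * (np.asarray(t, dtype=float) - t0))
    d2l = -L_inf * k**2 * e
    w_inf = asymptotic_weight(p, lw)
    d2w = b * w_inf * k**2 * e * np.maximum(1.0 - e, 0.0) ** (b - 2.0) * (b * e - 1.0)
    if np.isscalar(t):
        return float(d2l), float(d2w)
    return d2l, d2w


# ---------------------------------------------------------- derived ages


def inflection_age(p: VBGFParams, b: float) -> float:
    """Age of maximum weight growth rate: t_i = ln(b)/k + t0."""
    if b <= 1:
        raise ValueError(f"no inflection for b <= 1 (got b = {b})")
    return math.log(b) / p.k.value + p.t0.value


def critical_age(p: VBGFParams, b: float, M: float) -> float:
    """Age at which an unfished cohort's biomass peaks.

    t_c = [k t0 - ln M + ln(b k + M)] / k, the zero of
    d/dt [e^(-M (t - t0)) W_t].
    """
    if M <= 0:
        raise ValueError("M must be > 0")
    k, t0 = p.k.value, p.t0.value
    return (k * t0 - math.log(M) + math.log(b * k + M)) / k


def growth_performance_index(p: VBGFParams) -> float:
    """phi = log10(k) + 2 log10(L_inf), with L_inf in mm."""
    return math.log10(p.k.value) + 2.0 * math.log10(p.L_inf.value)


def derive_growth(p: VBGFParams, lw: LengthWeightFit, M: float) -> GrowthDerived:
    """Bundle the derived quantities used in assessment reports."""
    return GrowthDerived(
        W_inf=asymptotic_weight(p, lw),
        t_inflection=inflection_age(p, lw.b),
        t_critical=critical_age(p, lw.b, M),
        phi=growth_performance_index(p),
    )
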