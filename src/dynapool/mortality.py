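"""Mortality decomposition: Z (Beverton-Holt), M (Pauly), F, E, diagnostics.

Total mortality Z is estimated from mean length above the gear-selection
length Lc via the Beverton-Holt length-based estimator

    Z = k (L_inf - L_mean) / (L_mean - L_c),

natural mortality M from Pauly's empirical regression on L_inf, k and the
annual mean habitat temperature T, and fishing mortality by difference,
F = Z - M, with exploitation rate E = F/Z (the fraction of all deaths due
to fishing).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import DegenerateEstimateError, InsufficientDataError
from .samples import SampleSet

#: Pauly's empirical coefficients (intercept, ln L_inf, ln k, ln T).
PAULY_COEFFS = (-0.0066, -0.279, 0.6543, 0.4634)


@dataclass(frozen=True)
class MortalityEstimates:
    """Mortality coefficients (1/year) and the exploitation rate."""

    Z: float
    M: float
    F: float
    E: float
    L_mean: float  # mm
    L_c: float  # mm
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.Z > 0:
            raise ValueError("Z must be > 0")
        if not self.M > 0:
            raise ValueError("M must be > 0")
        if abs(self.F - (self.Z - self.M)) > 1e-9 * max(1.0, self.Z):
            raise ValueError("F must equal Z - M")
        if abs(self.E - self.F / self.Z) > 1e-9:
            raise ValueError("E must equal F/Z")


@dataclass(frozen=True)
class ReliabilityDiagnostics:
    """Ratio diagnostics for length-based mortality work.

    * e^-k < 1 validates the growth-equation parameterisation;
    * M/k within [1.5, 2.5] is the plausible band for natural mortality;
    * Z/k > 3 marks a fishing-dominated mortality regime.
    """

    exp_neg_k: float
    m_over_k: float
    z_over_k: float
    growth_valid: bool
    M_plausible: bool
    fishing_dominated: bool


def bh_z_from_mean(k: float, L_inf: float, L_mean: float, L_c: float) -> float:
    """Beverton-Holt Z from a known mean length above Lc."""
    if L_mean <= L_c:
        raise DegenerateEstimateError(
            f"mean length ({L_mean}) must exceed Lc ({L_c})"
        )
    return k * (L_inf - L_mean) / (L_mean - L_c)


def bh_total_mortality(
    k: float, L_inf: float, sample_set: SampleSet, L_c: float
) -> tuple[float, float]:
    """Estimate (Z, L_mean) from the samples with body length >= Lc.

    Requires at least 10 retained fish.  A mean length at or above L_inf
    is implausible under the model and is flagged with a warning rather
    than rejected.
    """
    if not L_c < L_inf:
        raise ValueError(f"Lc ({L_c}) must be below L_inf ({L_inf})")
    lengths = [x for x in sample_set.lengths if x >= L_c]
    if len(lengths) < 10:
        raise InsufficientDataError(
            f"need >= 10 samples with length >= Lc, got {len(lengths)}"
        )
    l_mean = sum(lengths) / len(lengths)
    if l_mean >= L_inf:
        warnings.warn(
            f"mean length ({l_mean:.1f}) >= L_inf ({L_inf:.1f}): "
            "Z estimate is implausible", stacklevel=2,
        )
    return bh_z_from_mean(k, L_inf, l_mean, L_c), l_mean


def invert_lc(k: float, L_inf: float, L_mean: float, Z: float) -> float:
    """Lc implied by a reported Z: the algebraic inverse of the Z estimator.

    Useful when Z and L_mean are published but the gear-selection length
    is not; round-trips exactly through :func:`bh_z_from_mean`.
    """
    if Z <= 0:
        raise ValueError("Z must be > 0")
    if L_inf <= L_mean:
        raise ValueError("L_inf must exceed L_mean")
    return L_mean - k * (L_inf - L_mean) / Z


def pauly_natural_mortality(
    L_inf_mm: float, k: float, T: float, *, variant: str = "log10_cm"
) -> float:
    """Pauly's empirical natural mortality.

    ``log10_cm`` (default) evaluates the coefficients as Pauly's original
    base-10 regression with L_inf in cm; ``ln_mm`` evaluates them with
    natural logarithms and L_inf in mm, as sometimes transcribed.
    """
    if T <= 0:
        raise ValueError("T must be > 0 degrees C")
    c0, cl, ck, ct = PAULY_COEFFS
    if variant == "log10_cm":
        expo = c0 + cl * math.log10(L_inf_mm / 10.0) + ck * math.log10(k) + ct * math.log10(T)
        return 10.0 ** expo
    if variant == "ln_mm":
        expo = c0 + cl * math.log(L_inf_mm) + ck * math.log(k) + ct * math.log(T)
        return math.exp(expo)
    raise ValueError(f"unknown variant {variant!r}")


def implied_temperature(
    M: float, L_inf_mm: float, k: float, *, variant: str = "log10_cm"
) -> float:
    """Habitat temperature (deg C) that Pauly's formula needs to return M.

    Sensitivity helper for when M is reported but T is not.
    """
    c0, cl, ck, ct = PAULY_COEFFS
    if variant == "log10_cm":
        num = math.log10(M) - c0 - cl * math.log10(L_inf_mm / 10.0) - ck * math.log10(k)
        return 10.0 ** (num / ct)
    if variant == "ln_mm":
        num = math.log(M) - c0 - cl * math.log(L_inf_mm) - ck * math.log(k)
        return math.exp(num / ct)
    raise ValueError(f"unknown variant {variant!r}")


def decompose(Z: float, M: float) -> tuple[float, float, bool]:
    """Split total mortality: returns (F, E, m_overestimated).

    F = Z - M and E = F/Z exactly.  A negative F (M exceeding Z) is
    reported as-is with the flag set, never clamped.
    """
    if Z == 0:
        raise ZeroDivisionError("Z must be non-zero to decompose")
    F = Z - M
    return F, F / Z, F < 0


def mortality_estimates(
    Z: float, M: float, L_mean: float, L_c: float, extra_warnings: tuple[str, ...] = ()
) -> MortalityEstimates:
    """Assemble the full record, enforcing the F and E identities."""
    F, E, m_over = decompose(Z, M)
    warns = tuple(extra_warnings)
    if m_over:
        warns = warns + ("M exceeds Z: natural mortality likely overestimated",)
    return MortalityEstimates(Z=Z, M=M, F=F, E=E, L_mean=L_mean, L_c=L_c, warnings=warns)


def diagnostics(Z: float, M: float, k: float) -> ReliabilityDiagnostics:
    """Ratio diagnostics; all thresholds are strict inequalities."""
    if min(Z, M, k) <= 0:
        raise ValueError("Z, M and k must all be > 0")
    exp_neg_k = math.exp(-k)
    m_over_k = M / k
    z_over_k = Z / k
    return ReliabilityDiagnostics(
        exp_neg_k=exp_neg_k,
        m_over_k=m_over_k,
        z_over_k=z_over_k,
        growth_valid=exp_neg_k < 1,
        M_plausible=1.5 <= m_over_k <= 2.5,
        fishing_dominated=z_over_k > 3,
    )
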