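"""Beverton-Holt relative yield- and biomass-per-recruit analysis.

The relative yield per recruit under knife-edge selection at Lc is

    Y'/R = E U^(M/k) [1 - 3U/(1+q) + 3U^2/(1+2q) - U^3/(1+3q)],

with U = 1 - Lc/L_inf and q = k/Z.  The exploitation rate E = F/Z closes
the model through Z = M/(1-E), i.e. q = (1-E)/(M/k), so the curve depends
only on c = Lc/L_inf and the ratio M/k.  Relative biomass per recruit is
B'/R = (Y'/R)/F; reported both raw and normalised by its unfished
(E -> 0) limit so that "B'/R falls to 50%" is well defined.

Reference points: E_max maximises Y'/R over E; E_50 is the exploitation
rate at which the normalised B'/R reaches one half.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .growth import VBGFParams, inflection_age, critical_age, length_at_age
from .length_weight import LengthWeightFit

_TOL = 1e-5


@dataclass(frozen=True)
class YPRInputs:
    """Dimensionless inputs of the relative dynamic-pool model.

    ``c`` is Lc/L_inf, ``m_ratio`` is M/k; ``M`` (1/year) only scales
    F = M E/(1-E) for the biomass-per-recruit denominator.
    """

    c: float
    m_ratio: float
    M: float

    def __post_init__(self):
        if not 0 <= self.c < 1:
            raise ValueError("c must lie in [0, 1)")
        if not self.m_ratio > 0:
            raise ValueError("m_ratio must be > 0")
        if not self.M > 0:
            raise ValueError("M must be > 0")


@dataclass(frozen=True)
class YPRResult:
    """Curves over E plus reference points."""

    E: np.ndarray
    yprime: np.ndarray
    bprime: np.ndarray
    bprime_ratio: np.ndarray
    E_max: float
    E_50: float
    ypr_at_Emax: float
    bprime_ratio_at_Emax: float


@dataclass(frozen=True)
class IsoplethGrid:
    """Y'/R over an (E, c) grid, with per-E and global argmax over c."""

    e_grid: np.ndarray
    c_grid: np.ndarray
    yprime: np.ndarray  # shape (len(e_grid), len(c_grid))
    c_star_at: dict[float, float]  # E -> argmax over c
    e_star_global: float
    c_star_global: float


def relative_ypr(E: float, inp: YPRInputs) -> float:
    """Closed-form relative yield per recruit at exploitation rate E."""
    if not 0 <= E <= 1:
        raise ValueError("E must lie in [0, 1]")
    if E == 0:
        return 0.0
    U = 1.0 - inp.c
    q = (1.0 - E) / inp.m_ratio  # k/Z under Z = M/(1-E)
    bracket = (
        1.0
        - 3.0 * U / (1.0 + q)
        + 3.0 * U**2 / (1.0 + 2.0 * q)
        - U**3 / (1.0 + 3.0 * q)
    )
    return E * U**inp.m_ratio * bracket


def _virgin_bpr(inp: YPRInputs) -> float:
    """lim_{E->0+} (Y'/R)/F: the unfished relative biomass per recruit."""
    U = 1.0 - inp.c
    q0 = 1.0 / inp.m_ratio
    bracket = (
        1.0
        - 3.0 * U / (1.0 + q0)
        + 3.0 * U**2 / (1.0 + 2.0 * q0)
        - U**3 / (1.0 + 3.0 * q0)
    )
    return U**inp.m_ratio * bracket / inp.M


def relative_bpr(E: float, inp: YPRInputs) -> tuple[float, float]:
    """(B'/R, B'/R normalised to its unfished limit) at exploitation E.

    At E = 0 the raw B'/R is undefined (no fishing mortality to divide
    by); the normalised ratio is 1 by definition of the limit.
    """
    virgin = _virgin_bpr(inp)
    if E == 0:
        return float("nan"), 1.0
    F = inp.M * E / (1.0 - E)
    bprime = relative_ypr(E, inp) / F
    return bprime, bprime / virgin


def find_e_max(inp: YPRInputs) -> float:
    """E maximising Y'/R, located by bounded 1-D search to ~1e-5.

    A coarse pre-scan guards against non-unimodal profiles (possible only
    for extreme inputs); in that case a fine grid argmax is used instead,
    with a warning.
    """
    grid = np.arange(0.01, 1.0, 0.01)
    vals = np.array([relative_ypr(e, inp) for e in grid])
    n_peaks = int(np.sum((np.diff(np.sign(np.diff(vals))) < 0)))
    if n_peaks > 1:
        warnings.warn("Y'/R profile not unimodal; falling back to fine grid argmax")
        fine = np.arange(1e-4, 1.0, 1e-4)
        fvals = [relative_ypr(e, inp) for e in fine]
        return float(fine[int(np.argmax(fvals))])
    res = minimize_scalar(
        lambda e: -relative_ypr(e, inp),
        bounds=(1e-9, 1.0 - 1e-9),
        method="bounded",
        options={"xatol": _TOL},
    )
    return float(res.x)


def find_e_50(inp: YPRInputs) -> float:
    """E at which normalised B'/R crosses one half (root-found to ~1e-5)."""
    f = lambda e: relative_bpr(e, inp)[1] - 0.5
    return float(brentq(f, 1e-9, 1.0 - 1e-9, xtol=_TOL))


def ypr_curve(inp: YPRInputs, e_grid: np.ndarray | None = None) -> YPRResult:
    """Evaluate the Y'/R and B'/R curves and both reference points."""
    if e_grid is None:
        e_grid = np.arange(0.01, 1.0, 0.01)
    e_grid = np.asarray(e_grid, dtype=float)
    yp = np.array([relative_ypr(e, inp) for e in e_grid])
    bp_pairs = [relative_bpr(e, inp) for e in e_grid]
    bp = np.array([p[0] for p in bp_pairs])
    bpr = np.array([p[1] for p in bp_pairs])
    e_max = find_e_max(inp)
    e_50 = find_e_50(inp)
    return YPRResult(
        E=e_grid,
        yprime=yp,
        bprime=bp,
        bprime_ratio=bpr,
        E_max=e_max,
        E_50=e_50,
        ypr_at_Emax=relative_ypr(e_max, inp),
        bprime_ratio_at_Emax=relative_bpr(e_max, inp)[1],
    )


def isopleth(
    m_ratio: float,
    M: float,
    e_grid: np.ndarray | None = None,
    c_grid: np.ndarray | None = None,
) -> IsoplethGrid:
    """Y'/R over the (E, Lc/L_inf) plane.

    Reports, for each E, the c maximising Y'/R, and the global argmax of
    the whole surface (the joint size-limit/effort optimum, which for
    this model sits on the high-E edge at c ~ 3/(M/k + 3)).
    """
    if e_grid is None:
        e_grid = np.arange(0.01, 1.0, 0.01)
    if c_grid is None:
        c_grid = np.arange(0.01, 1.0, 0.01)
    e_grid = np.asarray(e_grid, dtype=float)
    c_grid = np.asarray(c_grid, dtype=float)
    if e_grid.min() <= 0 or e_grid.max() >= 1 or c_grid.min() <= 0 or c_grid.max() >= 1:
        raise ValueError("grids must lie strictly inside (0, 1)")
    mat = np.empty((e_grid.size, c_grid.size))
    for i, e in enumerate(e_grid):
        for j, c in enumerate(c_grid):
            mat[i, j] = relative_ypr(e, YPRInputs(c=c, m_ratio=m_ratio, M=M))
    c_star_at = {float(e): float(c_grid[int(np.argmax(mat[i]))]) for i, e in enumerate(e_grid)}
    gi, gj = np.unravel_index(int(np.argmax(mat)), mat.shape)
    return IsoplethGrid(
        e_grid=e_grid,
        c_grid=c_grid,
        yprime=mat,
        c_star_at=c_star_at,
        e_star_global=float(e_grid[gi]),
        c_star_global=float(c_grid[gj]),
    )


def optimal_catch_length(L_inf: float, c_star: float) -> tuple[int, float]:
    """Catch length for a target Lc/L_inf: (nearest mm, unrounded mm)."""
    if not 0 <= c_star < 1:
        raise ValueError("c_star must lie in [0, 1)")
    exact = c_star * L_inf
    return int(round(exact)), exact


@dataclass(frozen=True)
class MinimumSizeRecommendation:
    """Three size-limit metrics and their average, all in mm.

    * length at the weight-growth inflection age (max commercial yield),
    * length at the critical age (cohort-biomass conservation),
    * length at the yield-per-recruit surface optimum.
    """

    inflection_length: float
    critical_length: float
    peak_ypr_length: float
    mean: float


def recommended_minimum_size(
    p: VBGFParams, lw: LengthWeightFit, M: float,
    c_grid: np.ndarray | None = None,
) -> MinimumSizeRecommendation:
    """Average the three candidate minimum-size metrics (see below)."""
    return minimum_size_metrics(p, lw.b, M, c_grid=c_grid)


def minimum_size_metrics(
    p: VBGFParams, b: float, M: float,
    c_grid: np.ndarray | None = None,
) -> MinimumSizeRecommendation:
    """Average the three candidate minimum-size metrics.

    The yield-per-recruit component uses the global optimum of the Y'/R
    surface over (E, c) (at c ~ 3/(M/k + 3)): the eumetric size limit the
    isopleth analysis recommends.  Only the allometry exponent ``b`` of
    the length-weight relationship enters these metrics.
    """
    t_i = inflection_age(p, b)
    t_c = critical_age(p, b, M)
    l_i = length_at_age(p, t_i)  # equals L_inf (1 - 1/b) analytically
    l_c = length_at_age(p, t_c)
    grid = isopleth(M / p.k.value, M, c_grid=c_grid)
    l_y = optimal_catch_length(p.L_inf.value, grid.c_star_global)[1]
    return MinimumSizeRecommendation(
        inflection_length=l_i,
        critical_length=l_c,
        peak_ypr_length=l_y,
        mean=(l_i + l_c + l_y) / 3.0,
    )
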