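"""Profile-likelihood identifiability analysis of fitted parameters.

For one fitted parameter, the profile fixes it on a log-spaced grid around
the estimate and re-optimizes all remaining free parameters at each grid
point (warm-started sweeping outward from the optimum).  Against the
pointwise 95% threshold ``chi2_best + 3.84`` (one degree of freedom) the
profile classifies the parameter as

``identifiable``
    the profile crosses the threshold on both sides of the estimate;
``practically_unidentifiable``
    the profile stays below the threshold over the whole span on at least
    one side (a unique optimum may exist but the data do not bound it);
``structurally_unidentifiable``
    the profile is flat at the optimal objective to numerical tolerance —
    a symmetry of the model exactly compensates the parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .calibrate import FitProblem, FitResult, weighted_residuals

__all__ = [
    "ProfileResult",
    "profile_likelihood",
    "classify_identifiability",
    "CHI2_95_1DOF",
]

#: 95% quantile of chi-square with 1 dof, the pointwise profile threshold.
CHI2_95_1DOF = 3.84


@dataclass
class ProfileResult:
    """Profile of one parameter: grid, re-optimized objective, CI, class."""

    param: str
    grid: np.ndarray  # natural scale, ascending
    chi2_profile: np.ndarray
    best_value: float
    best_chi2: float
    threshold: float
    ci: tuple[float, float]
    crossed_low: bool
    crossed_high: bool
    classification: str

    def contains(self, value: float) -> bool:
        return self.ci[0] <= value <= self.ci[1]


def _reoptimize(
    problem: FitProblem,
    fixed_name: str,
    fixed_value: float,
    other_names: tuple[str, ...],
    x0_log: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> tuple[float, np.ndarray]:
    def resid(x: np.ndarray) -> np.ndarray:
        values = {n: float(10.0**xi) for n, xi in zip(other_names, x)}
        values[fixed_name] = fixed_value
        return weighted_residuals(problem, values)

    if not other_names:
        r = resid(np.empty(0))
        return float(r @ r), np.empty(0)
    sol = least_squares(resid, np.clip(x0_log, lo, hi), bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12)
    return float(2.0 * sol.cost), sol.x


def profile_likelihood(
    fit: FitResult,
    problem: FitProblem,
    param: str,
    n_grid: int = 21,
    span_decades: float = 2.0,
    delta: float = CHI2_95_1DOF,
    flat_tol_rel: float = 1e-6,
) -> ProfileResult:
    """Profile one free parameter of a converged fit.

    ``span_decades`` is the half-width of the grid in decades around the
    estimate (clipped to the parameter's bounds).  A failed re-optimization at
    a grid point is recorded as NaN and skipped by the classification, never
    fatal.
    """
    if param not in problem.free_names:
        raise ValueError(f"{param!r} is not a free parameter of this problem")
    estimate = fit.values[param]
    b_lo, b_hi = problem.bounds[param]
    g_lo = max(np.log10(estimate) - span_decades, np.log10(b_lo))
    g_hi = min(np.log10(estimate) + span_decades, np.log10(b_hi))
    grid = np.logspace(g_lo, g_hi, n_grid)

    other_names = tuple(n for n in problem.free_names if n != param)
    lo = np.array([np.log10(problem.bounds[n][0]) for n in other_names])
    hi = np.array([np.log10(problem.bounds[n][1]) for n in other_names])
    x_fit = np.array([np.log10(fit.values[n]) for n in other_names])

    chi2 = np.full(n_grid, np.nan)
    anchor = int(np.argmin(np.abs(np.log10(grid) - np.log10(estimate))))
    # Sweep outward in both directions, warm-starting from the neighbour.
    for direction in (range(anchor, n_grid), range(anchor - 1, -1, -1)):
        x_warm = x_fit.copy()
        for i in direction:
            try:
                chi2[i], x_warm = _reoptimize(
                    problem, param, float(grid[i]), other_names, x_warm, lo, hi
                )
            except Exception:
                chi2[i] = np.nan

    ok = np.isfinite(chi2)
    if not ok.any():
        raise RuntimeError(f"profile of {param!r}: all grid points failed")
    best_chi2 = float(min(fit.chi2, np.nanmin(chi2)))
    threshold = best_chi2 + delta

    # Confidence interval: contiguous sub-threshold region around the anchor,
    # with log-linear interpolation of the crossing points.
    lo_edge, hi_edge = grid[0], grid[-1]
    crossed_low = crossed_high = False
    i = anchor
    while i > 0:
        j = i - 1
        if not np.isfinite(chi2[j]):
            i = j
            continue
        if chi2[j] > threshold:
            crossed_low = True
            lo_edge = _interp_crossing(grid[j], grid[i], chi2[j], chi2[i], threshold)
            break
        i = j
    else:
        lo_edge = grid[0]
    i = anchor
    while i < n_grid - 1:
        j = i + 1
        if not np.isfinite(chi2[j]):
            i = j
            continue
        if chi2[j] > threshold:
            crossed_high = True
            hi_edge = _interp_crossing(grid[i], grid[j], chi2[i], chi2[j], threshold)
            break
        i = j
    else:
        hi_edge = grid[-1]

    profile = ProfileResult(
        param=param,
        grid=grid,
        chi2_profile=chi2,
        best_value=estimate,
        best_chi2=best_chi2,
        threshold=threshold,
        ci=(float(min(lo_edge, estimate)), float(max(hi_edge, estimate))),
        crossed_low=crossed_low,
        crossed_high=crossed_high,
        classification="",
    )
    profile.classification = classify_identifiability(profile, flat_tol_rel=flat_tol_rel)
    return profile


def _interp_crossing(x_out: float, x_in: float, f_out: float, f_in: float, thr: float) -> float:
    """Log-linear interpolation of the threshold crossing between grid points."""
    if not np.isfinite(f_in) or f_out == f_in:
        return x_out
    t = (thr - f_in) / (f_out - f_in)
    t = min(max(t, 0.0), 1.0)
    return float(10.0 ** (np.log10(x_in) + t * (np.log10(x_out) - np.log10(x_in))))


def classify_identifiability(profile: ProfileResult, flat_tol_rel: float = 1e-6) -> str:
    """Classify a computed profile (see module docstring for the taxonomy)."""
    chi2 = profile.chi2_profile[np.isfinite(profile.chi2_profile)]
    flat_tol = flat_tol_rel * max(1.0, abs(profile.best_chi2))
    if chi2.max() - chi2.min() < flat_tol:
        return "structurally_unidentifiable"
    if profile.crossed_low and profile.crossed_high:
        return "identifiable"
    return "practically_unidentifiable"
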