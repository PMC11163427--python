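"""Fitting the repulsive Buckingham (Born-Mayer) term E(r) = A exp(-B r).

The fit is an unweighted nonlinear least squares on the linear energy scale,
solved with the Levenberg-Marquardt algorithm; a log-linear regression
provides the initial guess when all energies are positive.  Diagnostics
cover the two ways real deformation data misbehaves: negative energies at
short range and non-exponential shape, plus stability of the solution under
an exhaustive grid of initial guesses and under narrowing of the fit range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

Pathology = Literal["none", "negative_energy", "non_exponential", "failed"]

__all__ = [
    "BuckinghamFit",
    "fit_repulsive",
    "two_point_parameters",
    "detect_pathology",
    "initial_guess_grid_stability",
    "GridStabilityReport",
    "fit_range_sensitivity",
]

DEFAULT_INITIAL_GUESS = (1.0e4, 3.0)  # A kJ/mol, B 1/A
NON_EXPONENTIAL_R2_THRESHOLD = 0.99


@dataclass(frozen=True)
class BuckinghamFit:
    """Result of fitting A exp(-B r) to one energy-distance curve."""

    A: float  # kJ/mol
    B: float  # 1/A
    rmse: float  # kJ/mol, sqrt(mean squared residual), no dof correction
    n_points: int
    fit_range: tuple[float, float]  # Angstrom
    energy_kind: str = "deformation"
    converged: bool = True
    pathology: Pathology = "none"

    def __post_init__(self) -> None:
        if self.converged and self.pathology == "none":
            if not (self.A > 0 and self.B > 0 and self.rmse >= 0):
                raise ValueError(
                    f"converged fit must have A > 0, B > 0, rmse >= 0 "
                    f"(got A={self.A}, B={self.B}, rmse={self.rmse})"
                )

    def predict(self, r: np.ndarray) -> np.ndarray:
        return self.A * np.exp(-self.B * np.asarray(r, dtype=float))


def _model(r: np.ndarray, A: float, B: float) -> np.ndarray:
    # wild LM trial steps (B < 0, huge A) may overflow to inf; MINPACK backs
    # off from such steps on its own, so just keep the evaluation quiet
    with np.errstate(over="ignore"):
        return A * np.exp(np.clip(-B * r, -700.0, 700.0))


def _jacobian(r: np.ndarray, A: float, B: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        e = np.exp(np.clip(-B * r, -700.0, 700.0))
        return np.column_stack((e, -A * r * e))


def two_point_parameters(r1: float, e1: float, r2: float, e2: float) -> tuple[float, float]:
    """Exact (A, B) interpolating two points of a pure exponential.

    B = ln(E1/E2) / (r2 - r1), A = E1 exp(B r1); requires positive energies.
    """
    if e1 <= 0 or e2 <= 0:
        raise ValueError("two-point solution requires positive energies")
    if r1 == r2:
        raise ValueError("two-point solution requires distinct separations")
    B = np.log(e1 / e2) / (r2 - r1)
    A = e1 * np.exp(B * r1)
    return float(A), float(B)


def _log_linear_guess(r: np.ndarray, e: np.ndarray) -> tuple[float, float] | None:
    if np.any(e <= 0):
        return None
    res = stats.linregress(r, np.log(e))
    B = -res.slope
    A = float(np.exp(res.intercept))
    if not (np.isfinite(A) and np.isfinite(B)) or A <= 0:
        return None
    return A, float(B)


def fit_repulsive(
    separations: Sequence[float],
    energies: Sequence[float],
    energy_kind: str = "deformation",
    initial_guess: tuple[float, float] | None = None,
    fit_range: tuple[float, float] | None = None,
) -> BuckinghamFit:
    """Levenberg-Marquardt fit of A exp(-B r) to an energy-distance curve.

    With ``initial_guess=None`` the starting point is the log-linear
    regression of ln E on r when all energies are positive, else the default
    (1e4 kJ/mol, 3 1/A).  ``fit_range`` restricts the fitted points to
    r_lo <= r <= r_hi.  Non-convergence or a non-positive fitted A is
    reported as pathology 'failed' rather than raised.
    """
    r = np.asarray(separations, dtype=float)
    e = np.asarray(energies, dtype=float)
    if fit_range is not None:
        mask = (r >= fit_range[0]) & (r <= fit_range[1])
        r, e = r[mask], e[mask]
    if r.size < 3:
        raise ValueError(f"need at least 3 points to fit, got {r.size}")
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(e))):
        raise ValueError("non-finite separations or energies")
    rng = (float(r.min()), float(r.max()))

    if initial_guess is None:
        p0 = _log_linear_guess(r, e) or DEFAULT_INITIAL_GUESS
    else:
        p0 = initial_guess
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _model, r, e, p0=p0, jac=_jacobian, method="lm", maxfev=5000
            )
        A, B = float(popt[0]), float(popt[1])
        converged = np.isfinite(A) and np.isfinite(B)
    except RuntimeError:
        A, B, converged = float("nan"), float("nan"), False

    if not converged or A <= 0:
        return BuckinghamFit(
            A=A, B=B, rmse=float("nan"), n_points=int(r.size), fit_range=rng,
            energy_kind=energy_kind, converged=converged, pathology="failed",
        )
    resid = e - _model(r, A, B)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return BuckinghamFit(
        A=A, B=B, rmse=rmse, n_points=int(r.size), fit_range=rng,
        energy_kind=energy_kind, converged=True, pathology="none",
    )


def detect_pathology(
    separations: Sequence[float],
    energies: Sequence[float],
    r2_threshold: float = NON_EXPONENTIAL_R2_THRESHOLD,
) -> Pathology:
    """Classify a curve before fitting.

    'negative_energy' if any point is <= 0 (repulsion cannot be attractive);
    else 'non_exponential' if ln E vs r is a poor line (R^2 below threshold)
    or has a non-negative slope; else 'none'.
    """
    r = np.asarray(separations, dtype=float)
    e = np.asarray(energies, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(e <= 0):
        return "negative_energy"
    res = stats.linregress(r, np.log(e))
    if res.slope >= 0 or res.rvalue**2 < r2_threshold:
        return "non_exponential"
    return "none"


@dataclass(frozen=True)
class GridStabilityReport:
    """Outcome of re-fitting from every point of an initial-guess grid."""

    clusters: tuple[tuple[float, float], ...]  # distinct converged (A, B)
    n_grid_points: int
    n_converged: int
    n_failed: int

    @property
    def stable(self) -> bool:
        return len(self.clusters) == 1


def initial_guess_grid_stability(
    separations: Sequence[float],
    energies: Sequence[float],
    A_range: tuple[float, float] = (1.0e3, 1.0e5),
    A_step: float = 1.0e3,
    B_range: tuple[float, float] = (1.0, 10.0),
    B_step: float = 0.1,
    rel_tol: float = 1e-6,
) -> GridStabilityReport:
    """Fit from every (A0, B0) on the grid and cluster the converged optima.

    The default grid is A from 1e3 to 1e5 kJ/mol in steps of 1000 and B from
    1 to 10 1/A in steps of 0.1 (~9,100 starts).  Two optima belong to the
    same cluster when both parameters agree to ``rel_tol`` relative.
    """
    nA = int(round((A_range[1] - A_range[0]) / A_step)) + 1
    nB = int(round((B_range[1] - B_range[0]) / B_step)) + 1
    A0s = A_range[0] + A_step * np.arange(nA)
    B0s = B_range[0] + B_step * np.arange(nB)
    clusters: list[tuple[float, float]] = []
    n_conv = n_fail = 0
    for A0 in A0s:
        for B0 in B0s:
            fit = fit_repulsive(separations, energies, initial_guess=(float(A0), float(B0)))
            if fit.pathology == "failed":
                n_fail += 1
                continue
            n_conv += 1
            for cA, cB in clusters:
                if abs(fit.A - cA) <= rel_tol * abs(cA) and abs(fit.B - cB) <= rel_tol * abs(cB):
                    break
            else:
                clusters.append((fit.A, fit.B))
    return GridStabilityReport(
        clusters=tuple(clusters),
        n_grid_points=int(nA * nB),
        n_converged=n_conv,
        n_failed=n_fail,
    )


def fit_range_sensitivity(
    separations: Sequence[float],
    energies: Sequence[float],
    candidate_ranges: Iterable[tuple[float, float]],
    energy_kind: str = "deformation",
) -> pd.DataFrame:
    """Fit over each candidate (r_lo, r_hi) range; table sorted by range width.

    Ranges containing fewer than 3 points are skipped with a warning.
    """
    r = np.asarray(separations, dtype=float)
    rows = []
    for lo, hi in candidate_ranges:
        n_in = int(np.count_nonzero((r >= lo) & (r <= hi)))
        if n_in < 3:
            log.warning("fit range (%.3g, %.3g) contains %d < 3 points; skipped", lo, hi, n_in)
            continue
        fit = fit_repulsive(separations, energies, energy_kind=energy_kind, fit_range=(lo, hi))
        rows.append(
            {
                "r_lo": lo,
                "r_hi": hi,
                "width": hi - lo,
                "A": fit.A,
                "B": fit.B,
                "rmse": fit.rmse,
                "n_points": fit.n_points,
                "pathology": fit.pathology,
            }
        )
    return pd.DataFrame(rows).sort_values("width", ignore_index=True)
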