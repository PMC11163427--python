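"""Relationships among fitted Buckingham parameters.

Fitted (A, B) pairs from different molecules are strongly related: a plot of
ln A against B is close to a straight line (an exponential A-B relationship),
and for some data sets the relationship switches from exponential to linear
above a breakpoint in B.  This module fits both models, quantifies
substitution trends along ordered molecule sequences, and correlates
parameters with externally supplied molecular properties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RelationFit",
    "fit_ab_relation",
    "substitution_trend",
    "correlate_param_with_property",
]


@dataclass(frozen=True)
class RelationFit:
    """A-vs-B relationship model.

    exponential:  A = a * exp(b * B), fitted as OLS of ln A on B; r_squared
    is reported on that log scale.

    piecewise:  A = a * exp(b * B) for B <= breakpoint, continuing as the
    straight line A = A(B*) + d * (B - B*) above it; continuous at the
    breakpoint by construction; r_squared is 1 - SSE/SST on the linear A
    scale.
    """

    model: Literal["exponential", "piecewise"]
    a: float
    b: float
    d: float | None  # linear-segment slope (piecewise only)
    breakpoint: float | None  # B*, 1/A (piecewise only)
    r_squared: float
    sse: float  # total squared error on the linear A scale
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 or np.isnan(self.r_squared)):
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")

    def predict(self, B: np.ndarray) -> np.ndarray:
        B = np.asarray(B, dtype=float)
        exp_part = self.a * np.exp(self.b * B)
        if self.model == "exponential":
            return exp_part
        v_star = self.a * np.exp(self.b * self.breakpoint)
        return np.where(
            B <= self.breakpoint, exp_part, v_star + self.d * (B - self.breakpoint)
        )


def _sse_linear(A: np.ndarray, pred: np.ndarray) -> float:
    return float(np.sum((A - pred) ** 2))


def _fit_exponential(B: np.ndarray, A: np.ndarray) -> RelationFit:
    res = stats.linregress(B, np.log(A))
    a, b = float(np.exp(res.intercept)), float(res.slope)
    pred = a * np.exp(b * B)
    return RelationFit(
        model="exponential",
        a=a,
        b=b,
        d=None,
        breakpoint=None,
        r_squared=float(res.rvalue**2),
        sse=_sse_linear(A, pred),
        n_points=int(B.size),
    )


def fit_ab_relation(
    A_values: Sequence[float],
    B_values: Sequence[float],
    model: Literal["exponential", "piecewise"] = "exponential",
) -> RelationFit:
    """Fit the A-vs-B relationship across molecules.

    ``model='exponential'`` requires >= 3 points and all A > 0;
    ``model='piecewise'`` requires >= 5 points and chooses the breakpoint by
    exhaustive search over the observed B values, minimizing the total
    squared error in A under the continuity constraint.  The candidate set
    includes the largest observed B, for which the piecewise model collapses
    to the single exponential, so the piecewise SSE never exceeds the
    exponential SSE.
    """
    A = np.asarray(A_values, dtype=float)
    B = np.asarray(B_values, dtype=float)
    if A.size != B.size:
        raise ValueError("A and B must have equal length")
    if np.any(A <= 0):
        raise ValueError("all A values must be positive")
    order = np.argsort(B)
    A, B = A[order], B[order]
    if model == "exponential":
        if A.size < 3:
            raise ValueError("exponential relation needs >= 3 points")
        return _fit_exponential(B, A)
    if model != "piecewise":
        raise ValueError(f"unknown model {model!r}")
    if A.size < 5:
        raise ValueError("piecewise relation needs >= 5 points")

    best: RelationFit | None = None
    # breakpoint candidates: observed B values with >= 3 points on the left
    for bp in np.unique(B)[2:]:
        left = B <= bp
        res = stats.linregress(B[left], np.log(A[left]))
        a, b = float(np.exp(res.intercept)), float(res.slope)
        v_star = a * np.exp(b * bp)
        right = ~left
        if np.any(right):
            dx = B[right] - bp
            dy = A[right] - v_star
            denom = float(np.sum(dx**2))
            d = float(np.sum(dx * dy) / denom) if denom > 0 else 0.0
        else:
            d = float(b * v_star)  # continue with the exponential's slope
        candidate = RelationFit(
            model="piecewise",
            a=a,
            b=b,
            d=d,
            breakpoint=float(bp),
            r_squared=0.0,  # placeholder, recomputed below
            sse=0.0,
            n_points=int(A.size),
        )
        pred = candidate.predict(B)
        sse = _sse_linear(A, pred)
        sst = float(np.sum((A - A.mean()) ** 2))
        r2 = max(0.0, 1.0 - sse / sst) if sst > 0 else float("nan")
        candidate = RelationFit(
            model="piecewise", a=a, b=b, d=d, breakpoint=float(bp),
            r_squared=r2, sse=sse, n_points=int(A.size),
        )
        if best is None or candidate.sse < best.sse:
            best = candidate
    assert best is not None
    return best


Verdict = Literal["increasing", "decreasing", "non-monotone"]


def _monotonicity(values: Sequence[float]) -> tuple[Verdict, str]:
    v = np.asarray(values, dtype=float)
    d = np.diff(v)
    if np.all(d > 0):
        return "increasing", ""
    if np.all(d < 0):
        return "decreasing", ""
    note = "constant" if np.all(d == 0) else ""
    return "non-monotone", note


def substitution_trend(
    molecule_sequence: Sequence[str],
    fits: Mapping[str, Mapping[str, "object"]],
) -> pd.DataFrame:
    """Tabulate (A, B) along an ordered substitution sequence with verdicts.

    ``fits[molecule][energy_kind]`` must be a BuckinghamFit for energy kinds
    'deformation' and 'steric'.  Returns the per-molecule table; per-column
    monotonicity verdicts live in ``DataFrame.attrs['verdicts']`` (with a
    'constant' note where every step is exactly zero).
    """
    rows = []
    for mol in molecule_sequence:
        if mol not in fits:
            raise KeyError(f"no fits for molecule {mol!r}")
        per_kind = fits[mol]
        for kind in ("deformation", "steric"):
            if kind not in per_kind:
                raise KeyError(f"molecule {mol!r} is missing the {kind} fit")
        rows.append(
            {
                "molecule": mol,
                "deformation_A": per_kind["deformation"].A,
                "deformation_B": per_kind["deformation"].B,
                "steric_A": per_kind["steric"].A,
                "steric_B": per_kind["steric"].B,
            }
        )
    df = pd.DataFrame(rows)
    verdicts = {}
    for col in ("deformation_A", "deformation_B", "steric_A", "steric_B"):
        verdict, note = _monotonicity(df[col])
        verdicts[col] = {"verdict": verdict, "note": note}
    df.attrs["verdicts"] = verdicts
    return df


def correlate_param_with_property(
    parameters: Mapping[str, float],
    properties: Mapping[str, float],
) -> dict:
    """OLS of a fitted parameter against an external molecular property.

    Molecules missing from either mapping are skipped; the number used is
    reported.  Needs >= 3 paired values.
    """
    shared = sorted(set(parameters) & set(properties))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 molecules with both parameter and property, got {len(shared)}"
        )
    x = np.array([properties[m] for m in shared], dtype=float)
    y = np.array([parameters[m] for m in shared], dtype=float)
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "n_used": len(shared),
        "n_skipped": len(set(parameters) | set(properties)) - len(shared),
    }
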