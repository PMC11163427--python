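"""Cross-molecule transferability of fitted Buckingham parameters.

One molecule's fitted (A, B) is evaluated against another molecule's exact
energy-distance data of the same atom type:

    RMSE(X -> Y) = sqrt( (1/N_Y) sum_i (E^Y(r_i) - A_X exp(-B_X r_i))^2 )

The n x n grid of these values (rows = parameter source X, columns = data
target Y) is generally not symmetric; its diagonal reduces to each
molecule's own fit RMSE.  A transferred potential is conventionally called
transferable when the RMSE is below chemical accuracy, ~4 kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .decomposition import PairEnergyCurve
from .fitting import BuckinghamFit

__all__ = [
    "transfer_rmse",
    "TransferMatrix",
    "build_matrix",
    "summarize_matrix",
    "MatrixSummary",
    "export_heatmap",
    "read_matrix_csv",
]

CHEMICAL_ACCURACY_KJ_PER_MOL = 4.0


def transfer_rmse(fit: BuckinghamFit, separations, energies) -> float:
    """RMSE of molecule X's fitted potential against molecule Y's energy data."""
    r = np.asarray(separations, dtype=float)
    e = np.asarray(energies, dtype=float)
    if r.size == 0:
        raise ValueError("target curve is empty")
    resid = e - fit.predict(r)
    return float(np.sqrt(np.mean(resid**2)))


@dataclass(frozen=True)
class TransferMatrix:
    """Transferability RMSE grid for one atom type and one energy kind."""

    molecules: tuple[str, ...]
    values: np.ndarray  # (n, n) kJ/mol; rows = parameter source, cols = data target
    energy_kind: str
    atom_type: str
    excluded: tuple[str, ...] = ()  # molecules dropped for pathology

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        n = len(self.molecules)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("RMSE entries must be >= 0")

    @property
    def n(self) -> int:
        return len(self.molecules)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.molecules, columns=self.molecules)


def build_matrix(
    fits: Mapping[str, BuckinghamFit],
    curves: Mapping[str, PairEnergyCurve],
    energy_kind: Literal["deformation", "steric"],
    atom_type: str,
    molecule_order: Sequence[str] | None = None,
) -> TransferMatrix:
    """Build the transferability matrix over all non-pathological molecules.

    ``fits`` and ``curves`` are keyed by molecule id.  Molecules whose fit
    carries a pathology (or is missing) are excluded from both rows and
    columns and recorded in ``excluded``.
    """
    order = list(molecule_order) if molecule_order is not None else sorted(curves)
    excluded = [
        m for m in order if m not in fits or fits[m].pathology != "none"
    ]
    kept = [m for m in order if m not in excluded]
    if not kept:
        raise ValueError(
            f"no non-pathological fits for atom type {atom_type!r} / {energy_kind}"
        )
    n = len(kept)
    values = np.empty((n, n))
    for i, x in enumerate(kept):
        for j, y in enumerate(kept):
            curve = curves[y]
            values[i, j] = transfer_rmse(fits[x], curve.separations, curve.energy(energy_kind))
    return TransferMatrix(
        molecules=tuple(kept),
        values=values,
        energy_kind=energy_kind,
        atom_type=atom_type,
        excluded=tuple(excluded),
    )


@dataclass(frozen=True)
class MatrixSummary:
    """Average / min / max RMSE and the percentage below a threshold."""

    average: float
    minimum: float
    maximum: float
    pct_below_threshold: float
    threshold: float
    include_diagonal: bool
    n_entries: int


def summarize_matrix(
    matrix: TransferMatrix,
    threshold: float = CHEMICAL_ACCURACY_KJ_PER_MOL,
    include_diagonal: bool = False,
) -> MatrixSummary:
    """Summary statistics over the transferability entries.

    By default the diagonal (each molecule's own fit RMSE) is excluded, since
    only off-diagonal cells are cross-molecule transfers; ``include_diagonal``
    switches to the all-entries convention.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = matrix.values
    if include_diagonal or matrix.n == 1:
        entries = v.ravel()
    else:
        entries = v[~np.eye(matrix.n, dtype=bool)]
    return MatrixSummary(
        average=float(np.mean(entries)),
        minimum=float(np.min(entries)),
        maximum=float(np.max(entries)),
        pct_below_threshold=float(100.0 * np.mean(entries < threshold)),
        threshold=threshold,
        include_diagonal=include_diagonal,
        n_entries=int(entries.size),
    )


def pooled_fraction_below(
    matrices: Sequence[TransferMatrix],
    threshold: float = CHEMICAL_ACCURACY_KJ_PER_MOL,
    include_diagonal: bool = False,
) -> float:
    """Percentage of entries below ``threshold`` pooled across matrices."""
    pools = []
    for m in matrices:
        v = m.values
        pools.append(v.ravel() if include_diagonal or m.n == 1 else v[~np.eye(m.n, dtype=bool)])
    allv = np.concatenate(pools)
    return float(100.0 * np.mean(allv < threshold))


def export_heatmap(
    matrix: TransferMatrix,
    csv_path: str | Path,
    image_path: str | Path | None = None,
) -> None:
    """Write the matrix as CSV (authoritative, full precision) and optionally
    render a heatmap image (rows = parameter source, columns = data target)."""
    df = matrix.to_frame()
    with open(csv_path, "w") as fh:
        fh.write(f"# atom_type: {matrix.atom_type}\n")
        fh.write(f"# energy_kind: {matrix.energy_kind}\n")
        if matrix.excluded:
            fh.write(f"# excluded: {','.join(matrix.excluded)}\n")
        # default str() formatting round-trips doubles exactly
        df.to_csv(fh)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        fig, ax = plt.subplots(figsize=(0.4 * matrix.n + 2, 0.4 * matrix.n + 1.5))
        sns.heatmap(df, ax=ax, cmap="viridis", square=True,
                    cbar_kws={"label": "RMSE / kJ mol$^{-1}$"})
        ax.set_xlabel("data target $Y$")
        ax.set_ylabel("parameter source $X$")
        ax.set_title(f"{matrix.atom_type} {matrix.energy_kind} transferability")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)


def read_matrix_csv(path: str | Path) -> TransferMatrix:
    """Re-import a matrix written by :func:`export_heatmap` at full precision."""
    atom_type = energy_kind = ""
    excluded: tuple[str, ...] = ()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            key, val = key.strip(), val.strip()
            if key == "atom_type":
                atom_type = val
            elif key == "energy_kind":
                energy_kind = val
            elif key == "excluded":
                excluded = tuple(val.split(","))
    df = pd.read_csv(path, comment="#", index_col=0, float_precision="round_trip")
    return TransferMatrix(
        molecules=tuple(str(c) for c in df.columns),
        values=df.to_numpy(dtype=float),
        energy_kind=energy_kind,
        atom_type=atom_type,
        excluded=excluded,
    )
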