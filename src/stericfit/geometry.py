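"""Construction of face-to-face homodimer distance scans.

A rigid copy of the monomer is translated along the normal of the carbonyl
sp2 plane, centred on the carbonyl carbon, over a grid of separations; both
carbonyl groups stay parallel.  Separations are computed by index
(r_min + k*step) so the grid carries no accumulated floating-point drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .iqa_io import MonomerGeometry

__all__ = [
    "ScanSpec",
    "carbonyl_plane_normal",
    "build_dimer_scan",
    "rotate_methyl_to_max_separation",
    "formaldehyde",
]

MIN_INTERMONOMER_DISTANCE = 0.5  # Angstrom


class GeometryError(ValueError):
    pass


class OverlapError(GeometryError):
    pass


@dataclass(frozen=True)
class ScanSpec:
    """Separation grid and scan axis definition.

    ``axis=None`` means: use the carbonyl-plane normal computed from the
    geometry.  ``rotate_180`` optionally spins the second monomer half a turn
    about the scan axis (default off: the second monomer is a pure
    translated copy, keeping the carbonyls parallel).
    """

    r_min: float = 2.0
    r_max: float = 4.6
    step: float = 0.1
    axis: tuple[float, float, float] | None = None
    rotate_180: bool = False

    def __post_init__(self) -> None:
        if self.r_min <= 0 or self.step <= 0 or self.r_max < self.r_min:
            raise ValueError("need r_min > 0, step > 0, r_max >= r_min")

    @property
    def n_frames(self) -> int:
        return int(math.floor((self.r_max - self.r_min) / self.step + 1e-9)) + 1

    @property
    def separations(self) -> np.ndarray:
        return self.r_min + self.step * np.arange(self.n_frames)


def _plane_atom_indices(geometry: MonomerGeometry) -> list[int]:
    if geometry.plane_atoms:
        idx = list(geometry.plane_atoms)
        if geometry.carbonyl_c is not None and geometry.carbonyl_c not in idx:
            idx = [geometry.carbonyl_c] + idx
        if geometry.carbonyl_o is not None and geometry.carbonyl_o not in idx:
            idx = idx + [geometry.carbonyl_o]
        return idx
    if geometry.carbonyl_c is None:
        raise GeometryError(
            f"{geometry.molecule_id}: carbonyl carbon not identified and no plane atoms given"
        )
    # fall back to the carbonyl C, O and the two atoms nearest to C
    c = geometry.carbonyl_c
    d = np.linalg.norm(geometry.coords - geometry.coords[c], axis=1)
    order = [i for i in np.argsort(d) if i != c]
    idx = [c] + order[:3]
    return idx


def carbonyl_plane_normal(geometry: MonomerGeometry) -> np.ndarray:
    """Unit normal of the least-squares plane through the carbonyl region.

    The plane is fitted by SVD through the carbonyl C, O and the two
    substituent atoms bonded to C (or through ``geometry.plane_atoms`` when
    supplied).  The sign of the returned vector is unspecified.
    """
    idx = _plane_atom_indices(geometry)
    if len(idx) < 3:
        raise GeometryError(f"{geometry.molecule_id}: need >= 3 atoms to define a plane")
    pts = geometry.coords[idx]
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise GeometryError(
            f"{geometry.molecule_id}: plane-defining atoms {idx} are collinear"
        )
    normal = vt[2]
    return normal / np.linalg.norm(normal)


def build_dimer_scan(
    geometry: MonomerGeometry, spec: ScanSpec = ScanSpec()
) -> list[MonomerGeometry]:
    """Build the face-to-face dimer scan as a list of rigid dimer frames.

    Each frame contains the original monomer followed by a copy displaced by
    the nominal separation along the plane normal; the two carbonyl carbons
    are therefore exactly that distance apart and the internal geometry of
    both monomers is untouched.
    """
    if spec.axis is not None:
        axis = np.asarray(spec.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
    else:
        axis = carbonyl_plane_normal(geometry)
    frames: list[MonomerGeometry] = []
    second = geometry.coords.copy()
    if spec.rotate_180:
        if geometry.carbonyl_c is None:
            raise GeometryError("rotate_180 requires the carbonyl carbon index")
        center = geometry.coords[geometry.carbonyl_c]
        second = _rotate_about_axis(geometry.coords, center, axis, math.pi)
    for k in range(spec.n_frames):
        r = spec.r_min + spec.step * k
        shifted = second + r * axis
        dmin, pair = _min_intermonomer_distance(geometry.coords, shifted)
        if dmin < MIN_INTERMONOMER_DISTANCE:
            i, j = pair
            raise OverlapError(
                f"{geometry.molecule_id} at r={r:.3f} A: atoms "
                f"{geometry.elements[i]}{i + 1} and {geometry.elements[j]}{j + 1}' are "
                f"{dmin:.3f} A apart (< {MIN_INTERMONOMER_DISTANCE} A)"
            )
        frames.append(
            MonomerGeometry(
                molecule_id=f"{geometry.molecule_id}_dimer_r{r:.3f}",
                elements=list(geometry.elements) * 2,
                coords=np.vstack([geometry.coords, shifted]),
                carbonyl_c=geometry.carbonyl_c,
                carbonyl_o=geometry.carbonyl_o,
            )
        )
    return frames


def _min_intermonomer_distance(a: np.ndarray, b: np.ndarray) -> tuple[float, tuple[int, int]]:
    diff = a[:, None, :] - b[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return float(d[i, j]), (int(i), int(j))


def _rotate_about_axis(
    coords: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle: float
) -> np.ndarray:
    """Rodrigues rotation of ``coords`` about the line (origin, axis)."""
    axis = axis / np.linalg.norm(axis)
    p = coords - origin
    cos, sin = math.cos(angle), math.sin(angle)
    rotated = (
        p * cos
        + np.cross(axis, p) * sin
        + np.outer(p @ axis, axis) * (1 - cos)
    )
    return rotated + origin


def rotate_methyl_to_max_separation(
    dimer: MonomerGeometry,
    methyl_carbon: int,
    methyl_hydrogens: tuple[int, int, int],
    attached_atom: int,
    grid_degrees: float = 1.0,
) -> MonomerGeometry:
    """Rotate the second monomer's methyl group to maximize H...H' distances.

    Indices refer to atoms of the monomer (0-based); the corresponding atoms
    of the second monomer are at index + n_atoms/2.  The three hydrogens are
    rotated rigidly about the local C(attached)-C(methyl) axis through an
    exhaustive torsion grid (default 1 degree), maximizing the summed
    distances between corresponding hydrogen atoms of the two monomers.
    """
    n2 = dimer.n_atoms
    if n2 % 2:
        raise ValueError("dimer frame must contain an even number of atoms")
    n = n2 // 2
    hs = tuple(methyl_hydrogens)
    if len(hs) != 3:
        raise ValueError("a methyl group has exactly three hydrogens")
    for i in (methyl_carbon, attached_atom, *hs):
        if not (0 <= i < n):
            raise ValueError(f"monomer atom index {i} out of range (monomer has {n} atoms)")
    if dimer.elements[methyl_carbon] != "C":
        raise ValueError(f"atom {methyl_carbon} is {dimer.elements[methyl_carbon]}, not a carbon")
    if any(dimer.elements[h] != "H" for h in hs):
        raise ValueError("methyl_hydrogens must index hydrogen atoms")
    ch = np.linalg.norm(
        dimer.coords[list(hs)] - dimer.coords[methyl_carbon], axis=1
    )
    if np.any(ch > 1.3):
        raise ValueError("hydrogens are not bonded to the methyl carbon (C-H > 1.3 A)")

    coords = dimer.coords.copy()
    c2 = methyl_carbon + n
    att2 = attached_atom + n
    axis = coords[c2] - coords[att2]
    origin = coords[c2]
    h2 = [h + n for h in hs]

    def objective(pos_h2: np.ndarray) -> float:
        return float(np.sum(np.linalg.norm(pos_h2 - dimer.coords[list(hs)], axis=1)))

    best_angle, best_val = 0.0, objective(coords[h2])
    angles = np.deg2rad(np.arange(0.0, 360.0, grid_degrees))
    base = coords[h2]
    for ang in angles:
        rotated = _rotate_about_axis(base, origin, axis, float(ang))
        val = objective(rotated)
        if val > best_val:
            best_val, best_angle = val, float(ang)
    coords[h2] = _rotate_about_axis(base, origin, axis, best_angle)
    return MonomerGeometry(
        molecule_id=dimer.molecule_id,
        elements=list(dimer.elements),
        coords=coords,
        carbonyl_c=dimer.carbonyl_c,
        carbonyl_o=dimer.carbonyl_o,
    )


def formaldehyde() -> MonomerGeometry:
    """Idealized planar formaldehyde in the xy-plane (synthetic geometry).

    Bond lengths ~ equilibrium values: C=O 1.205 A, C-H 1.11 A, H-C-H 116.1
    degrees; the carbonyl C sits at the origin, so the scan axis is +/-z.
    """
    half = math.radians(116.13 / 2.0)
    coords = [
        [0.0, 0.0, 0.0],  # C
        [0.0, 1.205, 0.0],  # O
        [1.11 * math.sin(half), -1.11 * math.cos(half), 0.0],  # H
        [-1.11 * math.sin(half), -1.11 * math.cos(half), 0.0],  # H
    ]
    return MonomerGeometry(
        molecule_id="formaldehyde",
        elements=["C", "O", "H", "H"],
        coords=coords,
        carbonyl_c=0,
        carbonyl_o=1,
        plane_atoms=[0, 1, 2, 3],
    )
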