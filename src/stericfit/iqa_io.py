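"""Reading and writing of scan tables, ionization tables and XYZ geometries.

The scan table is the package's single ingestion format: one CSV row per
(molecule, atom, intermolecular separation), carrying the atom's intra-atomic
energy in the dimer and in the isolated monomer together with its electron
populations in both systems.  Upstream quantum-chemistry outputs (AIMAll .int
files and the like) are expected to be converted to this schema by the user;
parsing program-specific formats is deliberately out of scope.

Energies may be declared in hartree or kJ/mol in the file header and are
converted to kJ mol^-1 on read.  Files are written in a canonical sort order
with fixed formatting so that repeated runs diff cleanly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .units import ENERGY_UNITS, to_kj_per_mol

log = logging.getLogger(__name__)

SCAN_COLUMNS = (
    "molecule_id",
    "atom_label",
    "separation_angstrom",
    "e_intra_dimer",
    "e_intra_monomer",
    "n_dimer",
    "n_monomer",
)

_UNIT_RE = re.compile(r"#\s*energy_unit\s*[:=]\s*(\S+)")
_ATOM_LABEL_RE = re.compile(r"^([A-Z][a-z]?)(\d+)$")

def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the double exactly."""
    return repr(float(x))


class SchemaError(ValueError):
    """A required column or header declaration is missing or malformed."""


class DataError(ValueError):
    """Records violate a structural invariant (e.g. duplicate separations)."""


class CorrectionPreconditionError(ValueError):
    """|N - N0| >= 1, outside the validity domain of the charge-transfer correction."""


@dataclass(frozen=True)
class ScanRecord:
    """One topological atom at one intermolecular separation.

    Energies in kJ mol^-1, separation in Angstrom, electron populations
    dimensionless.
    """

    molecule_id: str
    atom_label: str
    separation: float
    e_intra_dimer: float
    e_intra_monomer: float
    n_dimer: float
    n_monomer: float

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise DataError(
                f"{self.molecule_id}/{self.atom_label}: separation must be positive, "
                f"got {self.separation}"
            )
        if self.n_dimer <= 0 or self.n_monomer <= 0:
            raise DataError(
                f"{self.molecule_id}/{self.atom_label}: electron populations must be "
                f"positive (got N={self.n_dimer}, N0={self.n_monomer})"
            )
        if abs(self.delta_n) >= 1:
            raise CorrectionPreconditionError(
                f"{self.molecule_id}/{self.atom_label} at r={self.separation} A: "
                f"|N - N0| = {abs(self.delta_n):.4f} >= 1; the grand-canonical "
                "charge-transfer correction assumes |dN| < 1"
            )

    @property
    def element(self) -> str:
        m = _ATOM_LABEL_RE.match(self.atom_label)
        if m is None:
            raise DataError(
                f"atom label {self.atom_label!r} is not element-symbol + index (e.g. C1)"
            )
        return m.group(1)

    @property
    def delta_n(self) -> float:
        """Electron-population shift dN = N(dimer) - N(monomer)."""
        return self.n_dimer - self.n_monomer


def _sort_key(rec: ScanRecord):
    return (rec.molecule_id, rec.atom_label, rec.separation)


def validate_groups(records: Sequence[ScanRecord]) -> None:
    """Check that separations are strictly increasing within each (molecule, atom)."""
    by_group: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        by_group.setdefault((rec.molecule_id, rec.atom_label), []).append(rec.separation)
    for (mol, atom), seps in by_group.items():
        ordered = sorted(seps)
        for a, b in zip(ordered, ordered[1:]):
            if not b > a:
                raise DataError(
                    f"{mol}/{atom}: duplicate or non-increasing separation {a} A"
                )


def read_scan_table(path: str | Path, unit: str | None = None) -> list[ScanRecord]:
    """Read a scan-table CSV into validated :class:`ScanRecord` objects.

    The energy unit is taken from a ``# energy_unit: ...`` header comment
    unless overridden by ``unit``.  Energies are converted to kJ mol^-1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header_unit = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _UNIT_RE.search(line)
            if m:
                header_unit = m.group(1)
    unit = unit or header_unit
    if unit is None:
        raise SchemaError(
            f"{path}: no energy unit declared (expected a '# energy_unit: ...' header "
            f"or an explicit unit argument; one of {ENERGY_UNITS})"
        )
    if unit not in ENERGY_UNITS:
        raise SchemaError(f"{path}: unknown energy unit {unit!r}; expected {ENERGY_UNITS}")

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty and df.columns.size <= 1:
        log.warning("scan table %s is empty", path)
        return []
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    records = [
        ScanRecord(
            molecule_id=str(row.molecule_id),
            atom_label=str(row.atom_label),
            separation=float(row.separation_angstrom),
            e_intra_dimer=to_kj_per_mol(float(row.e_intra_dimer), unit),
            e_intra_monomer=to_kj_per_mol(float(row.e_intra_monomer), unit),
            n_dimer=float(row.n_dimer),
            n_monomer=float(row.n_monomer),
        )
        for row in df.itertuples(index=False)
    ]
    if not records:
        log.warning("scan table %s contains a header but no rows", path)
    validate_groups(records)
    return sorted(records, key=_sort_key)


def write_scan_table(records: Iterable[ScanRecord], path: str | Path) -> None:
    """Write records as CSV in canonical (molecule, atom, separation) order.

    Energies are written in kJ mol^-1 with shortest round-trip decimal
    formatting, so a write/read cycle reproduces every field bit-for-bit.
    """
    records = sorted(records, key=_sort_key)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# energy_unit: kJ/mol\n")
        fh.write(",".join(SCAN_COLUMNS) + "\n")
        for r in records:
            fields = (
                r.molecule_id,
                r.atom_label,
                _fmt(r.separation),
                _fmt(r.e_intra_dimer),
                _fmt(r.e_intra_monomer),
                _fmt(r.n_dimer),
                _fmt(r.n_monomer),
            )
            fh.write(",".join(fields) + "\n")


# ---------------------------------------------------------------------------
# ionization table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonizationTable:
    """Ionization energies keyed by (element, upper electron count).

    The entry ``(el, k)`` is the energy, in kJ mol^-1, to remove one electron
    from the k-electron state of element ``el`` (equivalently the ionization
    energy "going from k-1 to k electrons" on the grand-canonical line).
    """

    entries: Mapping[tuple[str, int], float]

    def __post_init__(self) -> None:
        for (el, count), ip in self.entries.items():
            if ip <= 0:
                raise DataError(f"ionization energy for ({el}, {count}) must be > 0, got {ip}")

    def lookup(self, element: str, upper_count: int) -> float:
        try:
            return self.entries[(element, upper_count)]
        except KeyError:
            raise KeyError(
                f"no ionization energy for element {element!r} at electron count "
                f"{upper_count}; add an entry (element, electron_count_upper) to the table"
            ) from None


#: Literature first ionization energies and electron affinities (kJ mol^-1),
#: keyed by (element, upper electron count): (el, Z) is the neutral-atom IP,
#: (el, Z+1) the electron affinity (energy to detach the extra electron).
_DEFAULT_IP_ENTRIES: dict[tuple[str, int], float] = {
    ("H", 1): 1312.0,
    ("H", 2): 72.8,
    ("C", 6): 1086.5,
    ("C", 7): 121.8,
    ("N", 7): 1402.3,
    ("O", 8): 1313.9,
    ("O", 9): 141.0,
    ("F", 9): 1681.0,
    ("F", 10): 328.2,
}


def default_ionization_table() -> IonizationTable:
    """Ionization table from standard literature atomic IPs/EAs (kJ mol^-1)."""
    return IonizationTable(dict(_DEFAULT_IP_ENTRIES))


def read_ionization_table(path: str | Path) -> IonizationTable:
    """Read a CSV with columns element, electron_count_upper, ip_kj_per_mol."""
    df = pd.read_csv(path, comment="#")
    needed = ("element", "electron_count_upper", "ip_kj_per_mol")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    entries = {
        (str(row.element), int(row.electron_count_upper)): float(row.ip_kj_per_mol)
        for row in df.itertuples(index=False)
    }
    return IonizationTable(entries)


def write_ionization_table(table: IonizationTable, path: str | Path) -> None:
    rows = sorted(table.entries.items())
    with open(path, "w") as fh:
        fh.write("element,electron_count_upper,ip_kj_per_mol\n")
        for (el, count), ip in rows:
            fh.write(f"{el},{count},{_fmt(ip)}\n")


# ---------------------------------------------------------------------------
# XYZ geometries
# ---------------------------------------------------------------------------


class XYZParseError(ValueError):
    pass


@dataclass
class MonomerGeometry:
    """A rigid monomer: element symbols, Cartesian coordinates in Angstrom,
    and the indices of the carbonyl C and O (plus, optionally, the two
    substituent atoms completing the sp2 plane)."""

    molecule_id: str
    elements: list[str]
    coords: np.ndarray  # (n, 3) Angstrom
    carbonyl_c: int | None = None
    carbonyl_o: int | None = None
    plane_atoms: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")
        if self.carbonyl_c is not None and self.carbonyl_o is not None:
            d = float(np.linalg.norm(self.coords[self.carbonyl_c] - self.coords[self.carbonyl_o]))
            if not (1.0 <= d <= 1.6):
                raise DataError(
                    f"{self.molecule_id}: carbonyl C-O distance {d:.3f} A outside 1.0-1.6 A"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def read_xyz(path: str | Path, molecule_id: str | None = None) -> list[MonomerGeometry]:
    """Read a (possibly multi-frame) XYZ file.

    Returns one :class:`MonomerGeometry` per frame; carbonyl indices are left
    unset (they are not representable in plain XYZ).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise XYZParseError(f"{path}: file is empty")
    frames: list[MonomerGeometry] = []
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}")
        if i + 1 + natoms >= len(lines) + 1 and i + 2 + natoms > len(lines):
            raise XYZParseError(
                f"{path}:{i + 1}: frame declares {natoms} atoms but file ends early"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        elements: list[str] = []
        coords: list[list[float]] = []
        for j in range(natoms):
            ln = i + 2 + j
            if ln >= len(lines):
                raise XYZParseError(f"{path}:{ln + 1}: unexpected end of file mid-frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(f"{path}:{ln + 1}: expected 'El x y z', got {lines[ln]!r}")
            elements.append(parts[0])
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise XYZParseError(f"{path}:{ln + 1}: non-numeric coordinate in {lines[ln]!r}")
        mid = molecule_id or comment.strip() or path.stem
        frames.append(MonomerGeometry(molecule_id=mid, elements=elements, coords=coords))
        i += 2 + natoms
        frame_no += 1
    return frames


def write_xyz(frames: MonomerGeometry | Sequence[MonomerGeometry], path: str | Path,
              comments: Sequence[str] | None = None) -> None:
    """Write one or more frames as standard (multi-frame) XYZ."""
    if isinstance(frames, MonomerGeometry):
        frames = [frames]
    with open(Path(path), "w") as fh:
        for k, g in enumerate(frames):
            comment = comments[k] if comments is not None else g.molecule_id
            fh.write(f"{g.n_atoms}\n{comment}\n")
            for el, (x, y, z) in zip(g.elements, g.coords):
                fh.write(f"{el} {_fmt(x)} {_fmt(y)} {_fmt(z)}\n")
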