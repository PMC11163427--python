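"""Deformation, charge-transfer and steric energies of topological atoms.

The deformation energy of an atom is the change in its intra-atomic
(self) energy on going from the isolated monomer to the dimer; the pairwise
deformation energy between the two approaching atoms is the sum of their
individual deformation energies.  The grand-canonical charge-transfer
correction estimates the part of that change caused by a fractional
electron-population shift dQ = N - N0 as

    E_CT = IP_[N]+1 * dQ

where the ionization energy is evaluated at the integer electron count of
the reference (monomer) state plus one.  The steric energy is what remains:

    E_ST = E_def - E_CT

and, unlike the raw deformation energy, behaves as a purely repulsive
exponential in the systems for which the correction was designed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .iqa_io import IonizationTable, ScanRecord

log = logging.getLogger(__name__)

RoundingMode = Literal["floor", "ceiling"]

__all__ = [
    "PairEnergyCurve",
    "deformation_energy",
    "pair_deformation",
    "charge_transfer_energy",
    "steric_energy",
    "ionization_energy_from_states",
    "build_pair_curves",
]


class AlignmentError(ValueError):
    """Paired atoms do not share the same separation grid."""


@dataclass(frozen=True)
class PairEnergyCurve:
    """Energy decomposition of one atom pair over the separation grid.

    ``atom_pair`` holds the two atom labels; for a symmetric homodimer both
    members are the same label and per-atom values were doubled.  The
    identity E_ST = E_def - E_CT holds pointwise by construction.
    """

    molecule_id: str
    atom_pair: tuple[str, str]
    separations: np.ndarray  # Angstrom, strictly increasing
    e_def: np.ndarray  # kJ/mol, pair
    e_ct: np.ndarray  # kJ/mol, pair
    e_st: np.ndarray  # kJ/mol, pair
    rounding_mode: RoundingMode = "floor"

    def __post_init__(self) -> None:
        for name in ("separations", "e_def", "e_ct", "e_st"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.separations.size
        if not (self.e_def.size == self.e_ct.size == self.e_st.size == n):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.separations) <= 0):
            raise ValueError("separations must be strictly increasing")
        if np.max(np.abs(self.e_st - (self.e_def - self.e_ct)), initial=0.0) >= 1e-9:
            raise ValueError("E_ST != E_def - E_CT beyond 1e-9 kJ/mol")

    @property
    def atom_type(self) -> str:
        return "".join(ch for ch in self.atom_pair[0] if ch.isalpha())

    def energy(self, kind: Literal["deformation", "steric"]) -> np.ndarray:
        if kind == "deformation":
            return self.e_def
        if kind == "steric":
            return self.e_st
        raise ValueError(f"unknown energy kind {kind!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "separation_angstrom": self.separations,
                "e_def": self.e_def,
                "e_ct": self.e_ct,
                "e_st": self.e_st,
            }
        )


def deformation_energy(record: ScanRecord) -> float:
    """Per-atom deformation energy: E_intra(dimer) - E_intra(monomer), kJ/mol."""
    return record.e_intra_dimer - record.e_intra_monomer


def pair_deformation(record_a: ScanRecord, record_b: ScanRecord) -> float:
    """Pairwise deformation energy: sum of the two per-atom values."""
    if record_a.separation != record_b.separation:
        raise AlignmentError(
            f"records at different separations: {record_a.separation} vs "
            f"{record_b.separation} A"
        )
    return deformation_energy(record_a) + deformation_energy(record_b)


def _integer_count(n_reference: float, rounding_mode: RoundingMode) -> int:
    if rounding_mode == "floor":
        return math.floor(n_reference)
    if rounding_mode == "ceiling":
        return math.ceil(n_reference)
    raise ValueError(f"unknown rounding mode {rounding_mode!r}")


def charge_transfer_energy(
    record: ScanRecord,
    ionization_table: IonizationTable,
    rounding_mode: RoundingMode = "floor",
) -> float:
    """Per-atom charge-transfer energy IP * dQ with dQ = N - N0 (kJ/mol).

    ``rounding_mode`` selects how the integer electron count indexing the
    ionization energy is taken from the monomer population: 'floor' (the
    primary convention) or 'ceiling' (sometimes a better fit in practice).
    """
    n_int = _integer_count(record.n_monomer, rounding_mode)
    ip = ionization_table.lookup(record.element, n_int + 1)
    return ip * record.delta_n


def steric_energy(e_def: float, e_ct: float) -> float:
    """Steric energy E_ST = E_def - E_CT (kJ/mol); works elementwise on arrays."""
    return e_def - e_ct


def ionization_energy_from_states(e_upper_count: float, e_lower_count: float) -> float:
    """Ionization energy from two atomic/ionic state energies (kJ/mol).

    ``e_upper_count`` is the total energy of the state with [N]+1 electrons,
    ``e_lower_count`` that with [N] electrons; the result is the energy to
    remove one electron from the richer state, E([N]) - E([N]+1).
    """
    ip = e_lower_count - e_upper_count
    if ip <= 0:
        log.warning(
            "non-positive ionization energy %.6g kJ/mol: the (N+1)-electron state "
            "lies above the N-electron state",
            ip,
        )
    return ip


def _group_records(
    records: Iterable[ScanRecord],
) -> dict[str, dict[str, list[ScanRecord]]]:
    grouped: dict[str, dict[str, list[ScanRecord]]] = {}
    for rec in records:
        grouped.setdefault(rec.molecule_id, {}).setdefault(rec.atom_label, []).append(rec)
    for atoms in grouped.values():
        for label, recs in atoms.items():
            recs.sort(key=lambda r: r.separation)
    return grouped


def select_pairs_by_element(
    atom_labels: Sequence[str],
) -> list[tuple[str, str]]:
    """Default pair selection: one pair per element.

    Two atoms of the same element pair up (lowest indices first); a lone atom
    pairs with its mirror image in the other monomer of the symmetric
    homodimer (pair = (label, label), per-atom values doubled).  When more
    than two chemically equivalent atoms exist, the lowest-indexed ones are
    selected, deterministically.
    """

    def index_of(label: str) -> int:
        digits = "".join(ch for ch in label if ch.isdigit())
        return int(digits) if digits else 0

    by_element: dict[str, list[str]] = {}
    for label in sorted(set(atom_labels), key=index_of):
        el = "".join(ch for ch in label if ch.isalpha())
        by_element.setdefault(el, []).append(label)
    pairs = []
    for el in sorted(by_element):
        labels = by_element[el]
        if len(labels) >= 2:
            pairs.append((labels[0], labels[1]))
        else:
            pairs.append((labels[0], labels[0]))
    return pairs


def build_pair_curve(
    records: Iterable[ScanRecord],
    ionization_table: IonizationTable,
    pair: tuple[str, str],
    rounding_mode: RoundingMode = "floor",
) -> PairEnergyCurve:
    """Decompose one atom pair's scan into (E_def, E_CT, E_ST) curves.

    If both members of ``pair`` are the same label, the symmetric-homodimer
    convention applies and per-atom values are doubled.  Input row order is
    irrelevant; the curve is built on the sorted separation grid.
    """
    grouped = _group_records(records)
    molecules = sorted(grouped)
    if len(molecules) != 1:
        raise ValueError(f"expected records of one molecule, got {molecules}")
    mol = molecules[0]
    atoms = grouped[mol]
    a, b = pair
    for label in {a, b}:
        if label not in atoms:
            raise KeyError(f"{mol}: no records for atom {label!r}")
    recs_a = atoms[a]
    seps_a = [r.separation for r in recs_a]
    if a == b:
        e_def = np.array([2.0 * deformation_energy(r) for r in recs_a])
        e_ct = np.array(
            [2.0 * charge_transfer_energy(r, ionization_table, rounding_mode) for r in recs_a]
        )
    else:
        recs_b = atoms[b]
        seps_b = [r.separation for r in recs_b]
        if seps_a != seps_b:
            missing = sorted(set(seps_a).symmetric_difference(seps_b))
            raise AlignmentError(
                f"{mol}: atoms {a} and {b} disagree on separations {missing}"
            )
        e_def = np.array([pair_deformation(ra, rb) for ra, rb in zip(recs_a, recs_b)])
        e_ct = np.array(
            [
                charge_transfer_energy(ra, ionization_table, rounding_mode)
                + charge_transfer_energy(rb, ionization_table, rounding_mode)
                for ra, rb in zip(recs_a, recs_b)
            ]
        )
    return PairEnergyCurve(
        molecule_id=mol,
        atom_pair=pair,
        separations=np.array(seps_a),
        e_def=e_def,
        e_ct=e_ct,
        e_st=steric_energy(e_def, e_ct),
        rounding_mode=rounding_mode,
    )


def build_pair_curves(
    records: Iterable[ScanRecord],
    ionization_table: IonizationTable,
    pairs: Sequence[tuple[str, str]] | None = None,
    rounding_mode: RoundingMode = "floor",
) -> list[PairEnergyCurve]:
    """Build pair curves for every molecule in ``records``.

    With ``pairs=None`` one pair per element is selected per molecule (see
    :func:`select_pairs_by_element`).  Every atom of a pair must be present
    at every separation of its partner.
    """
    grouped = _group_records(records)
    curves: list[PairEnergyCurve] = []
    for mol in sorted(grouped):
        atoms = grouped[mol]
        mol_records = [r for recs in atoms.values() for r in recs]
        mol_pairs = pairs if pairs is not None else select_pairs_by_element(list(atoms))
        for pair in mol_pairs:
            curves.append(
                build_pair_curve(mol_records, ionization_table, pair, rounding_mode)
            )
    return curves
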