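"""Reading and writing PQR-family files and chain-based entity partitioning.

PQR is a PDB-like text format whose ATOM/HETATM records carry, after the
coordinates, the atomic partial charge (in units of the elementary charge e)
and a radius (Å).  The dialect accepted here is whitespace-tokenized, as
written by pdb2pqr, rather than fixed-column: pdb2pqr routinely emits wide
coordinate fields that overflow the strict PDB columns.

A complex is partitioned into two interacting entities by two disjoint
chain-selection strings; chains named in neither string are excluded with a
warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    ChainSelectionError,
    EmptyInputError,
    PQRParseError,
)

logger = logging.getLogger(__name__)

#: Sentinel chain identifier substituted for a blank chain field.
BLANK_CHAIN = "_"

_INT_RE = re.compile(r"-?\d+")


@dataclass(frozen=True)
class AtomRecord:
    """One charged sphere: a PQR ATOM/HETATM record.

    charge is in units of e, vdw_radius and position in Å.
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: tuple[float, float, float]
    charge: float
    vdw_radius: float
    record_type: str = "ATOM"

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position")
        if not self.chain_id:
            object.__setattr__(self, "chain_id", BLANK_CHAIN)


class MolecularEntity:
    """An ordered collection of atoms forming one interacting entity.

    ``label`` is "complex", "mol1" or "mol2".  Atom order is preserved from
    the input file; coordinate/charge/radius arrays are cached views used by
    the numerical routines.
    """

    def __init__(self, atoms: Sequence[AtomRecord], label: str = "complex") -> None:
        self.atoms: list[AtomRecord] = list(atoms)
        self.label = label
        self._positions: np.ndarray | None = None
        self._charges: np.ndarray | None = None
        self._radii: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chain_set(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    @property
    def positions(self) -> np.ndarray:
        if self._positions is None:
            self._positions = np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)
        return self._positions

    @property
    def charges(self) -> np.ndarray:
        if self._charges is None:
            self._charges = np.array([a.charge for a in self.atoms], dtype=float)
        return self._charges

    @property
    def radii(self) -> np.ndarray:
        if self._radii is None:
            self._radii = np.array([a.vdw_radius for a in self.atoms], dtype=float)
        return self._radii

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum()) if self.atoms else 0.0

    def subset(self, indices: Iterable[int], label: str | None = None) -> "MolecularEntity":
        return MolecularEntity([self.atoms[i] for i in indices], label or self.label)

    def translated(self, shift: Sequence[float], label: str | None = None) -> "MolecularEntity":
        dx, dy, dz = (float(s) for s in shift)
        atoms = [
            AtomRecord(
                serial=a.serial,
                name=a.name,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                residue_number=a.residue_number,
                position=(a.position[0] + dx, a.position[1] + dy, a.position[2] + dz),
                charge=a.charge,
                vdw_radius=a.vdw_radius,
                record_type=a.record_type,
            )
            for a in self.atoms
        ]
        return MolecularEntity(atoms, label or self.label)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MolecularEntity(label={self.label!r}, n_atoms={self.n_atoms}, chains={sorted(self.chain_set)})"


def _parse_int(token: str, line_no: int, what: str) -> int:
    m = _INT_RE.match(token)
    if m is None:
        raise PQRParseError(f"line {line_no}: cannot parse {what} from {token!r}")
    return int(m.group())


def _parse_float(token: str, line_no: int, what: str) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise PQRParseError(f"line {line_no}: cannot parse {what} from {token!r}") from exc


def _parse_record(tokens: list[str], line_no: int) -> AtomRecord:
    # Layout: REC serial name resname [chain] resnum x y z charge radius.
    # The chain field may be absent; charge and radius are the last two tokens.
    if len(tokens) < 10:
        raise PQRParseError(
            f"line {line_no}: expected >= 10 whitespace-separated fields, got {len(tokens)}"
        )
    record_type = tokens[0]
    serial = _parse_int(tokens[1], line_no, "serial")
    name = tokens[2]
    residue_name = tokens[3]
    if len(tokens) >= 11:
        chain_id = tokens[4]
        resnum_tok = tokens[5]
    else:
        chain_id = BLANK_CHAIN
        resnum_tok = tokens[4]
    residue_number = _parse_int(resnum_tok, line_no, "residue number")
    x = _parse_float(tokens[-5], line_no, "x coordinate")
    y = _parse_float(tokens[-4], line_no, "y coordinate")
    z = _parse_float(tokens[-3], line_no, "z coordinate")
    charge = _parse_float(tokens[-2], line_no, "charge")
    radius = _parse_float(tokens[-1], line_no, "radius")
    if radius <= 0:
        raise PQRParseError(f"line {line_no}: non-positive radius {radius}")
    if chain_id == BLANK_CHAIN:
        logger.warning("line %d: blank chain identifier mapped to %r", line_no, BLANK_CHAIN)
    return AtomRecord(
        serial=serial,
        name=name,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_number=residue_number,
        position=(x, y, z),
        charge=charge,
        vdw_radius=radius,
        record_type=record_type,
    )


def read_pqr(path: str | Path) -> MolecularEntity:
    """Read a PQR (or PQG) file into a MolecularEntity labelled "complex".

    Every ATOM/HETATM record is parsed; other record types (REMARK, TER,
    END...) are ignored.  Raises :class:`PQRParseError` naming the offending
    line for malformed numerics and :class:`EmptyInputError` for a file with
    no atoms.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0] not in ("ATOM", "HETATM"):
                continue
            atoms.append(_parse_record(tokens, line_no))
    if not atoms:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    return MolecularEntity(atoms, label="complex")


def partition_entities(
    complex_entity: MolecularEntity, chains1: str, chains2: str
) -> tuple[MolecularEntity, MolecularEntity]:
    """Split a complex into mol1/mol2 by two disjoint chain-selection strings.

    Each string's characters name the chains of one interacting entity
    (e.g. ``"A"`` and ``"BC"``).  Atoms whose chain appears in neither string
    are excluded with a warning.
    """
    set1, set2 = set(chains1), set(chains2)
    if not set1 or not set2:
        raise ChainSelectionError("both chain selections must be non-empty")
    overlap = set1 & set2
    if overlap:
        raise ChainSelectionError(f"chain selections overlap: {sorted(overlap)}")
    present = complex_entity.chain_set
    missing = (set1 | set2) - present
    if missing:
        raise ChainSelectionError(
            f"chains {sorted(missing)} not present in file (chains found: {sorted(present)})"
        )
    idx1 = [i for i, a in enumerate(complex_entity.atoms) if a.chain_id in set1]
    idx2 = [i for i, a in enumerate(complex_entity.atoms) if a.chain_id in set2]
    n_excluded = complex_entity.n_atoms - len(idx1) - len(idx2)
    if n_excluded:
        excluded_chains = sorted(present - set1 - set2)
        logger.warning(
            "%d atoms in chains %s are in neither selection and are excluded",
            n_excluded,
            excluded_chains,
        )
    return complex_entity.subset(idx1, "mol1"), complex_entity.subset(idx2, "mol2")


def _format_record(a: AtomRecord, radius: float) -> str:
    chain = a.chain_id if a.chain_id else BLANK_CHAIN
    return (
        f"{a.record_type:<6s} {a.serial:5d} {a.name:<4s} {a.residue_name:<4s} "
        f"{chain:1s} {a.residue_number:4d}    "
        f"{a.position[0]:10.4f} {a.position[1]:10.4f} {a.position[2]:10.4f} "
        f"{a.charge:8.4f} {radius:7.4f}"
    )


def write_pqr(entity: MolecularEntity, path: str | Path) -> None:
    """Write a PQR file (whitespace-tokenized dialect, 4-decimal precision)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"REMARK gbcplx entity {entity.label} n_atoms {entity.n_atoms}\n")
        for a in entity.atoms:
            fh.write(_format_record(a, a.vdw_radius) + "\n")
        fh.write("END\n")


def write_pqg(entity: MolecularEntity, radii, path: str | Path) -> None:
    """Write a PQG file: a PQR whose radius column holds the GB radius.

    ``radii`` is a :class:`~gbcplx.gb_core.GBRadiusSet` (or any object with a
    ``radii`` array) aligned index-wise with ``entity.atoms``.
    """
    values = np.asarray(getattr(radii, "radii", radii), dtype=float)
    if values.shape != (entity.n_atoms,):
        raise AlignmentError(
            f"GB radii length {values.shape} does not match {entity.n_atoms} atoms"
        )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"REMARK gbcplx entity {entity.label} GB radii in radius column\n")
        for a, r in zip(entity.atoms, values):
            fh.write(_format_record(a, float(r)) + "\n")
        fh.write("END\n")


def merge_entities(
    entity1: MolecularEntity, entity2: MolecularEntity, label: str = "complex"
) -> MolecularEntity:
    """Concatenate two entities (mol1 atoms first) into one complex."""
    return MolecularEntity(list(entity1.atoms) + list(entity2.atoms), label=label)
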