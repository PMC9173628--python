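"""PDB-format structures: reading, writing, selection, and geometry checks.

Atoms are stored in a flat, ordered table. HETATM records (NAD, phosphate,
Mg²⁺, waters, ligands) are first-class atoms. Altloc conflicts are resolved
to the highest-occupancy conformer (ties broken by altloc letter order) so
every downstream model is single-conformer and deterministic.

Distances on crystal structures default to heavy atoms only (crystal
structures lack hydrogens); synthetic fixtures carry explicit hydrogens and
measure all atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "SelectionSpec",
    "StructureError",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "min_residue_distance",
    "assess_reactive_geometry",
    "extract_subset",
]

WATER_NAMES = {"HOH", "WAT"}

_ELEMENTS = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "MN", "FE", "CO", "NI", "CU",
    "ZN", "SE", "BR", "I", "MO", "W", "D",
}


class StructureError(ValueError):
    """Invalid structure content or failed lookup."""


class PDBParseError(StructureError):
    """Malformed PDB record; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Atom:
    """One atom record with coordinates in Å and an optional partial charge."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    partial_charge: float | None = None
    insertion_code: str = ""
    record: str = "ATOM"
    altloc: str = ""

    def __post_init__(self):
        if not all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.serial} {self.name}: non-finite position")
        if self.element.upper() not in _ELEMENTS:
            raise StructureError(f"atom {self.serial}: unrecognized element {self.element!r}")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES


@dataclass
class Structure:
    """Ordered atom collection with convenience coordinate access."""

    atoms: list[Atom]
    title: str = ""
    source: str = "fixture"

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("duplicate atom serial numbers")
        keys = [(a.chain_id, a.residue_number, a.insertion_code, a.name, a.altloc) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate (chain, residue, atom-name) identity")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 3) float array of positions in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError(f"coordinate shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, position=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, title=self.title, source=self.source)

    def residue_atoms(self, chain_id: str, residue_number: int, heavy_only: bool = False) -> list[Atom]:
        out = [
            a for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
            and not (heavy_only and a.is_hydrogen)
        ]
        return out

    def find_atom(self, chain_id: str, residue_number: int, name: str) -> Atom:
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_number == residue_number and a.name == name:
                return a
        raise StructureError(f"atom {chain_id}:{residue_number}:{name} not found")

    def atom_by_serial(self, serial: int) -> Atom:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise StructureError(f"atom serial {serial} not found")


@dataclass(frozen=True)
class SelectionSpec:
    """Conjunctive atom selection: all set criteria must hold."""

    chain: str | None = None
    residue_names: frozenset[str] | None = None
    residue_numbers: frozenset[int] | None = None
    atom_names: frozenset[str] | None = None
    sphere_center: tuple[float, float, float] | None = None
    sphere_radius: float | None = None

    def __post_init__(self):
        criteria = (self.chain, self.residue_names, self.residue_numbers,
                    self.atom_names, self.sphere_center)
        if all(c is None for c in criteria):
            raise StructureError("SelectionSpec requires at least one criterion")
        if (self.sphere_center is None) != (self.sphere_radius is None):
            raise StructureError("sphere selection needs both center and radius")
        if self.sphere_radius is not None and self.sphere_radius <= 0:
            raise StructureError("sphere radius must be positive")

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain_id != self.chain:
            return False
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        if self.residue_numbers is not None and atom.residue_number not in self.residue_numbers:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.sphere_center is not None:
            d = np.linalg.norm(np.asarray(atom.position) - np.asarray(self.sphere_center))
            if d > self.sphere_radius:
                return False
        return True


# ---------------------------------------------------------------------------
# PDB parsing / writing (fixed columns)
# ---------------------------------------------------------------------------

def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {text.strip()!r}", lineno) from None


def _guess_element(name: str, residue_name: str) -> str:
    stripped = name.strip()
    if residue_name in ("MG",) or stripped == "MG":
        return "MG"
    # leading digits (e.g. 1HB) denote hydrogens
    s = stripped.lstrip("0123456789")
    if not s:
        return "C"
    if len(s) >= 2 and s[:2].upper() in _ELEMENTS and s[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN"):
        return s[:2].upper()
    return s[0].upper()


def read_pdb(path, keep_altloc: bool = False) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    One atom per ATOM/HETATM record; altloc groups are reduced to the
    highest-occupancy conformer unless ``keep_altloc`` is set. Raises
    :class:`PDBParseError` with the line number for malformed records and
    :class:`StructureError` when the file contains no atom records.
    """
    raw: list[Atom] = []
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "TITLE":
                title = (title + " " + line[10:].strip()).strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError("record shorter than coordinate columns", lineno)
            serial = int(_parse_float(line[6:11], "serial", lineno))
            name = line[12:16].strip()
            altloc = line[16].strip()
            residue_name = line[17:20].strip()
            chain_id = line[21].strip() or "A"
            try:
                residue_number = int(line[22:26])
            except ValueError:
                raise PDBParseError(f"malformed residue number {line[22:26].strip()!r}", lineno) from None
            icode = line[26].strip()
            x = _parse_float(line[30:38], "x-coordinate", lineno)
            y = _parse_float(line[38:46], "y-coordinate", lineno)
            z = _parse_float(line[46:54], "z-coordinate", lineno)
            occ_field = line[54:60].strip()
            occupancy = _parse_float(line[54:60], "occupancy", lineno) if occ_field else 1.0
            elem_field = line[76:78].strip() if len(line) >= 78 else ""
            element = elem_field.upper() if elem_field else _guess_element(name, residue_name)
            # partial charge: non-standard numeric columns 79-86 if present
            charge_field = line[78:86].strip() if len(line) > 78 else ""
            partial_charge = None
            if charge_field:
                try:
                    partial_charge = float(charge_field)
                except ValueError:
                    partial_charge = None
            raw.append(Atom(serial=serial, name=name, element=element,
                            residue_name=residue_name, residue_number=residue_number,
                            chain_id=chain_id, position=(x, y, z), occupancy=occupancy,
                            partial_charge=partial_charge, insertion_code=icode,
                            record=rec, altloc=altloc))
    if not raw:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    if not keep_altloc:
        raw = _resolve_altlocs(raw)
    return Structure(raw, title=title, source=str(path))


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    groups: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    out = []
    for key in order:
        grp = groups[key]
        # highest occupancy wins; ties broken by altloc letter order
        best = sorted(grp, key=lambda a: (-a.occupancy, a.altloc or "~"))[0]
        out.append(replace(best, altloc=""))
    return out


def write_pdb(structure: Structure, path) -> str:
    """Write fixed-column ATOM/HETATM records with TER between chains and END."""
    if len(structure) == 0:
        raise StructureError("refusing to write an empty structure")
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    prev_chain = None
    last = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain and last is not None:
            lines.append(_ter_line(last))
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = a.position
        charge = f"{a.partial_charge:8.4f}" if a.partial_charge is not None else ""
        lines.append(
            f"{a.record:<6s}{a.serial:>5d} {name:<4s}{a.altloc or ' ':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_number:>4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}{charge}"
        )
        prev_chain = a.chain_id
        last = a
    lines.append(_ter_line(last))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)


def _ter_line(a: Atom) -> str:
    return (f"TER   {a.serial + 1:>5d}      {a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_number:>4d}")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def min_residue_distance(structure: Structure, residue_a: tuple[str, int],
                         residue_b: tuple[str, int], heavy_only: bool = True) -> float:
    """Minimum inter-atomic distance (Å) between two residues.

    ``residue_a``/``residue_b`` are ``(chain_id, residue_number)``. Symmetric
    in its arguments; 0 for a residue against itself. Heavy atoms only by
    default (crystal structures carry no hydrogens).
    """
    atoms_a = structure.residue_atoms(*residue_a, heavy_only=heavy_only)
    atoms_b = structure.residue_atoms(*residue_b, heavy_only=heavy_only)
    if not atoms_a:
        raise StructureError(f"residue {residue_a[0]}:{residue_a[1]} not found or has no atoms")
    if not atoms_b:
        raise StructureError(f"residue {residue_b[0]}:{residue_b[1]} not found or has no atoms")
    pa = np.array([a.position for a in atoms_a])
    pb = np.array([a.position for a in atoms_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


def assess_reactive_geometry(structure: Structure, donor_c: tuple[str, int, str],
                             acceptor_c: tuple[str, int, str],
                             max_distance: float = 4.5) -> tuple[bool, float]:
    """Catalytic-feasibility check on a donor/acceptor carbon pair.

    Returns ``(feasible, distance)`` where feasible is True iff the
    donor–acceptor distance is within ``max_distance`` (inclusive, default
    4.5 Å — the threshold used to filter reactive poses).
    """
    if max_distance <= 0:
        raise StructureError("max_distance must be positive")
    a = structure.find_atom(*donor_c)
    b = structure.find_atom(*acceptor_c)
    d = float(np.linalg.norm(np.asarray(a.position) - np.asarray(b.position)))
    return d <= max_distance, d


def extract_subset(structure: Structure, spec: SelectionSpec) -> Structure:
    """Atoms satisfying all criteria of ``spec``, original order preserved."""
    atoms = [a for a in structure.atoms if spec.matches(a)]
    return Structure(atoms, title=structure.title, source=structure.source)
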