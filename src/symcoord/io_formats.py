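"""Structure file I/O: PDB (v3.3 fixed columns), SDF (V2000), XYZ, and the
result/vector export formats.

Dialects are pinned:

* PDB — ATOM/HETATM records, 1-based columns x 31-38, y 39-46, z 47-54,
  element 77-78 with fallback to the atom-name field; altloc policy keeps
  the highest occupancy (ties: 'A', then blank); waters excluded by default.
* SDF — V2000 connection tables only; counts line at fixed columns, 10-char
  coordinate fields, records split on ``$$$$``; V3000 is rejected
  explicitly.
* XYZ — count line, comment line, ``element x y z`` rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParseError, ValidationError

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

# recognised element symbols (through the lanthanides; enough for organics
# and coordination compounds)
_ELEMENTS = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "SC", "TI", "V", "CR", "MN", "FE",
    "CO", "NI", "CU", "ZN", "GA", "GE", "AS", "SE", "BR", "KR", "RB", "SR",
    "Y", "ZR", "NB", "MO", "TC", "RU", "RH", "PD", "AG", "CD", "IN", "SN",
    "SB", "TE", "I", "XE", "CS", "BA", "LA", "CE", "PR", "ND", "SM", "EU",
    "GD", "TB", "DY", "HO", "ER", "TM", "YB", "LU", "HF", "TA", "W", "RE",
    "OS", "IR", "PT", "AU", "HG", "TL", "PB", "BI",
}


def _normalize_element(sym: str) -> str:
    s = sym.strip()
    if s.upper() not in _ELEMENTS:
        raise ParseError(f"unknown element symbol {sym!r}")
    return s.capitalize() if len(s) > 1 else s.upper()


@dataclass(frozen=True)
class Atom:
    label: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Molecule:
    """Labeled atoms with coordinates (A) and an optional bond graph."""

    atoms: list
    bonds: list | None = None  # (i, j, order) or (i, j)
    source: str = ""
    id: str = ""

    def __post_init__(self):
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            raise ValidationError("atom labels are not unique")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms]).reshape(-1, 3)

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        coords = np.asarray(coords, dtype=float)
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, coords)
        ]
        return Molecule(atoms, self.bonds, self.source, self.id)

    def heavy(self) -> "Molecule":
        """Copy without hydrogens (bond graph reindexed)."""
        keep = [i for i, a in enumerate(self.atoms) if a.element != "H"]
        return self.subset(keep)

    def subset(self, indices) -> "Molecule":
        index_map = {old: new for new, old in enumerate(indices)}
        atoms = [self.atoms[i] for i in indices]
        bonds = None
        if self.bonds is not None:
            bonds = [
                (index_map[b[0]], index_map[b[1]], *b[2:])
                for b in self.bonds
                if b[0] in index_map and b[1] in index_map
            ]
        return Molecule(atoms, bonds, self.source, self.id)

    def permuted(self, perm) -> "Molecule":
        """Molecule with atom i placed at position perm[i] of the new order."""
        perm = np.asarray(perm, dtype=int)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        bonds = None
        if self.bonds is not None:
            bonds = [(int(perm[b[0]]), int(perm[b[1]]), *b[2:]) for b in self.bonds]
        return Molecule([self.atoms[i] for i in inv], bonds, self.source, self.id)

    def bonds_by_distance(self, cutoff: float = 1.75) -> list:
        """Heavy-atom bond list from a simple distance heuristic."""
        X = self.coords
        bonds = []
        for i in range(len(X)):
            for j in range(i + 1, len(X)):
                if self.atoms[i].element == "H" or self.atoms[j].element == "H":
                    continue
                if np.linalg.norm(X[i] - X[j]) < cutoff:
                    bonds.append((i, j, 1))
        return bonds


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_pdb(text: str, exclude_waters: bool = True, mol_id: str = "") -> Molecule:
    """Parse ATOM/HETATM records from PDB text (v3.3 fixed columns)."""
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ParseError("ATOM/HETATM record shorter than 54 columns", lineno)
        try:
            name = line[12:16]
            altloc = line[16].strip()
            resname = line[17:20].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ = float(line[54:60]) if line[54:60].strip() else 1.0
        except ValueError as exc:
            raise ParseError(f"malformed coordinate field ({exc})", lineno) from None
        if exclude_waters and resname in _WATER_RESNAMES:
            continue
        elem_field = line[76:78].strip() if len(line) >= 78 else ""
        if elem_field:
            element = _normalize_element(elem_field)
        else:
            # fallback: strip digits from the atom-name field
            stripped = "".join(c for c in name if c.isalpha())
            if not stripped:
                raise ParseError("cannot infer element from atom name", lineno)
            two = stripped[:2].upper()
            element = _normalize_element(two if two in _ELEMENTS else stripped[0])
        records.append((name.strip(), altloc, element, x, y, z, occ))
    if not records:
        raise ParseError("no ATOM/HETATM coordinate records found")

    # altloc selection: group by atom name, keep highest occupancy
    # (ties: 'A', then blank)
    chosen: dict = {}
    order: list = []
    for name, altloc, element, x, y, z, occ in records:
        key = name if altloc else f"{name}|{len(order)}"
        # blank-altloc atoms never collide; labeled altlocs compete by name
        if altloc:
            key = name
        if key not in chosen:
            chosen[key] = (name, altloc, element, x, y, z, occ)
            order.append(key)
        else:
            prev = chosen[key]
            rank = (occ, 0 if altloc == "A" else (1 if altloc == "" else 2))
            prev_rank = (
                prev[6],
                0 if prev[1] == "A" else (1 if prev[1] == "" else 2),
            )
            if (rank[0], -rank[1]) > (prev_rank[0], -prev_rank[1]):
                chosen[key] = (name, altloc, element, x, y, z, occ)
    atoms = []
    seen: dict = {}
    for key in order:
        name, altloc, element, x, y, z, occ = chosen[key]
        label = name
        if label in seen:
            seen[label] += 1
            label = f"{label}_{seen[name]}"
        else:
            seen[label] = 0
        atoms.append(Atom(label, element, x, y, z, occ, altloc))
    return Molecule(atoms, None, source="pdb", id=mol_id)


def read_sdf(text: str, mol_id: str = "") -> list:
    """Parse a (possibly multi-record) SD/MOL file; V2000 only."""
    if not text.strip():
        raise ParseError("empty SDF input")
    molecules = []
    offset = 0
    for record in text.split("$$$$"):
        lines = record.splitlines()
        # skip leading blank lines between records
        while lines and not lines[0].strip() and len(lines) > 4:
            lines.pop(0)
            offset += 1
        if not any(ln.strip() for ln in lines):
            offset += len(lines)
            continue
        molecules.append(_parse_molblock(lines, offset, f"{mol_id}_{len(molecules)}" if mol_id else ""))
        offset += len(lines) + 1
    if not molecules:
        raise ParseError("no molecule records found")
    return molecules


def _parse_molblock(lines, offset: int, mol_id: str) -> Molecule:
    if len(lines) < 4:
        raise ParseError("molblock shorter than 4 lines", offset + 1)
    counts_lineno = offset + 4
    counts = lines[3]
    if "V3000" in counts:
        raise ParseError("V3000 connection tables are not supported", counts_lineno)
    try:
        natoms = int(counts[0:3])
        nbonds = int(counts[3:6])
    except ValueError:
        raise ParseError(f"malformed counts line {counts!r}", counts_lineno) from None
    if len(lines) < 4 + natoms + nbonds:
        raise ParseError(
            f"connection table truncated: counts line declares {natoms} atoms "
            f"and {nbonds} bonds",
            counts_lineno,
        )
    atoms = []
    for i in range(natoms):
        ln = lines[4 + i]
        lineno = offset + 5 + i
        if len(ln) < 34:
            raise ParseError("atom block line shorter than 34 columns", lineno)
        try:
            x = float(ln[0:10])
            y = float(ln[10:20])
            z = float(ln[20:30])
        except ValueError:
            raise ParseError(f"malformed atom coordinates {ln!r}", lineno) from None
        element = _normalize_element(ln[31:34])
        atoms.append(Atom(f"{element}{i + 1}", element, x, y, z))
    bonds = []
    for i in range(nbonds):
        ln = lines[4 + natoms + i]
        lineno = offset + 5 + natoms + i
        try:
            a = int(ln[0:3]) - 1
            b = int(ln[3:6]) - 1
            order = int(ln[6:9]) if ln[6:9].strip() else 1
        except ValueError:
            raise ParseError(f"malformed bond block line {ln!r}", lineno) from None
        if not (0 <= a < natoms and 0 <= b < natoms):
            raise ParseError(f"bond references atom out of range: {ln!r}", lineno)
        bonds.append((a, b, order))
    name = lines[0].strip()
    return Molecule(atoms, bonds, source="sdf", id=mol_id or name or "mol")


def read_xyz(text: str, mol_id: str = "") -> Molecule:
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise ParseError("empty XYZ input")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"malformed count line {lines[0]!r}", 1) from None
    if len(lines) < n + 2:
        raise ParseError(f"count line declares {n} atoms but file has fewer rows", 1)
    atoms = []
    for i in range(n):
        parts = lines[2 + i].split()
        lineno = 3 + i
        if len(parts) < 4:
            raise ParseError("expected 'element x y z'", lineno)
        element = _normalize_element(parts[0])
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError:
            raise ParseError(f"malformed coordinates {parts[1:4]}", lineno) from None
        atoms.append(Atom(f"{element}{i + 1}", element, x, y, z))
    return Molecule(atoms, None, source="xyz", id=mol_id or lines[1].strip())


def read_structure(path, include_h: bool = False) -> Molecule:
    """Read a structure file by extension (.pdb/.ent, .sdf/.sd/.mol, .xyz)."""
    path = Path(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        mol = read_pdb(text, mol_id=path.stem)
    elif suffix in (".sdf", ".sd", ".mol"):
        mols = read_sdf(text, mol_id=path.stem)
        mol = mols[0]
        mol.id = path.stem
    elif suffix == ".xyz":
        mol = read_xyz(text, mol_id=path.stem)
    else:
        raise ValidationError(
            f"unrecognized structure format {suffix!r} (expected .pdb/.sdf/.xyz)"
        )
    mol.source = str(path)
    if not include_h:
        mol = mol.heavy()
    return mol


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_xyz(mol: Molecule, comment: str = "") -> str:
    lines = [str(len(mol)), comment or mol.id]
    for a in mol.atoms:
        lines.append(f"{a.element:<3s} {a.x:14.6f} {a.y:14.6f} {a.z:14.6f}")
    return "\n".join(lines) + "\n"


def write_sdf(mol: Molecule) -> str:
    """Minimal V2000 molblock (coordinates to 4 decimals, as the format pins)."""
    bonds = mol.bonds or []
    lines = [mol.id or "mol", "  symcoord", ""]
    lines.append(f"{len(mol):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in mol.atoms:
        lines.append(f"{a.x:10.4f}{a.y:10.4f}{a.z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for b in bonds:
        order = b[2] if len(b) > 2 else 1
        lines.append(f"{b[0] + 1:3d}{b[1] + 1:3d}{order:3d}  0")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def write_result(result, path) -> None:
    """Serialize a DecompositionResult to versioned JSON."""
    Path(path).write_text(json.dumps(result.to_json(), indent=2))


def write_vectors_xyz(result, path) -> None:
    """Per-atom mode-displacement export: model atoms plus one displacement
    column triple per mode (plain text, one row per atom)."""
    lines = ["# element x y z" + "".join(f" | d({m.irrep}{'/' + m.orientation if m.orientation else ''})" for m in result.modes)]
    coords = result.aligned_coords
    for i, el in enumerate(result.elements):
        row = f"{el:<3s} {coords[i, 0]:12.6f} {coords[i, 1]:12.6f} {coords[i, 2]:12.6f}"
        for m in result.modes:
            row += "  " + " ".join(f"{v:10.6f}" for v in m.vectors[i])
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")
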