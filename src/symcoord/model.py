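"""Idealized symmetric reference models.

A :class:`SymmetricModel` holds axis-conventioned coordinates that are
exactly invariant under every operation of its point group, plus a cached
atom permutation per operation.  Models are built from a single exemplar
structure by orienting it towards the group's symmetry operations and
iteratively averaging each atom with its symmetry images, or loaded from a
versioned JSON document.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import apply_axis_convention, orient_to_operations
from .assignment import AssignmentError, symmetry_permutation
from .errors import SchemaError, ValidationError
from .groups import PointGroup, build_group
from .io_formats import Atom, Molecule
from .projection import symmetrize

MODEL_SCHEMA = "symcoord.model/1"


@dataclass
class SymmetricModel:
    """Idealized symmetric reference coordinates with cached permutations."""

    name: str
    group: str
    coords: np.ndarray
    elements: list
    bonds: list | None = None
    perms: dict = field(default_factory=dict)  # operation label -> permutation
    provenance: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def point_group(self) -> PointGroup:
        return build_group(self.group)

    def perm_list(self) -> list:
        """Permutations ordered like the group's operation list."""
        group = self.point_group
        return [np.asarray(self.perms[op.label]) for op in group.operations]

    def as_molecule(self) -> Molecule:
        atoms = [
            Atom(f"{el}{i + 1}", el, *map(float, xyz))
            for i, (el, xyz) in enumerate(zip(self.elements, self.coords))
        ]
        return Molecule(atoms, self.bonds, source="model", id=self.name)

    def max_symmetry_deviation(self) -> float:
        """Worst per-atom deviation of the coordinates from exact invariance
        under the group operations (after permutation)."""
        group = self.point_group
        worst = 0.0
        for op, perm in zip(group.operations, self.perm_list()):
            image = np.empty_like(self.coords)
            image[perm] = self.coords @ op.matrix.T
            worst = max(worst, float(np.abs(image - self.coords).max()))
        return worst


def compute_operation_perms(
    coords: np.ndarray, elements, group: PointGroup, strict: bool = True
) -> dict:
    """Hungarian assignment of each atom to its image under every group
    operation, keyed by operation label.

    With ``strict=True`` the permutations are verified to compose like the
    group (a true representation); failure indicates an ambiguous
    assignment, for which graph-based matching is advised.
    """
    perms = {}
    for op in group.operations:
        perms[op.label] = symmetry_permutation(coords, elements, op).permutation
    if strict:
        plist = [perms[op.label] for op in group.operations]
        for i in range(group.order):
            for j in range(group.order):
                k = group.composition[i, j]
                if not np.array_equal(plist[i][plist[j]], plist[k]):
                    raise AssignmentError(
                        "cached permutations do not compose like the group "
                        f"({group.operations[i].label} o "
                        f"{group.operations[j].label}); the assignment is "
                        "ambiguous — consider graph-based matching (by_graph)"
                    )
    return perms


def build_model(
    exemplar: Molecule,
    group: PointGroup | str,
    name: str = "",
    include_h: bool = False,
    max_rounds: int = 5,
) -> SymmetricModel:
    """Generate an idealized symmetric model from one exemplar structure.

    The exemplar is oriented towards the group's symmetry operations,
    its atoms are iteratively averaged with their symmetry images until the
    coordinates are exactly invariant, and the axis convention is applied.
    Assignment permutations are then recomputed from the symmetric
    coordinates and cached.
    """
    if isinstance(group, str):
        group = build_group(group)
    mol = exemplar if include_h else exemplar.heavy()
    coords = mol.coords
    elements = mol.elements
    if group.order == 1:
        ideal = coords - coords.mean(axis=0)
        perms = {group.operations[0].label: np.arange(len(ideal))}
        return SymmetricModel(
            name or mol.id or "model", group.name, ideal, elements,
            mol.bonds, perms, provenance=f"built from {mol.source or mol.id}",
        )
    transform = orient_to_operations(mol, group)
    X = transform.apply(coords)
    full = range(group.order)
    for _ in range(max_rounds):
        perms = compute_operation_perms(X, elements, group, strict=False)
        plist = [perms[op.label] for op in group.operations]
        X_new = symmetrize(X, group, full, plist)
        if np.abs(X_new - X).max() < 1e-9:
            X = X_new
            break
        X = X_new
    X = X - X.mean(axis=0)
    X = apply_axis_convention(X, group)
    perms = compute_operation_perms(X, elements, group, strict=True)
    model = SymmetricModel(
        name=name or mol.id or "model",
        group=group.name,
        coords=X,
        elements=elements,
        bonds=mol.bonds,
        perms=perms,
        provenance=f"built from {mol.source or mol.id or 'exemplar'}",
    )
    dev = model.max_symmetry_deviation()
    if dev > 1e-8:
        raise ValidationError(
            f"model symmetrization did not converge (residual {dev:.2e} A)"
        )
    return model


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------


def save_model(model: SymmetricModel) -> dict:
    """Serialize to the versioned model-JSON schema (coordinates as decimal
    strings with 6 places, giving bit-stable round trips)."""
    return {
        "schema": MODEL_SCHEMA,
        "name": model.name,
        "group": model.group,
        "elements": list(model.elements),
        "coords": [[f"{v:.6f}" for v in row] for row in model.coords],
        "bonds": [list(b) for b in model.bonds] if model.bonds is not None else None,
        "perms": {k: [int(i) for i in v] for k, v in model.perms.items()},
        "provenance": model.provenance,
    }


def load_model(doc: dict) -> SymmetricModel:
    """Load a model from its JSON document (inverse of :func:`save_model`).

    Missing permutations are recomputed with a warning; schema violations
    raise :class:`SchemaError` with the JSON path of the offense.
    """
    if not isinstance(doc, dict):
        raise SchemaError("model document must be a JSON object", "$")
    if doc.get("schema") != MODEL_SCHEMA:
        raise SchemaError(
            f"expected schema {MODEL_SCHEMA!r}, got {doc.get('schema')!r}",
            "$.schema",
        )
    from .groups import SUPPORTED_GROUPS

    group_name = doc.get("group")
    if group_name not in SUPPORTED_GROUPS:
        raise SchemaError(
            f"unknown group {group_name!r}; supported: {SUPPORTED_GROUPS}",
            "$.group",
        )
    for key in ("name", "elements", "coords"):
        if key not in doc:
            raise SchemaError("missing required field", f"$.{key}")
    coords = []
    for i, row in enumerate(doc["coords"]):
        if len(row) != 3:
            raise SchemaError("coordinate row must have 3 entries", f"$.coords[{i}]")
        try:
            coords.append([float(v) for v in row])
        except (TypeError, ValueError):
            raise SchemaError(
                f"non-numeric coordinate {row!r}", f"$.coords[{i}]"
            ) from None
    coords = np.asarray(coords)
    if len(coords) != len(doc["elements"]):
        raise SchemaError(
            "element list and coordinate table lengths differ", "$.elements"
        )
    group = build_group(group_name)
    perms_doc = doc.get("perms") or {}
    expected_labels = {op.label for op in group.operations}
    if set(perms_doc) == expected_labels:
        perms = {k: np.asarray(v, dtype=int) for k, v in perms_doc.items()}
    else:
        warnings.warn(
            "model document lacks complete cached permutations; recomputing",
            stacklevel=2,
        )
        perms = compute_operation_perms(coords, doc["elements"], group)
    bonds = doc.get("bonds")
    model = SymmetricModel(
        name=doc["name"],
        group=group_name,
        coords=coords,
        elements=list(doc["elements"]),
        bonds=[tuple(b) for b in bonds] if bonds is not None else None,
        perms=perms,
        provenance=doc.get("provenance", ""),
    )
    dev = model.max_symmetry_deviation()
    if dev > 1e-5:
        raise SchemaError(
            f"coordinates are not {group_name}-symmetric (deviation {dev:.2e} A)",
            "$.coords",
        )
    return model


def save_model_file(model: SymmetricModel, path) -> None:
    Path(path).write_text(json.dumps(save_model(model), indent=2))


def load_model_file(path) -> SymmetricModel:
    return load_model(json.loads(Path(path).read_text()))
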