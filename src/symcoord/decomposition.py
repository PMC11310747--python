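"""Symmetry-coordinate decomposition: split an aligned fragment into
per-irrep displacement vector sets and summed magnitudes.

For a 1-D irrep Gamma with kernel K the component is the difference of two
symmetrized copies of the aligned coordinates:

    M_Gamma = symmetrize(X, K) - symmetrize(X, G)

i.e. the deviation of the K-symmetric representation from the co-kernel
(totally symmetric) representation.  The totally symmetric component is
compared to the reference model instead (and is zero when no model is
used).  Degenerate (E-type) irreps are resolved into oriented variant
components; the variant sum times the group's reconstruction weight (1/2
for D4h/D2d, 1/3 for D3h/D6h) is the full degenerate component.  The sum
of all components reproduces the aligned input coordinates.

The reported magnitude of a mode is the plain sum of its per-atom vector
norms, in Angstroms — no RMS, no mass weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import RigidTransform, apply_axis_convention, kabsch
from .assignment import assign_by_graph, assign_minimal_cost
from .errors import AlignmentError, SymcoordError, ValidationError
from .groups import IrrepRow, PointGroup, build_group
from .io_formats import Molecule
from .model import SymmetricModel, build_model
from .projection import oriented_projection, symmetrize


@dataclass
class ModeVectors:
    """Displacement vector set of one irrep (or one oriented variant)."""

    irrep: str
    vectors: np.ndarray
    orientation: str = ""
    angle: float | None = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)

    @property
    def magnitude(self) -> float:
        """Sum of per-atom Euclidean norms (A)."""
        return float(np.linalg.norm(self.vectors, axis=1).sum())

    def flattened(self) -> np.ndarray:
        return self.vectors.ravel()


@dataclass
class DecompositionResult:
    """Full output of one decomposition run."""

    group: str
    elements: list
    aligned_coords: np.ndarray
    model_coords: np.ndarray
    totally_symmetric_mode: ModeVectors
    modes: list  # reported ModeVectors (1-D irreps + degenerate pairs)
    variants: dict = field(default_factory=dict)  # irrep -> all variant modes
    reconstruction_residual: float = 0.0
    model_used: bool = False
    transform: RigidTransform | None = None
    structure_id: str = ""

    @property
    def magnitudes(self) -> dict:
        """Per-irrep summed magnitude (A).  For degenerate irreps this is
        the sum over the reported orientation pair."""
        out = {self.totally_symmetric_mode.irrep: self.totally_symmetric_mode.magnitude}
        for mode in self.modes:
            out[mode.irrep] = out.get(mode.irrep, 0.0) + mode.magnitude
        return out

    def mode(self, irrep: str, orientation: str = "") -> ModeVectors:
        if irrep == self.totally_symmetric_mode.irrep:
            return self.totally_symmetric_mode
        for m in self.modes:
            if m.irrep == irrep and (not orientation or m.orientation == orientation):
                return m
        raise ValidationError(f"no reported mode for irrep {irrep!r}")

    def to_json(self) -> dict:
        return {
            "schema": "symcoord.result/1",
            "group": self.group,
            "structure_id": self.structure_id,
            "model_used": self.model_used,
            "elements": list(self.elements),
            "aligned_coords": self.aligned_coords.tolist(),
            "model_coords": self.model_coords.tolist(),
            "reconstruction_residual": float(self.reconstruction_residual),
            "transform": self.transform.to_json() if self.transform else None,
            "magnitudes": {k: float(v) for k, v in self.magnitudes.items()},
            "modes": [
                {
                    "irrep": m.irrep,
                    "orientation": m.orientation,
                    "magnitude": float(m.magnitude),
                    "vectors": m.vectors.tolist(),
                }
                for m in [self.totally_symmetric_mode, *self.modes]
            ],
        }


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------


def project_irrep(
    coords: np.ndarray,
    group: PointGroup,
    irrep: IrrepRow,
    perms,
    model_coords: np.ndarray | None = None,
):
    """Component of aligned, conventioned coordinates in one irrep.

    Returns a single :class:`ModeVectors` for 1-D irreps, or a list with
    one entry per orientation variant for degenerate irreps.
    """
    if not any(r is irrep or r.label == irrep.label for r in group.irreps):
        raise ValidationError(
            f"irrep {irrep.label!r} does not belong to {group.name}"
        )
    X = np.asarray(coords, dtype=float)
    if irrep.is_degenerate:
        return [
            ModeVectors(
                irrep.label,
                oriented_projection(group, irrep, angle, X, perms),
                orientation=f"{angle:g}deg",
                angle=angle,
            )
            for angle in irrep.variant_angles
        ]
    full = symmetrize(X, group, range(group.order), perms)
    if irrep.label == group.totally_symmetric_label:
        if model_coords is None:
            return ModeVectors(irrep.label, np.zeros_like(X))
        return ModeVectors(irrep.label, full - np.asarray(model_coords))
    kernel_sym = symmetrize(X, group, irrep.kernel, perms)
    return ModeVectors(irrep.label, kernel_sym - full)


def reported_degenerate_pair(variants):
    """Reported pair for a degenerate irrep: the greatest-magnitude variant
    and its orthogonal counterpart (representation angle + 90 degrees)."""
    if not variants:
        raise ValidationError("empty variant list")
    angles = {v.angle for v in variants}
    needed = {(v.angle + 90.0) % 180.0 for v in variants} | {
        v.angle % 180.0 for v in variants
    }
    if any(a is None for a in angles) or not needed <= {a % 180.0 for a in angles}:
        raise ValidationError(
            "incomplete variant list: orthogonal counterparts missing"
        )
    primary = max(variants, key=lambda v: v.magnitude)
    counter_angle = (primary.angle + 90.0) % 180.0
    secondary = next(v for v in variants if v.angle % 180.0 == counter_angle)
    return primary, secondary


# ---------------------------------------------------------------------------
# alignment orchestration
# ---------------------------------------------------------------------------

_FLIP_STARTS = [
    np.eye(3),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
]


def align_to_model(
    query: Molecule, model: SymmetricModel, by_graph: bool = False
) -> tuple[RigidTransform, np.ndarray]:
    """Find the rigid transform placing the query in the model frame and
    return it with the model-ordered aligned coordinates.

    Distance route: the centered, axis-conventioned query is matched to the
    model by Hungarian assignment from four sign-flip starting orientations,
    iterating assignment and closed-form superposition until the permutation
    is stable; the lowest-cost start wins.  Graph route: one element- and
    adjacency-preserving graph match followed by superposition.
    """
    group = model.point_group
    Q = query.coords
    if len(Q) != len(model):
        raise AlignmentError(
            f"atom counts differ: query {len(Q)} vs model {len(model)}"
        )
    if by_graph:
        mapping = assign_by_graph(query, model.as_molecule())
        transform = kabsch(Q, model.coords[mapping.permutation])
        aligned = np.empty_like(Q)
        aligned[mapping.permutation] = transform.apply(Q)
        return transform, aligned

    centered = Q - Q.mean(axis=0)
    conv, P = apply_axis_convention(centered, group, return_transform=True)

    def _refine(X0):
        X, prev_perm, mapping, transform = X0, None, None, None
        for _ in range(30):
            mapping = assign_minimal_cost(
                X, model.coords, query.elements, model.elements
            )
            transform = kabsch(Q, model.coords[mapping.permutation])
            X = transform.apply(Q)
            if prev_perm is not None and np.array_equal(
                prev_perm, mapping.permutation
            ):
                break
            prev_perm = mapping.permutation
        cost = float(((X - model.coords[mapping.permutation]) ** 2).sum())
        return cost, transform, mapping

    # quick path: axis-conventioned query, four sign-flip starts
    best = None
    for flip in _FLIP_STARTS:
        result = _refine(conv @ flip.T)
        if best is None or result[0] < best[0]:
            best = result
    # accept the quick result only when the fit is unambiguously tight
    # (per-atom RMSD well below the model's minimum interatomic distance);
    # otherwise sweep principal-axis starts x in-plane rotations and keep
    # the global best
    from scipy.spatial.distance import pdist

    d_min = float(pdist(model.coords).min())
    if np.sqrt(best[0] / len(Q)) > 0.08 * d_min:
        from scipy.spatial.transform import Rotation

        from .alignment import _six_perpendicular_starts

        for base in _six_perpendicular_starts(Q):
            for ang in range(0, 360, 15):
                Rz = Rotation.from_euler("z", ang, degrees=True).as_matrix()
                result = _refine(centered @ (Rz @ base).T)
                if result[0] < best[0]:
                    best = result
    cost, transform, mapping = best
    transform.objective_value = cost
    aligned = np.empty_like(Q)
    aligned[mapping.permutation] = transform.apply(Q)
    return transform, aligned


# ---------------------------------------------------------------------------
# the decomposition driver
# ---------------------------------------------------------------------------


def decompose(
    query: Molecule,
    group_or_model,
    include_h: bool = False,
    by_graph: bool = False,
) -> DecompositionResult:
    """Run the full decomposition pipeline on one structure.

    ``group_or_model`` is either a point-group (name or :class:`PointGroup`)
    — in which case a throwaway symmetric model is generated from the query
    itself and the totally symmetric mode is zero — or a prebuilt
    :class:`SymmetricModel`, against which the totally symmetric distortion
    is measured.
    """
    mol = query if include_h else query.heavy()
    if isinstance(group_or_model, SymmetricModel):
        model = group_or_model
        model_used = True
    else:
        group = (
            build_group(group_or_model)
            if isinstance(group_or_model, str)
            else group_or_model
        )
        try:
            model = build_model(mol, group, name="dummy", include_h=True)
        except SymcoordError as exc:
            raise AlignmentError(
                f"model-free decomposition failed while building the dummy "
                f"model: {exc}"
            ) from exc
        model_used = False
    group = model.point_group
    perms = model.perm_list()

    try:
        transform, aligned = align_to_model(mol, model, by_graph=by_graph)
    except SymcoordError as exc:
        raise type(exc)(f"alignment stage: {exc}") from exc

    model_elements = list(model.elements)
    ts_label = group.totally_symmetric_label
    ts_row = group.irrep(ts_label)
    ts_mode = project_irrep(
        aligned, group, ts_row, perms,
        model_coords=model.coords if model_used else None,
    )

    modes = []
    variants: dict = {}
    recon = symmetrize(aligned, group, range(group.order), perms) if not model_used \
        else model.coords + ts_mode.vectors
    for row in group.irreps:
        if row.label == ts_label:
            continue
        component = project_irrep(aligned, group, row, perms)
        if row.is_degenerate:
            variants[row.label] = component
            primary, secondary = reported_degenerate_pair(component)
            modes.extend([primary, secondary])
            vsum = np.sum([v.vectors for v in component], axis=0)
            recon = recon + row.reconstruction_weight * vsum
        else:
            modes.append(component)
            recon = recon + component.vectors

    residual = float(np.linalg.norm(recon - aligned, axis=1).max())
    return DecompositionResult(
        group=group.name,
        elements=model_elements,
        aligned_coords=aligned,
        model_coords=model.coords,
        totally_symmetric_mode=ts_mode,
        modes=modes,
        variants=variants,
        reconstruction_residual=residual,
        model_used=model_used,
        transform=transform,
        structure_id=query.id,
    )
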