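"""Synthetic test structures: exactly symmetric reference frames, irrep-pure
distortion patterns, and seeded collections with ground truth.

The frames are idealized geometries (aromatic bond scale 1.40 A), not
crystallographic ones: an anthracene-like C14 sheet (D2h), a porphyrin-like
C20N4 core (D4h), a BODIPY-like C9N2B core (C2v), and generic
orbit-generated frames for the remaining groups.  Every frame is symmetric
to < 1e-12 A under its group, so decomposition of an undistorted frame
yields zero magnitudes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .groups import PointGroup, build_group
from .io_formats import Atom, Molecule
from .model import compute_operation_perms
from .projection import (
    character_projection,
    oriented_projection,
    remove_rigid_component,
)

BOND_SCALE = 1.40  # A, idealized aromatic bond


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------


def _orbit(group: PointGroup, seeds, tol: float = 1e-6):
    """Union of group orbits of seed points, deduplicated; exact symmetry is
    enforced by averaging each orbit point over its stabilizer images."""
    pts = []
    for seed in seeds:
        seed = np.asarray(seed, dtype=float)
        images = np.array([op.matrix @ seed for op in group.operations])
        for img in images:
            if not any(np.linalg.norm(img - p) < tol for p in pts):
                # snap to the mean of all images equivalent to this one
                close = images[np.linalg.norm(images - img, axis=1) < tol]
                pts.append(close.mean(axis=0))
    return np.array(pts)


def _molecule(coords, elements, mol_id):
    atoms = [
        Atom(f"{el}{i + 1}", el, *map(float, p))
        for i, (el, p) in enumerate(zip(elements, coords))
    ]
    mol = Molecule(atoms, None, source="fixture", id=mol_id)
    mol.bonds = mol.bonds_by_distance(1.05 * BOND_SCALE * 1.2)
    return mol


def _anthracene_frame() -> Molecule:
    """Three linearly fused regular hexagons, 14 carbons, D2h in the
    x-y plane with the long axis on x."""
    a = BOND_SCALE
    h = np.sqrt(3.0) / 2.0 * a
    pts = []
    for cx in (-2 * h, 0.0, 2 * h):
        for k in range(6):
            ang = np.pi / 6 + k * np.pi / 3
            p = (cx + a * np.cos(ang + np.pi / 3), a * np.sin(ang + np.pi / 3), 0.0)
            pts.append(p)
    uniq = []
    for p in pts:
        if not any(np.linalg.norm(np.subtract(p, q)) < 1e-8 for q in uniq):
            uniq.append(np.round(p, 12))
    coords = np.array(uniq)
    assert len(coords) == 14
    return _molecule(coords, ["C"] * 14, "anthracene_d2h")


def _porphyrin_frame() -> Molecule:
    """Idealized 24-atom porphyrin core (4 N + 20 C), D4h in the x-y plane."""
    group = build_group("D4h")
    n_orbit = _orbit(group, [(2.05, 0.0, 0.0)])
    alpha = _orbit(group, [(2.93, 1.12, 0.0)])
    meso = _orbit(group, [(2.43, 2.43, 0.0)])
    beta = _orbit(group, [(4.25, 0.69, 0.0)])
    coords = np.vstack([n_orbit, alpha, meso, beta])
    elements = ["N"] * len(n_orbit) + ["C"] * (len(coords) - len(n_orbit))
    assert len(coords) == 24
    return _molecule(coords, elements, "porphyrin_d4h")


def _bodipy_frame() -> Molecule:
    """Idealized 12-atom dipyrromethene-boron core (B + meso C + 2 N + 8 C),
    C2v: C2 axis on z, molecule in the x-z plane."""
    group = build_group("C2v")
    r5 = BOND_SCALE / (2.0 * np.sin(np.pi / 5.0))  # pentagon circumradius
    center = np.array([1.75, 0.0, 0.35])
    # pentagon vertex angles chosen so the N vertex points at the boron site
    base = np.deg2rad(212.0)
    ring = [
        center + r5 * np.array([np.cos(base + k * 2 * np.pi / 5), 0.0,
                                np.sin(base + k * 2 * np.pi / 5)])
        for k in range(5)
    ]
    seeds = {"N": [ring[0]], "C": ring[1:]}
    n_pts = _orbit(group, seeds["N"])
    c_pts = _orbit(group, seeds["C"])
    on_axis = np.array([[0.0, 0.0, -1.05], [0.0, 0.0, 1.95]])  # B, meso C
    coords = np.vstack([on_axis, n_pts, c_pts])
    elements = ["B", "C"] + ["N"] * len(n_pts) + ["C"] * len(c_pts)
    assert len(coords) == 12
    return _molecule(coords, elements, "bodipy_c2v")


def _generic_frame(group_name: str) -> Molecule:
    group = build_group(group_name)
    seeds = {
        "C1": [(1.2, 0.3, 0.1), (-0.8, 0.9, -0.4), (0.3, -1.1, 0.5)],
        "C2h": [(2.8, 0.5, 0.0), (1.5, -0.8, 0.0), (0.7, 1.2, 0.0)],
        "D2d": [(0.0, 0.0, 0.0), (1.25, 0.0, 0.95), (2.45, 0.0, 1.55)],
        "D3h": [(1.40, 0.0, 0.0), (2.80, 0.62, 0.0)],
        "D6h": [(1.40, 0.0, 0.0), (2.88, 0.66, 0.0)],
    }[group_name]
    coords = _orbit(group, seeds)
    elements = ["C"] * len(coords)
    if group_name == "D2d":
        elements[0] = "Si"
    mol_id = f"generic_{group_name.lower()}"
    return _molecule(coords, elements, mol_id)


_FRAME_BUILDERS = {
    "anthracene_d2h": _anthracene_frame,
    "porphyrin_d4h": _porphyrin_frame,
    "bodipy_c2v": _bodipy_frame,
}

_GROUP_FRAMES = {
    "D2h": "anthracene_d2h",
    "D4h": "porphyrin_d4h",
    "C2v": "bodipy_c2v",
}


def reference_frame(kind: str) -> Molecule:
    """A named, exactly symmetric reference frame.

    Kinds: ``anthracene_d2h`` (14 C), ``porphyrin_d4h`` (24 atoms),
    ``bodipy_c2v`` (12 atoms).
    """
    if kind not in _FRAME_BUILDERS:
        raise ValidationError(
            f"unknown frame kind {kind!r}; available: {sorted(_FRAME_BUILDERS)}"
        )
    return _FRAME_BUILDERS[kind]()


def frame_for_group(group_name: str) -> Molecule:
    """An exactly symmetric frame for any supported group (the named frames
    for D2h/D4h/C2v, orbit-generated synthetic frames otherwise)."""
    if group_name in _GROUP_FRAMES:
        return reference_frame(_GROUP_FRAMES[group_name])
    if group_name in ("C1", "C2h", "D2d", "D3h", "D6h"):
        return _generic_frame(group_name)
    raise ValidationError(f"no fixture frame for group {group_name!r}")


def frame_perms(frame: Molecule, group: PointGroup) -> list:
    """Exact per-operation permutations of a symmetric frame."""
    perms = compute_operation_perms(frame.coords, frame.elements, group)
    return [perms[op.label] for op in group.operations]


# ---------------------------------------------------------------------------
# distortion patterns
# ---------------------------------------------------------------------------


@dataclass
class DistortionPattern:
    """Unit-normalized displacement field lying in a single irrep."""

    irrep: str
    vectors: np.ndarray
    description: str = ""
    orientation: str = ""

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)

    @property
    def atom_norm_sum(self) -> float:
        """Sum of per-atom vector norms for the unit-norm pattern; a
        distortion of amplitude a has magnitude a * atom_norm_sum."""
        return float(np.linalg.norm(self.vectors, axis=1).sum())


_NAMED_FORMS = {
    # out-of-plane twist: z-displacement proportional to x*y
    "twist": lambda r: np.column_stack(
        [np.zeros(len(r)), np.zeros(len(r)), r[:, 0] * r[:, 1]]
    ),
    # out-of-plane arch: z proportional to x^2 (rigid z-shift removed later)
    "arch": lambda r: np.column_stack(
        [np.zeros(len(r)), np.zeros(len(r)), r[:, 0] ** 2]
    ),
    # saddle: z proportional to Re[(x+iy)^2] sign structure
    "saddle": lambda r: np.column_stack(
        [np.zeros(len(r)), np.zeros(len(r)), r[:, 0] ** 2 - r[:, 1] ** 2]
    ),
    # in-plane radial breathing (totally symmetric for planar frames)
    "breathing": lambda r: np.column_stack(
        [r[:, 0], r[:, 1], np.zeros(len(r))]
    ),
}


def make_pattern(
    frame: Molecule,
    group: PointGroup | str,
    irrep_label: str,
    form,
    orientation_angle: float | None = None,
    min_purity: float = 0.999,
) -> DistortionPattern:
    """Build a purified unit distortion pattern from a functional form.

    ``form`` is a callable mapping N x 3 positions to an N x 3 displacement
    field, or one of the named forms {twist, arch, saddle, breathing}.  The
    field is projected onto the target irrep (onto one orientation for
    degenerate irreps), stripped of rigid-body content and renormalized.
    An error is raised if the projection retains less than ``min_purity``
    of the field's norm.
    """
    if isinstance(group, str):
        group = build_group(group)
    if isinstance(form, str):
        if form not in _NAMED_FORMS:
            raise ValidationError(
                f"unknown form {form!r}; named forms: {sorted(_NAMED_FORMS)}"
            )
        form = _NAMED_FORMS[form]
    row = group.irrep(irrep_label)
    X = frame.coords
    field = np.asarray(form(X), dtype=float)
    if field.shape != X.shape:
        raise ValidationError("form must return an N x 3 displacement field")
    field = remove_rigid_component(field, X)
    perms = frame_perms(frame, group)
    if row.is_degenerate:
        angle = orientation_angle if orientation_angle is not None else row.variant_angles[0]
        projected = oriented_projection(group, row, angle, field, perms)
        orientation = f"{angle:g}deg"
    else:
        projected = character_projection(group, row, field, perms)
        orientation = ""
    norm_in = np.linalg.norm(field)
    norm_out = np.linalg.norm(projected)
    if norm_in < 1e-12 or norm_out < 1e-12:
        raise ValidationError(
            f"form has no component in irrep {irrep_label} "
            "(zero after projection/rigid removal)"
        )
    purity = norm_out / norm_in
    if purity < min_purity:
        raise ValidationError(
            f"form is not pure in irrep {irrep_label}: purity {purity:.4f} "
            f"< {min_purity}"
        )
    projected = remove_rigid_component(projected, X)
    projected /= np.linalg.norm(projected)
    desc = getattr(form, "__name__", "field")
    return DistortionPattern(irrep_label, projected, desc, orientation)


def random_irrep_pattern(
    frame: Molecule,
    group: PointGroup | str,
    irrep_label: str,
    seed: int,
    orientation_angle: float | None = None,
) -> DistortionPattern:
    """Unit pattern in one irrep from a random smooth field (projection of
    seeded low-order polynomial displacements); used to probe every irrep of
    every group without hand-crafting forms."""
    rng = np.random.default_rng(seed)

    def form(r):
        # random polynomial field over all monomials up to degree 6; the
        # high-order terms are needed to reach exotic irreps (e.g. A1u of
        # D4h/D6h) on planar frames
        from itertools import combinations_with_replacement

        cols = [np.ones(len(r))]
        for deg in (1, 2, 3, 4, 5, 6):
            for combo in combinations_with_replacement(range(3), deg):
                col = np.ones(len(r))
                for i in combo:
                    col = col * r[:, i]
                cols.append(col)
        phi = np.column_stack(cols)
        W = rng.standard_normal((phi.shape[1], 3)) * 0.2
        return phi @ W

    return make_pattern(
        frame, group, irrep_label, form,
        orientation_angle=orientation_angle, min_purity=0.0,
    )


# ---------------------------------------------------------------------------
# collections
# ---------------------------------------------------------------------------


def sample_collection(
    frame: Molecule,
    patterns,
    amplitudes,
    noise_sigma: float,
    n: int,
    seed: int,
):
    """Seeded collection of distorted copies of a frame with ground truth.

    Structure i is ``frame + sum_j c_ij * pattern_j + noise``, then given a
    random rigid motion and atom shuffle.  ``amplitudes`` is one standard
    deviation per pattern (c_ij ~ Normal(0, s_j^2)).  Returns
    ``(molecules, truth)`` where truth maps structure id to the drawn
    coefficients and the applied permutation.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if noise_sigma < 0:
        raise ValidationError("noise sigma must be non-negative")
    if len(amplitudes) != len(patterns):
        raise ValidationError("need one amplitude scale per pattern")
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    X0 = frame.coords
    molecules = []
    truth = {}
    for i in range(n):
        c = np.array([rng.normal(0.0, s) for s in amplitudes])
        X = X0 + sum(
            ci * p.vectors for ci, p in zip(c, patterns)
        ) + rng.normal(0.0, noise_sigma, X0.shape)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-5.0, 5.0, 3)
        X = X @ R.T + t
        perm = rng.permutation(len(X0))
        mol_id = f"sample_{i:04d}"
        mol = _molecule_from_arrays(
            X, frame.elements, perm, mol_id
        )
        molecules.append(mol)
        truth[mol_id] = {"coefficients": c, "permutation": perm, "rotation": R}
    return molecules, truth


def _molecule_from_arrays(coords, elements, perm, mol_id):
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    atoms = [
        Atom(f"{elements[j]}{k + 1}", elements[j], *map(float, coords[j]))
        for k, j in enumerate(inv)
    ]
    return Molecule(atoms, None, source="fixture", id=mol_id)
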