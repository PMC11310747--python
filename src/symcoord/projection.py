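"""Group actions on atom-resolved coordinate/displacement sets, subgroup
averaging, and irreducible-representation projections.

A point-group operation g acts on an N x 3 coordinate block X through its
matrix realization R(g) *and* an atom permutation pi(g) (which atom lands on
which): ``act(g, X)[pi(i)] = R(g) X[i]``.  The permutations are derived from
a symmetric reference frame, where they form a true representation
(pi(g o h) = pi(g) o pi(h)), making all the averaging operators below exact
projectors.

Two independent routes to the same components are kept deliberately:

* :func:`symmetrize` — iterative subgroup averaging; the production path for
  one-dimensional irreps (kernel average minus full-group average).
* :func:`character_projection` — the textbook projection
  (d/|G|) sum_g chi(g) act(g, X); used as the brute-force oracle.

Degenerate (E-type) components are extracted per orientation with
:func:`oriented_projection`, a rank-1 projection inside the irrep's isotypic
subspace built from explicit 2x2 representation matrices.
"""

from __future__ import annotations

import numpy as np

from .errors import ConvergenceError, ValidationError
from .groups import IrrepRow, PointGroup


def act(group: PointGroup, op_index: int, coords: np.ndarray, perms) -> np.ndarray:
    """Apply operation ``op_index`` to ``coords`` with atom reassignment."""
    perm = np.asarray(perms[op_index])
    out = np.empty_like(np.asarray(coords, dtype=float))
    out[perm] = coords @ group.operations[op_index].matrix.T
    return out


def _check_perms(group: PointGroup, n_atoms: int, perms) -> None:
    if len(perms) != group.order:
        raise ValidationError(
            f"need one permutation per operation ({group.order}), got {len(perms)}"
        )
    for p in perms:
        if len(p) != n_atoms:
            raise ValidationError(
                f"permutation length {len(p)} does not match atom count {n_atoms}"
            )


def average(
    group: PointGroup, op_indices, coords: np.ndarray, perms
) -> np.ndarray:
    """Mean of ``coords`` over the listed operations (single pass)."""
    X = np.asarray(coords, dtype=float)
    acc = np.zeros_like(X)
    for i in op_indices:
        acc += act(group, i, X, perms)
    return acc / len(op_indices)


def symmetrize(
    coords: np.ndarray,
    group: PointGroup,
    op_indices,
    perms,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Impose the symmetry of a subgroup by iterative averaging.

    ``op_indices`` must index a subgroup (closed under composition); the
    result is invariant under every listed operation to < 1e-8 A.  With
    permutations that form a true representation the average is an exact
    projector and a single iteration converges.
    """
    op_indices = list(op_indices)
    X = np.asarray(coords, dtype=float)
    _check_perms(group, len(X), perms)
    for i in op_indices:
        for j in op_indices:
            if group.composition[i, j] not in op_indices:
                raise ValidationError(
                    "operation subset is not closed under composition: "
                    f"{group.operations[i].label} o {group.operations[j].label}"
                )
    for _ in range(max_iter):
        Y = average(group, op_indices, X, perms)
        shift = float(np.abs(Y - X).max())
        X = Y
        if shift < tol:
            return X
    raise ConvergenceError(
        f"symmetrization did not converge (final shift {shift:.3e} A)",
        final_shift=shift,
    )


def character_projection(
    group: PointGroup, irrep: IrrepRow, coords: np.ndarray, perms
) -> np.ndarray:
    """Textbook projection of ``coords`` onto one irrep:
    (d/|G|) * sum_g chi(g) * act(g, coords).

    Components over all irreps sum to the input exactly (completeness).
    """
    X = np.asarray(coords, dtype=float)
    _check_perms(group, len(X), perms)
    acc = np.zeros_like(X)
    for i, chi in enumerate(irrep.characters):
        if chi != 0:
            acc += chi * act(group, i, X, perms)
    return acc * (irrep.degeneracy / group.order)


def oriented_projection(
    group: PointGroup,
    irrep: IrrepRow,
    angle_deg: float,
    coords: np.ndarray,
    perms,
) -> np.ndarray:
    """Oriented component of a degenerate irrep.

    Rank-1 projection onto the direction ``e = (cos a, sin a)`` inside the
    irrep's representation space:
    (d/|G|) * sum_g <e, D(g) e> * act(g, coords).
    Summing over an orthogonal pair of angles reproduces the full
    :func:`character_projection` component.
    """
    if not irrep.is_degenerate:
        raise ValidationError(f"{irrep.label} is not degenerate")
    X = np.asarray(coords, dtype=float)
    e = irrep.variant_direction(angle_deg)
    acc = np.zeros_like(X)
    for i, D in enumerate(irrep.rep_matrices):
        w = float(e @ D @ e)
        if abs(w) > 1e-14:
            acc += w * act(group, i, X, perms)
    return acc * (irrep.degeneracy / group.order)


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows, flattened 3N) of rigid translations and
    infinitesimal rotations about the centroid."""
    X = np.asarray(coords, dtype=float)
    n = len(X)
    C = X - X.mean(axis=0)
    modes = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        modes.append(t.ravel())
    for axis in np.eye(3):
        r = np.cross(np.broadcast_to(axis, C.shape), C)
        modes.append(r.ravel())
    M = np.array(modes)
    # orthonormalize, dropping null rotations (e.g. linear molecules)
    q, r = np.linalg.qr(M.T)
    keep = np.abs(np.diag(r)) > 1e-10
    return q.T[keep]


def remove_rigid_component(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Project rigid-body translation/rotation content out of a displacement
    field (N x 3)."""
    flat = np.asarray(field, dtype=float).ravel()
    B = rigid_body_basis(coords)
    flat = flat - B.T @ (B @ flat)
    return flat.reshape(np.asarray(field).shape)
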