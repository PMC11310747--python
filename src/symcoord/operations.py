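"""Point-group symmetry operations as geometric actions on coordinates.

An operation is one of identity, proper rotation C_n^p, improper rotation
S_n^p, mirror plane, or inversion.  Every operation has an explicit 3x3
orthogonal matrix realization; proper rotations have determinant +1,
mirrors, improper rotations and the inversion have determinant -1.

Rotations are realized as axis-angle matrices with angle 2*pi*power/order;
a mirror subtracts twice the projection onto the plane normal
(r' = r - 2 (r.n) n); an improper rotation is the rotation followed by the
reflection through the plane perpendicular to its axis; inversion negates
all coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

_KINDS = ("identity", "proper_rotation", "improper_rotation", "mirror", "inversion")

#: axis is ignored for these kinds
_AXLESS = ("identity", "inversion")


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _reflection_matrix(normal: np.ndarray) -> np.ndarray:
    return np.eye(3) - 2.0 * np.outer(normal, normal)


@dataclass(frozen=True)
class SymmetryOperation:
    """A single point-group operation.

    Parameters
    ----------
    kind :
        One of ``identity``, ``proper_rotation``, ``improper_rotation``,
        ``mirror``, ``inversion``.
    axis :
        Unit 3-vector: rotation axis for (im)proper rotations, plane normal
        for mirrors.  Ignored (and stored as +z) for identity/inversion.
    order, power :
        For C_n^p / S_n^p; the rotation angle is ``2*pi*power/order``.
    label :
        Human-readable tag, e.g. ``"C2(z)"`` or ``"sigma(xz)"``.
    """

    kind: str
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    order: int = 1
    power: int = 1
    label: str = ""
    # cached matrix realization; computed in __post_init__
    _matrix: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValidationError(
                f"unsupported operation kind {self.kind!r}; expected one of {_KINDS}"
            )
        ax = np.asarray(self.axis, dtype=float)
        if self.kind not in _AXLESS:
            n = np.linalg.norm(ax)
            if abs(n - 1.0) > 1e-12:
                raise ValidationError(
                    f"operation axis must have unit norm (got |axis| = {n:.3e})"
                )
        object.__setattr__(self, "axis", tuple(ax))
        object.__setattr__(self, "_matrix", self._realize())

    def _realize(self) -> np.ndarray:
        ax = np.asarray(self.axis)
        if self.kind == "identity":
            return np.eye(3)
        if self.kind == "inversion":
            return -np.eye(3)
        if self.kind == "mirror":
            return _reflection_matrix(ax)
        angle = 2.0 * np.pi * self.power / self.order
        R = _rotation_matrix(ax, angle)
        if self.kind == "improper_rotation":
            R = _reflection_matrix(ax) @ R
        return R

    @property
    def matrix(self) -> np.ndarray:
        """3x3 orthogonal matrix realization (read-only view)."""
        m = self._matrix.view()
        m.flags.writeable = False
        return m

    @property
    def is_proper(self) -> bool:
        return self.kind in ("identity", "proper_rotation")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an N x 3 coordinate block; row order is unchanged."""
        return apply_operation(self, coords)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "axis": [float(a) for a in self.axis],
            "order": self.order,
            "power": self.power,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetryOperation":
        return cls(
            kind=d["kind"],
            axis=tuple(d["axis"]),
            order=int(d["order"]),
            power=int(d["power"]),
            label=d["label"],
        )


def identity() -> SymmetryOperation:
    return SymmetryOperation("identity", label="E")


def inversion() -> SymmetryOperation:
    return SymmetryOperation("inversion", label="i")


def rotation(axis, order: int, power: int = 1, label: str = "") -> SymmetryOperation:
    ax = _unit(axis)
    label = label or f"C{order}^{power}"
    return SymmetryOperation("proper_rotation", ax, order, power, label)


def improper(axis, order: int, power: int = 1, label: str = "") -> SymmetryOperation:
    ax = _unit(axis)
    label = label or f"S{order}^{power}"
    return SymmetryOperation("improper_rotation", ax, order, power, label)


def mirror(normal, label: str = "") -> SymmetryOperation:
    ax = _unit(normal)
    label = label or "sigma"
    return SymmetryOperation("mirror", ax, order=1, power=1, label=label)


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValidationError("axis must be a nonzero vector")
    return tuple(a / n)


def apply_operation(op: SymmetryOperation, coords: np.ndarray) -> np.ndarray:
    """Apply a symmetry operation to an N x 3 coordinate matrix.

    The transformation is rigid (pairwise distances are preserved) and does
    not reassign atoms: row i of the output is the image of row i of the
    input.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValidationError(f"coords must be N x 3 (got shape {X.shape})")
    if not np.all(np.isfinite(X)):
        raise ValidationError("coords must be finite")
    return X @ op.matrix.T
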