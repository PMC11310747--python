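"""Many-structure analysis: per-irrep mode matrices, principal-component
pseudo-normal modes, coefficient fitting, and nearest-conformation search.

The PCA here is *uncentered* (components pass through the origin): a row of
zeros means an undistorted structure, and the fitted modes must vanish with
the distortion.  Components carry a deterministic sign convention (the
largest-magnitude entry of each component is positive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import decompose
from .errors import SymcoordError, ValidationError
from .model import SymmetricModel

logger = logging.getLogger(__name__)


@dataclass
class ModeMatrix:
    """Structures x (3N) flattened mode vectors for one irrep."""

    irrep: str
    rows: np.ndarray
    ids: list
    failures: dict = field(default_factory=dict)  # id -> error message

    def __post_init__(self):
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, index=self.ids)


@dataclass
class PrincipalModeSet:
    """Orthonormal pseudo-normal modes of one irrep with fitted amplitudes."""

    irrep: str
    components: np.ndarray  # k x 3N, orthonormal rows
    explained_variance: np.ndarray  # k fractions, non-increasing
    coefficients: np.ndarray  # structures x k (A)
    residuals: np.ndarray  # per-structure leftover magnitude (A)
    ids: list = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "schema": "symcoord.pca/1",
            "irrep": self.irrep,
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "coefficients": self.coefficients.tolist(),
            "residuals": self.residuals.tolist(),
            "ids": list(self.ids),
        }

    def coefficient_table(self) -> pd.DataFrame:
        cols = [f"{self.irrep}({j + 1})" for j in range(self.components.shape[0])]
        df = pd.DataFrame(self.coefficients, index=self.ids, columns=cols)
        df["residual"] = self.residuals
        return df


def mode_row(result, irrep: str) -> np.ndarray:
    """Flattened full irrep component of one decomposition result (for
    degenerate irreps: the weighted variant sum, i.e. the complete
    isotypic component)."""
    if irrep in result.variants:
        row = result.variants[irrep]
        weight = None
        from .groups import build_group

        weight = build_group(result.group).irrep(irrep).reconstruction_weight
        return weight * np.sum([v.vectors for v in row], axis=0).ravel()
    return result.mode(irrep).vectors.ravel()


def collect_mode_matrix(structures, model: SymmetricModel, irrep: str) -> ModeMatrix:
    """Decompose every structure against ``model`` and stack the flattened
    irrep components.  Per-structure failures are logged and reported in
    ``failures``, not fatal; zero successes raise."""
    group = model.point_group
    group.irrep(irrep)  # validates the label
    rows, ids, failures = [], [], {}
    for mol in structures:
        try:
            result = decompose(mol, model)
            rows.append(mode_row(result, irrep))
            ids.append(mol.id)
        except SymcoordError as exc:
            failures[getattr(mol, "id", "?")] = str(exc)
            logger.warning("decomposition failed for %s: %s", mol.id, exc)
    if not rows:
        raise ValidationError(
            f"no structure could be decomposed (of {len(list(structures))}); "
            f"first error: {next(iter(failures.values()), 'none')}"
        )
    return ModeMatrix(irrep, np.array(rows), ids, failures)


def fit_principal_modes(matrix: ModeMatrix, k: int) -> PrincipalModeSet:
    """Uncentered PCA of a mode matrix via singular value decomposition.

    ``explained_variance`` fractions come from the squared singular values;
    ``k`` beyond the matrix rank is truncated with a warning.
    """
    rows = matrix.rows
    if rows.shape[0] < 2:
        raise ValidationError("need at least 2 structures for PCA")
    if k < 1:
        raise ValidationError("k must be >= 1")
    U, s, Vt = np.linalg.svd(rows, full_matrices=False)
    tol = max(rows.shape) * np.finfo(float).eps * (s[0] if len(s) else 1.0)
    rank = int((s > tol).sum())
    if k > rank:
        warnings.warn(
            f"requested {k} components but matrix rank is {rank}; truncating",
            stacklevel=2,
        )
        k = max(rank, 1)
    components = Vt[:k].copy()
    # deterministic sign: largest-magnitude entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(components[j])))
        if components[j, i] < 0:
            components[j] = -components[j]
    total = float((s**2).sum()) or 1.0
    explained = (s[:k] ** 2) / total
    coeffs = rows @ components.T
    resid_vectors = rows - coeffs @ components
    residuals = np.linalg.norm(resid_vectors, axis=1)
    return PrincipalModeSet(
        irrep=matrix.irrep,
        components=components,
        explained_variance=explained,
        coefficients=coeffs,
        residuals=residuals,
        ids=list(matrix.ids),
    )


def project_coefficients(row: np.ndarray, modes: PrincipalModeSet):
    """Least-squares coefficients of one flattened mode row on the
    principal modes (inner products, by orthonormality) plus the magnitude
    of the leftover vector."""
    row = np.asarray(row, dtype=float).ravel()
    if row.shape[0] != modes.components.shape[1]:
        raise ValidationError(
            f"dimension mismatch: row has {row.shape[0]} entries, components "
            f"have {modes.components.shape[1]}"
        )
    coeffs = modes.components @ row
    residual = float(np.linalg.norm(row - coeffs @ modes.components))
    return coeffs, residual


def nearest_conformations(query_magnitudes, table, k: int) -> pd.DataFrame:
    """Rank table rows by squared-distance of per-irrep magnitudes.

    ``query_magnitudes``: mapping irrep -> magnitude (or a vector matching
    the table columns).  ``table``: DataFrame indexed by structure id with
    one column per irrep.  Returns the ``k`` nearest rows (ascending
    distance, ties broken by id order); a structure identical to the query
    ranks first at distance zero.
    """
    if isinstance(table, dict):
        table = pd.DataFrame(table).T
    if len(table) == 0:
        raise ValidationError("empty magnitude table")
    if isinstance(query_magnitudes, dict):
        q = np.array([query_magnitudes[c] for c in table.columns], dtype=float)
    else:
        q = np.asarray(query_magnitudes, dtype=float)
        if q.shape[0] != table.shape[1]:
            raise ValidationError(
                f"query has {q.shape[0]} magnitudes, table has "
                f"{table.shape[1]} columns"
            )
    if k > len(table):
        warnings.warn(
            f"k={k} exceeds table size {len(table)}; returning the full table",
            stacklevel=2,
        )
        k = len(table)
    dist = ((table.to_numpy(dtype=float) - q) ** 2).sum(axis=1)
    out = pd.DataFrame({"distance": dist}, index=table.index)
    out = out.sort_values(["distance"], kind="stable").iloc[:k]
    return out


def magnitude_table(structures, model: SymmetricModel) -> pd.DataFrame:
    """Per-structure, per-irrep magnitude table (A); failures skipped with a
    log entry."""
    rows = {}
    for mol in structures:
        try:
            rows[mol.id] = decompose(mol, model).magnitudes
        except SymcoordError as exc:
            logger.warning("decomposition failed for %s: %s", mol.id, exc)
    if not rows:
        raise ValidationError("no structure could be decomposed")
    group = model.point_group
    cols = [r.label for r in group.irreps]
    return pd.DataFrame.from_dict(rows, orient="index")[cols]
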