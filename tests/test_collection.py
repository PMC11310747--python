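"""Collection analysis: mode matrices, uncentered PCA, nearest neighbours."""

import warnings

import numpy as np
import pandas as pd
import pytest

from symcoord.collection import (
    collect_mode_matrix,
    fit_principal_modes,
    magnitude_table,
    nearest_conformations,
    project_coefficients,
)
from symcoord.errors import ValidationError
from symcoord.fixtures import random_irrep_pattern, sample_collection
from symcoord.groups import build_group


@pytest.fixture(scope="module")
def au_patterns(anthracene):
    group = build_group("D2h")
    u1 = random_irrep_pattern(anthracene, group, "Au", seed=11)
    u2 = random_irrep_pattern(anthracene, group, "Au", seed=22)
    # orthonormalize the second pattern against the first
    v = u2.vectors.ravel() - (u2.vectors.ravel() @ u1.vectors.ravel()) * u1.vectors.ravel()
    u2.vectors = (v / np.linalg.norm(v)).reshape(-1, 3)
    return u1, u2


@pytest.fixture(scope="module")
def recovery_set(anthracene, anthracene_model, au_patterns):
    u1, u2 = au_patterns
    mols, truth = sample_collection(
        anthracene, [u1, u2], [1.0, 0.3], 0.01, 60, seed=7
    )
    matrix = collect_mode_matrix(mols, anthracene_model, "Au")
    return mols, truth, matrix


def test_ideal_copies_give_a_zero_matrix(anthracene, anthracene_model):
    mols, _ = sample_collection(anthracene, [], [], 0.0, 10, seed=1)
    matrix = collect_mode_matrix(mols, anthracene_model, "Au")
    assert matrix.rows.shape == (10, 42)
    assert np.abs(matrix.rows).max() < 1e-6
    assert not matrix.failures


def test_rows_match_injected_distortions(recovery_set, au_patterns):
    u1, u2 = au_patterns
    mols, truth, matrix = recovery_set
    for i, mol_id in enumerate(matrix.ids):
        c = truth[mol_id]["coefficients"]
        expected = c[0] * u1.vectors.ravel() + c[1] * u2.vectors.ravel()
        # noise contributes its Au component only
        assert np.linalg.norm(matrix.rows[i] - expected) < 0.06


def test_unparsable_structure_is_isolated_not_fatal(
    anthracene, anthracene_model
):
    mols, _ = sample_collection(anthracene, [], [], 0.0, 9, seed=2)
    broken = anthracene.subset(range(5))
    broken.id = "broken"
    matrix = collect_mode_matrix([*mols, broken], anthracene_model, "Au")
    assert matrix.rows.shape[0] == 9
    assert "broken" in matrix.failures
    with pytest.raises(ValidationError):
        collect_mode_matrix([broken], anthracene_model, "Au")


def test_pca_recovers_planted_components(recovery_set, au_patterns):
    u1, u2 = au_patterns
    _, _, matrix = recovery_set
    modes = fit_principal_modes(matrix, 2)
    assert abs(modes.components[0] @ u1.vectors.ravel()) > 0.99
    assert abs(modes.components[1] @ u2.vectors.ravel()) > 0.95
    assert modes.explained_variance[0] >= modes.explained_variance[1]
    assert modes.explained_variance[:2].sum() > 0.99
    # orthonormal components
    gram = modes.components @ modes.components.T
    assert np.abs(gram - np.eye(2)).max() < 1e-10
    # reconstruction: coefficients x components + residual vector = row
    recon = modes.coefficients @ modes.components
    resid = np.linalg.norm(matrix.rows - recon, axis=1)
    assert np.abs(resid - modes.residuals).max() < 1e-9


def test_uncentered_pca_agrees_with_truncated_svd(recovery_set):
    """Independent route: sklearn's TruncatedSVD (arpack) factors the same
    uncentered matrix; singular structure and component directions agree."""
    from sklearn.decomposition import TruncatedSVD

    _, _, matrix = recovery_set
    modes = fit_principal_modes(matrix, 2)
    svd = TruncatedSVD(n_components=2, algorithm="arpack")
    svd.fit(matrix.rows)
    for j in range(2):
        cos = abs(float(svd.components_[j] @ modes.components[j]))
        assert cos > 1 - 1e-9
    total = float((matrix.rows**2).sum())
    frac = (svd.singular_values_**2) / total
    assert np.abs(frac - modes.explained_variance) .max() < 1e-9


def test_coefficient_recovery_within_noise_bounds(recovery_set):
    _, truth, matrix = recovery_set
    modes = fit_principal_modes(matrix, 2)
    bound = 3 * 0.01 * np.sqrt(matrix.rows.shape[1])
    for i, mol_id in enumerate(matrix.ids):
        c = truth[mol_id]["coefficients"]
        assert abs(abs(modes.coefficients[i, 0]) - abs(c[0])) < bound


def test_rank_one_matrix_yields_a_single_component(anthracene_model):
    rng = np.random.default_rng(5)
    v = rng.normal(size=42)
    rows = np.outer([1.0, -2.0, 0.5], v)
    from symcoord.collection import ModeMatrix

    matrix = ModeMatrix("Au", rows, ["a", "b", "c"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        modes = fit_principal_modes(matrix, 2)
    assert any("rank" in str(w.message) for w in caught)
    assert modes.components.shape[0] == 1
    assert modes.explained_variance[0] == pytest.approx(1.0, abs=1e-12)


def test_uncentered_pca_zero_row_has_zero_coefficients():
    rng = np.random.default_rng(3)
    v = rng.normal(size=30)
    v /= np.linalg.norm(v)
    rows = np.vstack([2.0 * v, -1.0 * v, np.zeros(30)])
    from symcoord.collection import ModeMatrix

    modes = fit_principal_modes(ModeMatrix("Au", rows, list("abc")), 1)
    assert abs(modes.coefficients[2, 0]) < 1e-12
    assert modes.residuals[2] < 1e-12


def test_project_coefficients_contracts():
    rng = np.random.default_rng(9)
    comps = np.linalg.qr(rng.normal(size=(30, 2)))[0].T
    from symcoord.collection import PrincipalModeSet

    modes = PrincipalModeSet(
        "Au", comps, np.array([0.8, 0.2]), np.zeros((0, 2)), np.zeros(0)
    )
    coeffs, resid = project_coefficients(2.0 * comps[0], modes)
    assert coeffs == pytest.approx([2.0, 0.0], abs=1e-12)
    assert resid < 1e-12
    # a row orthogonal to all components keeps its full magnitude as residual
    row = rng.normal(size=30)
    row -= comps.T @ (comps @ row)
    coeffs, resid = project_coefficients(row, modes)
    assert np.abs(coeffs).max() < 1e-10
    assert resid == pytest.approx(np.linalg.norm(row), abs=1e-10)
    with pytest.raises(ValidationError, match="mismatch"):
        project_coefficients(np.zeros(7), modes)


# --- nearest conformations --------------------------------------------------


def test_query_present_in_table_ranks_itself_first():
    table = pd.DataFrame(
        {"Au": [5.68, 1.2, 0.3], "B1u": [0.5, 0.1, 2.0]},
        index=["self", "other", "third"],
    )
    out = nearest_conformations({"Au": 5.68, "B1u": 0.5}, table, 2)
    assert list(out.index)[0] == "self"
    assert out.iloc[0, 0] == 0.0


def test_three_row_ordering_matches_hand_arithmetic():
    table = pd.DataFrame(
        {"Au": [1.0, 2.0, 4.0], "B1u": [0.0, 0.0, 0.0]},
        index=["a", "b", "c"],
    )
    out = nearest_conformations({"Au": 2.4, "B1u": 0.0}, table, 3)
    # distances: a=1.96, b=0.16, c=2.56
    assert list(out.index) == ["b", "a", "c"]
    assert out["distance"].tolist() == pytest.approx([0.16, 1.96, 2.56])


def test_oversized_k_returns_full_table_with_warning():
    table = pd.DataFrame({"Au": [1.0, 2.0]}, index=["a", "b"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        out = nearest_conformations({"Au": 0.0}, table, 10)
    assert len(out) == 2
    assert any("exceeds" in str(w.message) for w in caught)
    with pytest.raises(ValidationError):
        nearest_conformations({"Au": 0.0}, table.iloc[:0], 1)


def test_matches_brute_force_on_random_tables():
    rng = np.random.default_rng(1)
    for _ in range(10):
        table = pd.DataFrame(
            rng.normal(size=(8, 3)), columns=["a", "b", "c"],
            index=[f"s{i}" for i in range(8)],
        )
        q = rng.normal(size=3)
        out = nearest_conformations(q, table, 8)
        brute = ((table.to_numpy() - q) ** 2).sum(axis=1)
        order = [table.index[i] for i in np.argsort(brute, kind="stable")]
        assert list(out.index) == order


def test_magnitude_table_layout(anthracene, anthracene_model):
    mols, _ = sample_collection(anthracene, [], [], 0.005, 4, seed=3)
    table = magnitude_table(mols, anthracene_model)
    assert table.shape == (4, 8)
    assert list(table.columns) == [
        "Ag", "B1g", "B2g", "B3g", "Au", "B1u", "B2u", "B3u"
    ]
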