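"""Rigid superposition, operation-based orientation, axis conventions."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from symcoord.alignment import (
    RigidTransform,
    apply_axis_convention,
    kabsch,
    operation_distortion,
    orient_to_operations,
    superpose_to_model,
)
from symcoord.assignment import AssignmentMap, assign_minimal_cost
from symcoord.errors import AlignmentError
from symcoord.fixtures import frame_for_group, random_irrep_pattern
from symcoord.groups import build_group


def _identity_map(n):
    return AssignmentMap(np.arange(n), 0.0)


def test_exact_recovery_of_rotation_and_translation(anthracene):
    X = anthracene.coords
    R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    query = anthracene.with_coords((X - [1, 1, 1]) @ R.T)
    tr = superpose_to_model(query, anthracene, _identity_map(len(X)))
    assert tr.objective_value < 1e-12
    assert np.abs(tr.apply(query.coords) - X).max() < 1e-9


def test_identity_when_query_equals_model(anthracene):
    tr = superpose_to_model(anthracene, anthracene, _identity_map(len(anthracene)))
    assert np.abs(tr.rotation - np.eye(3)).max() < 1e-9
    assert np.abs(tr.translation).max() < 1e-9


def test_noise_residual_matches_least_squares_statistics(anthracene):
    # residual of fitting X+noise onto X concentrates near N*3*sigma^2
    sigma = 0.01
    n = len(anthracene)
    ratios = []
    rng = np.random.default_rng(42)
    for _ in range(100):
        noisy = anthracene.with_coords(
            anthracene.coords + rng.normal(0, sigma, (n, 3))
        )
        tr = superpose_to_model(noisy, anthracene, _identity_map(n))
        ratios.append(tr.objective_value / (n * 3 * sigma**2))
    assert 0.5 < np.mean(ratios) < 1.5
    assert all(0.3 < r < 2.0 for r in ratios)


def _quaternion_superpose(P, Q):
    """Independent closed-form route: Horn's quaternion eigenvalue method."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    S = P0.T @ Q0
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    K = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(K)
    q = v[:, -1]  # (w, x, y, z)
    return float((P0**2).sum() + (Q0**2).sum() - 2.0 * w[-1])


def test_agrees_with_independent_quaternion_formulation():
    rng = np.random.default_rng(11)
    for _ in range(20):
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        tr = kabsch(P, Q)
        assert tr.objective_value == pytest.approx(
            _quaternion_superpose(P, Q), abs=1e-10
        )


def test_collinear_input_rejected():
    line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])

    class _M:
        coords = line
        elements = ["C"] * 3

    with pytest.raises(AlignmentError, match="collinear"):
        superpose_to_model(_M(), _M(), _identity_map(3))


def test_rigid_transform_invariants():
    R = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
    tr = RigidTransform(R, [1.0, 2.0, 3.0])
    X = np.random.default_rng(0).normal(size=(5, 3))
    assert np.abs(tr.inverse().apply(tr.apply(X)) - X).max() < 1e-9
    with pytest.raises(Exception):
        RigidTransform(np.eye(3) * 2.0, np.zeros(3))


# --- orientation to operations ---------------------------------------------


def test_symmetric_frame_is_already_at_the_global_minimum():
    for name in ("C2v", "D2h", "D3h"):
        frame = frame_for_group(name)
        group = build_group(name)
        tr = orient_to_operations(frame, group)
        assert tr.objective_value < 1e-12


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_recovers_orientation_of_rotated_frame(seed):
    frame = frame_for_group("D2h")
    group = build_group("D2h")
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    rotated = frame.with_coords(frame.coords @ R.T + rng.uniform(-3, 3, 3))
    tr = orient_to_operations(rotated, group)
    assert tr.objective_value < 1e-9


def test_orientation_objective_insensitive_to_pure_irrep_distortion():
    frame = frame_for_group("D2h")
    group = build_group("D2h")
    pat = random_irrep_pattern(frame, group, "Au", seed=9)
    distorted = frame.with_coords(frame.coords + 0.3 * pat.vectors)
    obj_ref = operation_distortion(
        distorted.coords - distorted.coords.mean(axis=0), group, frame.elements
    )
    tr = orient_to_operations(distorted, group)
    assert tr.objective_value == pytest.approx(obj_ref, abs=1e-6)


@pytest.mark.parametrize("seed", range(20))
def test_orientation_objective_invariant_under_rigid_motion(seed):
    frame = frame_for_group("C2v")
    group = build_group("C2v")
    pat = random_irrep_pattern(frame, group, "B1", seed=4)
    base = frame.with_coords(frame.coords + 0.25 * pat.vectors)
    ref = orient_to_operations(base, group).objective_value
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    moved = base.with_coords(base.coords @ R.T + rng.uniform(-5, 5, 3))
    assert orient_to_operations(moved, group).objective_value == pytest.approx(
        ref, abs=1e-9
    )


# --- axis conventions -------------------------------------------------------


def test_planar_frame_moved_into_the_xy_plane():
    frame = frame_for_group("D2h")  # built in x-y, long axis x
    group = build_group("D2h")
    # put it in the x-z plane with the long axis on z
    X = frame.coords[:, [2, 1, 0]]  # swap x and z
    out = apply_axis_convention(X, group)
    var = out.var(axis=0)
    assert var[0] > var[1] > var[2] - 1e-12
    assert np.abs(out[:, 2]).max() < 1e-12  # back in the x-y plane


def test_convention_is_idempotent_and_distance_preserving():
    from scipy.spatial.distance import pdist

    frame = frame_for_group("C2v")
    group = build_group("C2v")
    X = frame.coords - frame.coords.mean(axis=0)
    once = apply_axis_convention(X, group)
    twice = apply_axis_convention(once, group)
    assert np.abs(once - twice).max() < 1e-12
    assert np.abs(pdist(once) - pdist(X)).max() < 1e-10


def test_swaps_axes_when_variance_order_is_violated():
    group = build_group("D2h")
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 3)) * [1.0, 2.0, 0.5]
    X -= X.mean(axis=0)
    out = apply_axis_convention(X, group)
    var = out.var(axis=0)
    assert var[0] >= var[1] >= var[2]
    from scipy.spatial.distance import pdist

    assert np.abs(pdist(out) - pdist(X)).max() < 1e-10


def test_variance_tie_warns_and_keeps_order():
    group = build_group("D2h")
    X = np.array(
        [[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0],
         [0, 0, 0.5], [0, 0, -0.5]]
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        out = apply_axis_convention(X, group)
    assert any("tie" in str(w.message) for w in caught)
    assert np.abs(out - X).max() < 1e-12
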