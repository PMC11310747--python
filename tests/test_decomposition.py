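"""The decomposition pipeline: zeros, linearity, invariance, degenerate
orientation handling, reconstruction."""

import numpy as np
import pytest

from symcoord.decomposition import decompose, reported_degenerate_pair
from symcoord.errors import ValidationError
from symcoord.fixtures import (
    frame_for_group,
    make_pattern,
    random_irrep_pattern,
    sample_collection,
)
from symcoord.groups import build_group
from symcoord.model import build_model

from conftest import NONTRIVIAL_GROUPS, rigid_motion


@pytest.mark.parametrize("name", NONTRIVIAL_GROUPS)
def test_ideal_frames_have_zero_magnitudes(name, frames, models):
    res = decompose(frames[name], models[name])
    assert max(res.magnitudes.values()) < 1e-8
    assert res.reconstruction_residual < 1e-10


@pytest.mark.parametrize("name", NONTRIVIAL_GROUPS)
def test_linearity_of_single_irrep_distortions(name, frames, models):
    frame, model = frames[name], models[name]
    group = build_group(name)
    for row in group.dissymmetric_irreps():
        try:
            pat = random_irrep_pattern(frame, group, row.label, seed=3)
        except ValidationError:
            continue  # irrep has no non-rigid content on this frame
        mags = {}
        for a in (0.25, 0.5):
            mol = frame.with_coords(frame.coords + a * pat.vectors)
            res = decompose(mol, model)
            got = res.magnitudes[row.label]
            want = a * pat.atom_norm_sum
            assert got == pytest.approx(want, rel=1e-8), (name, row.label, a)
            others = max(
                v for k, v in res.magnitudes.items() if k != row.label
            )
            assert others < 1e-8, (name, row.label)
            mags[a] = got
        # doubling the amplitude doubles the magnitude
        assert mags[0.5] == pytest.approx(2.0 * mags[0.25], rel=1e-9)


def test_no_model_path_zeroes_the_totally_symmetric_mode(anthracene):
    group = build_group("D2h")
    pat = random_irrep_pattern(anthracene, group, "Au", seed=1)
    mol = anthracene.with_coords(anthracene.coords + 0.4 * pat.vectors)
    res = decompose(mol, "D2h")
    assert not res.model_used
    assert res.totally_symmetric_mode.magnitude == 0.0
    assert res.magnitudes["Au"] == pytest.approx(
        0.4 * pat.atom_norm_sum, rel=1e-6
    )
    assert res.reconstruction_residual < 1e-8


def test_c1_with_model_is_a_plain_difference_of_vectors():
    frame = frame_for_group("C1")
    model = build_model(frame, "C1", name="c1_model")
    rng = np.random.default_rng(8)
    disp = rng.normal(0, 0.1, frame.coords.shape)
    disp -= disp.mean(axis=0)
    mol = frame.with_coords(frame.coords - frame.coords.mean(axis=0) + disp)
    res = decompose(mol, model)
    want = np.linalg.norm(res.aligned_coords - model.coords, axis=1).sum()
    assert res.magnitudes["A"] == pytest.approx(want, abs=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_magnitudes_invariant_under_rigid_motion_and_shuffle(
    seed, anthracene, anthracene_model
):
    group = build_group("D2h")
    p1 = random_irrep_pattern(anthracene, group, "Au", seed=1)
    p2 = random_irrep_pattern(anthracene, group, "B1u", seed=2)
    base = anthracene.coords + 0.5 * p1.vectors + 0.2 * p2.vectors
    ref = decompose(anthracene.with_coords(base), anthracene_model).magnitudes
    rng = np.random.default_rng(seed)
    moved = rigid_motion(base, rng)
    perm = rng.permutation(len(base))
    shuffled = anthracene.with_coords(moved).permuted(perm)
    mags = decompose(shuffled, anthracene_model).magnitudes
    assert max(abs(mags[k] - ref[k]) for k in ref) < 1e-6


@pytest.mark.parametrize("name", NONTRIVIAL_GROUPS)
def test_reconstruction_of_random_distortions(name, frames, models):
    frame, model = frames[name], models[name]
    group = build_group(name)
    limit = 1e-6 if any(r.is_degenerate for r in group.irreps) else 1e-8
    rng = np.random.default_rng(99)
    for _ in range(5):
        mol = frame.with_coords(
            frame.coords + rng.normal(0, 0.08, frame.coords.shape)
        )
        res = decompose(mol, model)
        assert res.reconstruction_residual < limit


def test_mode_component_orthogonality(anthracene, anthracene_model):
    rng = np.random.default_rng(12)
    mol = anthracene.with_coords(
        anthracene.coords + rng.normal(0, 0.1, anthracene.coords.shape)
    )
    res = decompose(mol, anthracene_model)
    flats = {m.irrep: m.flattened() for m in res.modes}
    labels = list(flats)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            va, vb = flats[a], flats[b]
            na, nb = np.linalg.norm(va), np.linalg.norm(vb)
            if na < 1e-12 or nb < 1e-12:
                continue
            assert abs(va @ vb) / (na * nb) < 1e-9


# --- degenerate irreps ------------------------------------------------------


def test_pure_x_variant_distortion_reports_x_primary(frames, models):
    frame, model = frames["D4h"], models["D4h"]
    group = build_group("D4h")
    pat = random_irrep_pattern(frame, group, "Eu", seed=6, orientation_angle=0.0)
    mol = frame.with_coords(frame.coords + 0.5 * pat.vectors)
    res = decompose(mol, model)
    primary, secondary = res.mode("Eu"), None
    eu_modes = [m for m in res.modes if m.irrep == "Eu"]
    assert len(eu_modes) == 2
    primary, secondary = eu_modes
    # the reported pair is an orthogonal (0/90 or 45/135) couple with the
    # distortion concentrated in the primary
    assert abs(primary.angle - secondary.angle) % 180.0 == 90.0
    assert primary.magnitude == pytest.approx(0.5 * pat.atom_norm_sum, rel=1e-6)
    assert secondary.magnitude < 1e-8


def test_diagonal_distortion_reports_the_diagonal_pair(frames, models):
    frame, model = frames["D4h"], models["D4h"]
    group = build_group("D4h")
    pat = random_irrep_pattern(frame, group, "Eu", seed=6, orientation_angle=45.0)
    mol = frame.with_coords(frame.coords + 0.5 * pat.vectors)
    res = decompose(mol, model)
    eu_modes = [m for m in res.modes if m.irrep == "Eu"]
    # alignment may settle in any group-equivalent orientation; the primary
    # variant must carry the full magnitude either way
    assert eu_modes[0].magnitude == pytest.approx(
        0.5 * pat.atom_norm_sum, rel=1e-6
    )
    assert eu_modes[1].magnitude < 1e-8


def test_reported_pair_requires_complete_variant_list(frames, models):
    frame, model = frames["D4h"], models["D4h"]
    rng = np.random.default_rng(3)
    mol = frame.with_coords(frame.coords + rng.normal(0, 0.05, frame.coords.shape))
    res = decompose(mol, model)
    variants = res.variants["Eu"]
    primary, secondary = reported_degenerate_pair(variants)
    assert abs(primary.angle - secondary.angle) % 180.0 == 90.0
    assert primary.magnitude >= max(v.magnitude for v in variants) - 1e-12
    with pytest.raises(ValidationError, match="incomplete"):
        reported_degenerate_pair(variants[:1])
    with pytest.raises(ValidationError):
        reported_degenerate_pair([])


def test_half_weighted_variant_sum_reconstructs_with_model(frames, models):
    frame, model = frames["D4h"], models["D4h"]
    group = build_group("D4h")
    rng = np.random.default_rng(21)
    mol = frame.with_coords(frame.coords + rng.normal(0, 0.08, frame.coords.shape))
    res = decompose(mol, model)
    recon = model.coords + res.totally_symmetric_mode.vectors
    seen = set()
    for row in group.dissymmetric_irreps():
        if row.is_degenerate:
            if row.label in seen:
                continue
            seen.add(row.label)
            vsum = np.sum([v.vectors for v in res.variants[row.label]], axis=0)
            recon = recon + row.reconstruction_weight * vsum
        else:
            recon = recon + res.mode(row.label).vectors
    assert np.abs(recon - res.aligned_coords).max() < 1e-9


# --- named pattern sanity ---------------------------------------------------


def test_named_twist_form_is_pure_au_on_anthracene(anthracene):
    pat = make_pattern(anthracene, "D2h", "Au", "twist")
    assert pat.irrep == "Au"
    assert np.linalg.norm(pat.vectors) == pytest.approx(1.0, abs=1e-12)


def test_breathing_form_is_totally_symmetric(anthracene):
    pat = make_pattern(anthracene, "D2h", "Ag", "breathing")
    assert pat.irrep == "Ag"


def test_form_orthogonal_to_irrep_is_rejected(anthracene):
    with pytest.raises(ValidationError):
        make_pattern(anthracene, "D2h", "B3u", "twist")


def test_sample_collection_is_deterministic_and_truthful(anthracene):
    group = build_group("D2h")
    pat = random_irrep_pattern(anthracene, group, "Au", seed=1)
    mols1, truth1 = sample_collection(anthracene, [pat], [0.5], 0.01, 5, seed=4)
    mols2, truth2 = sample_collection(anthracene, [pat], [0.5], 0.01, 5, seed=4)
    for a, b in zip(mols1, mols2):
        assert np.abs(a.coords - b.coords).max() == 0.0
    assert all(
        np.array_equal(truth1[k]["coefficients"], truth2[k]["coefficients"])
        for k in truth1
    )
    with pytest.raises(ValidationError):
        sample_collection(anthracene, [pat], [0.5], -0.1, 5, seed=4)
    with pytest.raises(ValidationError):
        sample_collection(anthracene, [pat], [0.5], 0.01, 0, seed=4)
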