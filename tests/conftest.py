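"""Shared fixtures: symmetric frames and prebuilt models per point group.

Everything is generated programmatically; model building (the expensive
orientation + symmetrization step) is done once per session.
"""

import warnings

import numpy as np
import pytest

from symcoord.fixtures import frame_for_group
from symcoord.groups import build_group
from symcoord.model import build_model

NONTRIVIAL_GROUPS = ("C2v", "C2h", "D2d", "D2h", "D3h", "D4h", "D6h")


@pytest.fixture(scope="session")
def frames():
    return {g: frame_for_group(g) for g in NONTRIVIAL_GROUPS}


@pytest.fixture(scope="session")
def models(frames):
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g, frame in frames.items():
            out[g] = build_model(frame, build_group(g), name=f"{g}_fixture")
    return out


@pytest.fixture(scope="session")
def anthracene(frames):
    return frames["D2h"]


@pytest.fixture(scope="session")
def anthracene_model(models):
    return models["D2h"]


def rigid_motion(coords: np.ndarray, rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-5.0, 5.0, 3)
    return coords @ R.T + t
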