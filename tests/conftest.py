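"""Shared fixtures: synthetic scenes with ground truth."""

import numpy as np
import pytest

from lhckit.membrane_geometry import MembraneFrame
from lhckit.synthetic_data import (
    HelixSpec, BundleSpec, SceneSpec, MacrocyclePlacement,
    core_belt_scene, make_bundle, make_scene, make_subfamily_analogs,
)
from lhckit.structure_io import MolecularModel


@pytest.fixture(scope="session")
def flat_frame() -> MembraneFrame:
    return MembraneFrame(np.array([0.0, 0.0, 1.0]), np.zeros(3), 1)


@pytest.fixture(scope="session")
def core_belt():
    """Core(48 Å) + 6 belt(31 Å) ring scene with truth and annotation."""
    model, truth, anns = make_scene(core_belt_scene())
    return model, truth, anns


@pytest.fixture(scope="session")
def three_helix_bundle():
    """One chain, three straight vertical helices at known heights."""
    spec = BundleSpec(helices=[
        HelixSpec(length=25, anchor=(0.0, 0.0)),
        HelixSpec(length=30, anchor=(12.0, 0.0), phase_deg=120.0),
        HelixSpec(length=21, anchor=(0.0, 12.0), phase_deg=240.0),
    ], chain_id="A")
    atoms, truths = make_bundle(spec)
    return MolecularModel("bundle3", atoms), truths


@pytest.fixture(scope="session")
def analogs():
    """Subfamily analogs with simulated maps at 5 and 15 Å."""
    return make_subfamily_analogs(resolutions=(5.0, 15.0))


@pytest.fixture(scope="session")
def ring_pair_scene():
    """Three macrocycles: constrained 6.0 Å pair + one lumenal chl c."""
    spec = SceneSpec(bundles=[], macrocycles=[
        MacrocyclePlacement(center=(0.0, 0.0, 4.0)),
        MacrocyclePlacement(center=(12.0, 0.0, 4.0), target_partner=0,
                            target_edge_to_edge=6.0),
        MacrocyclePlacement(center=(0.0, 14.0, -5.0), kind="chl_c"),
    ])
    return make_scene(spec)


def random_rigid(rng: np.random.Generator):
    """A uniformly random rotation + bounded translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50.0, 50.0, size=3)
    return R, t
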