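import numpy as np
import pytest

from surfcraft import (PatchScorer, make_two_helix_complex, select_interface,
                       sphere_cloud)


@pytest.fixture(scope="session")
def toy_complex():
    """Deterministic two-helix complex with a 3-residue designed interface
    (LEU/LYS/ASP) plus whatever else the C-beta rule selects."""
    return make_two_helix_complex(seed=0)


@pytest.fixture(scope="session")
def toy_interface(toy_complex):
    target, binder = toy_complex
    return select_interface(target, binder)


@pytest.fixture(scope="session")
def toy_patch_scorer(toy_complex, toy_interface):
    """Similarity scorer for the toy interface patch, bound context,
    reference = the native interface surface."""
    target, binder = toy_complex
    scorer = PatchScorer(reference=None,
                         patch_residues=set(toy_interface.positions),
                         objective="similarity", context=binder,
                         density=2.0)
    scorer.reference = scorer.patch_cloud(target)
    return scorer


@pytest.fixture()
def unit_sphere_cloud():
    return sphere_cloud(n=400, radius=5.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
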