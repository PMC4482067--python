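import numpy as np
import pytest

from rnapivot.structure_io import StructureModel
from rnapivot.synthetic import HingeSpec, make_aform_duplex, make_hinge_pair


@pytest.fixture(scope="session")
def duplex10():
    return make_aform_duplex(10)


@pytest.fixture
def hinge_factory():
    def make(n_stem=6, n_arm=12, theta=10.0, sigma=0.0, seed=0, motif="none",
             **kw):
        spec = HingeSpec(n_stem=n_stem, n_arm=n_arm, hinge_angle_deg=theta,
                         noise_sigma=sigma, seed=seed, motif_at_pivot=motif,
                         **kw)
        return make_hinge_pair(spec)
    return make


def two_helix_model(n_static=30, theta=15.0, sigma=0.0, seed=0):
    """One clearly static helix (chain S) plus one hinged helix (chain M),
    the hinged one a small fraction of the total so outlier rejection can
    lock the global fit onto the static frame."""
    static = make_aform_duplex(n_static)
    for res in static.chains["A"]:
        res.chain_id = "S"
        for atom in res.atoms:
            atom.position = atom.position + np.array([45.0, 0.0, 0.0])
    a, b, truth = make_hinge_pair(HingeSpec(
        n_stem=6, n_arm=8, hinge_angle_deg=theta, noise_sigma=sigma, seed=seed))
    for model in (a, b):
        for res in model.chains["A"]:
            res.chain_id = "M"
    model_a = StructureModel("two_helix_a",
                             {"S": static.chains["A"], "M": a.chains["A"]})
    model_b = StructureModel("two_helix_b",
                             {"S": static.copy().chains["A"], "M": b.chains["A"]})
    return model_a, model_b, truth


@pytest.fixture
def screen_pair():
    return two_helix_model()
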