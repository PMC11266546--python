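import numpy as np
import pytest

from ddgformer import BackboneConfig, GraphTransformerBackbone, StabilityModel
from ddgformer.microenv import build_masked_microenv
from ddgformer.structure_io import assign_partial_charges, compute_sasa
from ddgformer.synthetic import SyntheticSpec, make_helix_structure


@pytest.fixture(scope="session")
def helix():
    """20-residue featurized helix (charges + SASA assigned)."""
    spec = SyntheticSpec(seed=7, n_residues=20)
    st = make_helix_structure(spec, structure_id="helix20")
    assign_partial_charges(st)
    compute_sasa(st)
    return st


@pytest.fixture(scope="session")
def env(helix):
    return build_masked_microenv(helix, "A", 10)


@pytest.fixture(scope="session")
def desk_backbone():
    return GraphTransformerBackbone(BackboneConfig.desk(), seed=0)


@pytest.fixture(scope="session")
def desk_model(desk_backbone):
    model = StabilityModel(desk_backbone, n_head_blocks=1, seed=0)
    model.eval()
    return model


def rigid_motion(rng):
    """Random rotation matrix + translation vector."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q, rng.normal(scale=10.0, size=3)
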