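import numpy as np
import pytest

from jointline.frame import FrameConfig, build_frame
from jointline.synthetic import FemurSpec, build_landmarks, build_mesh

#: cohort means of the five distances (mm) used throughout as the reference femur
TABLE_MEANS = dict(ml=75.1, me_fj=29.4, le_fj=21.2, me_ej=25.1, le_ej=21.3)


@pytest.fixture(scope="session")
def reference_spec():
    return FemurSpec(**TABLE_MEANS, side="right", seed=1)


@pytest.fixture(scope="session")
def reference_landmarks(reference_spec):
    return build_landmarks(reference_spec)


@pytest.fixture(scope="session")
def clean_mesh(reference_spec):
    """Noise-free canonical-frame mesh at moderate resolution, built once."""
    mesh, truth = build_mesh(reference_spec)
    return mesh, truth


@pytest.fixture(scope="session")
def clean_frame(clean_mesh, reference_spec):
    mesh, _ = clean_mesh
    return build_frame(mesh, reference_spec.side, FrameConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240602)
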