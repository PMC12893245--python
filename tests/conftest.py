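import numpy as np
import pytest

from nepscreen import load_example_model
from nepscreen.pharmacophore import (
    FeatureKind,
    PharmacophoreFeature,
    PharmacophoreModel,
)


@pytest.fixture(scope="session")
def example_model():
    return load_example_model()


@pytest.fixture
def toy_model():
    """Small 2-HBA + 1-AR model used for brute-force oracle checks."""
    return PharmacophoreModel(
        name="toy",
        features=[
            PharmacophoreFeature("a1", FeatureKind.HBA, np.array([0.0, 0.0, 0.0]), 1.5),
            PharmacophoreFeature("a2", FeatureKind.HBA, np.array([3.0, 0.5, 0.0]), 1.5),
            PharmacophoreFeature("r1", FeatureKind.AR, np.array([1.5, 2.5, 1.0]), 1.5),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
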