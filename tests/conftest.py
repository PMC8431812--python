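import math

import pytest

from eecfold.gibbs_surface import BallAtom, BallModel, GibbsParams
from eecfold.harness.fixtures import generate_corpus
from eecfold.ss_predict import PredictorParams


@pytest.fixture(scope="session")
def default_params() -> PredictorParams:
    return PredictorParams()


@pytest.fixture(scope="session")
def synthetic_corpus():
    """200 clean multi-motif sequences with true labels (fixed seed)."""
    return generate_corpus(200, seed=11)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(30, seed=5)


@pytest.fixture
def two_ball_hydrophobic() -> BallModel:
    """Overlapping all-hydrophobic pair used by force/relax tests."""
    return BallModel(
        atoms=(
            BallAtom(center=(0.0, 0.0, 0.0), radius=3.2, hclass=1),
            BallAtom(center=(6.0, 0.0, 0.0), radius=3.2, hclass=1),
        ),
        class_count=2,
    )


@pytest.fixture
def toy_gibbs_params() -> GibbsParams:
    return GibbsParams(omega=(0.05, -0.05))


def lens_area_volume(r: float, d: float):
    """Closed-form union area/volume of two equal overlapping spheres.

    Independent oracle: each sphere loses a spherical cap of height
    h = r - d/2; the lens volume follows the standard two-sphere formula.
    """
    assert 0 < d < 2 * r
    h = r - d / 2.0
    area = 2.0 * (4.0 * math.pi * r * r - 2.0 * math.pi * r * h)
    volume = 2.0 * (4.0 / 3.0) * math.pi * r**3 - (math.pi / 12.0) * (
        4.0 * r + d
    ) * (2.0 * r - d) ** 2
    return area, volume
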