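import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from haplomap import DiploidGenotype, MarkerMap
from haplomap.synthetic_data import screen_map, screen_mother

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_locus_map() -> MarkerMap:
    """Lethal / focal-locus map at the screen's 0.57 cM distance."""
    return screen_map(0.0057)


@pytest.fixture
def screen_mom(two_locus_map) -> DiploidGenotype:
    return screen_mother(two_locus_map)


@pytest.fixture
def five_marker_map() -> MarkerMap:
    return MarkerMap(
        [(f"M{i + 1}", (i + 1) * 10_000, i * 0.1) for i in range(5)],
        scaffold="scaffold_23",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20100115)
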