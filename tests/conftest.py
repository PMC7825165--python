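import numpy as np
import pytest
from hypothesis import settings

from cnvpop import GenomeLayout, PopulationDesign, make_layout

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_layout() -> GenomeLayout:
    return make_layout([("chr1", 200_000), ("chr2", 100_000)], 100)


@pytest.fixture
def two_group_design():
    """Factory for an 8-vs-8 two-group cohort design."""

    def build(seed: int = 11, **overrides) -> PopulationDesign:
        params = dict(
            individuals=tuple(
                (f"s{i:02d}", "horned" if i < 8 else "polled") for i in range(16)
            ),
            seed=seed,
            n_shared_cnvs=6,
            n_group_specific_cnvs=1,
        )
        params.update(overrides)
        return PopulationDesign(**params)

    return build


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
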