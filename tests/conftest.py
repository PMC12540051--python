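import numpy as np
import pytest

from agscope import (
    BandDefinitions,
    CommunitySimSpec,
    SpectrumSimSpec,
    gen_community,
    gen_spectrum,
)


@pytest.fixture(scope="session")
def bands() -> BandDefinitions:
    return BandDefinitions()


@pytest.fixture(scope="session")
def clean_spectrum_30():
    """Noise-free spectrum encoding a true %CD of 30."""
    return gen_spectrum(SpectrumSimSpec(cd_fraction_true=30.0), cell_id="c30")


@pytest.fixture(scope="session")
def planted_community():
    """10-donor table with genera 1-3 enriched 4-fold in treated samples."""
    return gen_community(
        CommunitySimSpec(
            n_donors=10,
            n_genera=30,
            depth=50_000,
            enriched_genera=frozenset({1, 2, 3}),
            effect_multiplier=4.0,
            seed=11,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
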