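import numpy as np
import pytest
from hypothesis import settings

from panelseq.simulate import SimulationParams, generate_panel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_panel():
    """10 genes, 30 amplicons, deterministic; returns (panel, reference)."""
    return generate_panel(10, 30, (80, 160), seed=11)


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(11)


def make_call(**kwargs):
    """VariantCall with sensible defaults for filter tests."""
    from panelseq.variants import VariantCall

    defaults = dict(
        chrom="chr_KRAS",
        pos=100,
        ref="C",
        alt="T",
        total_depth=1000,
        alt_depth=300,
        sample_id="S1",
        consequence="missense",
        gene="KRAS",
    )
    defaults.update(kwargs)
    return VariantCall(**defaults)
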