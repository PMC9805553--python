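import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sylpbwt.panel import HaplotypePanel
from sylpbwt.synthetic_data import PanelSpec, generate_panel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def ld_panel_small() -> HaplotypePanel:
    """A 30 x 800 mosaic panel with clear linkage-disequilibrium blocks."""
    return generate_panel(
        PanelSpec(M=30, N=800, founders=4, switch_rate=0.01, mut_rate=0.002, seed=11)
    )


@pytest.fixture
def identical_panel() -> HaplotypePanel:
    """40 copies of the same haplotype (degenerate, maximally compressible)."""
    rng = np.random.default_rng(5)
    row = rng.integers(0, 2, 96, dtype=np.uint8)
    return HaplotypePanel(np.tile(row, (40, 1)))
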