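import numpy as np
import pytest

from btrefuge.engine import SimConfig
from btrefuge.landscape import GridGeometry, LayoutSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20230701)


@pytest.fixture
def default_geom():
    """The full-scale 25 ha grid: 50x50 ground under 10x10 sky."""
    return GridGeometry()


@pytest.fixture
def tiny_config():
    """A 1 ha desk-scale configuration (10x10 ground, 2x2 sky)."""
    def make(**overrides):
        defaults = dict(
            horizon_days=60,
            warmup_days=0,
            geometry=GridGeometry(total_area_ha=1),
            layout=LayoutSpec("single_block", 0.2),
            init_batches=2,
            batch_size=200,
            seed=7,
        )
        defaults.update(overrides)
        return SimConfig(**defaults)

    return make
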