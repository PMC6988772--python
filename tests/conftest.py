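import numpy as np
import pytest

from mscmorph.rendering import RenderConfig, render_field
from mscmorph.segment import (exclude_border_pair, segment_cells,
                              segment_nuclei)
from mscmorph.synth import EffectConfig, generate_cohort


@pytest.fixture(scope="session")
def default_donor():
    """First donor of the default cohort (seeded)."""
    return generate_cohort(EffectConfig(n_donors=4, seed=3))[0]


@pytest.fixture(scope="session")
def rendered_field(default_donor):
    """One rendered field with ground truth (shared, read-only)."""
    return render_field(default_donor, 0, seed=3)


@pytest.fixture(scope="session")
def segmented_field(rendered_field):
    """Segmentation of the shared field after border exclusion."""
    field, _ = rendered_field
    nuclei = segment_nuclei(field.channels["dapi"])
    cells = segment_cells(field.channels["tubulin"], nuclei)
    cells, nuclei = exclude_border_pair(cells, nuclei)
    return cells, nuclei


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_render_config():
    return RenderConfig(shape=(384, 384), cells_per_field=5)
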