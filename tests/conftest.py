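import numpy as np
import pytest

from spheromorph.morphometry import Volume3D


@pytest.fixture(scope="session")
def raster_ball():
    """Binary ball of radius 20 voxels at 0.5 mm/voxel."""
    r = 20
    ax = np.arange(-r - 2, r + 3)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return Volume3D((x * x + y * y + z * z) <= r * r, 0.5), r


@pytest.fixture(scope="session")
def proneural_timecourse():
    """Measured morphometry of a proneural-like culture (shared fixture)."""
    from spheromorph.morphometry import measure_table
    from spheromorph.synthetic import (
        PRONEURAL_LIKE, generate_biosphere_timecourse)

    tc = generate_biosphere_timecourse(
        PRONEURAL_LIKE, 120, [1.0, 7.0, 14.0, 18.0], seed=0)
    masks = [m for t in tc.masks for m in tc.masks[t]]
    return tc, measure_table(masks)
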