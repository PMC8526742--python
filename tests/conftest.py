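import math

import numpy as np
import pytest

from ablaquant.calibration import fit_two_point

# water / pure-ethanol reference radiodensities used throughout
WATER_HU = -66.5
ETHANOL_HU = -340.3


@pytest.fixture
def reference_model():
    """Two-point calibration from the water/ethanol reference means."""
    return fit_two_point(WATER_HU, ETHANOL_HU)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def brute_force_distribution_metrics(mask, spacing):
    """Independent plain-Python summation of the distribution metrics.

    Exhaustively enumerates voxels and accumulates with scalar arithmetic;
    shares no code with the implementation under test.
    """
    coords = []
    nz, ny, nx = mask.shape
    for i in range(nz):
        for j in range(ny):
            for k in range(nx):
                if mask[i, j, k]:
                    coords.append((i * spacing[0], j * spacing[1], k * spacing[2]))
    n = len(coords)
    voxvol = spacing[0] * spacing[1] * spacing[2]
    volume = n * voxvol
    if n == 0:
        return volume, None, math.nan, math.nan
    centroid = tuple(sum(c[a] for c in coords) / n for a in range(3))
    rg = sum(math.dist(c, centroid) for c in coords) / n
    r_eff = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return volume, centroid, rg, rg / r_eff
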