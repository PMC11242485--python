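import numpy as np
import pytest
from scipy.spatial.distance import cdist

from goldx import GoldXParams, build_template

# canonical acquisition parameters: 10 nm beads imaged at 4.59 A/px
PIXEL_SIZE_A = 4.59
BEAD_NM = 10.0


@pytest.fixture
def params():
    return GoldXParams(pixel_size_angstrom=PIXEL_SIZE_A,
                       bead_diameter_nm=BEAD_NM, seed=0)


@pytest.fixture
def template():
    return build_template(PIXEL_SIZE_A, BEAD_NM)


@pytest.fixture
def small_template():
    # 3 px bead radius: cheap enough for brute-force oracles
    return build_template(10.0, 6.0)


def match_markers(markers, centers, tol=2.0):
    """Match detected markers to true centers within ``tol`` px.

    Returns ``(tp, fp, fn)``: markers with a true center within tol, markers
    without one, and true centers with no marker within tol.
    """
    if len(markers) == 0:
        return 0, 0, len(centers)
    if len(centers) == 0:
        return 0, len(markers), 0
    d = cdist(markers[["y", "x"]].to_numpy(), centers[["y", "x"]].to_numpy())
    tp = int((d.min(axis=1) <= tol).sum())
    fp = len(markers) - tp
    fn = int((d.min(axis=0) > tol).sum())
    return tp, fp, fn
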