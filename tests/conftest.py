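import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from spectscore.imaging import ShortAxisVolume, Tracer
from spectscore.scoring import build_segment_mask
from spectscore.synthetic import Defect, PhantomSpec, make_phantom


def annulus_volume(
    n_slices: int = 8,
    size: int = 48,
    r_mid: float = 15.0,
    sigma: float = 5.0,
    peak: float = 100.0,
    sector_scale=None,
    voxel: float = 1.0,
) -> ShortAxisVolume:
    """Cylindrical annulus phantom: same wall radius on every slice.

    ``sector_scale(angle_deg) -> factor`` optionally modulates counts by
    voxel angle (angle 0 = anterior = toward row 0, counterclockwise
    through septal).
    """
    c = (size - 1) / 2.0
    rows = (np.arange(size) - c) * voxel
    rr, cc = np.meshgrid(rows, rows, indexing="ij")
    rho = np.hypot(rr, cc)
    angle = np.degrees(np.arctan2(-cc, -rr)) % 360.0
    sl = peak * np.exp(-((rho - r_mid) ** 2) / (2 * sigma**2))
    if sector_scale is not None:
        sl = sl * sector_scale(angle)
    counts = np.repeat(sl[None], n_slices, axis=0)
    return ShortAxisVolume(counts=counts, voxel_size_mm=(voxel, voxel, voxel))


@pytest.fixture(scope="session")
def default_mask():
    return build_segment_mask(36, 60)


@pytest.fixture(scope="session")
def fine_phantom_spec():
    """1 mm in-plane phantom used for quantitative uptake checks."""
    return PhantomSpec(grid=(96, 96), voxel_size_mm=(3.2, 1.0, 1.0))


@pytest.fixture(scope="session")
def defect_spec_covering_mid_anteroseptal():
    """5 % severity defect fully covering segment 8 (with margins)."""
    return PhantomSpec(
        defects=(Defect(center_deg=60.0, width_deg=90.0, span=(0.30, 0.70), severity=0.05),)
    )
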