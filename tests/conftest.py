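import numpy as np
import pytest

from memriq.core import ImageVolume, LabelMap
from memriq.phantom import PhantomSpec


@pytest.fixture
def small_spec() -> PhantomSpec:
    """Acquisition-resolution voxels on a reduced matrix: fast but geometrically
    faithful (annulus radii small relative to FOV)."""
    return PhantomSpec(grid_shape=(72, 66, 6), voxel_size=(28.0 / 120.0, 25.0 / 110.0, 0.8))


@pytest.fixture
def full_spec() -> PhantomSpec:
    """Full acquisition matrix 120 x 110 x 10, FOV 28 x 25 x 8 mm³."""
    return PhantomSpec()


@pytest.fixture
def tiny_labels() -> LabelMap:
    """Hand-built 4x4x1 label map: 2 septal + 2 lateral myocardium voxels."""
    tissue = np.zeros((4, 4, 1), dtype=np.int16)
    sector = np.zeros((4, 4, 1), dtype=np.int16)
    tissue[1, 1, 0] = tissue[1, 2, 0] = 2
    sector[1, 1, 0] = sector[1, 2, 0] = 1  # septal
    tissue[2, 1, 0] = tissue[2, 2, 0] = 2
    sector[2, 1, 0] = sector[2, 2, 0] = 2  # lateral
    tissue[0, 0, 0] = 1  # one cavity voxel
    return LabelMap(tissue=tissue, voxel_size=(1.0, 1.0, 1.0), sector=sector)


def volume_like(labels: LabelMap, values: np.ndarray) -> ImageVolume:
    return ImageVolume(np.asarray(values, dtype=float), labels.voxel_size)
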