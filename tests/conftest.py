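import numpy as np
import pytest

from recipet.delineation import (
    Delineation,
    DelineationSource,
    LabelMap,
    lesion_stats,
)
from recipet.imaging import PetVolume


@pytest.fixture
def make_volume():
    """Factory: PetVolume from an array (default 2 mm isotropic)."""

    def _make(values, spacing=(2.0, 2.0, 2.0), origin=(0.0, 0.0, 0.0)):
        return PetVolume(np.asarray(values, dtype=float), spacing, origin)

    return _make


@pytest.fixture
def make_delineation(make_volume):
    """Factory: Delineation from a label array and matching SUV array."""

    def _make(labels, suv=None, spacing=(2.0, 2.0, 2.0), source=DelineationSource.TRUTH):
        labels = np.asarray(labels, dtype=np.int32)
        if suv is None:
            suv = np.where(labels > 0, 5.0, 0.2)
        volume = make_volume(suv, spacing=spacing)
        labelmap = LabelMap(labels, volume)
        return Delineation(labelmap, lesion_stats(labelmap, volume), source=source)

    return _make
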