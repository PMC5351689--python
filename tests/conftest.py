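import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import sstrtex as sx


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_suv_phantom(diameter_mm=30.0, spacing=(2.0, 2.0, 2.0), texture="correlated_field",
                     heterogeneity=0.5, seed=0, weight=70.0, injected=140.0):
    """Generate a phantom and return (SUV volume, mask)."""
    vol, mask = sx.generate_lesion_image(
        sx.PhantomSpec(
            diameter_mm=diameter_mm,
            spacing_mm=spacing,
            texture_model=texture,
            heterogeneity_level=heterogeneity,
            seed=seed,
        )
    )
    vol = replace(vol, patient_weight_kg=weight, injected_activity_MBq=injected)
    return sx.to_suv(vol), mask


@pytest.fixture
def suv_phantom():
    return make_suv_phantom()


def random_levels(rng, shape, ng, p_mask=0.8):
    """Random discretized lesion grid with every level guaranteed present."""
    from sstrtex.features import DiscretizedLesion

    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < p_mask
    levels[~mask] = 0
    if not (levels > 0).any():
        levels.flat[0] = 1
    return DiscretizedLesion(levels=levels, n_levels=ng, bin_edges=np.linspace(0, 1, ng + 1))
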