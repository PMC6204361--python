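import numpy as np
import pytest

from isletquant.perifusion import SamplingGrid, build_sampling_grid
from isletquant.synthetic import PhantomObject, PhantomSpec


@pytest.fixture(scope="session")
def canonical_grid() -> SamplingGrid:
    return build_sampling_grid(70.0)


@pytest.fixture
def phantom_spec_factory():
    """Factory for centered single-object phantom specs in a 512x512 field."""

    def make(major_um=300.0, minor_um=150.0, orientation=0.0, noise_sd=0.0,
             n_debris=0, seed=0, shape=(9, 512, 512), pixel_size_um=1.0):
        obj = PhantomObject(
            center_xy=(shape[2] / 2.0, shape[1] / 2.0),
            major_axis_um=major_um,
            minor_axis_um=minor_um,
            orientation_rad=orientation,
        )
        return PhantomSpec(
            image_shape=shape,
            pixel_size_um=pixel_size_um,
            objects=(obj,),
            n_debris=n_debris,
            noise_sd=noise_sd,
            seed=seed,
        )

    return make
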