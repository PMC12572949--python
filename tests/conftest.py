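import numpy as np
import pytest

from cartizone.synth import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def flat_constant_phantom():
    """38.4 mm wide, constant 3.0 mm thick, flat bone, notch centred."""
    return make_phantom(PhantomSpec(profile=3.0))


@pytest.fixture(scope="session")
def arc_phantom():
    """Convex arc bone R = 20 mm, constant 3.0 mm cartilage."""
    return make_phantom(
        PhantomSpec(profile=3.0, bone_radius=20.0, band_width=30.0,
                    notch_x=15.0)
    )
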