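import numpy as np
import pytest

from capspec.synth import SimulationConfig, steady_program


@pytest.fixture(scope="session")
def short_centerline():
    """Straight 120-px centerline (~78 um at the default pixel size)."""
    return np.array([[4.0, 10.0], [124.0, 10.0]])


@pytest.fixture(scope="session")
def steady_video(short_centerline):
    """10-s dual-wavelength clip of one steadily perfused capillary."""
    from capspec.synth import generate_capillary_video

    cfg = SimulationConfig(
        frame_shape=(20, 130),
        duration=10.0,
        seed=11,
        capillary_programs=[
            steady_program(short_centerline, 200.0, capillary_id="cap1")
        ],
    )
    return generate_capillary_video(cfg)
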