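import numpy as np
import pytest

from miop import SimConfig, simulate
from miop.airpuff_simulator import render_frame_image


@pytest.fixture(scope="session")
def sim16():
    """A noise-free, perfectly centered simulated eye at 16 mmHg."""
    return simulate(SimConfig(iop=16.0, noise_sd=0.0, misalign=0.0))


@pytest.fixture(scope="session")
def rendered_mid_frame(sim16):
    """Noise-free rendering of a mid-deformation frame, truth attached."""
    return render_frame_image(
        sim16.sequence.frames[69], pixel_size=0.02, thickness_px=10
    )


def circle_contour(radius=7.8, half_aperture_mm=None, n=241, frame_index=1):
    """Contour samples on a circle with apex at the origin, z toward the eye."""
    from miop import ContourFrame

    if half_aperture_mm is None:
        half_aperture_mm = radius * np.sin(0.6)  # spans theta in [-0.6, 0.6]
    x = np.linspace(-half_aperture_mm, half_aperture_mm, n)
    z = radius - np.sqrt(radius**2 - x**2)
    return ContourFrame(frame_index=frame_index, time_ms=0.0, x=x, z=z)
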