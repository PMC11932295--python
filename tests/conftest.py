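import numpy as np
import pytest

from cadmilume import RasterImage, SyntheticPlateSpec, render_plate


def make_disk_image(shape=(120, 130), center=(60.0, 50.0), radius=20.0,
                    rgb=(40, 160, 20), background=0, dtype=np.uint8):
    """A flat-color disk on a uniform background. center is (x, y)."""
    h, w = shape
    img = np.full((h, w, 3), background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    disk = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
    img[disk] = rgb
    return RasterImage(img.astype(dtype))


@pytest.fixture(scope="session")
def noiseless_spec():
    return SyntheticPlateSpec(seed=0, photon_gain=0, read_sd=0, center_jitter=0)


@pytest.fixture(scope="session")
def noiseless_render(noiseless_spec):
    return render_plate(noiseless_spec)


@pytest.fixture(scope="session")
def seeded_render():
    spec = SyntheticPlateSpec(seed=1)
    image, truth = render_plate(spec)
    return spec, image, truth
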