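import numpy as np
import pytest

from sili.crypto import KeyMaterial
from sili.phantom import PhantomSpec, generate_logo, generate_patient_record, \
    generate_phantom_ct
from sili.pipeline import run_sender
from sili.segmentation import detect_roni

HEX_KEY = "A1B2C3D4E5F60718"


@pytest.fixture(scope="session")
def phantom7():
    """Default 256x256 phantom, seed 7 — the workhorse fixture."""
    return generate_phantom_ct(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def roni7(phantom7):
    return detect_roni(phantom7.image)


@pytest.fixture(scope="session")
def logo16():
    return generate_logo(16, 16, seed=3)


@pytest.fixture(scope="session")
def keys():
    return KeyMaterial.from_hex(HEX_KEY, scan_number=5, image_number=12)


@pytest.fixture(scope="session")
def record24():
    return generate_patient_record(24, seed=5)


@pytest.fixture(scope="session")
def sent7(phantom7, logo16, keys, record24):
    """Full sender output for the seed-7 phantom (index + logo embedded)."""
    return run_sender(phantom7.image, logo16, record24, keys)


@pytest.fixture(scope="session")
def rect_host():
    """Deterministic host with two rectangular dark lobes on bright tissue.

    Lobes at rows 20..80 span columns 10..40 and 60..90 of a 100x100
    frame, so the inter-lobe band is exactly rows 20..80 x cols 41..59
    (19 * 61 = 1159 pixels) — small enough to enumerate by brute force.
    """
    img = np.full((100, 100), 200, dtype=np.uint8)
    img[20:81, 10:41] = 20
    img[20:81, 60:91] = 20
    return img


@pytest.fixture(scope="session")
def rect_roni(rect_host):
    return detect_roni(rect_host)
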