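import numpy as np
import pytest

from retlesion.catalog import ImageMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_example_name():
    return "001_F_GA41_BW2905_PA44_DG2_PF0_RC3_S01_1.jpg"


def random_metadata(rng: np.random.Generator) -> ImageMetadata:
    """Seeded generator of valid metadata records (round-trip fodder)."""
    device = int(rng.integers(1, 4))
    ga = int(rng.integers(20, 46))
    return ImageMetadata(
        patient_id=int(rng.integers(1, 1000)),
        sex=str(rng.choice(["F", "M"])),
        gestational_age_weeks=ga,
        birth_weight_g=int(rng.integers(300, 5001)),
        postconceptual_age_weeks=ga + int(rng.integers(0, 60)),
        diagnosis_code=int(rng.integers(0, 14)),
        plus_form=int(rng.integers(0, 3)),
        device=device,
        device_token={1: "RC3", 2: "RE", 3: "ICON"}[device],
        series=int(rng.integers(1, 30)),
        image_index=int(rng.integers(1, 40)),
    )


@pytest.fixture
def two_region_image(rng):
    """Dark disc (60) on bright background (160) with noise sigma=8."""
    size = 64
    yy, xx = np.ogrid[:size, :size]
    truth = (yy - 32) ** 2 + (xx - 32) ** 2 <= 12**2
    image = np.full((size, size), 160.0)
    image[truth] = 60.0
    image += rng.normal(0, 8, image.shape)
    return image, truth
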