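"""Reference fixtures and recovery benchmarks used by tests and scripts.

The disc fixture is the standard segmentation benchmark: a dark circular
lesion (intensity 60) on a brighter fundus-like background (160) with
optional additive noise, multiplicative inhomogeneity and deterministic
texture.  Seeding convention throughout: the initial contour is a circle
of 0.9 x the true lesion radius at the lesion centre — the clinician's
circle drawn just inside the lesion.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .lgdf import LGDFParams, segment_lesion
from .preprocessing import preprocess_pipeline
from .synthetic import SyntheticSpec, generate_sample

__all__ = ["disc_fixture", "dice", "recover_disc_dice", "filter_comparison"]

SEED_FRACTION = 0.9


def disc_fixture(
    size: int = 128,
    radius: float = 20.0,
    lesion_level: float = 60.0,
    background_level: float = 160.0,
    noise_sigma: float = 8.0,
    inhomogeneity: float = 0.0,
    texture: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disc-lesion benchmark image and its ground-truth mask."""
    rng = np.random.default_rng(seed)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[:size, :size]
    truth = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    image = np.full((size, size), background_level)
    image[truth] = lesion_level
    if texture:
        image = image + texture * np.sin(yy * 0.7) * np.cos(xx * 0.9)
    if inhomogeneity:
        coarse = rng.uniform(-1.0, 1.0, (4, 4))
        fine = ndimage.zoom(coarse, (size / 4, size / 4), order=3)[:size, :size]
        image = image * (1.0 + inhomogeneity * fine / np.abs(fine).max())
    if noise_sigma:
        image = image + rng.normal(0.0, noise_sigma, image.shape)
    return image, truth


def dice(mask: np.ndarray, truth: np.ndarray) -> float:
    denom = mask.sum() + truth.sum()
    return 2.0 * float((mask & truth).sum()) / denom if denom else 1.0


def recover_disc_dice(
    noise_sigma: float = 8.0,
    inhomogeneity: float = 0.0,
    size: int = 128,
    radius: float = 20.0,
    iterations: int = 400,
    seed: int = 0,
) -> float:
    """Segment the disc fixture from the standard seed; return Dice."""
    image, truth = disc_fixture(
        size=size, radius=radius, noise_sigma=noise_sigma,
        inhomogeneity=inhomogeneity, seed=seed,
    )
    c = (size - 1) // 2
    params = LGDFParams(
        seed_center=(c, c), seed_radius=SEED_FRACTION * radius, iterations=iterations
    )
    mask, _, _ = segment_lesion(image, params, trace_every=0)
    return dice(mask, truth)


def _sample_dice(seed: int, smoothing: str, iterations: int = 400) -> float:
    sample = generate_sample(SyntheticSpec(seed=seed))
    lesion = sample.truth["lesions"][0]
    cy, cx = lesion["center"]
    pre = preprocess_pipeline(sample.image_rgb, smoothing=smoothing)
    params = LGDFParams(
        seed_center=(int(round(cy)), int(round(cx))),
        seed_radius=SEED_FRACTION * lesion["radius"],
        iterations=iterations,
    )
    mask, _, _ = segment_lesion(pre, params, trace_every=0)
    return dice(mask, sample.lesion_mask)


def filter_comparison(
    n_samples: int = 20, seed: int = 100, iterations: int = 400
) -> dict[str, list[float]]:
    """Downstream Dice of bilateral vs median preprocessing on generator samples."""
    seeds = [seed + k for k in range(n_samples)]
    return {
        "bilateral": [_sample_dice(s, "bilateral", iterations) for s in seeds],
        "median": [_sample_dice(s, "median", iterations) for s in seeds],
    }
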