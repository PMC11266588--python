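"""Image-enhancement suite for fundus photographs.

Five families of operations commonly applied to infant fundus images
before analysis or model training: geometric-mean brightness correction,
fixed-aspect circular cropping of the retinal field, a weighted blend of
the image with its Gaussian-smoothed version (structure boosting),
contrast-limited adaptive histogram equalisation (gray / green / HSV-V
variants) and simple channel operations.

All operations take and return 8-bit-range arrays (float internally,
clipped to [0, 255]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, exposure

__all__ = [
    "EnhancementParams",
    "geometric_mean_brightness",
    "adjust_brightness",
    "circle_crop",
    "smooth_blend",
    "clahe_enhance",
    "channel_ops",
]


@dataclass
class EnhancementParams:
    """Tunables of the enhancement suite.

    ``alpha``/``beta``/``gamma_offset`` are the weights of the smoothing
    blend (``dst = alpha*img + beta*smooth(img) + gamma``); the defaults
    5 / -5 / 128 cancel the DC component and centre the result mid-gray.
    ``b_min`` is the minimum acceptable geometric-mean brightness on the
    normalised [0, 1] scale below which a linear brightness boost is
    applied.
    """

    alpha: float = 5.0
    beta: float = -5.0
    gamma_offset: float = 128.0
    smooth_sigma_x: float = 15.0
    b_min: float = 0.35
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    crop_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.smooth_sigma_x <= 0:
            raise ValueError("smooth_sigma_x must be positive")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be positive")
        if not 0 < self.b_min < 1:
            raise ValueError("b_min must lie in (0, 1)")


_FLOOR = 1.0 / 255.0


def _field_mask(image: np.ndarray, threshold: float) -> np.ndarray:
    """Pixels that belong to the illuminated (non-black-border) field."""
    intensity = image if image.ndim == 2 else image.max(axis=2)
    return intensity > threshold


def geometric_mean_brightness(
    image: np.ndarray, params: EnhancementParams | None = None
) -> float:
    """Geometric-mean per-pixel brightness of the retinal field, on [0, 1].

    Brightness of a pixel is the channel mean normalised by 255; the
    geometric mean is taken over pixels inside the circular field only, so
    the black surround does not bias the estimate.  Zeros are floored at
    1/255 to keep the product finite.
    """
    params = params or EnhancementParams()
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    brightness = (image if image.ndim == 2 else image.mean(axis=2)) / 255.0
    mask = _field_mask(image, params.crop_threshold)
    if not mask.any():
        warnings.warn("all-black image: brightness floored", stacklevel=2)
        return _FLOOR
    values = np.maximum(brightness[mask], _FLOOR)
    return float(np.exp(np.mean(np.log(values))))


def adjust_brightness(
    image: np.ndarray,
    b_min: float | None = None,
    params: EnhancementParams | None = None,
    force: bool = False,
) -> np.ndarray:
    """Linearly rescale a too-dark image so its brightness reaches ``b_min``.

    If the geometric-mean brightness ``b`` is below ``b_min`` the image is
    multiplied by ``b_min / b`` (clipped to [0, 255]); brighter images pass
    through unchanged unless ``force`` is set, in which case the same
    transform standardises bright images downwards (scale < 1).
    """
    params = params or EnhancementParams()
    if b_min is None:
        b_min = params.b_min
    image = np.asarray(image, dtype=float)
    b = geometric_mean_brightness(image, params)
    if b >= b_min and not force:
        return image.copy()
    scale = b_min / b
    return np.clip(image * scale, 0.0, 255.0)


def circle_crop(
    image: np.ndarray, params: EnhancementParams | None = None
) -> np.ndarray:
    """Crop black margins and mask the retinal field to a centred circle.

    Rows and columns whose maximum intensity does not exceed the crop
    threshold are removed, a circular mask of radius ``min(w, h) / 2``
    centred in the cropped frame is applied, and the result is cut to the
    bounding square of that circle — so the output is always square and
    free of aspect-ratio distortion.
    """
    params = params or EnhancementParams()
    image = np.asarray(image, dtype=float)
    mask = _field_mask(image, params.crop_threshold)
    if not mask.any():
        raise ValueError("fully black image cannot be circle-cropped")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    cropped = image[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    h, w = cropped.shape[:2]
    # integer geometry keeps the operation exactly idempotent
    side = 2 * (min(w, h) // 2)
    r0, c0 = (h - side) // 2, (w - side) // 2
    out = cropped[r0 : r0 + side, c0 : c0 + side].copy()
    cy = cx = (side - 1) / 2.0
    radius = side / 2.0
    yy, xx = np.ogrid[:side, :side]
    out[(yy - cy) ** 2 + (xx - cx) ** 2 > radius**2] = 0.0
    return out


def smooth_blend(
    image: np.ndarray, params: EnhancementParams | None = None
) -> np.ndarray:
    """Blend the image with its Gaussian-smoothed version.

    ``dst = alpha * img + beta * smooth(img) + gamma`` with an isotropic
    Gaussian of std ``smooth_sigma_x`` (kernel truncated at 4 sigma).  With
    the default alpha = -beta = 5 the flat background cancels to the
    mid-gray offset while structures (vessels, lesion rims) are amplified.
    """
    params = params or EnhancementParams()
    image = np.asarray(image, dtype=float)
    sigma = (params.smooth_sigma_x, params.smooth_sigma_x) + (0,) * (image.ndim - 2)
    smoothed = ndimage.gaussian_filter(image, sigma=sigma, truncate=4.0)
    dst = image * params.alpha + smoothed * params.beta + params.gamma_offset
    return np.clip(dst, 0.0, 255.0)


def _clahe_channel(channel01: np.ndarray, params: EnhancementParams) -> np.ndarray:
    """CLAHE on one channel given on [0, 1]; returns [0, 1]."""
    h, w = channel01.shape
    kernel = (max(h // params.clahe_tiles[0], 1), max(w // params.clahe_tiles[1], 1))
    if float(channel01.max()) - float(channel01.min()) < 1e-12:
        return channel01.copy()  # no contrast to redistribute
    # OpenCV-style clip limit (counts relative to uniform histogram over
    # 256 bins) converted to skimage's normalised fraction of tile pixels.
    clip = min(params.clahe_clip / 256.0, 1.0)
    return exposure.equalize_adapthist(
        np.clip(channel01, 0.0, 1.0), kernel_size=kernel, clip_limit=clip
    )


def clahe_enhance(
    image: np.ndarray, mode: str = "gray", params: EnhancementParams | None = None
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation.

    ``gray``  — expects a single-channel image (or converts RGB to gray),
    ``green`` — equalises the green plane of an RGB image,
    ``hsv_v`` — converts RGB to HSV, equalises the V (value) channel and
    converts back, leaving hue and saturation untouched.
    """
    params = params or EnhancementParams()
    image = np.asarray(image, dtype=float)
    if image.max() > 255.0 or image.min() < 0.0:
        raise ValueError("expected an 8-bit-range image on [0, 255]")
    if mode == "gray":
        gray = image if image.ndim == 2 else image.mean(axis=2)
        return _clahe_channel(gray / 255.0, params) * 255.0
    if mode == "green":
        if image.ndim != 3:
            raise ValueError("green mode requires an RGB image")
        return _clahe_channel(image[..., 1] / 255.0, params) * 255.0
    if mode == "hsv_v":
        if image.ndim != 3:
            raise ValueError("hsv_v mode requires an RGB image")
        hsv = color.rgb2hsv(image / 255.0)
        hsv[..., 2] = _clahe_channel(hsv[..., 2], params)
        return np.clip(color.hsv2rgb(hsv), 0.0, 1.0) * 255.0
    raise ValueError(f"unknown CLAHE mode: {mode!r}")


def channel_ops(image: np.ndarray, op: str):
    """Channel plumbing: ``split`` into (R, G, B) planes or ``swap_rgb_bgr``."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("channel operations require a 3-channel image")
    if op == "split":
        return image[..., 0].copy(), image[..., 1].copy(), image[..., 2].copy()
    if op == "swap_rgb_bgr":
        return image[..., ::-1].copy()
    raise ValueError(f"unknown channel op: {op!r}")
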