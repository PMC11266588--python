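"""Seeded generator of fundus-like test images with known lesion masks.

The generator emulates the gross appearance of an infant fundus
photograph — a warm-toned circular retinal field on a black surround,
radial vignetting towards the rim, a bright optic-disc blob, curvilinear
vessel strokes (strongest in the green channel), one or more dark
hemorrhage-like lesions with known ground-truth masks, a smooth
multiplicative intensity-inhomogeneity field and additive Gaussian
noise — plus convention-named dataset trees with a matching metadata
workbook.  It is the test substrate standing in for the (large,
separately downloadable) clinical dataset; it is deliberately not a
photorealistic retina simulator.

Construction guarantees used by tests: with zero noise and zero
inhomogeneity the fused (red+green)/2 intensity inside a lesion equals
``background_level - lesion_contrast`` exactly, because vignetting is
held at 1 inside the lesion-placement zone and vessels / optic disc are
never drawn over a lesion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .catalog import ImageMetadata, format_filename

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "generate_sample",
    "generate_dataset_tree",
    "DEVICE_RESOLUTIONS",
]

#: (height, width) image size per imaging-device code.
DEVICE_RESOLUTIONS = {1: (480, 640), 2: (1080, 1440), 3: (1240, 1240)}

#: Patient counts per diagnosis code in the published cohort, used as
#: sampling weights for synthetic cohorts.
_DIAGNOSIS_WEIGHTS = {0: 135, 1: 4, 2: 12, 3: 11, 4: 2, 8: 1, 9: 13, 10: 2, 11: 35, 12: 2, 13: 1}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic fundus image.

    Defaults describe a small desk-scale field (128x128) with one dark
    lesion of contrast 70 on a background of 160 (fused scale), mild
    vignetting, six vessels, +/-20% multiplicative inhomogeneity and
    additive noise of sigma 8 — comparable, at reduced resolution, to the
    darker regions of real RetCam frames.
    """

    seed: int = 0
    size: tuple[int, int] = (128, 128)
    background_level: float = 160.0
    lesion_count: int = 1
    lesion_radius_range: tuple[float, float] = (8.0, 16.0)
    lesion_contrast: float = 70.0
    vessel_count: int = 6
    vessel_contrast: float = 40.0
    inhomogeneity_amplitude: float = 0.2
    noise_sigma: float = 8.0
    device: int = 1

    def __post_init__(self) -> None:
        if min(self.size) <= 0:
            raise ValueError("image size must be positive")
        if self.lesion_radius_range[0] < 3:
            raise ValueError("lesion radii must be >= 3 px")
        if self.lesion_count and self.lesion_contrast <= self.noise_sigma:
            raise ValueError("lesion_contrast must exceed noise_sigma")

    @classmethod
    def for_device(cls, device: int, **kwargs) -> "SyntheticSpec":
        """Preset at the native resolution of an imaging-device code."""
        return cls(size=DEVICE_RESOLUTIONS[device], device=device, **kwargs)


@dataclass
class SyntheticSample:
    image_rgb: np.ndarray  # float, [0, 255]
    lesion_masks: list[np.ndarray]
    metadata: ImageMetadata
    truth: dict = field(default_factory=dict)

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.lesion_masks[0]


def _deformed_ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smoothly deformed ellipse: r(theta) modulated by low-order harmonics."""
    ratio = rng.uniform(0.85, 1.0)
    angle = rng.uniform(0.0, math.pi)
    amps = rng.uniform(-0.08, 0.08, size=3)
    phases = rng.uniform(0.0, 2 * math.pi, size=3)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    ry = dy * math.cos(angle) - dx * math.sin(angle)
    rx = dy * math.sin(angle) + dx * math.cos(angle)
    theta = np.arctan2(ry, rx)
    boundary = radius * (
        1.0 + sum(a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    )
    rho = np.sqrt((rx / 1.0) ** 2 + (ry / ratio) ** 2)
    return rho <= boundary


def _smooth_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative low-frequency inhomogeneity field 1 +/- amplitude."""
    if amplitude == 0:
        return np.ones(shape)
    coarse = rng.uniform(-1.0, 1.0, size=(4, 4))
    fine = ndimage.zoom(coarse, (shape[0] / 4, shape[1] / 4), order=3)
    fine = fine[: shape[0], : shape[1]]
    peak = np.abs(fine).max()
    if peak > 0:
        fine = fine / peak
    return 1.0 + amplitude * fine


def _random_metadata(rng: np.random.Generator, patient_id: int, device: int,
                     series: int = 1, image_index: int = 1) -> ImageMetadata:
    ga = int(np.clip(round(rng.normal(33, 5)), 23, 41))
    bw = int(np.clip(round(rng.normal(2017, 1024)), 480, 4080))
    pa = max(ga, 30) + int(rng.integers(0, 6))
    codes = list(_DIAGNOSIS_WEIGHTS)
    weights = np.array([_DIAGNOSIS_WEIGHTS[c] for c in codes], dtype=float)
    dg = int(rng.choice(codes, p=weights / weights.sum()))
    pf = 2 if rng.random() < 0.015 else 0
    token = {1: "RC3", 2: "RE", 3: "ICON"}[device]
    return ImageMetadata(
        patient_id=patient_id,
        sex=str(rng.choice(["F", "M"])),
        gestational_age_weeks=ga,
        birth_weight_g=bw,
        postconceptual_age_weeks=pa,
        diagnosis_code=dg,
        plus_form=pf,
        device=device,
        device_token=token,
        series=series,
        image_index=image_index,
    ).validate()


def generate_sample(spec: SyntheticSpec) -> SyntheticSample:
    """Render one synthetic fundus image with ground-truth lesion masks."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    field_radius = 0.48 * min(h, w)
    inner_radius = 0.75 * field_radius  # vignetting-free placement zone

    yy, xx = np.mgrid[:h, :w]
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    in_field = rr <= field_radius

    bg = spec.background_level
    image = np.zeros((h, w, 3))
    image[..., 0] = bg + 30.0
    image[..., 1] = bg - 30.0
    image[..., 2] = bg * 0.3

    # optic disc: bright compact-support blob off-centre
    disc_r = 0.12 * min(h, w)
    disc_angle = rng.uniform(0.0, 2 * math.pi)
    disc_dist = 0.45 * field_radius
    disc_c = (cy + disc_dist * math.sin(disc_angle), cx + disc_dist * math.cos(disc_angle))
    dd = np.sqrt((yy - disc_c[0]) ** 2 + (xx - disc_c[1]) ** 2)
    profile = np.clip(1.0 - (dd / (1.5 * disc_r)) ** 2, 0.0, 1.0) ** 2
    for ch, gain in enumerate((60.0, 55.0, 40.0)):
        image[..., ch] += gain * profile

    # lesions: dark hemorrhage-like blobs in red and green, away from the
    # optic disc and each other
    masks: list[np.ndarray] = []
    occupied = dd <= 2.0 * disc_r
    lesion_params = []
    for _ in range(spec.lesion_count):
        for attempt in range(100):
            radius = rng.uniform(*spec.lesion_radius_range)
            max_c = inner_radius - radius
            ang = rng.uniform(0.0, 2 * math.pi)
            dist = rng.uniform(0.0, max(max_c, 1.0))
            center = (cy + dist * math.sin(ang), cx + dist * math.cos(ang))
            mask = _deformed_ellipse_mask((h, w), center, radius, rng)
            grown = ndimage.binary_dilation(mask, iterations=3)
            if not (grown & occupied).any() and mask.any():
                break
        else:
            raise RuntimeError("could not place a lesion inside the field")
        occupied |= grown
        masks.append(mask)
        lesion_params.append({"center": center, "radius": radius})
        image[..., 0][mask] = bg + 30.0 - spec.lesion_contrast
        image[..., 1][mask] = bg - 30.0 - spec.lesion_contrast

    # vessels: quadratic Bezier strokes radiating from the optic disc,
    # strongest in green, never drawn over a lesion
    any_lesion = np.any(masks, axis=0) if masks else np.zeros((h, w), bool)
    for _ in range(spec.vessel_count):
        a0 = rng.uniform(0.0, 2 * math.pi)
        p0 = np.array(disc_c)
        p2 = np.array([cy + 0.95 * field_radius * math.sin(a0),
                       cx + 0.95 * field_radius * math.cos(a0)])
        p1 = (p0 + p2) / 2 + rng.uniform(-0.15, 0.15, 2) * min(h, w)
        t = np.linspace(0.0, 1.0, 4 * int(np.linalg.norm(p2 - p0)) + 8)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
        stroke = np.zeros((h, w), bool)
        width = rng.uniform(0.8, 1.6)
        for py, px in pts:
            iy, ix = int(round(py)), int(round(px))
            r_int = int(math.ceil(width))
            y0, y1 = max(iy - r_int, 0), min(iy + r_int + 1, h)
            x0, x1 = max(ix - r_int, 0), min(ix + r_int + 1, w)
            sub_y, sub_x = np.mgrid[y0:y1, x0:x1]
            stroke[y0:y1, x0:x1] |= (sub_y - py) ** 2 + (sub_x - px) ** 2 <= width**2
        stroke &= in_field & ~any_lesion
        image[..., 0][stroke] -= 0.5 * spec.vessel_contrast
        image[..., 1][stroke] -= spec.vessel_contrast
        image[..., 2][stroke] -= 0.15 * spec.vessel_contrast

    # vignetting: flat inside the placement zone, falls to 0.8 at the rim
    vignette = np.ones((h, w))
    ramp = (rr - inner_radius) / (field_radius - inner_radius)
    outer = rr > inner_radius
    vignette[outer] = 1.0 - 0.2 * np.clip(ramp[outer], 0.0, 1.0)

    shading = _smooth_field((h, w), spec.inhomogeneity_amplitude, rng)
    image *= (vignette * shading)[..., None]
    image[~in_field] = 0.0

    if spec.noise_sigma > 0:
        image[in_field] += rng.normal(0.0, spec.noise_sigma, size=(int(in_field.sum()), 3))
    image = np.clip(image, 0.0, 255.0)

    meta = _random_metadata(rng, patient_id=int(rng.integers(1, 200)), device=spec.device)
    truth = {
        "spec": spec,
        "lesions": lesion_params,
        "field_center": (cy, cx),
        "field_radius": field_radius,
    }
    return SyntheticSample(image_rgb=image, lesion_masks=masks, metadata=meta, truth=truth)


def generate_dataset_tree(
    n_patients: int,
    spec: SyntheticSpec,
    out_root: str | Path,
    series_per_patient: int = 2,
    images_per_series: int = 3,
) -> pd.DataFrame:
    """Write a convention-named dataset tree plus its metadata workbook.

    Emits the ``images/<ID>/<series>/`` and flat ``images_stack/`` layouts
    (identical files), PNG ground-truth masks under ``masks/`` and
    ``infant_retinal_database_info.xlsx``; returns the attribute table
    (one row per image) that the workbook was written from.
    """
    import imageio.v3 as iio

    out_root = Path(out_root)
    (out_root / "images").mkdir(parents=True, exist_ok=True)
    (out_root / "images_stack").mkdir(exist_ok=True)
    (out_root / "masks").mkdir(exist_ok=True)

    rng = np.random.default_rng(spec.seed)
    # cap lesion radii to the placement zone of the requested image size
    r_cap = max(3.0, 0.35 * 0.75 * 0.48 * min(spec.size))
    radius_range = (
        min(spec.lesion_radius_range[0], r_cap),
        min(spec.lesion_radius_range[1], r_cap),
    )
    rows = []
    for pid in range(1, n_patients + 1):
        profile = _random_metadata(rng, patient_id=pid, device=int(rng.integers(1, 4)))
        for series in range(1, series_per_patient + 1):
            pa = max(profile.gestational_age_weeks, 30) + 2 * (series - 1) + int(rng.integers(0, 3))
            for idx in range(1, images_per_series + 1):
                meta = ImageMetadata(
                    patient_id=pid,
                    sex=profile.sex,
                    gestational_age_weeks=profile.gestational_age_weeks,
                    birth_weight_g=profile.birth_weight_g,
                    postconceptual_age_weeks=pa,
                    diagnosis_code=profile.diagnosis_code,
                    plus_form=profile.plus_form,
                    device=profile.device,
                    device_token=profile.device_token,
                    series=series,
                    image_index=idx,
                ).validate()
                sample = generate_sample(
                    SyntheticSpec(
                        **{
                            **spec.__dict__,
                            "seed": int(rng.integers(0, 2**31 - 1)),
                            "device": profile.device,
                            "lesion_radius_range": radius_range,
                        }
                    )
                )
                name = format_filename(meta, ".jpg")
                series_dir = out_root / "images" / f"{pid:03d}" / f"S{series:02d}"
                series_dir.mkdir(parents=True, exist_ok=True)
                img8 = sample.image_rgb.astype(np.uint8)
                iio.imwrite(series_dir / name, img8, quality=95)
                iio.imwrite(out_root / "images_stack" / name, img8, quality=95)
                for k, mask in enumerate(sample.lesion_masks):
                    iio.imwrite(
                        out_root / "masks" / f"{format_filename(meta)}_mask{k}.png",
                        mask.astype(np.uint8) * 255,
                    )
                rows.append(
                    {
                        "ID": pid,
                        "SEX": meta.sex,
                        "GESTATIONAL_AGE": meta.gestational_age_weeks,
                        "BIRTH_WEIGHT": meta.birth_weight_g,
                        "POSTCONCEPTUAL_AGE": pa,
                        "DIAGNOSIS_CODE": meta.diagnosis_code,
                        "PLUS_FORM": meta.plus_form,
                        "DEVICE": meta.device,
                        "SERIES_NUMBER": series,
                        "IMAGE_NUMBER": idx,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "ID", "SEX", "GESTATIONAL_AGE", "BIRTH_WEIGHT", "POSTCONCEPTUAL_AGE",
            "DIAGNOSIS_CODE", "PLUS_FORM", "DEVICE", "SERIES_NUMBER", "IMAGE_NUMBER",
        ],
    )
    table.to_excel(out_root / "infant_retinal_database_info.xlsx", index=False)
    return table
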