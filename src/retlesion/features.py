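"""Geometric and intensity quantification of a segmented lesion.

After segmentation the lesion mask is reduced to the clinically reported
descriptors: area, perimeter, major/minor axis lengths of the
second-moment-equivalent ellipse, and the median / standard deviation of
the lesion's intensity spectrum on the fused monochrome channel.  A
results bundle (JSON features + mask PNG + intensity CSV + preprocessed
image PNG, optional histogram figure) mirrors what a clinician-facing
tool would save per analysed lesion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from skimage import measure

__all__ = ["LesionFeatures", "compute_features", "save_results_bundle"]


@dataclass
class LesionFeatures:
    area_px: int
    perimeter_px: float
    major_axis_px: float
    minor_axis_px: float
    intensity_median: float
    intensity_std: float

    @property
    def n_pixels(self) -> int:
        return self.area_px


def _contour_perimeter(mask: np.ndarray) -> float:
    """Polygonal length of the traced sub-pixel boundary contour(s)."""
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        total += float(np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1)))
    return total


def compute_features(
    mask: np.ndarray, image: np.ndarray, perimeter: str = "contour"
) -> LesionFeatures:
    """Quantify one lesion mask over the supplied monochrome image.

    ``perimeter`` selects the traced-contour polygon length (default) or
    the Crofton four-direction estimate (``"crofton"``).  Axes come from
    the ellipse with identical second central moments; intensity stats are
    taken over the mask pixels (population std).
    """
    mask = np.asarray(mask).astype(bool)
    image = np.asarray(image, dtype=float)
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    if not mask.any():
        raise ValueError("empty mask has no features")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    if perimeter == "contour":
        perim = _contour_perimeter(mask)
    elif perimeter == "crofton":
        perim = float(props.perimeter_crofton)
    else:
        raise ValueError(f"unknown perimeter estimator: {perimeter!r}")
    values = image[mask]
    return LesionFeatures(
        area_px=int(props.area),
        perimeter_px=perim,
        major_axis_px=float(props.axis_major_length),
        minor_axis_px=float(props.axis_minor_length),
        intensity_median=float(np.median(values)),
        intensity_std=float(values.std(ddof=0)),
    )


def _write_png(path: Path, array: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.clip(array, 0, 255).astype(np.uint8))


def save_results_bundle(
    features: LesionFeatures,
    mask: np.ndarray,
    image_mono: np.ndarray,
    preprocessed: np.ndarray,
    out_dir: str | Path,
    name: str = "lesion",
    provenance: dict | None = None,
    plot_histogram: bool = False,
) -> list[Path]:
    """Persist the per-lesion results bundle; returns the written paths.

    ``<name>_features.json`` (features + provenance), ``<name>_mask.png``
    ({0,255}), ``<name>_intensities.csv`` (lesion-pixel intensities on the
    native monochrome channel) and ``<name>_preprocessed.png``; with
    ``plot_histogram`` an additional intensity-histogram figure.
    """
    if mask is None:
        raise ValueError("mask is required")
    mask = np.asarray(mask).astype(bool)
    image_mono = np.asarray(image_mono, dtype=float)
    preprocessed = np.asarray(preprocessed, dtype=float)
    if mask.shape != image_mono.shape or mask.shape != preprocessed.shape:
        raise ValueError("mask/image shape mismatch")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []
    payload = {"features": asdict(features), "provenance": provenance or {}}
    json_path = out_dir / f"{name}_features.json"
    json_path.write_text(json.dumps(payload, indent=2))
    written.append(json_path)

    mask_path = out_dir / f"{name}_mask.png"
    _write_png(mask_path, mask.astype(np.uint8) * 255)
    written.append(mask_path)

    csv_path = out_dir / f"{name}_intensities.csv"
    np.savetxt(csv_path, image_mono[mask], fmt="%.6g", header="intensity", comments="")
    written.append(csv_path)

    pre_path = out_dir / f"{name}_preprocessed.png"
    _write_png(pre_path, preprocessed)
    written.append(pre_path)

    if plot_histogram:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(image_mono[mask], bins=32, color="firebrick")
        ax.set_xlabel("intensity")
        ax.set_ylabel("pixels")
        ax.set_title("lesion intensity spectrum")
        fig.tight_layout()
        hist_path = out_dir / f"{name}_histogram.png"
        fig.savefig(hist_path, dpi=100)
        plt.close(fig)
        written.append(hist_path)
    return written


def load_features(path: str | Path) -> LesionFeatures:
    """Read back a ``*_features.json`` bundle file."""
    payload = json.loads(Path(path).read_text())
    return LesionFeatures(**payload["features"])
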