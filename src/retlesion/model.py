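"""Model/Results interface over the LGDF segmentation engine.

`LGDFModel` is built from an image plus a seed (the clinician's click
inside the lesion); `fit()` runs the level-set evolution and returns an
`LGDFResults` carrying the mask, the final level-set state, the energy
trace, the lesion features and a text `summary()`.
"""

from __future__ import annotations

import time
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np

from .features import LesionFeatures, compute_features, save_results_bundle
from .lgdf import LGDFParams, LevelSetState, lgdf_energy, segment_lesion
from .preprocessing import FilterParams, fuse_red_green

__all__ = ["LGDFModel", "LGDFResults"]


class LGDFModel:
    """Seed-initialised LGDF active contour for one lesion in one image.

    Parameters
    ----------
    image : ndarray
        RGB or monochrome fundus image on the 8-bit scale.
    seed_center : (row, col)
        A point inside the lesion of interest.
    seed_radius : float
        Radius of the initial circular contour in pixels.
    params : LGDFParams, optional
        Full parameter set; seed fields are overridden by the arguments.
    preprocess : bool
        Run red+green fusion, adaptive equalisation and bilateral
        smoothing before evolving the contour.
    """

    def __init__(
        self,
        image: np.ndarray,
        seed_center: tuple[int, int],
        seed_radius: float = 10.0,
        params: LGDFParams | None = None,
        preprocess: bool = False,
        filter_params: FilterParams | None = None,
    ) -> None:
        self.image = np.asarray(image, dtype=float)
        base = params or LGDFParams()
        self.params = replace(base, seed_center=tuple(seed_center), seed_radius=float(seed_radius))
        self.preprocess = preprocess
        self.filter_params = filter_params

    @classmethod
    def from_file(cls, path: str | Path, seed_center: tuple[int, int], **kwargs) -> "LGDFModel":
        import imageio.v3 as iio

        return cls(iio.imread(path), seed_center, **kwargs)

    @property
    def monochrome(self) -> np.ndarray:
        """The fused red+green channel the features are measured on."""
        return fuse_red_green(self.image) if self.image.ndim == 3 else self.image

    def fit(self, iterations: int | None = None, trace_every: int = 25) -> "LGDFResults":
        params = self.params if iterations is None else replace(self.params, iterations=iterations)
        t0 = time.perf_counter()
        mask, state, trace = segment_lesion(
            self.image,
            params,
            preprocess=self.preprocess,
            filter_params=self.filter_params,
            trace_every=trace_every,
        )
        elapsed = time.perf_counter() - t0
        return LGDFResults(self, params, mask, state, trace, elapsed)


class LGDFResults:
    """Fitted segmentation: mask, level-set state, energy trace, features."""

    def __init__(
        self,
        model: LGDFModel,
        params: LGDFParams,
        mask: np.ndarray,
        state: LevelSetState,
        trace: list[tuple[int, float]],
        elapsed_s: float,
    ) -> None:
        self.model = model
        self.params = params
        self.mask = mask
        self.state = state
        self.energy_trace = trace
        self.elapsed_s = elapsed_s
        self._features: LesionFeatures | None = None

    @property
    def features(self) -> LesionFeatures:
        if self._features is None:
            self._features = compute_features(self.mask, self.model.monochrome)
        return self._features

    @property
    def final_energy(self) -> float:
        return lgdf_energy(self.model.monochrome, self.state, self.params)

    def summary(self) -> str:
        f = self.features if self.mask.any() else None
        lines = [
            "LGDF lesion segmentation results",
            "=" * 44,
            f"image shape:          {self.model.image.shape}",
            f"seed (row, col):      {self.params.seed_center}",
            f"seed radius:          {self.params.seed_radius:g} px",
            f"iterations:           {self.params.iterations}",
            f"kernel sigma/radius:  {self.params.kernel_sigma:g} / {self.params.kernel_radius}",
            f"nu, mu, dt, epsilon:  {self.params.nu:g}, {self.params.mu:g}, "
            f"{self.params.dt:g}, {self.params.epsilon:g}",
            f"wall time:            {self.elapsed_s:.2f} s",
            "-" * 44,
        ]
        if f is None:
            lines.append("lesion:               EMPTY (contour vanished)")
        else:
            lines += [
                f"lesion area:          {f.area_px} px",
                f"perimeter:            {f.perimeter_px:.1f} px",
                f"major / minor axis:   {f.major_axis_px:.1f} / {f.minor_axis_px:.1f} px",
                f"intensity median:     {f.intensity_median:.1f}",
                f"intensity std:        {f.intensity_std:.2f}",
            ]
        if self.energy_trace:
            first, last = self.energy_trace[0], self.energy_trace[-1]
            lines += [
                "-" * 44,
                f"energy @ iter {first[0]:<4d}    {first[1]:.6g}",
                f"energy @ iter {last[0]:<4d}    {last[1]:.6g}",
            ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path, name: str = "lesion", plot_histogram: bool = False):
        provenance = {
            "params": asdict(self.params),
            "preprocess": self.model.preprocess,
            "elapsed_s": self.elapsed_s,
            "energy_trace": self.energy_trace,
        }
        mono = self.model.monochrome
        preprocessed = mono  # native channel doubles as the record when no preprocessing ran
        if self.model.preprocess:
            from .preprocessing import preprocess_pipeline

            preprocessed = preprocess_pipeline(self.model.image, self.model.filter_params)
        return save_results_bundle(
            self.features,
            self.mask,
            mono,
            preprocessed,
            out_dir,
            name=name,
            provenance=provenance,
            plot_histogram=plot_histogram,
        )

    def plot(self, ax=None):
        """Overlay the fitted contour on the input image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from skimage import measure

        if ax is None:
            _, ax = plt.subplots()
        show = self.model.image
        ax.imshow(show.astype(np.uint8) if show.ndim == 3 else show, cmap="gray")
        for contour in measure.find_contours(self.mask.astype(float), 0.5):
            ax.plot(contour[:, 1], contour[:, 0], "-", color="cyan", lw=1.5)
        ax.plot(self.params.seed_center[1], self.params.seed_center[0], "r+", ms=10)
        ax.set_axis_off()
        return ax
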