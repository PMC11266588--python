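# retlesion

Segmentation and quantification of retinal lesions in infant fundus
photographs — the kind acquired during retinopathy-of-prematurity (ROP)
screening with RetCam-class cameras. Given a clinician's seed point inside a
lesion (most often a hemorrhage), the toolkit evolves an active contour
without edges to delineate the lesion, then reports its geometric and
intensity features. Around the segmentation core it provides the
preprocessing and image-enhancement methods used on such images, evaluation
metrics against expert consensus masks, tooling for the structured filename
convention and metadata workbook of the public infant-retina database, and a
seeded synthetic fundus generator used as the test substrate.

## The model

The contour is a level-set field Φ whose zero crossing is the lesion
boundary (lesion = {Φ < 0}, the sign of the seed). Intensities near each
pixel *x* are modelled by two **local Gaussian distributions** — one per
region — with spatially varying means *uᵢ(x)* and variances *σᵢ(x)²*,
weighted by a truncated Gaussian window ω of scale σ (local Gaussian
distribution fitting, LGDF). The fitted energy

&nbsp;&nbsp;&nbsp;&nbsp;F(Φ, u₁, u₂, σ₁², σ₂²) = E^LGDF + ν·L(Φ) + μ·P(Φ)

combines the localized negative log-likelihood E^LGDF with a contour-length
penalty L(Φ) = ∫|∇H(Φ)| and a signed-distance penalty
P(Φ) = ∫½(|∇Φ|−1)², so no re-initialisation is needed. Region membership
uses a smoothed Heaviside H_ε(x) = ½[1 + (2/π)·arctan(x/ε)], and Φ follows
the gradient-descent flow

&nbsp;&nbsp;&nbsp;&nbsp;∂Φ/∂t = −δ_ε(Φ)(e₁−e₂) + ν·δ_ε(Φ)·div(∇Φ/|∇Φ|) + μ·(∇²Φ − div(∇Φ/|∇Φ|)),

where the data force e₁−e₂ compares the two local Gaussian models. Because
both means and variances are local, e₁−e₂ is invariant to a multiplicative
illumination field b(x) — the property that makes the model robust on
unevenly lit fundus images. Before segmentation the image is reduced to the
(R+G)/2 channel, locally equalised (CLAHE) and smoothed with an
edge-preserving bilateral filter

&nbsp;&nbsp;&nbsp;&nbsp;I_filt(x) = (1/W_p) Σ_{xᵢ∈Ω} I(xᵢ)·f(‖I(xᵢ)−I(x)‖)·g(‖xᵢ−x‖).

Segmentations are scored with MSE (on {0,255}-coded masks), Pearson
correlation, the Sørensen–Dice coefficient 2|X∩Y|/(|X|+|Y|), sensitivity,
specificity and accuracy.

## Worked example

```python
from retlesion import LGDFModel, SyntheticSpec, generate_sample, score_pair

sample = generate_sample(SyntheticSpec(seed=42))     # fundus-like image + truth
lesion = sample.truth["lesions"][0]
cy, cx = (int(round(v)) for v in lesion["center"])

model = LGDFModel(sample.image_rgb, seed_center=(cy, cx),
                  seed_radius=0.9 * lesion["radius"], preprocess=True)
res = model.fit()
print(res.summary())
```

```
LGDF lesion segmentation results
============================================
image shape:          (128, 128, 3)
seed (row, col):      (83, 77)
seed radius:          10.8075 px
iterations:           400
kernel sigma/radius:  3 / 6
nu, mu, dt, epsilon:  1, 1, 0.1, 1
wall time:            1.81 s
--------------------------------------------
lesion area:          413 px
perimeter:            75.6 px
major / minor axis:   23.3 / 22.6 px
intensity median:     92.4
intensity std:        6.56
--------------------------------------------
energy @ iter 25      58319.5
energy @ iter 400     56969.6
```

The fitted mask covers 413 pixels; the moment-equivalent ellipse is nearly
circular (axes 23.3 / 22.6 px), and the lesion's intensity spectrum on the
fused red+green channel has median 92.4 — consistent with the generator's
dark hemorrhage-like blob on a background of 160. The energy trace decreases
monotonically, and scoring against the generator's ground-truth mask gives

```
Dice vs ground truth: 0.999   MSE: 4.0   sensitivity: 1.000
```

`res.save("out/")` writes the per-lesion results bundle (features JSON,
mask PNG, lesion-intensity CSV, preprocessed image PNG); `res.plot()`
overlays the contour on the input image.

The same operations are available from the shell:

```sh
retlesion segment --in image.jpg --seed-row 83 --seed-col 77 --radius 11 \
    --iterations 400 --out-mask mask.png --out-features features.json
retlesion enhance --method clahe-hsv --in image.jpg --out enhanced.png
retlesion synth --n-patients 5 --seed 1 --out dataset/
retlesion summarize --root dataset/images_stack
```

## Dataset tooling

Images in the public infant-retina database are named
`ID_sex_GAxx_BWxxxx_PAxx_DGx_PFx_device_Sxx_n.jpg` (gestational age,
birth weight, postconceptual age in weeks; diagnosis code 0–13; plus-form
0/1/2; device RC3/RE/ICON; series and image number). `parse_filename` /
`format_filename` round-trip this grammar, `scan_dataset` catalogues folder
trees or the metadata workbook, and `summarize` computes the cohort
statistics (patient-level gestational age and birth weight, series-level
postconceptual age, categorical counts).

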