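"""Synthetic tongue images and labeled feature tables.

The clinical images behind this pipeline (pre-cropped tongue photographs from
a standardized acquisition instrument) are private, so every downstream stage
is exercised on synthetic data with known ground truth:

* :func:`make_tongue_image` renders an elliptical tongue whose *body* pixels
  cluster around a reddish mean color and whose *coating* pixels cluster
  around a paler/yellower mean, with controllable per-pixel gray texture and
  additive channel noise, plus exact body/coating masks.
* :func:`make_feature_dataset` draws a two-class Gaussian feature table with
  a controllable class-mean separation and the 296/531-style imbalance of
  the study population.
* :func:`make_cohort` renders a whole labeled cohort of images with
  per-subject color variation, a class-dependent color shift, and covariates
  (gender, age, BMI) whose distributions mirror the study groups.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .image import TongueImage

__all__ = [
    "SyntheticSpec",
    "LabeledDatasetSpec",
    "CohortSpec",
    "make_tongue_image",
    "make_feature_dataset",
    "make_cohort",
]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic tongue image.

    ``texture_amplitude`` is the std (gray levels) of a per-pixel luminance
    offset shared across channels; ``noise_sigma`` the std of i.i.d. Gaussian
    noise added per channel.  Both are applied about the region mean color
    and clipped to [0, 255].
    """

    height: int = 96
    width: int = 128
    body_color: tuple = (180, 120, 120)
    coating_color: tuple = (210, 200, 170)
    coating_fraction: float = 0.35
    texture_amplitude: float = 6.0
    noise_sigma: float = 3.0
    seed: int = 0

    def validate(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.coating_fraction <= 1.0:
            raise ValueError("coating_fraction must lie in [0, 1]")
        for c in (*self.body_color, *self.coating_color):
            if not 0 <= c <= 255:
                raise ValueError("colors must be valid 8-bit triples")
        if self.texture_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("texture_amplitude and noise_sigma must be >= 0")


def _ellipse_mask(h, w, cy, cx, ay, ax):
    yy, xx = np.mgrid[0:h, 0:w]
    if ay <= 0 or ax <= 0:
        return np.zeros((h, w), dtype=bool)
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_tongue_image(spec: SyntheticSpec):
    """Render one synthetic tongue image.

    Returns ``(TongueImage, body_mask, coating_mask)``.  The tongue region is
    an ellipse inscribed in the frame; the coating is a smaller concentric
    ellipse scaled by sqrt(coating_fraction) and shifted into the upper half
    of the tongue (kept fully inside it, so the coating is connected and its
    area fraction is close to the request).  Body and coating masks partition
    the tongue mask exactly.
    """
    spec.validate()
    h, w = spec.height, spec.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = h / 2.0 - 0.5, w / 2.0 - 0.5
    tongue = _ellipse_mask(h, w, cy, cx, ay, ax)
    if not tongue.any():  # 1x1 or similar degenerate frame: keep center pixel
        tongue = np.zeros((h, w), dtype=bool)
        tongue[int(cy), int(cx)] = True

    f = spec.coating_fraction
    if f <= 0.0:
        coating = np.zeros_like(tongue)
    elif f >= 1.0:
        coating = tongue.copy()
    else:
        s = np.sqrt(f)
        # vertical shift of half the slack keeps the coating inside the tongue
        dy = 0.5 * ay * (1.0 - s)
        coating = _ellipse_mask(h, w, cy - dy, cx, s * ay, s * ax) & tongue
    body = tongue & ~coating

    rng = np.random.default_rng(spec.seed)
    pixels = np.full((h, w, 3), 20.0)
    for mask, color in ((body, spec.body_color), (coating, spec.coating_color)):
        n = int(mask.sum())
        if n == 0:
            continue
        vals = np.asarray(color, dtype=float) + rng.normal(
            0.0, spec.texture_amplitude, size=(n, 1)
        )
        vals = vals + rng.normal(0.0, spec.noise_sigma, size=(n, 3))
        pixels[mask] = vals
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    return TongueImage(pixels, tongue), body, coating


@dataclass
class LabeledDatasetSpec:
    """Two Gaussian classes in feature space.

    Class 1 (the diabetes-analog minority) and class 0 (control majority)
    have unit-variance isotropic Gaussian features whose means are
    ``class_separation`` apart in Euclidean distance.
    """

    n_minority: int = 296
    n_majority: int = 531
    n_features: int = 10
    class_separation: float = 2.0
    seed: int = 0

    def validate(self):
        if self.n_minority < 1 or self.n_majority < 1:
            raise ValueError("class counts must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")


def make_feature_dataset(spec: LabeledDatasetSpec) -> pd.DataFrame:
    """Draw the labeled feature table described by ``spec``.

    Columns ``f0 .. f{d-1}`` plus a final integer ``label`` column
    (1 = minority/diabetes-analog, 0 = majority/control).  Rows are shuffled;
    the whole table is reproducible under the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    d = spec.n_features
    offset = spec.class_separation / np.sqrt(d)
    x0 = rng.normal(0.0, 1.0, size=(spec.n_majority, d))
    x1 = rng.normal(offset, 1.0, size=(spec.n_minority, d))
    x = np.vstack([x0, x1])
    y = np.concatenate([np.zeros(spec.n_majority, int), np.ones(spec.n_minority, int)])
    order = rng.permutation(len(y))
    df = pd.DataFrame(x[order], columns=[f"f{i}" for i in range(d)])
    df["label"] = y[order]
    return df


@dataclass
class CohortSpec:
    """A labeled cohort of synthetic tongue images with covariates.

    The diabetes-analog class shifts the body and coating mean colors by
    ``class_color_shift``; individual subjects additionally jitter their
    region colors (``subject_color_sigma``, per channel) and coating area.
    Covariate distributions mirror the study groups: diabetic subjects
    age ~ N(58.35, 12.99), 53.7% male; controls age ~ N(62.37, 8.13),
    36.0% male; BMI is given a mild class shift.
    """

    n_per_class: int = 60
    image: SyntheticSpec = field(default_factory=SyntheticSpec)
    class_color_shift: tuple = (12, -10, -4)
    subject_color_sigma: float = 5.0
    coating_fraction_range: tuple = (0.25, 0.45)
    informative_covariates: bool = True  # False: pooled covariate draws
    seed: int = 0


def make_cohort(spec: CohortSpec):
    """Generate ``2 * n_per_class`` subjects as a list of records.

    Each record is a dict with keys ``image`` (TongueImage), ``body_mask``,
    ``coating_mask``, ``label``, ``gender``, ``age``, ``bmi``,
    ``subject_id``.
    """
    rng = np.random.default_rng(spec.seed)
    shift = np.asarray(spec.class_color_shift, dtype=float)
    records = []
    for label in (0, 1):
        for i in range(spec.n_per_class):
            jitter = rng.normal(0.0, spec.subject_color_sigma, size=3)
            body = np.asarray(spec.image.body_color, float) + label * shift + jitter
            coat = (
                np.asarray(spec.image.coating_color, float)
                + label * shift
                + rng.normal(0.0, spec.subject_color_sigma, size=3)
            )
            frac = rng.uniform(*spec.coating_fraction_range)
            img_spec = replace(
                spec.image,
                body_color=tuple(np.clip(body, 0, 255)),
                coating_color=tuple(np.clip(coat, 0, 255)),
                coating_fraction=float(frac),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            image, body_mask, coating_mask = make_tongue_image(img_spec)
            cls = label if spec.informative_covariates else int(rng.random() < 0.5)
            if cls == 1:
                gender = int(rng.random() < 0.537)
                age = rng.normal(58.35, 12.99)
                bmi = rng.normal(25.5, 3.5)
            else:
                gender = int(rng.random() < 0.360)
                age = rng.normal(62.37, 8.13)
                bmi = rng.normal(23.5, 3.0)
            records.append(
                {
                    "subject_id": f"s{label}{i:04d}",
                    "image": image,
                    "body_mask": body_mask,
                    "coating_mask": coating_mask,
                    "label": label,
                    "gender": gender,
                    "age": float(np.clip(age, 18, 95)),
                    "bmi": float(np.clip(bmi, 15, 45)),
                }
            )
    return records
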