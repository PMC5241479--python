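"""Assembly of the per-subject feature vector.

One row per subject: 3 covariates (gender 0/1, age in years, BMI in kg/m2),
9 mean-color features per region (RGB, HSI, CIELAB) for body and coating,
and 4 gray-difference texture statistics per region — 29 numeric columns
plus the 0/1 ``label``.  Column names follow ``{region}_{space}_{channel}``
for color and ``{region}_tex_{stat}`` for texture.  An absent coating leaves
its features NaN, to be mean-imputed from the training set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .color import region_color_means
from .texture import region_texture_features

__all__ = ["extract_features", "feature_columns", "COVARIATE_COLUMNS"]

COVARIATE_COLUMNS = ("gender", "age", "bmi")
_COLOR_KEYS = (("rgb", "R"), ("rgb", "G"), ("rgb", "B"),
               ("hsi", "H"), ("hsi", "S"), ("hsi", "I"),
               ("lab", "L"), ("lab", "a"), ("lab", "b"))
_TEX_KEYS = ("CON", "ASM", "ENT", "MEAN")


def feature_columns(include_covariates: bool = True) -> list:
    cols = list(COVARIATE_COLUMNS) if include_covariates else []
    for region in ("body", "coating"):
        cols += [f"{region}_{space}_{ch}" for space, ch in _COLOR_KEYS]
    for region in ("body", "coating"):
        cols += [f"{region}_tex_{k}" for k in _TEX_KEYS]
    return cols


def extract_features(image, body_mask, coating_mask, covariates=None) -> dict:
    """Feature dict for one subject; ``covariates`` maps gender/age/bmi."""
    row = {}
    if covariates is not None:
        for k in COVARIATE_COLUMNS:
            row[k] = covariates[k]
    for region, mask in (("body", body_mask), ("coating", coating_mask)):
        cf = region_color_means(image, mask)
        for space, ch in _COLOR_KEYS:
            row[f"{region}_{space}_{ch}"] = getattr(cf, ch)
    for region, mask in (("body", body_mask), ("coating", coating_mask)):
        tf = region_texture_features(image, mask)
        for k in _TEX_KEYS:
            row[f"{region}_tex_{k}"] = getattr(tf, k)
    return row


def features_table(rows, labels=None) -> pd.DataFrame:
    """Stack feature dicts into a table in the canonical column order."""
    df = pd.DataFrame(list(rows))
    cols = [c for c in feature_columns() if c in df.columns]
    df = df[cols + [c for c in df.columns if c not in cols]]
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=int)
    return df
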