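"""Leakage-free preprocessing for tabular and image cohorts.

Tabular: per-feature mean imputation and standard normalization (mean 0,
sd 1), with all parameters estimated from the training partition only.
Constant features pass through centered with a unit divisor.

Images: zero-signal preserving contrast enhancement — tissue (nonzero)
pixels are standardized per image while background zeros stay bit-identical,
amplifying intensity variation inside the signal region without inventing
signal where there is none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Preprocessor", "fit_preprocessor", "zero_signal_contrast_enhance"]


@dataclass(frozen=True)
class Preprocessor:
    """Frozen imputation + standardization parameters (train-derived)."""

    means: np.ndarray  # per-feature imputation / centering mean
    stds: np.ndarray  # per-feature divisor; 1.0 where the feature is constant

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64).copy()
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.broadcast_to(self.means, X.shape)[nan]
        return (X - self.means) / self.stds


def fit_preprocessor(train_features: np.ndarray) -> Preprocessor:
    """Estimate imputation means and normalization parameters from train rows.

    Missing values are NaN.  Raises if a feature has no observed value at
    all, naming the column.
    """
    X = np.asarray(train_features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D feature matrix with at least 2 training rows")
    observed = ~np.isnan(X)
    empty = np.where(observed.sum(axis=0) == 0)[0]
    if empty.size:
        raise ValueError(
            f"feature column(s) {empty.tolist()} contain no observed values"
        )
    means = np.nanmean(X, axis=0)
    filled = np.where(observed, X, means)
    stds = filled.std(axis=0)  # population sd, matching the normalization target
    stds = np.where(stds > 0, stds, 1.0)
    return Preprocessor(means=means, stds=stds)


def zero_signal_contrast_enhance(
    image: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Standardize tissue pixels to mean 0 / sd 1; keep background zeros.

    ``mask`` selects tissue explicitly; by default every nonzero pixel is
    tissue.  An all-background image is returned unchanged with a warning.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single 2D image")
    tissue = (img != 0) if mask is None else np.asarray(mask, dtype=bool)
    out = img.copy()
    n = int(tissue.sum())
    if n == 0:
        warnings.warn("image has no tissue pixels; returned unchanged", stacklevel=2)
        return out
    vals = img[tissue]
    sd = vals.std()
    out[tissue] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    return out


def enhance_stack(images: np.ndarray) -> np.ndarray:
    """Apply zero-signal contrast enhancement image-by-image to (n, H, W)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.stack([zero_signal_contrast_enhance(im) for im in images])
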