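"""Histogram statistics, mean + k·σ thresholding and binarization.

The classification cutoff is computed from the intensity histogram of the
whole analysis area: threshold = mean + k·σ with k = 0.5 validated against
polystyrene size standards.  σ is the population standard deviation
(divisor n); all pixels of the area enter the histogram — there is no
background pre-masking.  Pixels at or above the threshold are the object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import BandImage

__all__ = [
    "HistogramStats",
    "ThresholdSpec",
    "BinaryImage",
    "KSigmaBinarizer",
    "histogram_stats",
    "threshold_value",
    "binarize",
]

MODE_MEAN_K_SIGMA = "mean_plus_k_sigma"
MODE_NEG_DERIV_ZERO = "negative_derivative_zero"


@dataclass(frozen=True)
class HistogramStats:
    """Mean, population σ and maximum of a band image's intensity histogram."""

    mean: float
    sigma: float
    maximum: float
    n_pixels: int

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        # allow for accumulation rounding in the mean of near-constant images
        slack = 1e-9 * max(1.0, abs(self.mean))
        if self.maximum < self.mean - slack:
            raise ValueError("maximum cannot be below the mean")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


@dataclass(frozen=True)
class ThresholdSpec:
    """Threshold rule: ``mean_plus_k_sigma`` (default k = 0.5) or
    ``negative_derivative_zero`` (threshold 0 on the sign-flipped image,
    i.e. keep pixels whose second derivative is negative)."""

    k: float = 0.5
    mode: str = MODE_MEAN_K_SIGMA

    def __post_init__(self):
        if self.mode not in (MODE_MEAN_K_SIGMA, MODE_NEG_DERIV_ZERO):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == MODE_MEAN_K_SIGMA and self.k < 0:
            raise ValueError("k must be >= 0 for mean_plus_k_sigma")


@dataclass
class BinaryImage:
    """Object mask (True = object) with provenance of the threshold used."""

    mask: np.ndarray
    pixel_size: float
    threshold_used: float

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.mask = m.astype(bool)
        self.pixel_size = float(self.pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def object_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_percent(self) -> float:
        return 100.0 * self.object_pixels / self.mask.size


def histogram_stats(img: BandImage | np.ndarray) -> HistogramStats:
    """Mean / population σ / maximum over all pixels of one analysis area."""
    values = img.values if isinstance(img, BandImage) else np.asarray(img, dtype=float)
    if values.size == 0:
        raise ValueError("empty image")
    return HistogramStats(
        mean=float(values.mean()),
        sigma=float(values.std(ddof=0)),
        maximum=float(values.max()),
        n_pixels=int(values.size),
    )


def threshold_value(stats: HistogramStats, spec: ThresholdSpec | None = None) -> float:
    """Classification cutoff for the given histogram statistics."""
    if spec is None:
        spec = ThresholdSpec()
    if spec.mode == MODE_NEG_DERIV_ZERO:
        return 0.0
    return stats.mean + spec.k * stats.sigma


def binarize(img: BandImage, threshold: float) -> BinaryImage:
    """Mask of pixels at or above the threshold (>=, not >)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryImage(
        mask=img.values >= threshold,
        pixel_size=img.pixel_size,
        threshold_used=float(threshold),
    )


class KSigmaBinarizer(BaseEstimator, TransformerMixin):
    """Histogram-statistics binarizer as a scikit-learn transformer.

    ``fit(X)`` computes the intensity histogram's mean and population σ over
    every element of ``X`` (one analysis area) and derives
    ``threshold_ = mean_ + k·sigma_`` (or 0 in ``negative_derivative_zero``
    mode); ``transform(X)`` returns the boolean object mask ``X >=
    threshold_``.  The pixel grid shape is preserved: 2-D input yields a 2-D
    mask.

    Parameters
    ----------
    k : float, default 0.5
        Multiplier on σ; k = 0.5 is the value validated on polystyrene
        size-standard model tablets.
    mode : str, default "mean_plus_k_sigma"

    Attributes
    ----------
    mean_, sigma_, maximum_ : float
    threshold_ : float
    n_pixels_ : int
    """

    def __init__(self, k: float = 0.5, mode: str = MODE_MEAN_K_SIGMA):
        self.k = k
        self.mode = mode

    def fit(self, X, y=None):
        spec = ThresholdSpec(self.k, self.mode)
        X = check_array(X, allow_nd=True, ensure_2d=False, ensure_min_samples=1)
        stats = histogram_stats(np.asarray(X, dtype=float))
        self.mean_ = stats.mean
        self.sigma_ = stats.sigma
        self.maximum_ = stats.maximum
        self.n_pixels_ = stats.n_pixels
        self.threshold_ = threshold_value(stats, spec)
        return self

    def transform(self, X):
        check_is_fitted(self, "threshold_")
        X = check_array(X, allow_nd=True, ensure_2d=False)
        return np.asarray(X, dtype=float) >= self.threshold_

    def fit_binarize(self, img: BandImage) -> BinaryImage:
        """Convenience: fit on a band image and return its BinaryImage."""
        self.fit(img.values)
        return BinaryImage(
            mask=img.values >= self.threshold_,
            pixel_size=img.pixel_size,
            threshold_used=self.threshold_,
        )
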