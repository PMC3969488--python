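"""Savitzky–Golay second-derivative preprocessing and band-image extraction.

Each pixel spectrum is converted to its second derivative with a
Savitzky–Golay filter (default 31-point window, cubic polynomial).  The
second derivative suppresses slowly varying baseline — constant and linear
backgrounds vanish identically — while a genuine Raman band becomes a
negative trough; multiplying by -1 turns it back into a positive peak, which
is the convention used downstream for thresholding.

The derivative is scaled by the channel spacing (``delta`` of the filter), so
values are per cm^-2 and comparable across maps with different axis spacing.
Edge channels (half a window at each end) are not trusted: they are tracked
as an invalid margin and band selection inside the margin is refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import (
    SIGN_RAW,
    SIGN_SECOND_DERIVATIVE,
    BandImage,
    HyperMap,
)

__all__ = [
    "DerivativeParams",
    "SavitzkyGolayDerivative",
    "second_derivative_map",
    "band_image",
    "nearest_channel",
]

_AXIS_RTOL = 1e-6  # relative tolerance on axis uniformity


@dataclass(frozen=True)
class DerivativeParams:
    """Savitzky–Golay second-derivative settings.

    window_points must be odd and >= poly_order + 1; poly_order >= 2 so a
    second derivative exists.  The derivative order is fixed at 2.
    """

    window_points: int = 31
    poly_order: int = 3
    deriv_order: int = 2

    def __post_init__(self):
        if self.deriv_order != 2:
            raise ValueError("deriv_order is fixed at 2")
        if self.window_points % 2 == 0 or self.window_points < self.poly_order + 1:
            raise ValueError(
                "window_points must be odd and >= poly_order + 1 "
                f"(got window={self.window_points}, order={self.poly_order})"
            )
        if self.poly_order < self.deriv_order:
            raise ValueError("poly_order must be >= 2 for a second derivative")

    @property
    def margin(self) -> int:
        """Number of untrusted edge channels at each end of the axis."""
        return self.window_points // 2


def _check_uniform_spacing(wavenumbers: np.ndarray) -> float:
    d = np.diff(wavenumbers)
    spacing = float(np.mean(d))
    if spacing <= 0:
        raise ValueError("axis must be ascending")
    if np.max(np.abs(d - spacing)) > _AXIS_RTOL * abs(spacing):
        raise ValueError(
            "wavenumber axis is not uniformly spaced; the Savitzky-Golay "
            "convolution assumes a uniform grid"
        )
    return spacing


class SavitzkyGolayDerivative(BaseEstimator, TransformerMixin):
    """Second-derivative transformer over a matrix of spectra.

    Operates on ``X`` of shape ``(n_spectra, n_channels)``; rows are
    independent spectra on a common uniform axis.  Stateless apart from the
    axis spacing resolved at fit time.

    Parameters
    ----------
    window_points : int, default 31
        Odd filter window length in channels.
    poly_order : int, default 3
        Fitting polynomial degree (>= 2).
    spacing : float, default 1.0
        Channel spacing in cm^-1; the output is scaled to per cm^-2.

    Attributes
    ----------
    n_features_in_ : int
    margin_ : int
        Edge channels at each end whose output is untrusted.
    """

    def __init__(self, window_points: int = 31, poly_order: int = 3, spacing: float = 1.0):
        self.window_points = window_points
        self.poly_order = poly_order
        self.spacing = spacing

    def _params(self) -> DerivativeParams:
        return DerivativeParams(self.window_points, self.poly_order)

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=2)
        params = self._params()
        if X.shape[1] < params.window_points:
            raise ValueError(
                f"window ({params.window_points} points) exceeds channel count ({X.shape[1]})"
            )
        if not (float(self.spacing) > 0):
            raise ValueError("spacing must be > 0")
        self.n_features_in_ = X.shape[1]
        self.margin_ = params.margin
        return self

    def transform(self, X):
        check_is_fitted(self, "margin_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("channel count changed between fit and transform")
        return savgol_filter(
            X,
            window_length=self.window_points,
            polyorder=self.poly_order,
            deriv=2,
            delta=float(self.spacing),
            axis=-1,
            mode="interp",
        )


def second_derivative_map(hmap: HyperMap, params: DerivativeParams | None = None) -> HyperMap:
    """Per-pixel SG second derivative of a raw hyperspectral map.

    Refuses maps already carrying a derivative sign convention (re-deriving a
    derivative map is always a mistake) and non-uniform axes.  The result has
    the same shape, ``sign_convention == "second_derivative"``, and a
    ``valid_channel_margin`` of half the filter window recorded in ``meta``.
    """
    if params is None:
        params = DerivativeParams()
    if hmap.sign_convention != SIGN_RAW:
        raise ValueError(
            f"map already holds a derivative (sign convention "
            f"{hmap.sign_convention!r}); refusing to differentiate again"
        )
    if hmap.n_channels < params.window_points:
        raise ValueError(
            f"window ({params.window_points} points) exceeds channel count "
            f"({hmap.n_channels})"
        )
    spacing = _check_uniform_spacing(hmap.wavenumbers)
    est = SavitzkyGolayDerivative(params.window_points, params.poly_order, spacing)
    flat = hmap.intensities.reshape(-1, hmap.n_channels)
    deriv = est.fit_transform(flat).reshape(hmap.intensities.shape)
    meta = dict(hmap.meta)
    meta["sign_convention"] = SIGN_SECOND_DERIVATIVE
    meta["valid_channel_margin"] = params.margin
    meta["derivative_params"] = {
        "window_points": params.window_points,
        "poly_order": params.poly_order,
        "deriv_order": 2,
    }
    return HyperMap(deriv, hmap.wavenumbers.copy(), hmap.pixel_size, meta)


def nearest_channel(wavenumbers: np.ndarray, target: float) -> int:
    """Index of the channel nearest ``target``; ties resolve to the lower
    wavenumber."""
    wn = np.asarray(wavenumbers, dtype=float)
    if not (wn[0] <= target <= wn[-1]):
        raise ValueError(
            f"target {target} cm^-1 outside axis range [{wn[0]}, {wn[-1]}]"
        )
    dist = np.abs(wn - target)
    # argmin returns the first (lower-wavenumber) index on exact ties
    return int(np.argmin(dist))


def band_image(hmap: HyperMap, target_wavenumber: float, flip_sign: bool = True) -> BandImage:
    """Univariate image at the channel nearest ``target_wavenumber``.

    With ``flip_sign`` (the default) the map must be a second-derivative map
    and the selected channel is multiplied by -1, so a genuine Raman band
    yields positive values.  Selection within the filter's invalid edge
    margin is refused.
    """
    if flip_sign and hmap.sign_convention != SIGN_SECOND_DERIVATIVE:
        raise ValueError(
            "flip_sign expects a second-derivative map; got sign convention "
            f"{hmap.sign_convention!r}"
        )
    ch = nearest_channel(hmap.wavenumbers, target_wavenumber)
    margin = int(hmap.meta.get("valid_channel_margin", 0))
    if margin and not (margin <= ch < hmap.n_channels - margin):
        raise ValueError(
            f"channel {ch} ({hmap.wavenumbers[ch]} cm^-1) lies within the "
            f"{margin}-channel edge margin of the derivative filter"
        )
    values = hmap.intensities[:, :, ch]
    if flip_sign:
        values = -values
    return BandImage(
        values=values.copy(),
        band_wavenumber_requested=float(target_wavenumber),
        band_wavenumber_actual=float(hmap.wavenumbers[ch]),
        pixel_size=hmap.pixel_size,
        sign_flipped=bool(flip_sign),
    )
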