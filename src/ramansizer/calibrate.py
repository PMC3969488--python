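"""Model-tablet calibration: recovery, post-vs-pre regression, threshold sweep.

A model tablet embeds size standards of known (pre-formulation) mean
diameter in the production excipient matrix.  Running the imaging pipeline
on its cross-sections yields post-formulation pooled mean diameters; the
quality of a candidate binarization threshold is judged by

* recovery — 100 x post / pre per standard, and
* the ordinary least-squares regression (with intercept) of post pooled
  means on pre means across standards, whose slope should be ~1 at a good
  threshold (1.02 at mean + 0.5 sigma for the polystyrene standards, falling
  to 0.49 at mean + 1.5 sigma as the threshold erodes large particles).

``threshold_sweep`` runs the whole chain (derivative -> band image ->
mean + k sigma mask -> labelling -> pooling) over a grid of k values and
tabulates per-standard statistics plus slope/r per k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .core import HyperMap
from .preprocess import DerivativeParams, band_image, second_derivative_map
from .segment import KSigmaBinarizer
from .sizing import PooledSummary, label_particles, pool_areas

__all__ = [
    "StandardPair",
    "CalibrationResult",
    "CalibrationRegression",
    "recovery",
    "calibration_regression",
    "size_areas",
    "threshold_sweep",
]


@dataclass(frozen=True)
class StandardPair:
    """One size standard: its pre-formulation mean and post-formulation pooling."""

    label: str
    pre_mean: float
    post_pooled: PooledSummary

    def __post_init__(self):
        if not (self.pre_mean > 0):
            raise ValueError("pre_mean must be > 0")

    @property
    def recovery(self) -> float:
        return recovery(self.pre_mean, self.post_pooled.pooled_mean)


@dataclass
class CalibrationResult:
    """Post-vs-pre regression across standards at one threshold multiplier."""

    slope: float
    intercept: float
    r: float
    recoveries: dict = field(default_factory=dict)  # standard label -> %
    k: float | None = None

    def __post_init__(self):
        if np.isfinite(self.r) and not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("correlation r must lie in [-1, 1]")


def recovery(pre_mean: float, post_mean: float) -> float:
    """Recovery in percent: 100 x post-formulation / pre-formulation mean."""
    if not (pre_mean > 0):
        raise ValueError("pre_mean must be > 0")
    return 100.0 * post_mean / pre_mean


class CalibrationRegression(BaseEstimator, RegressorMixin):
    """OLS fit (with intercept) of post-formulation on pre-formulation means.

    ``X`` is ``(n_standards, 1)`` pre-formulation mean diameters, ``y`` the
    matching post-formulation pooled means.  Exposes ``slope_``,
    ``intercept_`` and the Pearson correlation ``r_``.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be (n_standards, 1) pre-formulation means")
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        if X.shape[0] < 2:
            raise ValueError("need at least two standards for a regression")
        x = X[:, 0]
        if np.ptp(x) == 0:
            raise ValueError("identical pre-formulation means: singular fit")
        res = _stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_ = float(res.rvalue)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.slope_ * X[:, 0] + self.intercept_


def calibration_regression(pairs) -> CalibrationResult:
    """Regression + recoveries over ``StandardPair`` items (>= 2 distinct)."""
    pairs = list(pairs)
    pre = np.array([p.pre_mean for p in pairs], dtype=float)
    post = np.array([p.post_pooled.pooled_mean for p in pairs], dtype=float)
    est = CalibrationRegression().fit(pre[:, None], post)
    return CalibrationResult(
        slope=est.slope_,
        intercept=est.intercept_,
        r=est.r_,
        recoveries={p.label: p.recovery for p in pairs},
    )


def size_areas(
    maps,
    band: float,
    k: float = 0.5,
    connectivity: int = 8,
    deriv_params: DerivativeParams | None = None,
) -> PooledSummary:
    """Run derivative -> band image -> mean+k·σ mask -> labelling on each raw
    map (one analysis area each) and pool the per-area results.

    Maps already carrying the second-derivative sign convention skip the
    derivative stage, so a pre-differentiated map list may be reused across
    k values without recomputation.
    """
    particle_sets = []
    for hmap in maps:
        dmap = (
            hmap
            if hmap.sign_convention == "second_derivative"
            else second_derivative_map(hmap, deriv_params)
        )
        img = band_image(dmap, band, flip_sign=True)
        mask = KSigmaBinarizer(k=k).fit_binarize(img)
        particle_sets.append(label_particles(mask, connectivity=connectivity))
    return pool_areas(particle_sets)


def threshold_sweep(
    maps_by_standard: dict,
    band: float,
    pre_means: dict,
    ks=(0.0, 0.5, 1.0, 1.5),
    connectivity: int = 8,
    deriv_params: DerivativeParams | None = None,
):
    """Full calibration sweep over threshold multipliers.

    Parameters
    ----------
    maps_by_standard : dict
        standard label -> list of raw HyperMap (one per analysis area).
    band : float
        Analysis wavenumber in cm^-1.
    pre_means : dict
        standard label -> pre-formulation mean diameter (um).  May instead
        map to a dict ``{k: pre_mean}`` when the pre-formulation reference
        itself was measured per threshold.
    ks : sequence of float

    Returns
    -------
    table : pandas.DataFrame
        One row per (standard, k): pooled mean/STD (um), area %, particle
        count, recovery (%).
    results : dict
        k -> CalibrationResult (slope/r are NaN for a single standard;
        flagged, not an error, so a degenerate sweep still reports).
    """
    missing = set(maps_by_standard) - set(pre_means)
    if missing:
        raise ValueError(f"no pre-formulation mean for standards {sorted(missing)}")

    # differentiate each area once, reuse across k values
    deriv_by_standard: dict = {}
    for label, maps in maps_by_standard.items():
        if not maps:
            raise ValueError(f"standard {label!r} has no analysis areas")
        deriv = []
        for i, hmap in enumerate(maps):
            try:
                deriv.append(
                    hmap
                    if hmap.sign_convention == "second_derivative"
                    else second_derivative_map(hmap, deriv_params)
                )
            except Exception as exc:
                raise RuntimeError(
                    f"derivative stage failed (standard={label!r}, area={i})"
                ) from exc
        deriv_by_standard[label] = deriv

    rows = []
    results: dict = {}
    for k in ks:
        pairs = []
        for label, dmaps in deriv_by_standard.items():
            try:
                pooled = size_areas(dmaps, band, k=k, connectivity=connectivity)
            except Exception as exc:
                raise RuntimeError(
                    f"sizing stage failed (standard={label!r}, k={k})"
                ) from exc
            pre = pre_means[label]
            pre_k = pre[k] if isinstance(pre, dict) else pre
            pairs.append(StandardPair(label, float(pre_k), pooled))
            rows.append(
                {
                    "standard": label,
                    "k": k,
                    "pre_mean_um": float(pre_k),
                    "mean_um": pooled.pooled_mean,
                    "std_um": pooled.pooled_std,
                    "area_percent": pooled.pooled_area_percent,
                    "particle_count": pooled.total_particles,
                    "recovery_percent": pairs[-1].recovery,
                }
            )
        if len(pairs) >= 2:
            res = calibration_regression(pairs)
            res.k = k
        else:
            res = CalibrationResult(
                slope=float("nan"),
                intercept=float("nan"),
                r=float("nan"),
                recoveries={p.label: p.recovery for p in pairs},
                k=k,
            )
        results[k] = res
    return pd.DataFrame(rows), results
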