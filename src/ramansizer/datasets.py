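"""Published model-tablet validation results, as worked-example inputs.

These tables come from a published validation of the mean + k·σ binarization
threshold against NIST-traceable polystyrene microsphere size standards
(certified 4.9 ± 0.4, 9.8 ± 0.5 and 15.8 ± 0.6 um) embedded in a commercial
antihistamine tablet formulation, plus its application to the production
tablet's micronized API.  They serve as inputs to the pooling, recovery and
regression operations — the imaging raw data are not public, but the
per-area statistics are, and the pooled results are exactly recomputable
from them.

``MODEL_TABLET_AREAS`` holds, per standard, the pre-formulation Raman
sizing mean and the three per-area post-formulation results at the
validated threshold (k = 0.5).  ``SWEEP_POOLED_MEANS`` holds the pre and
pooled post means at each threshold multiplier k in {0, 0.5, 1.0, 1.5}.
``API_TABLET_AREAS`` is the same layout for the production tablet's API.
"""

from __future__ import annotations

from .core import SizingSummary

__all__ = [
    "MODEL_TABLET_AREAS",
    "API_TABLET_AREAS",
    "SWEEP_POOLED_MEANS",
    "CERTIFIED_SIZES",
    "model_tablet_summaries",
    "api_tablet_summaries",
]

# standard -> dict(pre_mean, pre_std, pre_area_percent, pre_count,
#                  areas=[(mean_um, std_um, area_percent, count), ...])
MODEL_TABLET_AREAS = {
    "ps5": {
        "pre_mean": 6.30,
        "pre_std": 0.58,
        "pre_area_percent": 3.46,
        "pre_count": 11,
        "areas": [
            (7.07, 4.73, 11.18, 20),
            (6.36, 4.37, 14.97, 32),
            (5.74, 3.53, 17.39, 49),
        ],
    },
    "ps10": {
        "pre_mean": 10.58,
        "pre_std": 0.65,
        "pre_area_percent": 6.18,
        "pre_count": 10,
        "areas": [
            (11.17, 5.70, 9.63, 8),
            (10.16, 5.35, 14.41, 14),
            (9.81, 5.97, 19.40, 19),
        ],
    },
    "ps15": {
        "pre_mean": 15.79,
        "pre_std": 0.36,
        "pre_area_percent": 7.84,
        "pre_count": 4,
        "areas": [
            (16.42, 10.13, 10.89, 4),
            (14.15, 8.12, 12.03, 6),
            (16.96, 4.13, 19.01, 8),
        ],
    },
}

# Production (API) tablet, micronized ebastine at the validated threshold.
API_TABLET_AREAS = {
    "ebastine": {
        "pre_mean": 4.11,
        "pre_std": 3.78,
        "pre_area_percent": 10.72,
        "pre_count": 52,
        "areas": [
            (3.94, 4.34, 22.83, 85),
            (4.62, 4.35, 24.25, 77),
            (4.42, 3.85, 22.79, 85),
        ],
    },
}

# Threshold sweep: k -> standard -> (pre_mean_um, post_pooled_mean_um).
# Pre-formulation references were themselves re-measured at each k.
SWEEP_POOLED_MEANS = {
    0.0: {"ps5": (7.14, 6.89), "ps10": (11.26, 11.11), "ps15": (16.51, 17.42)},
    0.5: {"ps5": (6.30, 6.20), "ps10": (10.58, 10.19), "ps15": (15.79, 15.90)},
    1.0: {"ps5": (5.96, 5.18), "ps10": (10.15, 8.50), "ps15": (15.41, 12.56)},
    1.5: {"ps5": (5.63, 4.63), "ps10": (9.87, 7.39), "ps15": (14.99, 9.26)},
}

# Certified mean diameter and certificate population SD per standard (um).
CERTIFIED_SIZES = {"ps5": (4.9, 0.5), "ps10": (9.8, 1.0), "ps15": (15.8, 1.3)}


def _summaries(table: dict, standard: str) -> list[SizingSummary]:
    entry = table[standard]
    return [
        SizingSummary(mean_diameter=m, std_diameter=s, area_percent=a, particle_count=n)
        for m, s, a, n in entry["areas"]
    ]


def model_tablet_summaries(standard: str) -> list[SizingSummary]:
    """Per-area post-formulation summaries for one PS standard (k = 0.5)."""
    return _summaries(MODEL_TABLET_AREAS, standard)


def api_tablet_summaries() -> list[SizingSummary]:
    """Per-area post-formulation summaries for the production tablet's API."""
    return _summaries(API_TABLET_AREAS, "ebastine")
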