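"""Connected-component particle sizing and cross-area pooling.

Each connected object region in a binary image is one "particle" (complete
individual particles, agglomerates and colocalized particles alike — the
method accepts these as part of its statistics).  A particle is approximated
by the circle occupying the same area, so its size is the equivalent
circular diameter d = 2·sqrt(A/pi).

Per-area summaries report the mean and sample STD of equivalent diameters,
the object area percentage and the particle count.  Results from the several
areas scanned per tablet cross-section are pooled with particle-count
weights, which is identical to summarizing the concatenation of all areas'
particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import SizingSummary
from .segment import BinaryImage

__all__ = [
    "Particle",
    "ParticleSet",
    "PooledSummary",
    "label_particles",
    "equivalent_diameter",
    "summarize",
    "pool_areas",
]

_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def equivalent_diameter(pixel_count: int, pixel_size: float) -> float:
    """Equivalent circular diameter (um) of a region of ``pixel_count`` pixels.

    d = 2 * sqrt(pixel_count * pixel_size**2 / pi)
    """
    if pixel_count < 1:
        raise ValueError("pixel_count must be >= 1")
    if not (pixel_size > 0):
        raise ValueError("pixel_size must be > 0")
    return 2.0 * math.sqrt(pixel_count * pixel_size * pixel_size / math.pi)


@dataclass(frozen=True)
class Particle:
    """One labelled object region.

    centroid is (x, y) in pixel coordinates (x = column, y = row);
    touches_border marks regions reaching the image edge (included in all
    statistics, flagged so callers may exclude them).
    """

    label: int
    pixel_count: int
    area: float
    equivalent_diameter: float
    centroid: tuple[float, float]
    touches_border: bool

    def __post_init__(self):
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")


@dataclass
class ParticleSet:
    """Labelled particles of one analysis area."""

    particles: list[Particle]
    source_shape: tuple[int, int]
    pixel_size: float

    def __post_init__(self):
        labels = [p.label for p in self.particles]
        if labels != list(range(1, len(labels) + 1)):
            raise ValueError("labels must be contiguous from 1 in order")
        total = sum(p.pixel_count for p in self.particles)
        if total > self.source_shape[0] * self.source_shape[1]:
            raise ValueError("total pixel count exceeds image size")

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def diameters(self) -> np.ndarray:
        return np.array([p.equivalent_diameter for p in self.particles], dtype=float)

    @property
    def total_object_pixels(self) -> int:
        return sum(p.pixel_count for p in self.particles)

    @property
    def area_percent(self) -> float:
        rows, cols = self.source_shape
        return 100.0 * self.total_object_pixels / (rows * cols)


@dataclass
class PooledSummary:
    """Particle-count-weighted pooling of several areas' summaries.

    pooled_mean = sum(n_i * mean_i) / sum(n_i), identical to the unweighted
    mean over all particles pooled together; pooled_std is the sample STD of
    the concatenated diameters; pooled_area_percent is the unweighted mean of
    the per-area area percentages (areas share pixel dimensions).
    """

    pooled_mean: float
    pooled_std: float
    pooled_area_percent: float
    total_particles: int
    per_area: list[SizingSummary] = field(default_factory=list)


def label_particles(mask: BinaryImage | np.ndarray, connectivity: int = 8,
                    pixel_size: float | None = None) -> ParticleSet:
    """Label maximal connected object regions of a binary mask.

    connectivity 8 (the default) joins diagonal neighbours; 4 joins only
    edge neighbours.  Labels are assigned in raster-scan order of each
    region's first pixel.
    """
    if connectivity not in _STRUCTURE:
        raise ValueError("connectivity must be 4 or 8")
    if isinstance(mask, BinaryImage):
        arr = mask.mask
        px = mask.pixel_size if pixel_size is None else float(pixel_size)
    else:
        arr = np.asarray(mask).astype(bool)
        px = 1.0 if pixel_size is None else float(pixel_size)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    labelled, n = ndimage.label(arr, structure=_STRUCTURE[connectivity])

    # enforce raster-scan label order by each region's first pixel
    flat = labelled.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier raster indices overwrite later ones
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first_idx[1:], kind="stable")  # old label - 1, raster order
    remap = np.zeros(n + 1, dtype=np.int64)
    remap[order + 1] = np.arange(1, n + 1)
    labelled = remap[labelled]

    rows, cols = arr.shape
    particles: list[Particle] = []
    if n:
        objects = ndimage.find_objects(labelled)
        counts = np.bincount(labelled.ravel(), minlength=n + 1)
        cy, cx = np.mgrid[0:rows, 0:cols]
        sum_y = ndimage.sum_labels(cy, labelled, index=np.arange(1, n + 1))
        sum_x = ndimage.sum_labels(cx, labelled, index=np.arange(1, n + 1))
        for lbl in range(1, n + 1):
            sl = objects[lbl - 1]
            cnt = int(counts[lbl])
            touches = (
                sl[0].start == 0
                or sl[1].start == 0
                or sl[0].stop == rows
                or sl[1].stop == cols
            )
            particles.append(
                Particle(
                    label=lbl,
                    pixel_count=cnt,
                    area=cnt * px * px,
                    equivalent_diameter=equivalent_diameter(cnt, px),
                    centroid=(float(sum_x[lbl - 1] / cnt), float(sum_y[lbl - 1] / cnt)),
                    touches_border=bool(touches),
                )
            )
    return ParticleSet(particles=particles, source_shape=(rows, cols), pixel_size=px)


def summarize(ps: ParticleSet) -> SizingSummary:
    """Per-area summary: mean / sample STD (divisor n-1; 0 for a single
    particle) of equivalent diameters, object area %, particle count."""
    n = len(ps)
    if n == 0:
        return SizingSummary(float("nan"), float("nan"), ps.area_percent, 0)
    d = ps.diameters
    return SizingSummary(
        mean_diameter=float(d.mean()),
        std_diameter=float(d.std(ddof=1)) if n > 1 else 0.0,
        area_percent=ps.area_percent,
        particle_count=n,
    )


def _as_summary(area) -> SizingSummary:
    if isinstance(area, ParticleSet):
        return summarize(area)
    if isinstance(area, SizingSummary):
        return area
    raise TypeError(f"expected SizingSummary or ParticleSet, got {type(area)!r}")


def pool_areas(areas) -> PooledSummary:
    """Particle-count-weighted pooling across analysis areas.

    Accepts SizingSummary or ParticleSet items (mixed is fine).  When
    ParticleSets are given the pooled mean/STD equal a summary of the
    concatenated particle list exactly; from summaries alone the pooled STD
    is recovered through the within+between decomposition of the sample
    variance, which is algebraically the same quantity.
    """
    areas = list(areas)
    if not areas:
        raise ValueError("pool_areas needs at least one area")
    summaries = [_as_summary(a) for a in areas]
    total = sum(s.particle_count for s in summaries)
    if total == 0:
        raise ValueError("all areas are empty; nothing to pool")
    pooled_area = float(np.mean([s.area_percent for s in summaries]))
    nonempty = [s for s in summaries if s.particle_count > 0]
    pooled_mean = (
        sum(s.particle_count * s.mean_diameter for s in nonempty) / total
    )
    if total > 1:
        within = sum(
            (s.particle_count - 1) * s.std_diameter**2 for s in nonempty
        )
        between = sum(
            s.particle_count * (s.mean_diameter - pooled_mean) ** 2 for s in nonempty
        )
        pooled_std = math.sqrt((within + between) / (total - 1))
    else:
        pooled_std = 0.0
    return PooledSummary(
        pooled_mean=float(pooled_mean),
        pooled_std=float(pooled_std),
        pooled_area_percent=pooled_area,
        total_particles=int(total),
        per_area=summaries,
    )
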