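"""Synthetic hyperspectral tablet-cross-section phantoms with ground truth.

The generator emulates the model-tablet experiment: a 100 x 100 um tablet
cross-section scanned at a 1-um step over a static spectral window, with
microsphere-like particles (an isolated discriminating band at 1,605 cm^-1
for the polystyrene analog, 1,601 cm^-1 for the ebastine analog) embedded in
a multi-component excipient matrix with per-pixel baseline drift and
detector noise.  Every pipeline stage can therefore be exercised, and its
output compared with ground truth, without instrument data.

Particles are 2-D disks placed in the section plane, not random chords of
3-D spheres: the imaging method sizes what the laser interrogates, and its
reference (pre-formulation) sizing is itself a 2-D projected measurement, so
sampling chord circles would build in a bias the method does not model.
Sub-surface response and surface roughness are mimicked qualitatively by a
one-pixel intensity skirt ("halo") outside each disk, not by an optical
model.

Generation is fully deterministic for a fixed seed (single NumPy generator,
fixed call order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import SIGN_RAW, HyperMap, SizingSummary, Spectrum

__all__ = [
    "ComponentSpectrum",
    "PhantomSpec",
    "GroundTruth",
    "default_library",
    "generate",
    "truth_section_summary",
    "preset",
    "PRESETS",
]

PS_BAND = 1605.0
EBASTINE_BAND = 1601.0


@dataclass(frozen=True)
class ComponentSpectrum:
    """Parametric pure-component spectrum: Gaussian bands + polynomial baseline.

    peaks are (center cm^-1, width sigma cm^-1, height counts) triples;
    baseline coefficients are ascending-order polynomial coefficients in the
    scaled variable (wavenumber - 1950) / 1750 (so the constant term is the
    mid-window offset).
    """

    name: str
    peaks: tuple = ()
    baseline: tuple = (0.0,)

    def __post_init__(self):
        for center, width, height in self.peaks:
            if not (width > 0):
                raise ValueError(f"{self.name}: band width must be > 0")
            if height < 0:
                raise ValueError(f"{self.name}: band height must be >= 0")

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        wn = np.asarray(wavenumbers, dtype=float)
        out = np.polynomial.polynomial.polyval((wn - 1950.0) / 1750.0, self.baseline)
        out = np.broadcast_to(out, wn.shape).astype(float).copy()
        for center, width, height in self.peaks:
            out += height * np.exp(-0.5 * ((wn - center) / width) ** 2)
        return out

    def as_spectrum(self, wavenumbers: np.ndarray) -> Spectrum:
        return Spectrum(wavenumbers, self.evaluate(wavenumbers), name=self.name)


def default_library() -> list[ComponentSpectrum]:
    """Built-in component library.

    * ``polystyrene_analog`` — isolated discriminating band at 1,605 cm^-1
      (plus ring-breathing and CH-stretch analogs outside the analysis
      window);
    * ``ebastine_analog`` — discriminating band at 1,601 cm^-1 of comparable
      height;
    * ``lactose_analog`` — excipient with a modest band at 1,620 cm^-1
      (spectral crowding next to the analysis bands) and strong bands
      elsewhere;
    * ``cellulose_analog`` — excipient whose 1,633 cm^-1 band sits on the
      negative side lobe of the particle band's smoothed second derivative,
      giving excipient-rich pixels the distinctly negative flipped-derivative
      values that shape the left tail of real intensity histograms;
    * ``matrix_analog`` — broad-featured matrix (binder/resin) contributing
      baseline only after differentiation.
    """
    return [
        ComponentSpectrum(
            "polystyrene_analog",
            peaks=((1605.0, 8.0, 1000.0), (1585.0, 7.0, 220.0), (1450.0, 9.0, 160.0),
                   (1001.0, 6.0, 1200.0), (3054.0, 12.0, 500.0)),
            baseline=(40.0,),
        ),
        ComponentSpectrum(
            "ebastine_analog",
            peaks=((1601.0, 8.0, 950.0), (1580.0, 8.0, 150.0), (1450.0, 10.0, 200.0),
                   (1680.0, 9.0, 300.0), (2930.0, 14.0, 420.0)),
            baseline=(45.0,),
        ),
        ComponentSpectrum(
            "lactose_analog",
            peaks=((1620.0, 9.0, 80.0), (1460.0, 10.0, 420.0), (1720.0, 8.0, 120.0),
                   (1085.0, 8.0, 600.0), (2900.0, 15.0, 380.0)),
            baseline=(60.0,),
        ),
        ComponentSpectrum(
            "cellulose_analog",
            peaks=((1633.0, 8.0, 700.0), (1470.0, 10.0, 350.0), (1380.0, 9.0, 250.0),
                   (1096.0, 8.0, 550.0), (2895.0, 14.0, 360.0)),
            baseline=(55.0,),
        ),
        ComponentSpectrum(
            "matrix_analog",
            peaks=((1500.0, 60.0, 140.0), (2950.0, 80.0, 200.0)),
            baseline=(80.0, 25.0),
        ),
    ]


# Excipient mixing proportions (categorical per pixel: granule-scale patches
# of a single dominant excipient, which is what tablet cross-sections show).
DEFAULT_EXCIPIENT_WEIGHTS = {
    "lactose_analog": 0.60,
    "cellulose_analog": 0.08,
    "matrix_analog": 0.32,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom generation parameters.

    Defaults mirror the model-tablet acquisition geometry: 100 x 100 pixels
    at 1 um/pixel over 200-3,700 cm^-1 at 2 cm^-1 spacing.  The axis must
    cover the particle band with at least 15 channels to spare on each side
    (the derivative filter's edge margin).

    target_area_fraction is the true disk coverage of the section, 0.12 by
    default — consistent with the formulation's ~6 wt% particle loading at
    polystyrene vs excipient densities, and with the object area observed at
    the validated threshold.  agglomeration_prob is the chance a disk is
    placed tangent to an existing one (sharing an agglomerate id);
    halo_strength is the peak relative intensity of the one-pixel skirt
    outside each disk; noise_sd is per-channel Gaussian detector noise in
    counts; baseline_drift_amplitude scales the per-pixel linear baseline.
    """

    rows: int = 100
    cols: int = 100
    pixel_size: float = 1.0
    wn_start: float = 200.0
    wn_stop: float = 3700.0
    wn_step: float = 2.0
    particle_diameter_mean: float = 9.8
    particle_diameter_sd: float = 1.0
    target_area_fraction: float = 0.12
    agglomeration_prob: float = 0.05
    halo_strength: float = 0.15
    noise_sd: float = 8.0
    baseline_drift_amplitude: float = 60.0
    seed: int = 0
    particle_component: str = "polystyrene_analog"
    particle_band: float = PS_BAND
    spherical_response: bool = True
    excipient_weights: tuple = tuple(sorted(DEFAULT_EXCIPIENT_WEIGHTS.items()))

    def __post_init__(self):
        for name, val in (
            ("target_area_fraction", self.target_area_fraction),
            ("agglomeration_prob", self.agglomeration_prob),
            ("halo_strength", self.halo_strength),
        ):
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (self.particle_diameter_mean > 0):
            raise ValueError("particle_diameter_mean must be > 0")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("phantom needs at least one pixel")
        margin = 15 * self.wn_step
        if not (self.wn_start + margin <= self.particle_band <= self.wn_stop - margin):
            raise ValueError(
                "axis must cover the particle band with >= 15 channels to spare"
            )

    @property
    def wavenumbers(self) -> np.ndarray:
        n = int(round((self.wn_stop - self.wn_start) / self.wn_step)) + 1
        return self.wn_start + self.wn_step * np.arange(n)

    def thin_axis(self, lo: float = 1400.0, hi: float = 1800.0) -> "PhantomSpec":
        """Same phantom on a narrow window around the analysis band — the
        fast option for tests and sweeps."""
        return replace(self, wn_start=lo, wn_stop=hi)


@dataclass
class GroundTruth:
    """Truth channel: placed disks and the per-pixel coverage fraction map.

    disks rows are (center_x_um, center_y_um, diameter_um, agglomerate_id);
    fraction_map is coverage before the halo is applied (the halo is an
    instrument artifact, not particle).
    """

    disks: list
    fraction_map: np.ndarray
    pixel_size: float = 1.0

    @property
    def diameters(self) -> np.ndarray:
        return np.array([d[2] for d in self.disks], dtype=float)


def truth_section_summary(gt: GroundTruth) -> SizingSummary:
    """Sizing summary of the true placed disks (the target of recovery)."""
    d = gt.diameters
    n = d.size
    rows, cols = gt.fraction_map.shape
    image_area = rows * cols * gt.pixel_size**2
    true_area = float(np.sum(np.pi * d**2 / 4.0))
    area_pct = 100.0 * true_area / image_area
    if n == 0:
        return SizingSummary(float("nan"), float("nan"), area_pct, 0)
    return SizingSummary(
        mean_diameter=float(d.mean()),
        std_diameter=float(d.std(ddof=1)) if n > 1 else 0.0,
        area_percent=area_pct,
        particle_count=int(n),
    )


def _place_disks(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection placement of non-overlapping disks (tangent for
    agglomerates) until the target coverage is reached.

    Non-agglomerate disks keep a one-pixel clearance so distinct particles
    stay distinct in the truth labelling; disks lie fully inside the image.
    Raises if the coverage is unreachable within a bounded attempt budget.
    """
    width = spec.cols * spec.pixel_size
    height = spec.rows * spec.pixel_size
    target_area = spec.target_area_fraction * width * height
    clearance = spec.pixel_size  # between non-agglomerated particles

    disks: list = []  # (cx, cy, r, agg_id)
    placed_area = 0.0
    next_agg = 0
    consecutive_failures = 0
    max_consecutive = 2000
    while placed_area < target_area:
        diameter = 0.0
        while diameter < 1.0:  # physical floor of 1 um
            diameter = rng.normal(spec.particle_diameter_mean, spec.particle_diameter_sd)
        r = diameter / 2.0
        if r > min(width, height) / 2.0:
            consecutive_failures += 1
            if consecutive_failures > max_consecutive:
                raise RuntimeError(
                    "cannot reach target_area_fraction "
                    f"{spec.target_area_fraction}: disks do not fit; "
                    "lower the fraction or the diameter"
                )
            continue
        as_agglomerate = bool(disks) and rng.random() < spec.agglomeration_prob
        placed = False
        for _ in range(50):
            if as_agglomerate:
                px, py, pr, pagg = disks[rng.integers(len(disks))]
                theta = rng.uniform(0.0, 2.0 * math.pi)
                cx = px + (pr + r) * math.cos(theta)
                cy = py + (pr + r) * math.sin(theta)
                partner = (px, py, pr)
            else:
                cx = rng.uniform(r, width - r)
                cy = rng.uniform(r, height - r)
                partner = None
            if not (r <= cx <= width - r and r <= cy <= height - r):
                continue
            ok = True
            for ox, oy, orr, _ in disks:
                if partner is not None and (ox, oy, orr) == partner:
                    continue
                gap = clearance if partner is None else 0.0
                if (cx - ox) ** 2 + (cy - oy) ** 2 < (r + orr + gap) ** 2:
                    ok = False
                    break
            if ok:
                if as_agglomerate:
                    if pagg is None:  # retro-tag the partner with a fresh id
                        pagg = next_agg
                        next_agg += 1
                        for i, (ox, oy, orr, aid) in enumerate(disks):
                            if (ox, oy, orr) == partner and aid is None:
                                disks[i] = (ox, oy, orr, pagg)
                                break
                    agg_id = pagg
                else:
                    agg_id = None
                disks.append((cx, cy, r, agg_id))
                placed_area += math.pi * r * r
                placed = True
                consecutive_failures = 0
                break
        if not placed:
            consecutive_failures += 50
            if consecutive_failures > max_consecutive:
                raise RuntimeError(
                    "cannot reach target_area_fraction "
                    f"{spec.target_area_fraction} after bounded rejection "
                    "attempts; lower the fraction"
                )
    return disks


_SUPERSAMPLE = 4  # linear supersampling factor for coverage fractions


def _coverage_map(spec: PhantomSpec, disks, spherical: bool = False) -> np.ndarray:
    """Per-pixel particle fraction by 4x supersampling.

    With ``spherical`` False this is the geometric disk coverage (the truth
    channel).  With ``spherical`` True each subpixel carries the relative
    chord thickness sqrt(1 - (rho/r)^2) of a sphere sectioned at its equator
    — the signal profile of a spherical particle whose Raman response scales
    with the material inside the focal volume, peaking at the particle
    centre and falling toward the rim.
    """
    s = _SUPERSAMPLE
    rows, cols, px = spec.rows, spec.cols, spec.pixel_size
    grid = np.zeros((rows * s, cols * s), dtype=float)
    sub = px / s
    for cx, cy, r, _ in disks:
        j0 = max(int((cx - r) / sub) - 1, 0)
        j1 = min(int((cx + r) / sub) + 2, cols * s)
        i0 = max(int((cy - r) / sub) - 1, 0)
        i1 = min(int((cy + r) / sub) + 2, rows * s)
        jj = (np.arange(j0, j1) + 0.5) * sub - cx
        ii = (np.arange(i0, i1) + 0.5) * sub - cy
        rho2 = (ii[:, None] ** 2 + jj[None, :] ** 2) / (r * r)
        if spherical:
            vals = np.sqrt(np.clip(1.0 - rho2, 0.0, None))
        else:
            vals = (rho2 <= 1.0).astype(float)
        np.maximum(grid[i0:i1, j0:j1], vals, out=grid[i0:i1, j0:j1])
    return grid.reshape(rows, s, cols, s).mean(axis=(1, 3))


def _halo_map(spec: PhantomSpec, disks) -> np.ndarray:
    """Linear one-pixel skirt outside each disk: halo_strength at the edge,
    0 one pixel away."""
    rows, cols, px = spec.rows, spec.cols, spec.pixel_size
    halo = np.zeros((rows, cols), dtype=float)
    if spec.halo_strength == 0 or not disks:
        return halo
    xs = (np.arange(cols) + 0.5) * px
    ys = (np.arange(rows) + 0.5) * px
    for cx, cy, r, _ in disks:
        j0 = max(int((cx - r - 2 * px) / px), 0)
        j1 = min(int((cx + r + 2 * px) / px) + 1, cols)
        i0 = max(int((cy - r - 2 * px) / px), 0)
        i1 = min(int((cy + r + 2 * px) / px) + 1, rows)
        dd = np.hypot(
            ys[i0:i1, None] - cy, xs[None, j0:j1] - cx
        ) - r  # distance outside the edge, in um
        contrib = spec.halo_strength * np.clip(1.0 - dd / px, 0.0, 1.0)
        contrib[dd <= 0] = 0.0
        np.maximum(halo[i0:i1, j0:j1], contrib, out=halo[i0:i1, j0:j1])
    return halo


def generate(spec: PhantomSpec, library: list[ComponentSpectrum] | None = None):
    """Generate a raw hyperspectral phantom and its ground truth.

    Returns ``(HyperMap, GroundTruth)``.  Deterministic for a fixed
    ``spec.seed``.
    """
    if library is None:
        library = default_library()
    by_name = {c.name: c for c in library}
    if spec.particle_component not in by_name:
        raise ValueError(f"library has no component {spec.particle_component!r}")
    weights = dict(spec.excipient_weights)
    missing = set(weights) - set(by_name)
    if missing:
        raise ValueError(f"library missing excipients {sorted(missing)}")

    rng = np.random.default_rng(spec.seed)
    disks = _place_disks(spec, rng)
    coverage = _coverage_map(spec, disks, spherical=False)
    signal = (
        _coverage_map(spec, disks, spherical=True)
        if spec.spherical_response
        else coverage
    )
    halo = _halo_map(spec, disks)
    effective = np.clip(signal + halo * (signal == 0), 0.0, 1.0)

    wn = spec.wavenumbers
    nch = wn.size
    n_px = spec.rows * spec.cols

    particle_spectrum = by_name[spec.particle_component].evaluate(wn)
    exc_names = sorted(weights)
    probs = np.array([weights[n] for n in exc_names], dtype=float)
    probs = probs / probs.sum()
    exc_spectra = np.stack([by_name[n].evaluate(wn) for n in exc_names])
    identity = rng.choice(len(exc_names), size=n_px, p=probs)

    f = effective.ravel()[:, None]
    cube = f * particle_spectrum[None, :] + (1.0 - f) * exc_spectra[identity]

    # per-pixel linear baseline drift (removed exactly by the 2nd derivative)
    t = (wn - wn.mean()) / max(wn[-1] - wn[0], 1.0)
    offs = rng.uniform(0.0, spec.baseline_drift_amplitude, size=n_px)
    slopes = rng.uniform(
        -spec.baseline_drift_amplitude, spec.baseline_drift_amplitude, size=n_px
    )
    cube += offs[:, None] + slopes[:, None] * t[None, :]
    if spec.noise_sd > 0:
        cube += rng.normal(0.0, spec.noise_sd, size=cube.shape)

    hmap = HyperMap(
        cube.reshape(spec.rows, spec.cols, nch),
        wn,
        spec.pixel_size,
        {
            "sign_convention": SIGN_RAW,
            "phantom_seed": spec.seed,
            "particle_component": spec.particle_component,
            "particle_band": spec.particle_band,
        },
    )
    truth = GroundTruth(
        disks=[(cx, cy, 2.0 * r, agg) for cx, cy, r, agg in disks],
        fraction_map=coverage,
        pixel_size=spec.pixel_size,
    )
    return hmap, truth


# Presets mirroring the certified size standards (4.9 +/- 0.4, 9.8 +/- 0.5,
# 15.8 +/- 0.6 um; certificate population SDs 0.5 / 1.0 / 1.3 um) and the
# measured micronized-API size (4.11 um, STD 3.78 um, measured band 1,601).
PRESETS: dict[str, dict] = {
    "ps5": dict(particle_diameter_mean=4.9, particle_diameter_sd=0.5),
    "ps10": dict(particle_diameter_mean=9.8, particle_diameter_sd=1.0),
    "ps15": dict(particle_diameter_mean=15.8, particle_diameter_sd=1.3),
    "ebastine": dict(
        particle_diameter_mean=4.11,
        particle_diameter_sd=3.78,
        particle_component="ebastine_analog",
        particle_band=EBASTINE_BAND,
    ),
}


def preset(name: str, seed: int = 0, thin_axis: bool = False, **overrides) -> PhantomSpec:
    """PhantomSpec for a named preset (ps5 / ps10 / ps15 / ebastine)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    spec = PhantomSpec(seed=seed, **kwargs)
    return spec.thin_axis() if thin_axis else spec
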