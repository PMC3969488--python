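"""Domain containers and on-disk formats for hyperspectral Raman maps.

A hyperspectral map is a regular XY grid of Raman spectra: a ``rows x cols x
channels`` array of counts, a strictly ascending wavenumber axis in cm^-1 and
a spatial step in micrometres per pixel.  Two on-disk dialects are supported:

* long-form CSV with header ``x,y,wavenumber_cm1,intensity`` — portable and
  hand-inspectable, intended for small fixtures;
* an HDF5 container with datasets ``intensities`` (rows x cols x channels) and
  ``wavenumbers`` plus scalar attributes ``pixel_size_um`` and
  ``sign_convention`` — intended for full-size cubes (100 x 100 x ~1,750).

Coordinate convention (used everywhere in this package): row-major, 0-based
pixel indices, origin at the top-left, ``x`` = column index, ``y`` = row index.
The channel axis is stored ascending in cm^-1 internally; files written with a
descending axis are flipped on read.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SIGN_RAW",
    "SIGN_SECOND_DERIVATIVE",
    "SIGN_NEG_SECOND_DERIVATIVE",
    "Spectrum",
    "HyperMap",
    "BandImage",
    "SizingSummary",
    "RaggedGridError",
    "read_hypermap",
    "write_hypermap",
    "read_spectrum_table",
    "write_spectrum_table",
    "write_particle_table",
    "read_particle_table",
]

# Sign-convention flags carried in HyperMap.meta["sign_convention"]: a raw map
# may be differentiated; a derivative map may not be differentiated again.
SIGN_RAW = "raw"
SIGN_SECOND_DERIVATIVE = "second_derivative"
SIGN_NEG_SECOND_DERIVATIVE = "neg_second_derivative"
_SIGN_FLAGS = (SIGN_RAW, SIGN_SECOND_DERIVATIVE, SIGN_NEG_SECOND_DERIVATIVE)

PARTICLE_TABLE_COLUMNS = [
    "label",
    "pixel_count",
    "area_um2",
    "equivalent_diameter_um",
    "centroid_x",
    "centroid_y",
    "touches_border",
]


class RaggedGridError(ValueError):
    """Raised when a long-form CSV does not cover the full XY grid."""

    def __init__(self, x: int, y: int):
        self.missing = (x, y)
        super().__init__(f"ragged spatial grid: pixel (x={x}, y={y}) is missing")


def _as_monotonic_axis(wavenumbers: Sequence[float]) -> np.ndarray:
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.ndim != 1 or wn.size < 1:
        raise ValueError("wavenumber axis must be a 1-D non-empty sequence")
    d = np.diff(wn)
    if wn.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("wavenumber axis must be strictly monotonic")
    return wn


@dataclass(frozen=True)
class Spectrum:
    """A single Raman spectrum: wavenumbers (cm^-1) and matching intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    name: str = ""

    def __post_init__(self):
        wn = _as_monotonic_axis(self.wavenumbers)
        it = np.asarray(self.intensities, dtype=float)
        if it.shape != wn.shape:
            raise ValueError(
                f"wavenumbers ({wn.size}) and intensities ({it.size}) differ in length"
            )
        if wn.size > 1 and wn[0] > wn[-1]:  # normalize to ascending
            wn, it = wn[::-1], it[::-1]
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass
class HyperMap:
    """Hyperspectral cube: ``intensities[row, col, channel]`` counts.

    Parameters
    ----------
    intensities : ndarray, shape (rows, cols, channels)
    wavenumbers : ndarray, shape (channels,), strictly ascending cm^-1
        (a descending axis is flipped, together with the channel dimension).
    pixel_size : float
        Spatial step in micrometres per pixel, > 0.
    meta : dict
        Free-form provenance.  ``meta["sign_convention"]`` is one of
        ``"raw"``, ``"second_derivative"``, ``"neg_second_derivative"``;
        ``meta["valid_channel_margin"]`` (int) marks how many channels at each
        end of the axis are edge artifacts of a derivative filter.
    """

    intensities: np.ndarray
    wavenumbers: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError("intensities must be a rows x cols x channels array")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("map must have at least one row and one column")
        wn = _as_monotonic_axis(self.wavenumbers)
        if wn.size != arr.shape[2]:
            raise ValueError(
                f"axis length {wn.size} != channel count {arr.shape[2]}"
            )
        if wn.size > 1 and wn[0] > wn[-1]:
            wn = wn[::-1].copy()
            arr = arr[:, :, ::-1].copy()
        if not (float(self.pixel_size) > 0):
            raise ValueError("pixel_size must be > 0")
        meta = dict(self.meta)
        meta.setdefault("sign_convention", SIGN_RAW)
        if meta["sign_convention"] not in _SIGN_FLAGS:
            raise ValueError(f"unknown sign convention {meta['sign_convention']!r}")
        self.intensities = arr
        self.wavenumbers = wn
        self.pixel_size = float(self.pixel_size)
        self.meta = meta

    @property
    def rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def cols(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[2]

    @property
    def sign_convention(self) -> str:
        return self.meta["sign_convention"]

    def pixel_spectrum(self, x: int, y: int) -> Spectrum:
        """Spectrum at column x, row y (0-based)."""
        return Spectrum(self.wavenumbers, self.intensities[y, x, :])


@dataclass
class BandImage:
    """Univariate image: scalar intensity at one wavenumber channel per pixel."""

    values: np.ndarray
    band_wavenumber_requested: float
    band_wavenumber_actual: float
    pixel_size: float
    sign_flipped: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("band image values must be 2-D")
        self.values = v
        self.pixel_size = float(self.pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SizingSummary:
    """Per-area sizing statistics, mirroring a model-tablet results row.

    ``mean_diameter`` / ``std_diameter`` are NaN when ``particle_count`` is 0
    (``std_diameter`` is 0 for a single particle; sample STD otherwise).
    """

    mean_diameter: float
    std_diameter: float
    area_percent: float
    particle_count: int

    def __post_init__(self):
        if self.particle_count < 0:
            raise ValueError("particle_count must be >= 0")
        if not (0.0 <= self.area_percent <= 100.0):
            raise ValueError("area_percent must be within [0, 100]")
        if self.particle_count > 0:
            if not (self.mean_diameter > 0):
                raise ValueError("mean_diameter must be > 0 for a non-empty area")
            if not (self.std_diameter >= 0):
                raise ValueError("std_diameter must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: str, format_hint: str | None) -> str:
    if format_hint in ("csv", "hdf5"):
        return format_hint
    if format_hint not in (None, "auto"):
        raise ValueError(f"unknown format hint {format_hint!r}")
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".csv", ".txt"):
        return "csv"
    if ext in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise ValueError(f"cannot infer container format from extension {ext!r}")


def read_hypermap(path, format_hint: str | None = None, pixel_size: float | None = None) -> HyperMap:
    """Read a hyperspectral map from long-form CSV or the HDF5 container.

    Parameters
    ----------
    path : str or PathLike
    format_hint : {"csv", "hdf5", "auto", None}
        ``None``/``"auto"`` infers from the file extension.
    pixel_size : float, optional
        Spatial step in um/pixel for the CSV dialect (which does not carry
        it); defaults to 1.0.  Ignored for HDF5, which stores it.

    The channel axis is normalised to ascending order regardless of on-disk
    order.  A CSV missing any (x, y) pixel raises :class:`RaggedGridError`
    naming the first missing pixel in raster order.
    """
    fmt = _infer_format(path, format_hint)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            arr = f["intensities"][()]
            wn = f["wavenumbers"][()]
            px = float(f.attrs.get("pixel_size_um", 1.0))
            sign = f.attrs.get("sign_convention", SIGN_RAW)
            if isinstance(sign, bytes):
                sign = sign.decode()
            margin = int(f.attrs.get("valid_channel_margin", 0))
        meta = {"sign_convention": str(sign), "source": str(path)}
        if margin:
            meta["valid_channel_margin"] = margin
        return HyperMap(arr, wn, px, meta)

    df = pd.read_csv(path, float_precision="round_trip")
    required = {"x", "y", "wavenumber_cm1", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"long-form CSV must have columns {sorted(required)}; got {list(df.columns)}"
        )
    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    wn_sorted = np.sort(df["wavenumber_cm1"].unique())
    _as_monotonic_axis(wn_sorted)
    rows, cols, nch = len(ys), len(xs), len(wn_sorted)
    if not (np.array_equal(xs, np.arange(cols)) and np.array_equal(ys, np.arange(rows))):
        raise ValueError("pixel indices must be contiguous 0-based integers")
    # detect ragged grids before pivoting; report first missing pixel (raster order)
    counts = df.groupby(["y", "x"]).size()
    for y in range(rows):
        for x in range(cols):
            if (y, x) not in counts.index:
                raise RaggedGridError(x, y)
            if counts[(y, x)] != nch:
                raise RaggedGridError(x, y)
    cube = np.empty((rows, cols, nch), dtype=float)
    order = df.sort_values(["y", "x", "wavenumber_cm1"], kind="mergesort")
    cube[:] = order["intensity"].to_numpy().reshape(rows, cols, nch)
    return HyperMap(
        cube,
        wn_sorted,
        1.0 if pixel_size is None else pixel_size,
        {"sign_convention": SIGN_RAW, "source": str(path)},
    )


def write_hypermap(hmap: HyperMap, path, format_hint: str | None = None) -> None:
    """Write a map in either dialect (inverse of :func:`read_hypermap`)."""
    fmt = _infer_format(path, format_hint)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("intensities", data=hmap.intensities)
            f.create_dataset("wavenumbers", data=hmap.wavenumbers)
            f.attrs["pixel_size_um"] = hmap.pixel_size
            f.attrs["sign_convention"] = hmap.sign_convention
            if "valid_channel_margin" in hmap.meta:
                f.attrs["valid_channel_margin"] = int(hmap.meta["valid_channel_margin"])
        return
    rows, cols, nch = hmap.intensities.shape
    y, x, w = np.meshgrid(
        np.arange(rows), np.arange(cols), np.arange(nch), indexing="ij"
    )
    pd.DataFrame(
        {
            "x": x.ravel(),
            "y": y.ravel(),
            "wavenumber_cm1": hmap.wavenumbers[w.ravel()],
            "intensity": hmap.intensities.ravel(),
        }
    ).to_csv(path, index=False)


def read_spectrum_table(path, name: str = "") -> Spectrum:
    """Read a two-column text table (wavenumber_cm1, intensity)."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("spectrum table needs two columns: wavenumber, intensity")
    return Spectrum(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(), name=name)


def write_spectrum_table(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": spectrum.wavenumbers, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def write_particle_table(particles, path) -> None:
    """Write one CSV row per particle, ordered by label.

    Columns: label, pixel_count, area_um2, equivalent_diameter_um,
    centroid_x, centroid_y, touches_border.  An empty particle set yields a
    header-only file.
    """
    rows = [
        {
            "label": p.label,
            "pixel_count": p.pixel_count,
            "area_um2": p.area,
            "equivalent_diameter_um": p.equivalent_diameter,
            "centroid_x": p.centroid[0],
            "centroid_y": p.centroid[1],
            "touches_border": int(p.touches_border),
        }
        for p in sorted(particles.particles, key=lambda p: p.label)
    ]
    df = pd.DataFrame(rows, columns=PARTICLE_TABLE_COLUMNS)
    # full float precision so diameters round-trip exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_particle_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(PARTICLE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"particle table missing columns {sorted(missing)}")
    return df
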