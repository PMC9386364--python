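"""Multiband raster containers, ROIs, and ground-truth tables.

Conventions used throughout the package:

* images are row-major ``H x W x B`` arrays;
* pixel coordinates are 0-based, half-open ``[min, max)``;
* nodata is carried as a boolean mask (``True`` = excluded), never as a
  sentinel value, so a reflectance of exactly 0.0 is a legal observation;
* bands are addressed by their center wavelength in nm via a
  :class:`BandMap`.

Two on-disk containers are supported: multiband TIFF (band order equals
the band-map order; the interchange format) and an ``.npz`` container
(``pixels``, ``mask``, ``wavelengths``, ``bandwidths`` arrays) that needs
no raster library at all.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    BandCountMismatchError,
    BandLookupError,
    InputError,
    RoiError,
    UnreadableRasterError,
)

__all__ = [
    "BandMap",
    "ReflectanceCube",
    "PlotROI",
    "GroundTruthRecord",
    "lai_from_samples",
    "read_cube",
    "write_cube",
    "clip_roi",
    "read_ground_truth",
    "write_ground_truth",
    "read_rois",
    "write_rois",
    "MINI_MCA_WAVELENGTHS",
    "default_bandmap",
]

#: Center wavelengths (nm) of the 12-band camera, in band order.
MINI_MCA_WAVELENGTHS = (490, 520, 550, 570, 670, 680, 700, 720, 800, 850, 900, 950)

#: Bandwidths (nm) matching :data:`MINI_MCA_WAVELENGTHS`.
MINI_MCA_BANDWIDTHS = (10, 10, 10, 10, 10, 10, 10, 10, 10, 10, 20, 40)


@dataclass(frozen=True)
class BandMap:
    """Mapping from center wavelength (nm) to 0-based band index.

    Parameters
    ----------
    entries : tuple of (wavelength_nm, band_index, bandwidth_nm)
        Wavelengths must be unique; band indices must be unique and
        contiguous from 0.
    """

    entries: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        wls = [e[0] for e in self.entries]
        idx = sorted(e[1] for e in self.entries)
        if len(set(wls)) != len(wls):
            raise InputError("duplicate wavelengths in band map")
        if idx != list(range(len(idx))):
            raise InputError("band indices must be unique and contiguous from 0")

    @property
    def n_bands(self) -> int:
        return len(self.entries)

    @property
    def wavelengths(self) -> tuple[int, ...]:
        """Wavelengths ordered by band index."""
        return tuple(e[0] for e in sorted(self.entries, key=lambda e: e[1]))

    @property
    def bandwidths(self) -> tuple[int, ...]:
        return tuple(e[2] for e in sorted(self.entries, key=lambda e: e[1]))

    def index_of(self, wavelength: int) -> int:
        """Band index for a center wavelength; raises :class:`BandLookupError`."""
        for wl, i, _bw in self.entries:
            if wl == int(wavelength):
                return i
        raise BandLookupError(
            f"wavelength {wavelength} nm not in band map {self.wavelengths}"
        )

    def __contains__(self, wavelength: object) -> bool:
        try:
            self.index_of(int(wavelength))  # type: ignore[arg-type]
            return True
        except (BandLookupError, TypeError, ValueError):
            return False


def default_bandmap() -> BandMap:
    """Band map of the 12-band camera (490-950 nm) in sensor band order."""
    return BandMap(
        tuple(
            (wl, i, bw)
            for i, (wl, bw) in enumerate(
                zip(MINI_MCA_WAVELENGTHS, MINI_MCA_BANDWIDTHS)
            )
        )
    )


@dataclass
class ReflectanceCube:
    """An ``H x W x B`` reflectance (or raw-DN) stack with a nodata mask."""

    pixels: np.ndarray
    bandmap: BandMap
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise InputError(f"pixels must be H x W x B, got shape {self.pixels.shape}")
        if self.pixels.shape[2] != self.bandmap.n_bands:
            raise BandCountMismatchError(
                f"cube has {self.pixels.shape[2]} bands, "
                f"band map declares {self.bandmap.n_bands}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.pixels.shape[:2], dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.pixels.shape[:2]:
                raise InputError("nodata mask shape must match image H x W")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def band(self, wavelength: int) -> np.ndarray:
        """The ``H x W`` image of one center wavelength."""
        return self.pixels[:, :, self.bandmap.index_of(wavelength)]


@dataclass(frozen=True)
class PlotROI:
    """Axis-aligned rectangle, 0-based half-open ``[min, max)`` bounds."""

    plot_id: str
    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_min < self.row_max and 0 <= self.col_min < self.col_max):
            raise RoiError(f"degenerate ROI bounds for plot {self.plot_id!r}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    def validate_against(self, h: int, w: int) -> None:
        if self.row_max > h or self.col_max > w:
            raise RoiError(
                f"ROI {self.plot_id!r} ({self.row_min},{self.col_min},"
                f"{self.row_max},{self.col_max}) exceeds image {h}x{w}"
            )


@dataclass(frozen=True)
class GroundTruthRecord:
    """Destructive-sampling record for one plot-date.

    ``la_total`` is the summed leaf area (m^2) of the three sampled
    bundles; ``rho`` is the planting density in bundles per m^2.
    """

    plot_id: str
    la_total: float
    rho: float
    lai: float | None = None

    def __post_init__(self) -> None:
        if self.la_total < 0:
            raise InputError("la_total must be >= 0")
        if self.rho <= 0:
            raise InputError("rho must be > 0")
        derived = lai_from_samples(self.la_total, self.rho)
        if self.lai is None:
            object.__setattr__(self, "lai", derived)
        elif abs(self.lai - derived) > 1e-9:
            raise InputError(
                f"inconsistent record for {self.plot_id!r}: "
                f"LAI {self.lai} != (LA/3)*rho = {derived}"
            )


#: Planting density (bundles per m^2) used in both field experiments.
DEFAULT_RHO = 22.5


def lai_from_samples(la_total: float, rho: float = DEFAULT_RHO) -> float:
    """Leaf area index from three-bundle leaf area and planting density.

    ``LAI = (LA / 3) * rho`` where ``LA`` is the total one-sided leaf
    area (m^2) of the three sampled bundles and ``rho`` the planting
    density (bundles per m^2).
    """
    if rho <= 0:
        raise InputError("rho must be > 0")
    if la_total < 0:
        raise InputError("la_total must be >= 0")
    return (la_total / 3.0) * rho


# ---------------------------------------------------------------------------
# raster containers
# ---------------------------------------------------------------------------

def write_cube(path: str | os.PathLike, cube: ReflectanceCube) -> None:
    """Write a cube as multiband TIFF (``.tif``/``.tiff``) or NPZ.

    TIFF stores bands as separate planes in band-map order; the mask is
    stored as an extra all-or-nothing plane convention is avoided —
    masked pixels are written as NaN and recovered as mask on read.
    NPZ stores pixels, mask and the band map losslessly.
    """
    path = os.fspath(path)
    if path.endswith((".tif", ".tiff")):
        data = cube.pixels.copy()
        data[cube.nodata_mask, :] = np.nan
        # planar (B, H, W) layout; band order == bandmap order
        tifffile.imwrite(
            path,
            np.moveaxis(data, 2, 0).astype(np.float64),
            photometric="minisblack",
        )
    elif path.endswith(".npz"):
        np.savez(
            path,
            pixels=cube.pixels,
            mask=cube.nodata_mask,
            wavelengths=np.array(cube.bandmap.wavelengths, dtype=np.int64),
            bandwidths=np.array(cube.bandmap.bandwidths, dtype=np.int64),
        )
    else:
        raise InputError(f"unsupported raster extension: {path}")


def read_cube(path: str | os.PathLike, bandmap: BandMap) -> ReflectanceCube:
    """Read a multiband TIFF or NPZ cube and attach *bandmap*.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    BandCountMismatchError
        If the file's band count differs from the band map.
    UnreadableRasterError
        If the file cannot be parsed as a supported container.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith((".tif", ".tiff")):
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # tifffile raises assorted types
            raise UnreadableRasterError(f"cannot read TIFF {path}: {exc}") from exc
        if data.ndim == 2:
            data = data[None, :, :]
        if data.ndim != 3:
            raise UnreadableRasterError(f"unexpected TIFF rank {data.ndim} in {path}")
        pixels = np.moveaxis(np.asarray(data, dtype=np.float64), 0, 2)
    elif path.endswith(".npz"):
        try:
            with np.load(path) as z:
                pixels = np.asarray(z["pixels"], dtype=np.float64)
                mask = np.asarray(z["mask"], dtype=bool)
        except Exception as exc:
            raise UnreadableRasterError(f"cannot read NPZ {path}: {exc}") from exc
        if pixels.shape[2] != bandmap.n_bands:
            raise BandCountMismatchError(
                f"{path}: {pixels.shape[2]} bands vs band map {bandmap.n_bands}"
            )
        return ReflectanceCube(pixels=pixels, bandmap=bandmap, nodata_mask=mask)
    else:
        raise UnreadableRasterError(f"unsupported raster extension: {path}")

    if pixels.shape[2] != bandmap.n_bands:
        raise BandCountMismatchError(
            f"{path}: {pixels.shape[2]} bands vs band map {bandmap.n_bands}"
        )
    mask = np.any(np.isnan(pixels), axis=2)
    pixels = np.where(np.isnan(pixels), 0.0, pixels)
    return ReflectanceCube(pixels=pixels, bandmap=bandmap, nodata_mask=mask)


def clip_roi(cube: ReflectanceCube, roi: PlotROI) -> ReflectanceCube:
    """Sub-cube covering *roi*; values copied unmodified."""
    h, w, _ = cube.shape
    roi.validate_against(h, w)
    return ReflectanceCube(
        pixels=cube.pixels[roi.row_min : roi.row_max, roi.col_min : roi.col_max].copy(),
        bandmap=cube.bandmap,
        nodata_mask=cube.nodata_mask[
            roi.row_min : roi.row_max, roi.col_min : roi.col_max
        ].copy(),
    )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_ground_truth(path: str | os.PathLike) -> list[GroundTruthRecord]:
    """CSV with columns plot_id, LA_total_m2, rho[, LAI]."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"plot_id", "LA_total_m2", "rho"}
    if not required.issubset(df.columns):
        raise InputError(f"ground-truth CSV must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            GroundTruthRecord(
                plot_id=str(row["plot_id"]),
                la_total=float(row["LA_total_m2"]),
                rho=float(row["rho"]),
                lai=float(row["LAI"]) if "LAI" in df.columns else None,
            )
        )
    return out


def write_ground_truth(path: str | os.PathLike, records: list[GroundTruthRecord]) -> None:
    pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in records],
            "LA_total_m2": [r.la_total for r in records],
            "rho": [r.rho for r in records],
            "LAI": [r.lai for r in records],
        }
    ).to_csv(path, index=False)


def read_rois(path: str | os.PathLike) -> list[PlotROI]:
    """CSV with columns plot_id, row_min, col_min, row_max, col_max."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"plot_id", "row_min", "col_min", "row_max", "col_max"}
    if not required.issubset(df.columns):
        raise InputError(f"ROI CSV must have columns {sorted(required)}")
    return [
        PlotROI(
            plot_id=str(r["plot_id"]),
            row_min=int(r["row_min"]),
            col_min=int(r["col_min"]),
            row_max=int(r["row_max"]),
            col_max=int(r["col_max"]),
        )
        for _, r in df.iterrows()
    ]


def write_rois(path: str | os.PathLike, rois: list[PlotROI]) -> None:
    pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in rois],
            "row_min": [r.row_min for r in rois],
            "col_min": [r.col_min for r in rois],
            "row_max": [r.row_max for r in rois],
            "col_max": [r.col_max for r in rois],
        }
    ).to_csv(path, index=False)
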