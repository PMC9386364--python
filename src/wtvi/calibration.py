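"""Empirical-line radiometric calibration: raw DN -> reflectance.

One ordinary-least-squares line ``reflectance = gain * DN + offset`` is
fitted per band on calibration targets of known reflectance; applying
the correction converts a DN cube pixel-wise and clips to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError
from .raster_io import BandMap, ReflectanceCube

__all__ = [
    "CalibrationTarget",
    "LinearCorrection",
    "fit_empirical_line",
    "fit_all_bands",
    "apply_correction",
    "read_targets",
    "TARGET_REFLECTANCES",
]

#: Nominal reflectances of the eight field calibration tarps.
TARGET_REFLECTANCES = (0.03, 0.06, 0.12, 0.24, 0.36, 0.48, 0.56, 0.80)


@dataclass(frozen=True)
class CalibrationTarget:
    """One tarp observation for one band: known reflectance + mean DN."""

    target_id: str
    wavelength: int
    reflectance: float
    mean_dn: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.reflectance <= 1.0:
            raise InputError("target reflectance must lie in [0, 1]")
        if self.mean_dn < 0:
            raise InputError("mean DN must be >= 0")


@dataclass(frozen=True)
class LinearCorrection:
    """Per-band affine DN->reflectance map with fit diagnostics."""

    wavelength: int
    gain: float
    offset: float
    residual_rmse: float
    n_targets: int


def fit_empirical_line(
    targets: list[CalibrationTarget], wavelength: int
) -> LinearCorrection:
    """OLS fit of reflectance against DN over the targets of one band.

    Requires at least two targets with distinct DN for *wavelength*.
    """
    sel = [t for t in targets if t.wavelength == int(wavelength)]
    if len(sel) < 2:
        raise DegenerateDataError(
            f"need >= 2 calibration targets for {wavelength} nm, got {len(sel)}"
        )
    dn = np.array([t.mean_dn for t in sel], dtype=np.float64)
    refl = np.array([t.reflectance for t in sel], dtype=np.float64)
    if np.ptp(dn) == 0:
        raise DegenerateDataError(
            f"all target DN identical for {wavelength} nm: degenerate design"
        )
    # closed-form simple OLS
    dn_c = dn - dn.mean()
    gain = float(np.dot(dn_c, refl - refl.mean()) / np.dot(dn_c, dn_c))
    offset = float(refl.mean() - gain * dn.mean())
    resid = refl - (gain * dn + offset)
    return LinearCorrection(
        wavelength=int(wavelength),
        gain=gain,
        offset=offset,
        residual_rmse=float(np.sqrt(np.mean(resid**2))),
        n_targets=len(sel),
    )


def fit_all_bands(
    targets: list[CalibrationTarget], bandmap: BandMap
) -> dict[int, LinearCorrection]:
    """One :func:`fit_empirical_line` per band-map wavelength."""
    return {wl: fit_empirical_line(targets, wl) for wl in bandmap.wavelengths}


def apply_correction(
    dn_cube: ReflectanceCube, corrections: dict[int, LinearCorrection]
) -> ReflectanceCube:
    """Convert a DN cube to reflectance, clipping to [0, 1].

    Every band of the cube must have a fitted correction; the nodata
    mask propagates unchanged.
    """
    out = np.empty_like(dn_cube.pixels)
    for wl in dn_cube.bandmap.wavelengths:
        if wl not in corrections:
            raise InputError(f"no fitted correction for band {wl} nm")
        c = corrections[wl]
        i = dn_cube.bandmap.index_of(wl)
        out[:, :, i] = np.clip(c.gain * dn_cube.pixels[:, :, i] + c.offset, 0.0, 1.0)
    return ReflectanceCube(
        pixels=out,
        bandmap=dn_cube.bandmap,
        nodata_mask=dn_cube.nodata_mask.copy(),
    )


def read_targets(path: str) -> list[CalibrationTarget]:
    """CSV with columns target_id, wavelength_nm, reflectance, mean_DN."""
    df = pd.read_csv(path)
    required = {"target_id", "wavelength_nm", "reflectance", "mean_DN"}
    if not required.issubset(df.columns):
        raise InputError(f"target CSV must have columns {sorted(required)}")
    return [
        CalibrationTarget(
            target_id=str(r["target_id"]),
            wavelength=int(r["wavelength_nm"]),
            reflectance=float(r["reflectance"]),
            mean_dn=float(r["mean_DN"]),
        )
        for _, r in df.iterrows()
    ]
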