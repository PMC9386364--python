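"""Seeded synthetic multispectral canopy scenes with known LAI.

The generator is a statistical stand-in for field imagery, not a
radiative-transfer model. Its job is to reproduce the structure the
fusion method exploits:

* canopy cover follows a Beer-Lambert gap fraction
  ``f = 1 - exp(-k_ext * LAI)``, so band-ratio indices saturate once the
  canopy closes;
* leaf NIR reflectance keeps rising with LAI (multiple leaf layers), so
  the LL-energy texture of the NIR band stays LAI-sensitive after
  closure;
* the vegetated/background pattern is a thresholded smoothed Gaussian
  random field whose correlation length grows with LAI;
* post-heading stages mix bright, low-NIR panicle pixels into the
  canopy, perturbing the spectral indices more than the texture;
* the tillering background is a water/soil blend (flooded paddy), soil
  afterwards.

All randomness flows from a single seed; every plot-date draws from its
own deterministic substream, so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .calibration import TARGET_REFLECTANCES, CalibrationTarget
from .errors import InputError
from .raster_io import (
    MINI_MCA_WAVELENGTHS,
    BandMap,
    GroundTruthRecord,
    PlotROI,
    ReflectanceCube,
    default_bandmap,
)

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "generate_scene",
    "generate_plot",
    "generate_targets",
    "STAGES",
]

STAGES = ("tillering", "jointing", "booting_heading", "ripening")

# per-band endmember reflectances, keyed by center wavelength (nm)
_LEAF = {
    490: 0.040, 520: 0.060, 550: 0.100, 570: 0.090, 670: 0.040, 680: 0.042,
    700: 0.080, 720: 0.180, 800: 0.320, 850: 0.330, 900: 0.330, 950: 0.310,
}
# additional leaf reflectance per unit LAI (multiple-scattering proxy),
# NIR-plateau bands only
_LEAF_LAI_SLOPE = {
    490: 0.0, 520: 0.0, 550: 0.004, 570: 0.003, 670: 0.0, 680: 0.0,
    700: 0.004, 720: 0.012, 800: 0.040, 850: 0.041, 900: 0.042, 950: 0.038,
}
_SOIL = {
    490: 0.060, 520: 0.080, 550: 0.100, 570: 0.110, 670: 0.150, 680: 0.155,
    700: 0.165, 720: 0.180, 800: 0.220, 850: 0.230, 900: 0.240, 950: 0.250,
}
_WATER = {
    490: 0.060, 520: 0.055, 550: 0.050, 570: 0.045, 670: 0.030, 680: 0.028,
    700: 0.025, 720: 0.022, 800: 0.015, 850: 0.012, 900: 0.010, 950: 0.008,
}
_PANICLE = {
    490: 0.100, 520: 0.140, 550: 0.180, 570: 0.200, 670: 0.220, 680: 0.230,
    700: 0.250, 720: 0.280, 800: 0.400, 850: 0.405, 900: 0.405, 950: 0.395,
}

_POST_HEADING = ("booting_heading", "ripening")


@dataclass(frozen=True)
class SceneConfig:
    """Everything the generator needs; the seed is mandatory."""

    seed: int
    n_plots: int = 24
    plot_size: int = 32
    stages: tuple[str, ...] = STAGES
    lai_ranges: dict = field(
        default_factory=lambda: {
            "tillering": (0.5, 2.5),
            "jointing": (2.5, 5.0),
            "booting_heading": (4.0, 7.0),
            "ripening": (2.0, 8.0),
        }
    )
    k_ext: float = 0.5
    rho: float = 22.5
    leaf: dict = field(default_factory=lambda: dict(_LEAF))
    leaf_lai_slope: dict = field(default_factory=lambda: dict(_LEAF_LAI_SLOPE))
    soil: dict = field(default_factory=lambda: dict(_SOIL))
    water: dict = field(default_factory=lambda: dict(_WATER))
    panicle: dict = field(default_factory=lambda: dict(_PANICLE))
    water_fraction_tillering: float = 0.6  # background water share pre-jointing
    corr_length_base: float = 1.0          # texture smoothing sigma at LAI=0
    corr_length_slope: float = 0.25        # added sigma per unit LAI
    panicle_density: float = 0.18          # share of canopy pixels, post-heading
    soil_brightness_cv: float = 0.08       # per-plot soil multiplier spread
    leaf_brightness_cv: float = 0.04       # per-plot leaf multiplier spread
    noise_sigma: float = 0.01              # additive pixel noise
    # calibration-target synthesis (reflectance = gain*DN + offset)
    dn_per_reflectance: float = 1200.0
    dn_dark: float = 40.0
    dn_noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.k_ext <= 0:
            raise InputError("k_ext must be > 0")
        if self.n_plots < 1 or self.plot_size < 4:
            raise InputError("need n_plots >= 1 and plot_size >= 4")
        for lib in (self.leaf, self.soil, self.water, self.panicle):
            vals = np.array([lib[wl] for wl in MINI_MCA_WAVELENGTHS])
            if np.any(vals < 0) or np.any(vals > 1):
                raise InputError("endmember reflectances must lie in [0, 1]")
        for st in self.stages:
            if st not in self.lai_ranges:
                raise InputError(f"no LAI range for stage {st!r}")

    @property
    def bandmap(self) -> BandMap:
        return default_bandmap()


@dataclass
class SyntheticScene:
    """One cube + ground-truth record + ROI per plot-date."""

    config: SceneConfig
    plot_ids: list[str]
    stages: list[str]
    cubes: list[ReflectanceCube]
    records: list[GroundTruthRecord]
    rois: list[PlotROI]

    def __len__(self) -> int:
        return len(self.cubes)


def _spectrum(lib: dict, wavelengths) -> np.ndarray:
    return np.array([lib[wl] for wl in wavelengths], dtype=np.float64)


def _smooth_indicator(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float, frac: float
) -> np.ndarray:
    """Boolean field with spatial correlation ``sigma`` and mean ``frac``."""
    if frac <= 0.0:
        return np.zeros(shape, dtype=bool)
    if frac >= 1.0:
        return np.ones(shape, dtype=bool)
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    thresh = np.quantile(g, 1.0 - frac)
    return g > thresh


def generate_plot(
    config: SceneConfig,
    lai: float,
    stage: str,
    rng: np.random.Generator,
) -> ReflectanceCube:
    """One plot-date reflectance cube at a prescribed LAI and stage."""
    if stage not in STAGES:
        raise InputError(f"unknown stage {stage!r}")
    n = config.plot_size
    wls = config.bandmap.wavelengths
    cover = 1.0 - np.exp(-config.k_ext * lai)
    sigma = config.corr_length_base + config.corr_length_slope * lai

    canopy = _smooth_indicator(rng, (n, n), sigma, cover)

    leaf = np.clip(
        _spectrum(config.leaf, wls)
        + lai * _spectrum(config.leaf_lai_slope, wls),
        0.0,
        1.0,
    )
    leaf = leaf * (1.0 + config.leaf_brightness_cv * rng.standard_normal())
    soil = _spectrum(config.soil, wls) * (
        1.0 + config.soil_brightness_cv * rng.standard_normal()
    )
    if stage == "tillering":
        wf = config.water_fraction_tillering
        background = wf * _spectrum(config.water, wls) + (1.0 - wf) * soil
    else:
        background = soil

    m = canopy[:, :, None].astype(np.float64)
    pixels = m * leaf[None, None, :] + (1.0 - m) * background[None, None, :]

    if stage in _POST_HEADING and config.panicle_density > 0:
        density = config.panicle_density * (1.0 + 0.3 * rng.standard_normal())
        density = float(np.clip(density, 0.0, 0.6))
        speckle = _smooth_indicator(rng, (n, n), max(sigma * 0.4, 0.5), density)
        pan = speckle & canopy
        pixels[pan, :] = _spectrum(config.panicle, wls)[None, :]

    pixels += config.noise_sigma * rng.standard_normal(pixels.shape)
    return ReflectanceCube(
        pixels=np.clip(pixels, 0.0, 1.0), bandmap=config.bandmap
    )


def _plot_rng(config: SceneConfig, plot: int, stage_idx: int) -> np.random.Generator:
    # deterministic substream per plot-date
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(plot, stage_idx))
    )


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """All plot-dates of a season: ``n_plots x len(stages)`` cubes."""
    plot_ids, stages, cubes, records, rois = [], [], [], [], []
    margin = 1  # keep ROI inside the border so LL mapping stays interior
    for stage_idx, stage in enumerate(config.stages):
        lo, hi = config.lai_ranges[stage]
        for plot in range(config.n_plots):
            rng = _plot_rng(config, plot, stage_idx)
            lai = float(rng.uniform(lo, hi))
            cube = generate_plot(config, lai, stage, rng)
            pid = f"p{plot:03d}_{stage}"
            plot_ids.append(pid)
            stages.append(stage)
            cubes.append(cube)
            records.append(
                GroundTruthRecord(
                    plot_id=pid,
                    la_total=3.0 * lai / config.rho,
                    rho=config.rho,
                )
            )
            rois.append(
                PlotROI(
                    plot_id=pid,
                    row_min=margin,
                    col_min=margin,
                    row_max=config.plot_size - margin,
                    col_max=config.plot_size - margin,
                )
            )
    return SyntheticScene(
        config=config,
        plot_ids=plot_ids,
        stages=stages,
        cubes=cubes,
        records=records,
        rois=rois,
    )


def generate_targets(
    config: SceneConfig,
    reflectances: tuple[float, ...] = TARGET_REFLECTANCES,
    noise_sigma: float | None = None,
) -> tuple[list[CalibrationTarget], ReflectanceCube]:
    """Calibration tarps plus a raw-DN cube from a known empirical line.

    DN values are synthesized by inverting
    ``reflectance = gain * DN + offset`` with
    ``gain = 1 / dn_per_reflectance`` and ``offset = -dn_dark * gain``,
    i.e. ``DN = dn_per_reflectance * reflectance + dn_dark`` plus
    Gaussian noise of width ``dn_noise_sigma`` (overridable).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(999999,))
    )
    sigma = config.dn_noise_sigma if noise_sigma is None else noise_sigma
    targets = []
    for wl in config.bandmap.wavelengths:
        for j, refl in enumerate(reflectances):
            dn = config.dn_per_reflectance * refl + config.dn_dark
            dn += sigma * rng.standard_normal()
            targets.append(
                CalibrationTarget(
                    target_id=f"t{j}",
                    wavelength=wl,
                    reflectance=float(refl),
                    mean_dn=float(max(dn, 0.0)),
                )
            )
    # a raw-DN scene cube from the same line
    refl_cube = generate_plot(
        config, lai=3.0, stage="jointing", rng=rng
    )
    dn_pixels = config.dn_per_reflectance * refl_cube.pixels + config.dn_dark
    dn_pixels += sigma * rng.standard_normal(dn_pixels.shape)
    dn_cube = ReflectanceCube(
        pixels=np.maximum(dn_pixels, 0.0), bandmap=config.bandmap
    )
    return targets, dn_cube


def with_seed(config: SceneConfig, seed: int) -> SceneConfig:
    """Same configuration, different master seed."""
    return replace(config, seed=seed)
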