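"""End-to-end workflow: scene -> features -> fused indices -> CV results.

``run_pipeline`` chains the stages: (optional) DN round-trip through the
empirical-line calibration, per-cube vegetation indices, Haar LL-energy
texture of the chosen NIR band, plot-level extraction, multiplicative
fusion, and k-fold evaluation of every feature column. Outputs embed a
hash of the fully-resolved configuration so identical configs are
verifiably identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration as cal
from .errors import InputError
from .fusion import CVResult, fuse, plot_vi, rank_indices
from .indices import INDEX_NAMES, compute_vi, get_index
from .raster_io import (
    GroundTruthRecord,
    PlotROI,
    ReflectanceCube,
    default_bandmap,
    read_cube,
    read_ground_truth,
    read_rois,
    write_cube,
    write_ground_truth,
    write_rois,
)
from .synthetic import SceneConfig, SyntheticScene, generate_scene, generate_targets
from .wavelet import energy_texture, haar_decompose, plot_energy

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "extract_features",
    "write_scene_dir",
    "load_scene_dir",
    "config_hash",
]


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved pipeline configuration.

    Exactly one of ``scene`` (simulate in-process) or ``scene_dir``
    (load a simulated/prepared directory) must be set. Defaults mirror
    the reference workflow: 800 nm texture band, all 12 indices, k=10.
    """

    seed: int = 0
    k: int = 10
    texture_band: int = 800
    indices: tuple[str, ...] = INDEX_NAMES
    variant: str = "paper"
    normalization: str = "orthonormal"
    calibrate: bool = False
    scene: SceneConfig | None = None
    scene_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.scene is not None:
            d["scene"] = dataclasses.asdict(self.scene)
        return d


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of the config."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    table: pd.DataFrame
    cv_results: list[CVResult]
    hash: str = field(default="")


def extract_features(
    plot_ids: list[str],
    stages: list[str],
    cubes: list[ReflectanceCube],
    rois: list[PlotROI],
    records: list[GroundTruthRecord],
    *,
    texture_band: int = 800,
    index_names: tuple[str, ...] = INDEX_NAMES,
    variant: str = "paper",
    normalization: str = "orthonormal",
) -> pd.DataFrame:
    """One feature row per plot-date: VI_*, Ene, WTVI_* and measured LAI."""
    if not (len(plot_ids) == len(stages) == len(cubes) == len(rois) == len(records)):
        raise InputError("plot_ids, stages, cubes, rois, records must align")
    lai_by_id = {r.plot_id: r.lai for r in records}
    defs = [get_index(n, variant) for n in index_names]
    rows = []
    for pid, stage, cube, roi in zip(plot_ids, stages, cubes, rois):
        if pid not in lai_by_id:
            raise InputError(f"no ground-truth LAI for plot {pid!r}")
        decomp = haar_decompose(
            cube.band(texture_band), wavelength=texture_band,
            normalization=normalization,
        )
        ene = plot_energy(energy_texture(decomp), roi)
        row = {"plot_id": pid, "stage": stage, "LAI": lai_by_id[pid], "Ene": ene}
        for d in defs:
            vi = plot_vi(compute_vi(cube, d), roi)
            row[f"VI_{d.name}"] = vi
            row[f"WTVI_{d.name}"] = fuse(vi, ene)
        rows.append(row)
    return pd.DataFrame(rows)


def _calibration_roundtrip(
    scene: SyntheticScene, config: RunConfig
) -> list[ReflectanceCube]:
    """Exercise the calibration stage: invert reflectance to DN with the
    scene's known line + noise, refit the line on synthetic targets, and
    convert back."""
    sc = scene.config
    targets, _dn = generate_targets(sc)
    corrections = cal.fit_all_bands(targets, sc.bandmap)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=sc.seed, spawn_key=(424242,))
    )
    out = []
    for cube in scene.cubes:
        dn = sc.dn_per_reflectance * cube.pixels + sc.dn_dark
        dn += sc.dn_noise_sigma * rng.standard_normal(dn.shape)
        dn_cube = ReflectanceCube(
            pixels=np.maximum(dn, 0.0),
            bandmap=cube.bandmap,
            nodata_mask=cube.nodata_mask,
        )
        out.append(cal.apply_correction(dn_cube, corrections))
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow and return features plus CV rankings."""
    if (config.scene is None) == (config.scene_dir is None):
        raise InputError("set exactly one of scene / scene_dir")
    if config.scene is not None:
        scene = generate_scene(config.scene)
        plot_ids, stages = scene.plot_ids, scene.stages
        cubes, rois, records = scene.cubes, scene.rois, scene.records
        if config.calibrate:
            cubes = _calibration_roundtrip(scene, config)
    else:
        plot_ids, stages, cubes, rois, records = load_scene_dir(config.scene_dir)
        if config.calibrate:
            raise InputError(
                "calibrate=True requires in-process simulation; for disk "
                "inputs run `wtvi calibrate` on the DN rasters first"
            )
    table = extract_features(
        plot_ids, stages, cubes, rois, records,
        texture_band=config.texture_band,
        index_names=config.indices,
        variant=config.variant,
        normalization=config.normalization,
    )
    cv = rank_indices(table, k=config.k, seed=config.seed)
    return PipelineResult(
        config=config, table=table, cv_results=cv, hash=config_hash(config)
    )


def write_result(result: PipelineResult, out_dir: str | os.PathLike) -> None:
    """Persist features.csv + results.json, both tagged with the config hash."""
    os.makedirs(out_dir, exist_ok=True)
    feat_path = os.path.join(out_dir, "features.csv")
    with open(feat_path, "w") as fh:
        fh.write(f"# config_hash={result.hash}\n")
        result.table.to_csv(fh, index=False, lineterminator="\n")
    with open(os.path.join(out_dir, "results.json"), "w") as fh:
        json.dump(
            {
                "config_hash": result.hash,
                "config": result.config.to_dict(),
                "cv_results": [r.to_dict() for r in result.cv_results],
            },
            fh,
            indent=2,
            sort_keys=True,
            default=str,
        )
        fh.write("\n")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# scene directory layout: cubes/<plot_id>.npz + rois.csv + ground_truth.csv
# + manifest.json (plot order, stages, config echo)
# ---------------------------------------------------------------------------

def write_scene_dir(
    scene: SyntheticScene, out_dir: str | os.PathLike, raster_format: str = "npz"
) -> None:
    if raster_format not in ("npz", "tif"):
        raise InputError("raster_format must be 'npz' or 'tif'")
    out_dir = os.fspath(out_dir)
    cube_dir = os.path.join(out_dir, "cubes")
    os.makedirs(cube_dir, exist_ok=True)
    for pid, cube in zip(scene.plot_ids, scene.cubes):
        write_cube(os.path.join(cube_dir, f"{pid}.{raster_format}"), cube)
    write_rois(os.path.join(out_dir, "rois.csv"), scene.rois)
    write_ground_truth(os.path.join(out_dir, "ground_truth.csv"), scene.records)
    manifest = {
        "plot_ids": scene.plot_ids,
        "stages": scene.stages,
        "raster_format": raster_format,
        "config": dataclasses.asdict(scene.config),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def load_scene_dir(path: str | os.PathLike):
    path = os.fspath(path)
    manifest_path = os.path.join(path, "manifest.json")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    plot_ids = list(manifest["plot_ids"])
    stages = list(manifest["stages"])
    fmt = manifest.get("raster_format", "npz")
    bandmap = default_bandmap()
    cubes = [
        read_cube(os.path.join(path, "cubes", f"{pid}.{fmt}"), bandmap)
        for pid in plot_ids
    ]
    rois_by_id = {r.plot_id: r for r in read_rois(os.path.join(path, "rois.csv"))}
    records = read_ground_truth(os.path.join(path, "ground_truth.csv"))
    try:
        rois = [rois_by_id[pid] for pid in plot_ids]
    except KeyError as exc:
        raise InputError(f"ROI missing for plot {exc.args[0]!r}") from exc
    return plot_ids, stages, cubes, rois, records
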