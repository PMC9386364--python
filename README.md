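# wtvi

Spectral–texture fused vegetation indices for rice leaf-area-index (LAI)
estimation from UAV multispectral imagery.

The package implements the full workflow:

1. **Radiometric calibration** (`wtvi.calibration`) — per-band
   empirical-line fits (`reflectance = gain·DN + offset`) on targets of
   known reflectance; pixel-wise conversion clipped to [0, 1].
2. **Vegetation indices** (`wtvi.indices`) — the 12 classic indices
   (NDVI, GNDVI, NDRE, SR, CI_red_edge, CI_green, WDRVI, MTCI, EVI2,
   OSAVI, RVI, VARI) over the 550/670/720/800 nm bands, as per-pixel
   rasters with explicit zero-denominator handling. OSAVI and RVI
   default to their red-edge (720 nm) forms; a `variant="classical"`
   switch restores the conventional 670 nm forms.
3. **Wavelet texture** (`wtvi.wavelet`) — level-1 2D Haar decomposition
   (orthonormal convention, so Parseval holds exactly) of a single NIR
   band; the texture feature *Ene* is the 3×3 sliding mean of squared
   LL-sub-band coefficients.
4. **Fusion + evaluation** (`wtvi.fusion`) — plot-level means of VI and
   Ene, fused multiplicatively (`WT-VI = VI × Ene`), linear LAI models
   scored by seeded k-fold cross-validation (mean Coef², R², RMSE,
   rRMSE; rRMSE = 100·RMSE / mean observed LAI).
5. **Synthetic canopy scenes** (`wtvi.synthetic`) — a seeded generator
   of 12-band plot cubes with known LAI across four growth stages
   (tillering → ripening). Canopy cover follows a Beer–Lambert gap
   fraction so band-ratio indices saturate after closure, while leaf
   NIR reflectance keeps rising with LAI so the LL-energy texture stays
   sensitive; post-heading stages mix in panicle speckle. This makes
   every stage of the pipeline testable offline.
6. **I/O** (`wtvi.raster_io`) — multiband TIFF and NPZ cube containers,
   CSV for ROIs, calibration targets and ground-truth LAI
   (`LAI = (LA/3)·ρ` from three-bundle destructive samples).

## CLI

Each stage has its own subcommand (exit codes: 0 ok, 2 input error,
3 degenerate data):

```sh
wtvi simulate --seed 1 --out scene/               # synthetic scene dir
wtvi calibrate --targets targets.csv --in dn.tif --out refl.tif
wtvi indices  --in refl.tif --index NDVI,WDRVI --out vi/
wtvi texture  --in refl.tif --band 800 --out ene.tif
wtvi fit      --table features.csv --k 10 --seed 42 --out cv.json
wtvi run      --scene-dir scene/ --seed 1 --k 10 --out results/
```

`wtvi run` writes `features.csv` (one row per plot-date with VI, Ene,
WT-VI and measured LAI) and `results.json` (cross-validated metrics per
feature, best first). Both embed a hash of the fully-resolved
configuration; reruns with the same config are byte-identical.

`wtvi simulate --config scene.yaml` accepts a YAML file whose keys are
the fields of `wtvi.synthetic.SceneConfig` (seed, n_plots, plot_size,
LAI ranges, endmember spectra, panicle density, noise, …).

## Notes on conventions

- Coordinates are 0-based, half-open, row-major; nodata is a mask, not
  a sentinel.
- Haar normalization defaults to orthonormal (1/√2 filters); a
  unit-sum "average" convention is available for sensitivity checks.
- Odd image dimensions are cropped (trailing row/column) before the
  transform; the 3×3 energy window uses symmetric edge padding.
- Plot-level VI is the mean of the VI image over the ROI (not the VI
  of mean reflectances); plot-level Ene maps the ROI to LL resolution
  by floor-halving its bounds.
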