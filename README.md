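# lensxct

Quantitative 3D morphometry of calcium precipitates in ocular lens
micro-CT volumes.

Age-related nuclear cataracts in connexin-46 knockout (Cx46KO) mice are
accompanied by micron-scale calcium precipitates in the lens core.
Synchrotron phase-contrast micro-CT resolves these precipitates as
high-attenuation objects concentrated in one or two thin spherical shell
layers on the anterior side of the core, clustered around the branches of
the anterior Y-suture.  `lensxct` is a reproducible, scriptable pipeline
for quantifying such populations — for lens biologists and for anyone
doing per-object calcification morphometry in attenuation volumes:

* **segmentation** — global absorption threshold (default: robust
  background median + 5 robust SD) followed by 26-connected component
  labeling with a minimum-size filter;
* **morphometry** — per precipitate: voxel count, physical volume
  *V = N·p³* (pitch *p*), **Maximum Feret diameter** (MFD: the largest
  caliper width, computed as the convex-hull diameter of voxel centers
  plus one pitch), minimum principal-axis extent, **aspect ratio**
  AR = min extent / MFD ∈ (0, 1] (≈1 spheres, →0 chains), and mean
  absorption per cm;
* **spatial analysis** — lens localization (Otsu + largest component),
  per-precipitate distance to the lens center, radial histogram with
  smoothed peak detection (the shell layers), anterior/posterior split;
* **reporting** — MFD class fractions (<40, 40–100, 100–200, ≥200 µm),
  eight-bin absorption histogram, AR × log-volume heat map, JSON/CSV/PNG;
* **synthetic phantoms** — a lens-core phantom generator with exact
  ground truth, whose four named configurations (`P23-B6`, `P27-129`,
  `P31-B6`, `P31-129`) encode the published age/strain trends of Cx46KO
  precipitate populations, so every stage is testable by parameter
  recovery without any data download.

## Worked example

Generate the severe-cataract phantom (two anterior shells at 420 and
520 µm, 2000 precipitates, 5 µm voxels) and analyze it end to end:

```sh
$ lensxct generate --preset P31-129 --seed 1 --out p31
wrote p31/volume.tif (2000 precipitates planted)

$ lensxct analyze p31/volume.tif --figures --out p31-analysis
2000 precipitates measured; 2 radial peaks detected
```

`p31-analysis/` now holds `records.csv` (one row per precipitate),
`radial_profile.csv`, `radial_peaks.json`, `report.json`, provenance, and
figures.  The detected shell peaks:

```json
"peaks": [
 {"location_um": 419.29577464788736, "prominence": 87.66666666666666},
 {"location_um": 521.9736842105264,  "prominence": 175.0}
]
```

— the two planted shell layers, recovered at 419.3 and 522.0 µm,
102.7 µm apart.  The MFD class fractions in `report.json`,

```
mfd_bins = [0.8915, 0.1045, 0.004, 0.0]
```

say that 89.2% of measured precipitates are shorter than 40 µm (this
configuration is calibrated to 90%), 10.5% fall in 40–100 µm, 0.4% in
100–200 µm, and none reach 200 µm.  The segmentation threshold chosen
automatically for this volume was 7.51 cm⁻¹ (background 5 cm⁻¹, noise
SD 0.5 cm⁻¹).

The same stages are available as library functions:

```python
import lensxct as lx

cfg = lx.named_config("P31-129", seed=1)
truth = lx.sample_precipitate_population(cfg)   # exact ground truth
volume = lx.render_phantom(cfg, truth)
result = lx.run_analysis(volume)                # mask -> segment -> measure
result["profile"].peaks                         # [(419.3, 87.7), (522.0, 175.0)]
```

## Layout

```
src/lensxct/
  phantom.py       synthetic lens phantoms + ground truth
  volume_io.py     TIFF/raw volumes, sidecars, label maps, CSV tables
  segmentation.py  background estimation, threshold + 26-CC labeling
  morphometry.py   MFD, aspect ratio, per-object measurement
  spatial.py       lens mask/center, radial profile, peak detection
  reporting.py     summary report + figures
  cli.py           pipeline orchestration and the lensxct command
docs/methods.md    model, parameters, and numerical choices
```
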