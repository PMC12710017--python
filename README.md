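# crownchl

Shadow-resistant retrieval of leaf and canopy chlorophyll content (LCC/CCC)
for individual tree crowns, exercised end-to-end on synthetic orchard
imagery with known ground truth.

The package simulates nadir multispectral views of a row-structured orchard
with a simplified ray-cast scene (ellipsoidal turbid crowns, Beer's-law
attenuation), quantifies how crown shadows vary through the day, ranks
broadband vegetation indices (VIs) by their resistance to shadow variation,
trains a hybrid inversion model (radiative-transfer LUT + Gaussian process
regression), and maps per-tree LCC, LAI and CCC = LCC x LAI.

## Components

| module | role |
| --- | --- |
| `crownchl.leaf_rtm` | plate-model leaf reflectance/transmittance on a 400-2500 nm grid (packaged surrogate calibration tables) |
| `crownchl.solar` | NOAA-style solar zenith/azimuth from time and location |
| `crownchl.canopy_scene` | orchard scene, four-component rendering (sunlit/shaded leaf/ground), crown shadow fraction, Monte-Carlo photon escape (fesc), spectral mixing, LUT builder |
| `crownchl.spectral_indices` | 5-band sensor resampling (450/560/650/730/840 nm, +/-16 nm boxcar) and a 21-entry broadband VI registry |
| `crownchl.shadow_resistance` | per-scenario VI-to-chlorophyll R^2, summed-rank shadow-resistance ranking, rate-of-change and disturbance-sensitivity analyses |
| `crownchl.hybrid_inversion` | 7:3 splits, GPR training, rank-ordered forward VI selection, per-tree trait prediction, R^2/RMSE/nRMSE metrics |
| `crownchl.synthetic_orchard` | synthetic survey generator: layouts, truncated-normal truth, 5-band rasters + crown-ID maps, crown-mean extraction |
| `crownchl.pipeline` / `crownchl.cli` | config-driven orchestration with manifests and per-stage seeding |

## CLI

```bash
# full workflow at desk scale into ./out
crownchl run-all --preset mini --seed 3 --outdir out

# or stage by stage
crownchl simulate-lut --preset mini --seed 3 --outdir out
crownchl rank-vis    --outdir out
crownchl select-vis  --outdir out
crownchl synth-survey --preset mini --seed 3 --outdir out
crownchl train       --outdir out
crownchl invert      --outdir out
crownchl map         --outdir out
```

Presets: `mini` (reduced parameter ladders, 24-tree survey), `orchard1`
(429 trees), `orchard2` (215 trees). All defaults live in
`crownchl.pipeline.DEFAULT_CONFIG` and can be overridden with a YAML file
via `--config`. Outputs are plain CSV/JSON/TIFF plus a `manifest.json`
with per-stage seeds and artifact digests; re-running with the same global
seed reproduces the digests.

## Regenerating packaged data

`scripts/build_calibration.py` rewrites the CSV calibration tables under
`src/crownchl/data/` (leaf coefficient spectra, soil/bark reflectance).
The leaf table is an analytic surrogate calibration — Gaussian absorption
bands placed at the classic pigment/water/dry-matter features — not a copy
of any published coefficient set.
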