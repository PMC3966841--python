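# retnathist

Natural-history analysis toolkit for an all-cone mouse model of retinal
degeneration and its human counterpart: OCT reflectivity-profile layer
segmentation, en-face pseudorosette detection, foveal-island metrics, and
exponential ERG-decay modelling with a treatment-window calculator — all
exercised against a synthetic-data generator with exact ground truth.

## Modules

| module | purpose |
| --- | --- |
| `retnathist.synthdata` | synthetic OCT volumes (layered retina, RPE curvature, hyperreflective pseudorosettes, speckle-like noise), ERG amplitude cohorts on a log-linear decay, foveal ONL island profiles — every phantom carries exact ground truth |
| `retnathist.oct_layers` | LRP extraction and repeat averaging, RPE detection (second hyperreflective band from the scleral side), integer-pixel flattening, ONL+/total-thickness segmentation, meridian profile montage, ONH/rosette exclusion, cohort statistics and Welch t-tests |
| `retnathist.enface` | integrated slab backscatter maps, bright-spot detection (Otsu / robust threshold + watershed splitting), quadrant/hemifield sector counts and densities |
| `retnathist.fovea` | 5-sample foveal ONL average, island width at half-maximum ONL, normal limits (mean − 2 SD), OLS regressions with a slope test |
| `retnathist.natural_history` | log10-linear amplitude decay fits, 95% prediction intervals, percent-per-day rates, treatment-window thresholds from interocular asymmetry bounds |
| `retnathist.pipeline` / `retnathist.cli` | YAML-configured end-to-end runs, TIFF+JSON / CSV I/O, provenance sidecars, deterministic per-stage seeding |
| `retnathist.reference` | reference cohort designs wiring the full pipelines together for validation studies |

## CLI

```bash
retnathist simulate-oct --out eye.tiff --seed 1 --rosettes "superior=44,inferior=73"
retnathist segment      --volume eye.tiff --out-prefix eye
retnathist enface       --volume eye.tiff --out-prefix eye --scheme halves
retnathist simulate-erg --out erg.csv --intercept 2.6203 --slope -0.015396 \
                        --ages 31,45,59,73,83 --n-per-age 7 --scatter 0.2
retnathist fit-decay    --erg erg.csv --out fit.json
retnathist plan-window  --fit fit.json --inject-age 37 --assess-delay 28 --asym 0.3
retnathist run          --config examples/demo.yaml
```

A pipeline config is a YAML mapping with `seed`, `output_dir` and an ordered
`stages` list (see `examples/demo.yaml`). Every output carries a provenance
sidecar with the config hash and seed; identical configs reproduce
byte-identical outputs.

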