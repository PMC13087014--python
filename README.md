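# braintx

Imaging-transcriptomics of regional brain atrophy: a tested, reusable
pipeline that

1. **simulates** every input it needs (parcellation geometry, spatially
   autocorrelated gene-expression maps, multi-donor microarray sample sets,
   and control/patient cohorts with known planted effects),
2. **processes** donor microarray bundles into a normative region-by-gene
   expression matrix (background-intensity probe filtering, differential-
   stability probe selection, 2 mm nearest-centroid sample assignment,
   nearest-sample interpolation, scaled robust sigmoid normalization, donor
   averaging),
3. **fits normative w-scores**: per-region OLS of grey-matter volume on
   TIV + age + sex in controls; patient deviations scaled by the control
   residual SD, averaged into a regional atrophy map,
4. **tests gene-atrophy associations** per gene by simple linear regression
   with *spatial* p-values from variogram-matched surrogate maps
   (permute -> kNN kernel smooth -> variogram least-squares match ->
   rank-remap), with Benjamini-Hochberg FDR across the 12-gene panel, and
5. **fits a random forest** (ntree=500, mtry=p/3, nodesize=2) of atrophy on
   the panel, reporting OOB MSE, %Var(y) and increase-in-MSE importance,
   each tested against surrogate-predictor null forests.

## CLI

```bash
braintx simulate  --seed 1 --out data/ --effect GBA=-0.5   # synthetic inputs
braintx expression --donors data/donors --atlas data/atlas.tsv --out expr.csv
braintx wscore    --subjects data/subjects.csv --atlas data/atlas.tsv --out w/
braintx surrogates --map expr.csv --atlas data/atlas.tsv --gene GBA \
                   --n 10000 --seed 1 --out surr.csv
braintx associate --subjects data/subjects.csv --expression expr.csv \
                  --atlas data/atlas.tsv --out assoc.tsv
braintx forest    --subjects data/subjects.csv --expression expr.csv \
                  --atlas data/atlas.tsv --out forest.json
braintx run-all   --config cfg.yaml --out results/   # full study replica
```

`run-all` without `--config` uses a bundled demo configuration (fully
synthetic cohort, 200 regression surrogates, 100 forest nulls) that
completes in a few seconds and writes the complete report bundle
(atrophy map + t-tests, gene correlation matrix, association table, forest
JSON, provenance log with config hash and seeds).

## Layout

| module | contents |
| --- | --- |
| `braintx.atlas` | `RegionAtlas` / `RegionMap` geometry types |
| `braintx.synthetic` | atlas, SA-map, cohort and donor generators |
| `braintx.expression` | donor-microarray processing chain |
| `braintx.wscore` | normative models, w-scores, regional t-tests |
| `braintx.surrogates` | variograms, surrogate ensembles, empirical p |
| `braintx.association` | per-gene regression, spatial p, BH FDR |
| `braintx.forest` | bagged trees, OOB importance, surrogate nulls |
| `braintx.io` / `config` / `pipeline` / `cli` | I/O, config, orchestration |

All file formats are plain text (TSV/CSV/JSON/YAML); every stochastic step
is driven by an explicit seed and reruns are byte-identical.
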