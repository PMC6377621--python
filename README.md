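# polarscape

Landscape-scale biocomplexity analysis for polar soil ecosystems: from ARISA
community fingerprints and terrain-derived abiotic covariates, through
environment-independent spatial filters, to composite-variable structural
equation models (SEM) that partition abiotic, spatial, and biotic controls on
the richness of cyanobacteria, fungi, and multicellular taxa.

A synthetic-landscape generator with a known ground-truth path model makes
every stage testable without any external data.

## Modules

| module | what it does |
|---|---|
| `polarscape.synth` | synthetic DEMs, sample tables from recursive structural equations + a Gaussian-process spatial component, nested community matrices, electropherograms that round-trip the peak-calling rules |
| `polarscape.arisa` | true-peak calling (size window, >30 RFU floor, >0.3% relative fluorescence), 1-bp single-linkage fragment binning, per-sample richness |
| `polarscape.terrain` | Horn slope/aspect, D8 flow accumulation (optionally source-weighted), wetness index `CTI = ln(A_s/tan beta)`, Euclidean distance to the zero-elevation coastline |
| `polarscape.community` | Bray–Curtis, non-metric multidimensional scaling (Kruskal stress-1), smooth-isocline nestedness temperature with permutation nulls, richness–axis correlations |
| `polarscape.spatial` | PCNM eigenvector basis, residualization against the environment, regression-based richness prediction, PCA summarization into `s1`/`s2` |
| `polarscape.sem` | path-model parser (composites, fixed parameters), ML covariance-structure fitting with analytic gradients, chi-square/CFI, standardized solutions, total & net effects, residual diagnostics, landscape prediction |
| `polarscape.pipeline` | seeded end-to-end runs with plain-text artifacts and JSON/Markdown reports |

The built-in model `final_2019` encodes the final landscape path model
(14 observed variables, df = 35); `predictive_2019` is the remote-sensing-only
variant used for prediction rasters.

## CLI

```sh
polarscape synth --n-sites 490 --seed 1 --out data/          # synthetic bundle
polarscape terrain --dem data/dem.asc --out terr/            # terrain rasters
polarscape arisa --group cyanobacteria --in data/peaks_cyanobacteria.csv --out ar/
polarscape community --in data/community_multi_s.csv --out comm/
polarscape spatial --samples run/samples_final.csv --out sp/
polarscape sem fit --model final_2019 --samples run/samples_final.csv --out fit/
polarscape run --config config.yaml                          # full pipeline
```

A minimal `config.yaml`:

```yaml
seed: 1
out_dir: run
synth: {n_sites: 200}
community: {n_perm: 199, null_model: r00}
sem: {model: final_2019}
```

Point `samples:`/`dem:`/`peaks:` at your own CSV/ASCII-grid files to analyze
real data instead of a synthetic bundle.

## Model syntax

```text
y <- x1 + x2 + 0.5*x3       # paths (numeric prefix fixes the coefficient)
composite C <= 1*s1 + s2    # emergent composite, first weight fixed
a ~~ b                      # free covariance
a ~~ b @0                   # fixed covariance
```

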