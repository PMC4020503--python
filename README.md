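# arealscan

Spatial and space-time scan statistics for areal disease-registry data.

`arealscan` implements covariate-adjusted Poisson cluster detection over
areal units (e.g. counties): circular-window scans, flexibly shaped
(adjacency-constrained) scans, space-time Poisson scans over cylindrical
windows, and the space-time permutation scan that detects space-time
interaction net of purely spatial and purely temporal structure.
Significance is assessed by conditional Monte Carlo replication of the
scan maximum, with an optional Gumbel extreme-value tail approximation.
A synthetic county-registry generator produces stratified populations and
Poisson case counts with embedded clusters, so the whole pipeline can be
exercised and validated without any registry extract.

## Components

| module                 | what it does |
|------------------------|--------------|
| `arealscan.geo`        | regions, centroids, distances, Delaunay/k-NN adjacency, coordinates file I/O, GeoJSON-ready region model |
| `arealscan.registry`   | stratified case/population counts, indirect standardization to expected counts, annual incidence rates, case/population file I/O |
| `arealscan.scan`       | circular windows, Poisson log likelihood ratio, ranked non-overlapping clusters, conditional Monte Carlo null, rank and Gumbel p-values |
| `arealscan.spacetime`  | cylindrical windows, space-time Poisson scan, space-time permutation scan, trend-artifact diagnosis |
| `arealscan.flex`       | flexibly shaped scan: connected subsets of k-nearest-neighbor sets |
| `arealscan.synth`      | synthetic registry generator (maps, stratified populations, Poisson cases, cluster ground truth) |
| `arealscan.report`     | summary tables, sex-specific / covariate-subset reruns, GeoJSON cluster overlays |

## CLI

Simulate a registry, then scan it:

```sh
arealscan simulate --n-regions 67 --periods 9 --cluster 4:1.7 --seed 1 --out synthetic/
arealscan scan --cas synthetic/registry.cas --pop synthetic/registry.pop \
    --geo synthetic/map.geo --adjust age,sex,race --replicates 999 --seed 1 \
    --out run/
```

`run/` will contain `report.txt` (a summary table: population, cases,
annual rate per 100,000, relative risk, log likelihood ratio, p-value for
the study area and each reported cluster), `results.json` and
`clusters.geojson`. Other subcommands: `scan-flex` (`--K` neighborhood
size), `scan-st` (space-time Poisson), `scan-stp` (space-time permutation;
also reports a `trend_artifact` flag when the Poisson space-time scan
flags a cluster the permutation scan does not confirm), and `report`.

Input files are whitespace-delimited text: coordinates (`id x y`), cases
(`id count period covariates...`) and population (`id period count
covariates...`); blank lines and `#` comments are ignored.

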