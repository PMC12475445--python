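# microniche

Spatial quantification of tumor microniches from segmented whole-slide-image
exports: contact calling around tumor cells, invasion-front distance
profiles, compartment phenotype statistics, stromal layer and gradient
analysis, and lineage-barcode clonality post-processing — together with a
ground-truthed synthetic-tissue generator so the entire pipeline is testable
without any clinical data.

## Modules

| module | what it does |
| --- | --- |
| `microniche.io_formats` | cell tables (CSV/TSV), region annotations and invasion fronts (GeoJSON), intensity fields (text matrix + JSON sidecar), barcode count tables (CSV), tidy result writers with manifests |
| `microniche.spatial` | exact 2D primitives: point-to-geometry distances, strict fixed-radius neighbor queries, concentric outward annuli, disk intensity aggregation |
| `microniche.niche` | per-class contact fractions within a strict 20 µm radius, composition stratified by distance to the invasion front, compartment area fractions, exocrine composition by atrophy stage, proximity-conditioned intensity comparisons |
| `microniche.stats` | marker × ROI positive-fraction matrices, paired Wilcoxon + BH, Kruskal–Wallis with Dunn post-hoc, binned Gini–Simpson diversity, Ward clustering of ROIs, predominant-subtype contingency tests |
| `microniche.stromal` | 15 µm concentric layer fractions, coexpression overlaps, disk-intensity gradients vs front distance (fibrosis-contact conditioned), thresholded positive-area fractions |
| `microniche.clonality` | depth normalization, 1000-count filter, index-hopping bleed-through removal, clone summaries |
| `microniche.synthetic` | deterministic generators for cohorts, intensity fields, barcode tables, layered and atrophy-staged cell populations, with a full planted-truth manifest |

## CLI

```bash
microniche simulate  --config cfg.yaml --seed 1 --out sim/
microniche contacts  --cells sim/cells.csv --annotations sim/regions.geojson --radius 20 --out out/
microniche phenotype --cells sim/cells.csv --markers classical,basal --out out/
microniche layers    --cells cells.csv --tumor-regions ann.geojson --markers ASMA --width 15 --n-rings 3 --out out/
microniche gradient  --cells cells.csv --annotations ann.geojson --field field.txt --roi R1 --out out/
microniche clonality --counts counts.csv --min-count 1000 --hop-fraction 0.05 --out out/
```

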