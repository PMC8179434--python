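# mcspace

Macrocycle-specific molecular descriptors and chemical-space analysis.

`mcspace` maps collections of macrocyclic compounds (MCs) into a
90-descriptor property space built on a ring / peripheral / substituent
decomposition of each molecule, fits a PCA chemical-space model on 0–100
scaled descriptors, and scores compound sets for structural diversity
(10-D hyperellipsoid volumes) and proximity to oral-MC-druglike property
space (centroid distances and a 13-property range filter).

## Components

| module | what it does |
|---|---|
| `mcspace.chem_io` | SMILES/SDF reading, macrocycle admission filter (largest ring ≥ 11 atoms by default) |
| `mcspace.decomposition` | MC ring perception (largest chordless cycle), atom classes, substituent gaps, restricted-bond fraction, peri-fusion detection |
| `mcspace.registry` | the 90 molecular descriptors (32 classic, 12 prior-guideline, 46 MC-specific) |
| `mcspace.scaling` | two-regime 0–100 scaling (discrete: 0→max; MW/tPSA/clogP: μ±2σ window) |
| `mcspace.chem_space` | mean-centered SVD PCA, projection of new designs, hyperellipsoid volumes, normalized centroid distances |
| `mcspace.importance` | descriptor importance over retained PCs, correlation-based redundancy pruning |
| `mcspace.druglikeness` | packaged 13-property oral-MC-druglike ranges, violation counting, ≤4-violation classifier |
| `mcspace.selection` | PAM k-medoids representative selection (k = 42 default, Z-scored) |
| `mcspace.synthetic` | macrocycle generator with construction-time ground truth (profiles: oral-like, sparse, kinase-like, random) |

## CLI

```bash
# generate a synthetic library with ground truth
mcspace simulate --n 200 --profile oral-like --seed 7 --out lib.smi --truth truth.csv

# admission filter and descriptor matrix
mcspace filter --in lib.smi --out report.csv --kept kept.smi
mcspace descriptors --in lib.smi --out mold.csv --multifusion merge

# chemical-space model and projection
mcspace fit-space --matrix mold.csv --scaling-out scaling.json --model-out model.json
mcspace project --matrix mold.csv --scaling scaling.json --model model.json --out scores.csv
mcspace metrics --scores scores.csv --reference oral_scores.csv --universe all_scores.csv

# importance ranking, druglikeness filter, representative selection
mcspace importance --matrix mold.csv --top 20
mcspace violations --in lib.smi --ranges table2 --threshold 4 --out viol.csv
mcspace select --matrix mold.csv --k 42 --seed 17 --out medoids.csv
```

## Notes

- Descriptor formulas not fully specified by their source (peptide
  character index, ring complexity) are flagged `reconstructed` in the
  registry manifest and can be overridden.
- clogP/tPSA come from RDKit's Crippen and Ertl implementations; absolute
  values differ from other toolkits.
- Compounds with peri-fused ring systems ("multifusion") are either
  merged into one fused substituent (default) or routed to an exceptions
  output, per `--multifusion`.
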