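# ullmannkit

Interpretable success prediction and ligand recommendation for Cu-catalyzed
Ullmann C–N coupling screens, built around precomputed structure descriptors:
the Cu–ligand interaction distance *d* (Å), the amine nitrogen NBO charge
(au), and the aryl bromide percent buried volume %VBur (2.5 Å radius).

The package covers an end-to-end screening workflow on CSV tables:

- **core_model** — domain records, on/off yield labeling (on ⇔ yield
  strictly above 20%), control-experiment curation (a product fails if
  either its ligand-free or ligand-and-copper-free control reaches 20%),
  and binary classification metrics.
- **design** — library filtering (LogP < 4, MW < 400 u), 2-D UMAP chemical
  space, Ward clustering, per-cluster representative picking, and
  cross-cluster product pairing.
- **screen** — single-node decision-stump classification of ligands by any
  descriptor (the Cu–L distance with its ≈2.07 Å cut in practice) and
  active-learning reselection of candidate ligands predicted active.
- **classifier** — a 3-node greedy Gini decision tree (the "three nodes"
  budget caps internal nodes, not depth) with a 75:25 seeded split and
  stratified k-fold cross-validation, plus the fixed published rule:
  on ⇔ d ≤ 2.07 Å ∧ N-charge ≤ −0.803 au ∧ %VBur ≤ 33.5% (equality is on).
- **confidence_map** — per-product prediction confidence as one minus the
  base-10 information entropy of the observed on/off ligand outcomes
  (2 on of 18 → 85% confidence), signed by the predicted class and
  interpolated over the (N-charge, %VBur) plane with a thin-plate RBF.
- **recommend** — top-3 ligands from each of the query's two nearest
  dataset products in standardized substrate space, with shared-ligand
  flags and the leave-self-out neighbor hit-rate diagnostic.
- **synthetic_data** — a seeded simulator producing the full staged-screen
  dataset (12 products × 24 ligands, +12 reselected ligands, +16 products
  × 18 ligands = 720 reactions; 37 products with 9 control-failing
  backgrounds) with a planted three-feature rule, structured ~13% label
  noise, and neighbor-transferable ligand quality.
- **io_cli** — schema-validated CSV IO, YAML run configuration, and the
  command-line interface.

## CLI

```bash
ullmannkit simulate --seed 42 --out data/            # write the 7 CSV tables
ullmannkit curate --products data/products.csv --controls data/controls.csv \
    --out-passing passing.csv --out-failed failed.csv
ullmannkit screen fit --reactions data/reactions.csv --ligands data/ligands.csv \
    --out stump.json
ullmannkit screen select --candidates data/ligands.csv --stump stump.json \
    --out selected.csv
ullmannkit train --reactions data/reactions.csv --ligands data/ligands.csv \
    --bromides data/bromides.csv --amines data/amines.csv \
    --products data/products.csv --seed 42 --out model.json
ullmannkit predict --model fixed --input queries.csv --out predictions.csv
ullmannkit map build --reactions data/reactions.csv --bromides data/bromides.csv \
    --amines data/amines.csv --products data/products.csv --out map.json
ullmannkit map query --map map.json --n-charge -0.85 --vbur 30.0
ullmannkit recommend --reactions data/reactions.csv --bromides data/bromides.csv \
    --amines data/amines.csv --products data/products.csv \
    --n-charge -0.85 --vbur 30.0
```

`python -m` style invocation works too: the console entry point is
`ullmannkit.io_cli:main`. Exit codes: 0 success, 1 validation error,
2 usage error. `predict --model` accepts `fixed` (the published thresholds)
or a trained model JSON; `map build` uses the fixed rule's substrate
marginal (the ligand axis is marginalized because mapped products share a
favorable-distance ligand panel).

Table schemas (CSV, UTF-8, header row): `ligands(ligand_id, cu_l_distance,
…)`, `bromides(bromide_id, vbur, …)`, `amines(amine_id, n_charge, …)`,
`products(product_id, bromide_id, amine_id)`, `reactions(product_id,
ligand_id, yield_percent)`, `controls(product_id, control_type,
yield_percent)`. Extra numeric columns pass through as descriptors.

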