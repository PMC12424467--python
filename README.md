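# mclspace

Data-driven selection of **measurable compound lists (MCLs)** for non-target
LC-HRMS method development. Starting from a compound table (id + SMILES,
optionally precomputed descriptors), the pipeline:

1. builds a 13-variable chemical-space model per compound — molecular weight,
   XLogP, TPSA, H-bond donor/acceptor counts, six elemental (Kendrick-style)
   mass defects (default base units CH2, CO, CCl, CN, CF2, CS), an
   environmental mobility class coded 1/2/3 (Non-mobile / Mobile / Very
   mobile), and a log10 electrospray ionization efficiency (LogIE);
2. mean-centers and unit-scales the matrix and fits a PCA (deterministic
   SVD-based, sample-variance convention);
3. applies a *symmetric grid* (equal bin counts and widths per retained score
   axis) over the PCA score space and samples candidates per cell;
4. enforces structural dissimilarity (greedy filter, pairwise distance
   > 0.15; continuous Tanimoto on the scaled model variables by default,
   Jaccard on non-hashed MACCS fingerprints as an option);
5. filters for ionization compatibility — LogIE > 3.5 for ESI(+); LogIE < 1.5
   *and* at least one H-bond donor for ESI(−) (all inequalities strict);
6. groups the survivors by mobility class, ranks each class by descending
   LogIE, and takes a user-defined number per class into ranked
   `mcl_positive.csv` / `mcl_negative.csv` files;
7. reports diagnostics: grid-cell coverage (also vs. a reference watch list),
   RPLC domain classification (−1 outside / 0 maybe / 1 inside), RI-vs-mass
   regression, and offline patent/literature availability counts.

Mobility, LogIE, and retention-index values are expected as precomputed
columns from the published external predictors (passthrough mode); simple
documented *surrogate* baselines are bundled so the pipeline runs
self-contained.

## CLI

All subcommands accept `--config <yaml>`, `--seed <int>`, `--log-level`.

```bash
# synthetic fixture with ground truth (deterministic per seed)
mclspace --seed 7 simulate --n 10000 --out-features features.csv --out-truth truth.csv

# compound table -> 13-variable feature table
mclspace --config config.yaml featurize -i compounds.csv -o features.csv

# fit scaling + PCA + grid; write model JSON and score table
mclspace --config config.yaml space -i features.csv --model model.json --scores scores.csv

# run the selection cascade
mclspace --config config.yaml sample --features features.csv --scores scores.csv \
    --model model.json --out-dir mcl/

# coverage / retention / availability diagnostics
mclspace --config config.yaml report --features features.csv --scores scores.csv \
    --model model.json --mcl mcl/mcl_positive.csv --mcl mcl/mcl_negative.csv -o report.json
```

Example config (all keys optional; defaults shown partially):

```yaml
columns: {id: cid, smiles: smiles, mobility_class: mob, log_ie: logie}
emd_units: [CH2, CO, CCl, CN, CF2, CS]
grid: {k: 3, bins_per_axis: 20}
selection:
  distance_threshold: 0.15
  distance_metric: continuous_tanimoto_on_features  # or jaccard_on_fingerprints
  logie_pos_min: 3.5
  logie_neg_max: 1.5
  hbd_min_neg: 1
  per_class_n: 50
predictors:
  mobility: {kind: passthrough}
  log_ie: {kind: passthrough}
  ri: {kind: baseline}
rplc_bounds: [0, 50, 950, 1000]
```

## Notes

- A threshold note: the dissimilarity criterion retains structures with
  pairwise **distance** > 0.15. The similarity family used is
  Jaccard/Tanimoto; Rogers–Tanimoto (which counts matching zeros) is
  intentionally not implemented.
- Baseline predictor outputs are surrogates with documented linear forms —
  they are not the published mobility/IE/RI models.
- The embedded monoisotopic atomic-mass table lives at
  `src/mclspace/data/atomic_masses.json`.
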