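# diliqsar

A QSAR pipeline for predicting drug-induced liver injury (DILI) from
chemical structure. The package takes tables of labeled compounds (SMILES or
SDF), curates them into a modeling-grade dataset, and trains a
probability-averaging ensemble of eight classifiers, with the validation
machinery (cross-validation, ROC analysis, Y-randomization, published-table
reconstruction) needed to trust — or distrust — the result.

It is written for cheminformaticians and computational toxicologists who
need a reproducible, inspectable implementation of the full
curation-to-ensemble workflow rather than a black-box predictor.

## The method

Hepatotoxicity labels are noisy and come from sources of unequal trust, so
most of the pipeline is curation:

1. **Standardization** — strip counterions/solvents (salts become the free
   acid/base), reject metal-containing, inorganic and mixture inputs,
   kekulize, neutralize, clear stereochemistry; reject parents with < 4
   carbons or molecular weight > 900. Identity is a hash of the
   standardized canonical SMILES, so salt forms and enantiomers
   deduplicate.
2. **Merge with precedence** — tier-1 (authoritative database) labels win;
   tier-2 structures with conflicting labels are removed.
3. **Descriptors** — a versioned set of 85 RDKit descriptors (30
   physicochemical, 55 topological); diversity via Tanimoto similarity on
   1024-bit path fingerprints (paths ≤ 7 bonds).
4. **Feature filtering** — drop near-constant features (modal frequency
   > 0.95) and, greedily in canonical order, the later member of any pair
   with |Pearson r| > 0.95.
5. **Kennard–Stone balancing** — reduce the majority (negative) class by
   max-min selection in z-scored descriptor space; excluded negatives
   become a reverse-validation pool.
6. **Voting mislabel filter** — each of the 8 classifiers votes, via
   out-of-fold predictions under shared stratified 10-fold CV, on whether
   it can reproduce each compound's label; compounds with fewer than 2
   votes out of 8 are removed as probable label errors.
7. **Ensemble** — naive Bayes, 1-NN, distance-weighted 5-NN, AdaBoost,
   bagging, decision tree, random forest, and a small neural network; the
   positive-class probability is the unweighted mean of the eight
   per-classifier probabilities (soft voting), thresholded at 0.5 with
   ties positive. Evaluated by pooled out-of-fold stratified 10-fold CV:

       ACC = (TP+TN)/(TP+TN+FP+FN)   SE = TP/(TP+FN)   SP = TN/(TN+FP)
       BACC = (SE+SP)/2              AUC = P(s⁺ > s⁻) + ½·P(s⁺ = s⁻)

8. **Y-randomization** — refit the whole cross-validated ensemble on 100
   label permutations; a sound pipeline lands at ACC ≈ 0.5 on balanced
   data, and a real model must clear that band decisively.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Everything below is runnable offline; datasets are generated by
`diliqsar.synthetic_fixtures`.

```python
from diliqsar import standardize_dataset, diversity_summary, toy_smiles_fixture

records, report = standardize_dataset(toy_smiles_fixture())
print(report)
# StandardizationReport(input_count=32, rejected_unparsable=1,
#   rejected_metal_or_rare=3, rejected_mixture_inorganic=6,
#   rejected_size=4, passed=18)

div = diversity_summary([r for r in records if r.is_active])
print(f"mean Tanimoto {div.mean_tanimoto:.3f} over {div.n_pairs} pairs")
# mean Tanimoto 0.155 over 153 pairs
```

The 32-compound truth-table fixture exercises every rejection branch: the
mercury and tin compounds fall to the element whitelist, saline and silica
are inorganic, the two-component inputs are mixtures, propane has too few
carbons — while sodium ibuprofen is *kept* (stripped to ibuprofen) and the
L/D-phenylalanine pair collapses to one structure key. A mean pairwise
Tanimoto of 0.155 says the surviving set is chemically diverse (identical
molecules would give 1.0).

Full pipeline on 300 generated structures whose labels follow a noisy
molecular-weight rule:

```python
from diliqsar.pipeline import PipelineConfig, run_pipeline
from diliqsar.synthetic_fixtures import generate_smiles_dataset

recs = generate_smiles_dataset(300, seed=7)
cfg = PipelineConfig(output_dir="runs/demo", cv_folds=10, seed=2024)
result = run_pipeline(cfg, tier1=recs[:150], tier2=recs[150:])
print(result.metrics.rounded())
# {'TP': 124, 'FN': 13, 'TN': 127, 'FP': 4, 'SE': 0.905, 'SP': 0.969,
#  'ACC': 0.937, 'BACC': 0.937, 'AUC': 0.973}
```

The vote filter removed 32 of 300 compounds (the generator flips ~15% of
labels, and compounds no model family can reconcile with their label score
below 2 of 8 votes); on the cleaned set the ensemble reaches CV accuracy
0.937 against the 0.5 chance level — the run directory (`runs/demo/`)
holds every stage report, the vote scores, out-of-fold predictions, ROC
points and a manifest with per-stage record counts.

The same workflow is available from the shell:

```sh
diliqsar run --config cfg.yaml
diliqsar standardize raw.csv -o std.csv
diliqsar predict model.pkl new_compounds.csv -o predictions.csv
```

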