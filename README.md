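# pudi

**Positive-unlabeled learning for disease gene identification.**

Machine-learning approaches to disease-gene discovery have a structural
problem: confirmed disease genes give a positive training set *P*, but
there is no confirmed *non*-disease gene set.  Treating the remaining
unknown genes as negatives trains a classifier on a noisy negative set,
because some of those "negatives" are simply diseases genes nobody has
confirmed yet.  `pudi` treats the unknown genes as an unlabeled set *U*
and builds a classifier from *P* and *U* alone:

1. **Gene characterisation** — each gene becomes a vector
   V_g = (D, MF, BP, CC, PPI): binary protein-domain memberships, per
   ontology namespace the maximal DAG semantic similarity
   sim(A, B) = Σ_{t∈T_A∩T_B}(S_A(t)+S_B(t)) / (SV(A)+SV(B)) between the
   namespace's feature terms and the gene's annotations (edge decay 0.8
   for `is_a`, 0.6 for `part_of`), and four interaction-network features
   (degree, positive-neighbour fractions 1N/2N, clustering coefficient).
2. **Feature selection** — every feature is scored by its discrimination
   ability da(f) = max(af_P, af_U)·|af_P − af_U| / (af_P + af_U), where
   af is the feature's affinity frequency in each gene set; the top
   N = 1000 per category are kept.
3. **Partitioning U** — genes farther from the positive representative
   vector than average become *reliable negatives* (RN); the rest are
   scored by label propagation G_r = αS G_{r−1} + (1−α)G_0 (α = 0.8,
   S the symmetrically normalised top-Q similarity graph, priors +1 on P
   and −|P|/|RN| on RN) and split into *likely positives* (LP), *likely
   negatives* (LN) and *weak negatives* (WN).
4. **Multi-level weighted SVM** — a soft-margin SVM
   min ½‖w‖² + Σ_i C_set(i)·ξ_i with per-set penalties
   C_P ≥ C_LP (positive side) and C_RN ≥ C_LN ≥ C_WN (negative side),
   so label confidence scales the cost of a training error.  Decision
   scores are calibrated to probabilities with a monotone sigmoid.

The package is aimed at computational biologists who have a curated
disease-gene list plus standard annotation resources (an OBO ontology,
gene-term and gene-domain tables, a PPI edge list) and want ranked,
probability-calibrated disease-gene predictions — and at method
developers who need a fully synthetic, seeded benchmark with planted
hidden positives to study PU-learning behaviour end to end.

## Worked example

Generate a synthetic study — 600 genes, 100 confirmed positives, and a
contaminated unlabeled set in which 43 hidden disease genes lurk among
457 true negatives — then run the full pipeline:

```bash
pudi simulate --out-dir demo --seed 11
pudi run --obo demo/ontology.obo --annotations demo/annotations.tsv \
         --domains demo/domains.tsv --ppi demo/ppi.tsv \
         --positives demo/positives.txt --unlabeled demo/unlabeled.txt \
         --seed 11 --out-dir demo_out
```

which prints the run manifest:

```json
{
  "pudi_version": "0.1.0",
  "seed": 11,
  "n_positives": 100,
  "n_unlabeled": 500,
  "n_features": 234,
  "partition_sizes": {"P": 100, "RN": 222, "LP": 210, "LN": 26, "WN": 42},
  "runtime_s": 1.053
}
```

The 500 unlabeled genes were split into 222 reliable negatives, 210
likely positives, 26 likely negatives and 42 weak negatives, and a
234-dimensional feature space (50 domains + 3×60 ontology terms + 4 PPI
features) was used.  `demo_out/predictions.tsv` ranks every unlabeled
gene; its head, sorted by probability:

```
gene_id   label    score  probability
 g00400 disease 5.221456     0.987915
 g00412 disease 5.080634     0.985875
 g00102 disease 4.269760     0.965633
 g00599 disease 3.692491     0.936310
 g00084 disease 3.339560     0.908203
```

Checking against the generator's truth list
(`demo/hidden_positives.txt`), all 10 of the top 10 predictions are
hidden disease genes that the pipeline never saw labeled.

Cross-validated performance on a balanced study
(`pudi evaluate --config ...` or `pudi run --with-cv`) reports mean
precision, recall, F-measure and ROC AUC over seeded folds, with all
training-side quantities recomputed inside each fold.

## Library use

```python
from pudi import StudyConfig, run_pipeline

cfg = StudyConfig(obo_path="demo/ontology.obo",
                  annotation_path="demo/annotations.tsv",
                  domain_path="demo/domains.tsv",
                  ppi_path="demo/ppi.tsv",
                  positive_path="demo/positives.txt",
                  unlabeled_path="demo/unlabeled.txt",
                  seed=11)
result = run_pipeline(cfg)
print(result.predictions.sort_values("probability", ascending=False).head())
```

All stages are also importable individually (`pudi.ontology`,
`pudi.features`, `pudi.selection`, `pudi.partition`, `pudi.classifier`,
`pudi.evaluate`, `pudi.simulate`, `pudi.experiments`).  See
`docs/methods.md` for the model details, parameter meanings and the
synthetic-study design.

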