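# afmscreen

Scoring and screening of AlphaFold-Multimer (AF-M) pairwise structure
predictions.

AF-M readily produces plausible-looking interfaces for protein pairs that do
not interact, so in large *in silico* screens — a bait folded against
hundreds or thousands of candidate preys — its native confidence metrics
(ipTM, pDockQ, PAE-derived scores) leave true partners buried among false
positives. `afmscreen` implements a complete screening/scoring stack for
people running such screens: structural biologists and computational
biologists who already have folded two-chain predictions (ColabFold-style
PDB + JSON score files) and need to rank them.

## What it computes

**Contact filter and C+ call.** A cross-chain residue pair (x, y) is a
valid interfacial contact iff

    min heavy-atom distance < 5 Å,   pLDDT(x) > 50 and pLDDT(y) > 50,
    no heavy-atom pair < 1 Å,        PAE(x,y) < 15 Å and PAE(y,x) < 15 Å,

and a prediction is *contact-positive* (C+) when ≥ 5 valid contacts occur in
one model. Only C+ pairs are analyzed further.

**Consensus and canonical metrics.** Cross-model agreement

    avg_models = mean over the union U of observed contacts of m(c)/M,

with m(c) the number of the M models reproducing contact c (> 0.5 means the
average contact is supported by more than half the models); IF-PAE (mean
directional PAE over < 5 Å interface pairs); and the published pDockQ /
pDockQ2 sigmoids, with ipTM passed through from the predictor.

**Classifier.** A random forest over identity-blind pair features —
structural (avg_models, contact-count statistics, IF-PAE, interface pLDDT,
salt bridges, hydrogen bonds, pDockQ/pDockQ2/ipTM) plus biological
annotations (BioGRID evidence counts, DEPMAP co-dependency correlation,
mutual coexpression, DeepLoc co-localization, protein-embedding similarity,
CRISPR hit-profile Jaccard, interface missense constraint) — trained with a
75/25 per-refset split, an exhaustive 72-combination hyperparameter grid
scored by 3-fold cross-validated AUC, and iterative pruning of features with
GINI importance < 0.01. Output is a 0–1 score.

**Evaluation.** ROC/AUC; recall–FDR curves on seeded test sets subsampled to
N:P ratios from 1:1 to 128:1 (FDR = FP/(TP+FP) above a threshold); recall at
a 5% FDR cap; F1-threshold scans; ranking experiments (one target among
1,000 decoys, competition rank and Z-score) with Wilcoxon signed-rank
comparisons between metrics.

**Curation.** Reference-set operators: crosslink agreement (Cα–Cα ≤ 36 Å in
≥ 1 model), over-representation trimming (≤ 28 appearances per protein, ≤ 1%
per flagged class), frequency-matched randomized negatives, decoy extraction
from resolved complexes (< 10 close residue pairs = non-contacting),
homology reduction over cluster maps, and DockQ filtering (> 0.23).

**Synthetic fixtures.** Generators for prediction bundles with planted
contacts/clashes/pLDDT/PAE, labeled feature datasets with controlled class
separation, and annotation stores with planted pair signal — every input the
pipeline reads, with ground-truth manifests.

## Worked example

```python
import tempfile
from afmscreen import load_prediction_set, find_valid_contacts, compute_pair_metrics
from afmscreen.synthetic_fixtures import PairFixtureSpec, PlantedContact, make_prediction_set

# a synthetic prediction bundle: 8 contacts in all models, 1 in models 1-2 only
spec = PairFixtureSpec(
    len_a=40, len_b=35,
    contacts=[PlantedContact(i, i, 3.5) for i in range(1, 9)]
    + [PlantedContact(12, 12, 4.2, models=(1, 2))],
)
with tempfile.TemporaryDirectory() as d:
    make_prediction_set(spec, d)
    pset = load_prediction_set(d, pair_id=("EXAMPLE_A", "EXAMPLE_B"))
    contact_sets = [find_valid_contacts(m) for m in pset.models]
    metrics = compute_pair_metrics(pset, contact_sets)
```

This prints:

```
pair:            EXAMPLE_A--EXAMPLE_B
models:          [1, 2, 4]
valid contacts:  [9, 9, 8]
contact-positive (C+): True
avg_models:      0.963
IF-PAE (best):   8.00 A
ipTM (best):     0.80
pDockQ (best):   0.040
pDockQ2 (best):  0.131
```

Nine planted residue pairs pass the four-tier filter in models 1–2 and eight
in model 4, so the pair is C+; avg_models = (8·1 + 1·2/3)/9 ≈ 0.963 because
one contact is reproduced by only two of the three models. The low pDockQ
reflects the deliberately small synthetic interface; the classifier, not any
single metric, is the intended ranking signal.

Training and scoring (`InteractionClassifier.from_dataframe(df).fit()`
returning a results object with `summary()`, `predict()`, `save()`) and the
evaluation operators are shown in `docs/methods.md`. A `click` CLI wraps the
same library:

```
afmscreen contacts SCREEN_DIR --out out/        # contact tables + C+ flags
afmscreen featurize SCREEN_DIR --store store.json --out features.tsv
afmscreen train features.tsv --out-model model.joblib
afmscreen score model.joblib features.tsv --out scores.tsv
afmscreen eval scores.tsv --out eval.json       # AUC, recall@5%FDR, F1 scan
afmscreen rank scores.tsv --target PAIR_ID --out rank.tsv
```

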