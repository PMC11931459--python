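# Methods

`afmscreen` scores two-chain AlphaFold-Multimer (AF-M) predictions to
separate biologically meaningful protein–protein interactions (PPIs) from
the abundant spurious interfaces the predictor produces in large screens.
This note records the models and procedures the package implements, the
parameters that matter, what the synthetic generators emulate, and the
numerical choices made where the design was genuinely open.

## Contact model

AF-M emits, per model, coordinates, per-residue pLDDT (0–100 local
confidence), a directional PAE matrix (0–30 Å, entry (x, y) is the expected
error of residue y's position when aligned on x), and ipTM/pTM. A
cross-chain residue pair is a **valid interfacial contact** iff all four
conditions hold, each with a strict inequality:

1. minimum heavy-atom distance < `d_max` (default 5 Å),
2. both residues' pLDDT > `plddt_min` (default 50),
3. no heavy-atom pair < `d_clash` (default 1 Å) — a clash filter,
4. both directional PAE entries < `pae_max` (default 15 Å).

A prediction is **contact-positive (C+)** when at least `min_pairs`
(default 5) valid contacts occur in a single model. The C+ call is
per-model rather than pooled across models: pooling is not obviously
well-defined when models disagree, and the per-model reading is consistent
with cross-model agreement scores below 1 on C+ pairs. Only C+ pairs are
featurized and scored; pairs where the predictor finds no interface are out
of reach of the method by construction.

Contact detection uses a k-d tree over heavy atoms (`scipy.spatial.cKDTree`)
with squared-distance comparisons; its results are bit-identical to a
brute-force scan over all residue/atom pairs, which the test suite asserts
on randomized structures.

Interface chemistry is counted between valid-contact residues only:

* **salt bridge** — an acidic side-chain oxygen (Asp OD1/OD2, Glu OE1/OE2)
  within 4.0 Å of a basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2;
  His ND1/NE2), at most one per residue pair;
* **hydrogen bond** — any N/O–N/O atom pair within 3.5 Å not already
  attributed to a salt bridge, counted per atom pair, no angle term.

These are deliberately simple geometric definitions (both cutoffs
configurable); they feed a random forest, which only needs a monotone
signal, not a physically exact count.

## Consensus and canonical metrics

**avg_models** quantifies agreement among the independently trained AF-M
models: with U the union of valid contacts over all M models and m(c) the
number of models supporting contact c,

    avg_models = mean_{c in U} m(c) / M     (0 when U is empty).

A value above 0.5 means the average contact is supported by more than half
the models; 1.0 means all models agree on every contact. Contacts are
matched by exact residue-pair identity (no window tolerance).

**IF-PAE** is the mean over both directional PAE entries of all interface
residue pairs (< 5 Å heavy-atom distance, no pLDDT/PAE filter), absent when
there is no interface.

**pDockQ** (Bryant et al. 2022) and **pDockQ2** (Zhu et al. 2023) are the
published sigmoid estimators; their constants are stored verbatim in
`PDOCKQ_PARAMS` / `PDOCKQ2_PARAMS`. Interface contacts for these metrics
follow the original definitions: Cβ–Cβ pairs (Cα for glycine) below 8 Å
(pDockQ) and 10 Å (pDockQ2, with PAE weight 1/(1+(PAE/10)²) averaged over
both directions). With no interface each returns its sigmoid floor. ipTM is
never recomputed — it is the predictor's own output, passed through.

Per-pair aggregation over models takes the maximum for goodness metrics
(ipTM, pDockQ, pDockQ2) and the minimum for IF-PAE.

## Pair features

Feature vectors combine the two proteins' properties symmetrically —
correlation, inner product, max, Jaccard, cosine/Euclidean, sorted per-chain
counts — so the classifier cannot learn protein identities. Structural
features: avg_models, per-model contact-count min/mean/max, best IF-PAE,
best ipTM/pDockQ/pDockQ2, mean interface pLDDT, salt-bridge and
hydrogen-bond counts, and the smaller/larger per-chain interface residue
counts. Biological features are consumed from prepared per-protein tables
(never computed from raw sources here): BioGRID evidence counts, Pearson
correlation of DEPMAP gene-effect vectors (length 1,095, pairwise-complete),
mutual top-500 coexpression score (max over both directions), inner product
of DeepLoc 10-dim localization probabilities, cosine and Euclidean
similarity of 1,024-dim protein language-model embeddings, Jaccard index of
1,243-dim binary CRISPR-screen hit profiles, and min/max of the two chains'
mean interface missense-constraint scores.

Missing annotations stay informative: after min-max scaling each feature to
[0, 1] over observed values, missing entries are imputed with a −1 sentinel
(outside the scaled range, so a tree can isolate absence) and flagged with a
companion `*_missing` indicator. Present values are never overwritten. The
feature schema is versioned and data-driven so a curated list can replace
the default reconstruction.

## Classifier training regimen

`RandomForestClassifier` (scikit-learn) with every hyperparameter at the
library default except the tuned grid:

    n_estimators ∈ {150, 200, 250}, max_depth ∈ {3, 5, 7},
    min_samples_split ∈ {2, 5}, bootstrap ∈ {True, False},
    criterion ∈ {gini, log_loss}          — 72 combinations.

Data are split 75% / 25% into training and test within each reference set
(seeded). The grid is searched exhaustively with 3-fold stratified
cross-validated ROC AUC as the objective; the winner is refit on all
training rows. After each tuning round, features with GINI importance below
0.01 are dropped and the entire search re-runs on the reduced set, until a
round drops nothing. Ties in the grid go to smaller `n_estimators`, then
shallower `max_depth` (prefer the simpler forest). Scores are raw
fraction-of-trees probabilities in [0, 1]; no calibration, no class
weighting — imbalance is handled by dataset composition.

Numerical implementation of the search: forests differing only in
`n_estimators` share their earlier trees (one `warm_start` forest grown to
250 trees is scored at 150/200/250 — the first k trees of a forest are a
valid k-tree forest), newly grown trees are scored incrementally, and fold
AUC uses a midrank Mann–Whitney computation identical to
`sklearn.metrics.roc_auc_score`. These choices change runtime, not what is
evaluated; fixed seed ⇒ identical split, winning hyperparameters, and
scores.

## Evaluation framework

All curves are exact step functions over the sorted observed scores plus
endpoints. At threshold t (capture = score ≥ t): recall = TP/P and
FDR = FP/(TP+FP), with FDR defined as 0 when nothing is captured. Recall at
an FDR cap is the maximum recall over thresholds meeting the cap (0 if
none). F1 = TP/(TP + 0.5·(FP + FN)); the scan returns the lowest
argmax threshold.

Class-imbalance test sets are built by seeded subsampling at a given N:P
ratio, 10 replicates: with enough negatives, all positives are kept and
N = P·ratio negatives drawn; otherwise all negatives are kept and
P = max(1, round(N/ratio)) positives drawn. (At a 128:1 ratio with 2,912
negatives this formula yields 23 positives; reports of 24 for the same
configuration exist, and the exact rounding convention used there is not
recoverable — the formula above is this package's normative rule.) Recall
at a fixed threshold is invariant to the ratio in expectation while FDR is
non-decreasing in it; the test suite asserts both over seeds.

Ranking experiments embed one target pair among decoy pairs scored by the
same metric: rank = 1 + #{strictly better} + floor(#{tied}/2) (competition
ranking at the floored midrank; pairs with no C+ prediction score 0 and rank
last), and z = (target − mean(decoys)) / sd(decoys) with the sample standard
deviation (ddof = 1), undefined when all decoys tie. Paired rank lists are
compared with a two-sided Wilcoxon signed-rank test (`scipy.stats.wilcoxon`);
all-zero differences are reported as p = 1 with a degeneracy flag.

## Reference-set curation

* **Crosslink agreement**: a C+ pair is kept when at least one reported
  crosslink is satisfied in at least one model — Cα–Cα distance of the
  linked residues ≤ 36 Å, the upper bound of the crosslinker lengths. Cα is
  the conventional anchor for linkers of this class; links referencing
  residues outside the modeled chains are skipped with a warning.
* **Over-representation trimming**: after residue-level then pair-level
  deduplication, the most common protein has randomly chosen pairs removed
  until it appears ≤ 28 times, iterated to a fixed point; then pairs from a
  flagged protein class (e.g. histones) are randomly removed until they are
  ≤ 1% of the set. Idempotent and seeded.
* **Frequency-matched randoms**: the real set's proteins are re-paired at
  their observed frequencies, excluding self-pairs and any real pair,
  reshuffling until > 80% of proteins occur at exactly their real frequency
  (best effort flagged if the iteration cap is hit). The overlap statistic
  counts exact frequency matches.
* **Decoy extraction**: in a resolved complex of ≥ 3 chains, two chains are
  in contact when ≥ 10 residue pairs have heavy atoms closer than 5 Å; every
  chain pair below that is a decoy candidate.
* **Homology reduction**: pairs grouped by unordered cluster-id pair, one
  random survivor per group. Cluster maps come from an external
  sequence-clustering backend (overlap/identity parameters belong to it); a
  greedy k-mer-Jaccard fallback is included for small test fixtures only.
  Negative sets are additionally purged of pairs whose cluster pair matches
  any interacting pair in the PDB.
* **DockQ filter**: externally computed per-pair maxima over models, kept
  when strictly > 0.23 (the CAPRI "acceptable" cutoff); missing scores drop
  the pair with a warning.

## Synthetic study conditions

The generators produce every input the pipeline reads, with planted ground
truth, and they define the conditions under which the package's claims are
tested:

* **Prediction bundles** — simplified residues (planar backbone N/CA/C/O
  plus a charged-tip atom for D/E/K/R, all template atoms in one plane) so
  that translating a residue by (0, d, 0) plants an exact minimum heavy-atom
  distance d; chains are laid out 40 Å apart on lines 300 Å apart, so the
  only proximity is the planted one. PAE matrices are block-constant
  (background 25 Å, interface 8 Å) with per-pair directional overrides;
  pLDDT defaults to 90 with per-residue overrides. Files are written in the
  exact dialects the loader reads (PDB via gemmi; ColabFold-style JSON with
  pae/plddt/iptm/ptm), with a JSON manifest of expected valid contacts per
  model. These fixtures exercise every geometric and confidence rule but are
  not physically realistic proteins; passing tests demonstrate the rules are
  implemented exactly, not that the thresholds are optimal on real
  structures.
* **Labeled feature datasets** — positives draw informative features from
  N(effect, 1), negatives from N(0, 1), noise features N(0, 1) in both
  classes, optional uniform missingness. The default recovery conditions are
  5 informative + 5 noise features, a 3-sd shift, and n = 1,000 (500/500) —
  a planted-signal setting in which pruning must keep all informative and
  discard the noise features. Real screening features are correlated and
  far weaker; these conditions test the regimen's mechanics, not real-data
  performance.
* **Annotation stores** — full-length vectors (1,095 / 1,243 / 10 / 1,024)
  with planted pairs given correlated gene-effect vectors, near-identical
  hit sets, shared localization, similar embeddings, mutual coexpression
  entries and nonzero BioGRID counts; all other proteins independent.

## Degenerate inputs and edge conventions

Missing ipTM/pTM are reported absent, never 0. A structure without exactly
two non-empty chains, an insertion-coded residue, or a PAE matrix whose
dimension disagrees with the residue count is rejected with a specific
error. AUC is undefined on single-class data (error). Zero-variance vectors
make correlations missing rather than NaN; zero embedding norms make cosine
missing. A refset with fewer than 4 rows goes entirely to training with a
warning. Pruning that removes every feature raises rather than returning a
constant model.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the contact-filter oracle on
100 randomized structures (≤ 30 residues/chain), the agreement enumeration
on all support-count patterns for 2/3/5 models and ≤ 4 contacts, the
recovery regimen on n = 1,000 datasets over 10 seeds, the imbalance
invariants on 200 positives / 3,000 negatives across ratios 1–128, and
ranking experiments with 1,000 decoys. These sizes were chosen as the
smallest at which the planted effects dominate sampling noise.

## Known limitations

* The exact curated feature lists of the original screening protocol are
  not public; the default schema is a faithful reconstruction of every
  named feature, and the pruning regimen is feature-list-agnostic.
* The classifier's reported performance here is on planted-signal synthetic
  data; absolute recall/FDR numbers on real screens depend on the curated
  corpora and folded predictions, which this package consumes but does not
  generate.
* Only binary (two-chain) predictions are scored; larger complexes are
  rejected at load time.
* Salt-bridge/H-bond geometry has no angular terms; counts are upper bounds
  on chemically strict definitions.
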