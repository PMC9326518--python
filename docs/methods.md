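# Methods

## Problem and pipeline

`disimir` predicts which miRNAs in a disease-context expression dataset
are *disease-causal* (their perturbation drives disease phenotypes)
rather than merely *disease-associated* (e.g. differentially expressed).
The method assumes that causal miRNAs tend to be (i) influential
regulators in the miRNA co-regulation network of the diseased tissue and
(ii) evolutionarily conserved. It proceeds in five stages:

1. **Consensus network inference.** Five regulatory-network inference
   algorithms are run on the miRNA × sample expression matrix: CLR,
   ARACNE, MRNET and MRNETB on a shared mutual-information matrix, and
   GENIE3 as tree-ensemble regression. Each network is min–max scaled to
   [0, 1], the five are averaged entrywise with equal weights, and edges
   with mean confidence below 0.7 are pruned (the comparison is
   inclusive: an edge exactly at 0.7 is kept).
2. **Influence scoring.** A node's influence is
   `C_m = Σ_{m'} n_{m'} ^ (1/d)` over all nodes `m'` reachable from `m`
   (including `m` itself), where `n_{m'}` is the out-degree of `m'` and
   `d` is the directed hop distance from `m` to `m'` plus one. Only the
   pruned topology enters; edge weights are used as zero/nonzero.
   *Disease-specific* influence is the same score on the subnetwork
   induced by the disease-associated miRNAs (taken from an HMDD-3.2
   style causality table); non-associated miRNAs get 0.
3. **Conservation.** Per miRNA: family size |F| (miRBase-style families,
   members counted within and across species) plus the sequence
   similarity `S_m = Σ_{m'∈F} (len(m) − lev(m, m'))/len(m)` over mature
   sequences, self term included, with `lev` the unit-cost Levenshtein
   distance. Missing families or sequences contribute 0, never an error.
4. **Feature matrix.** One row per consensus-network node (isolated
   nodes included) with columns `disease_influence, network_influence,
   conservation, n_targets` plus the curated causality label and the
   association flag. No feature scaling: boosted stumps are invariant
   to monotone rescaling.
5. **Classification.** AdaBoost over depth-1 decision trees, 1500
   rounds, learning rate 1.0. Each of `n_splits` (default 100) random
   splits places one third of the causal miRNAs — and the same fraction
   of the non-causal ones — in the test set. A miRNA's reported
   probability is the mean of its *out-of-fold* predictions, so the
   headline AUC never scores a row with a model that trained on its
   label. The decision threshold minimizes FP + FN among cutoffs with
   at least `min_fp` (default 10) false positives, falling back to the
   unconstrained minimizer when infeasible; the confusion matrix, an
   upper-tail hypergeometric enrichment p-value, a 95% percentile CI
   of per-split AUCs, the associated-only AUC (causal vs merely
   associated) and mean feature importances complete the report.

## Numerical and algorithmic choices

- **MI estimation**: per-miRNA equal-frequency discretization into
  `floor(sqrt(n_samples))` bins (minimum 2, ties broken by stable rank),
  plug-in MI in nats with the Miller–Madow bias correction
  `(K_x + K_y − K_xy − 1)/(2n)`, clipped at zero. This mirrors the most
  common configuration of discrete MI network inference; both bin count
  and estimator live behind `ConsensusConfig` and are configurable.
- **CLR**: per-pair z-scores against row/column backgrounds (off-diagonal
  mean and population sd, negative z clipped), combined as
  `sqrt(z_i² + z_j²)`. A zero-variance background row yields z = 0 with a
  warning.
- **ARACNE**: DPI pruning with tolerance `eps` (default 0): the strictly
  weakest edge of each fully connected MI triangle is removed; ties
  remove nothing. Comparisons use the original MI values, so removal
  order cannot matter.
- **MRNET**: per-target forward-selection MRMR; a variable's weight is
  its score (relevance − mean redundancy with the already-selected set)
  at the moment of selection, floored at zero. **MRNETB** optimizes the
  same objective by backward elimination (drop the worst member while
  its score is negative) followed by bounded sequential replacement
  (swap an excluded variable in whenever it raises the subset's minimum
  score; at most 20 swap passes). Both are symmetrized by the entrywise
  max.
- **GENIE3**: one random-forest regression per target (default 100
  trees); the edge weight predictor→target is the predictor's total
  variance-reduction importance, normalized per target to sum one.
  The feature-sampling parameter K defaults to *all* predictors rather
  than sqrt: with co-regulated targets the candidate-subsampling variant
  spreads importance over redundant siblings of the true regulator,
  which erases the directional signal GENIE3 alone contributes to the
  consensus (the four MI methods are symmetric). `sqrt` remains
  available in `ConsensusConfig`. Trees stop splitting at 5 samples per
  leaf: near-singleton splits add importance noise, not signal, and
  dominate runtime; on the planted-hub design the scaled edge
  statistics are unchanged to two decimals relative to fully grown
  trees. An optional `genie3_sample_cap` randomly subsamples columns
  for very large cohorts.
- **Direction conventions**: weight [i, j] is the confidence that i
  influences j. The MI methods write each confidence to both [i, j] and
  [j, i]; only GENIE3 distinguishes the two.
- **Consensus**: plain unweighted mean of the five scaled matrices
  (weighted averaging was considered and rejected as adding complexity
  for negligible gain); scale-then-average order; inclusive 0.7 cutoff.
- **Influence**: BFS distances on the unweighted topology; `0^(1/d)` is
  defined as 0, so leaves score exactly 0 and `I(m) = 0 ⇔ out-degree 0`.
  The self term enters at d = 1 (a node's own out-degree at full
  strength).
- **Levenshtein**: computed with edlib (global alignment, unit costs);
  empty strings are handled explicitly (distance = length of the other
  string). Similarity terms may be negative when a family member is more
  than `len(m)` edits away; they are kept as computed.
- **Splits and determinism**: split `s` derives from `seed + s`; every
  random choice in the package flows from explicit seeds, so a full
  pipeline run is bit-reproducible given its config. A miRNA that never
  lands in a test set (probability (2/3)^n_splits) triggers one extra
  forced split.
- **Boosting variant**: discrete SAMME boosting on stumps (the variant
  implemented by current scikit-learn). Learning rate 1.0.
- **Minimum causal count**: training refuses feature tables with fewer
  than 20 causal miRNAs by default (configurable): a handful of
  positives cannot support a meaningful repeated-split evaluation, a
  regime in which this class of method is known to fail.

## Synthetic study design

The generator plants `n_hubs` regulator miRNAs, each driving
`targets_per_hub` target miRNAs as `target = slope · hub + ε` with
`slope ~ U(0.9, 1.1)`, `ε ~ N(0, noise_sd²)` (default 0.3) and hub rows
drawn `N(0, hub_amplitude²)` (default 0.85; the pure noise rows have
unit scale); everything else is i.i.d. noise, and all rows are shifted
to positive, expression-like units. Defaults: 300 miRNAs × 60 samples,
10 hubs, 8 targets per hub.

Causality labels follow hub membership (probability
`causal_link_strength`, default 0.8, vs a 0.05 baseline); the associated
set contains all causal miRNAs, each hub target with probability 0.6 and
a 20% random background. Conservation is linked to causality: causal
miRNAs receive a sequence family of size 3 + Poisson(5) at per-base
divergence 0.1, while non-causal miRNAs receive a small family
(1 + Poisson(1)) with probability 0.15. Predicted-target counts are 20 ×
planted out-degree + Poisson(15).

The cluster geometry was chosen so that the planted dependence survives
every one of the five inference algorithms. Two failure modes constrain
it: with many targets per hub, or with hub amplitude at or above the
noise-row scale, sibling targets become nearly as mutually dependent as
the hub–target pairs themselves, so ARACNE's DPI starts deleting true
edges and GENIE3's importance spreads across the redundant siblings;
both depress consensus edge survival. 8 targets per hub at amplitude
0.85 is a regime where hub→target edges dominate the consensus while
target→target edges mostly fall below the cutoff.

What the generator does **not** emulate: real miRNA sequence biology
(sequences are uniform random RNA), platform- or batch-specific noise,
count-based measurement error, indirect regulation chains deeper than
one level, and the heavily skewed family-size and target-count
distributions of miRBase/TargetScan. Tests passing on these fixtures
demonstrate that the pipeline's stages carry a planted signal end to
end and that its arithmetic is correct — not that the biological claims
hold on any real cohort.

## Problem sizes used in the shipped experiments

The shipped end-to-end experiments run the full pipeline on the default
300 × 60 fixture with 100-tree GENIE3 and 20 classifier splits over 5
generator seeds, and the determinism check on a 50-miRNA fixture; the
unit and oracle suites use matrices of at most a dozen nodes. These
sizes exercise every code path at desk scale; the pipeline itself has
no size-specific logic, and a real analysis would simply raise the
split count to 100 (the default) and use the full platform matrix.

## Known limitations

- The consensus at the 0.7 cutoff is conservative: at 60 samples the
  discrete MI estimates are noisy enough that roughly half of genuinely
  planted edges fall below the threshold. Hub recovery through the
  influence ranking is accordingly good but not perfect (see the
  recovery experiment in the test suite).
- Identifier reconciliation across sources is case-folding plus exact
  match only — no -3p/-5p stripping, no alias tables — so miRNAs named
  inconsistently across platforms are (auditable but silently) treated
  as distinct.
- The per-split AUC confidence interval is a percentile interval over
  split AUCs, which reflects split-to-split variability, not sampling
  variability of the underlying cohort.
- Literature validation consumes a manually curated table; the package
  deliberately performs no PubMed querying, as live query results drift
  over time and are not reproducible.
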