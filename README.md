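# chromdyn

Integrative analysis of chromatin-accessibility and transcriptome
dynamics across a differentiation time course. The package targets the
kind of study where ATAC-seq, TF ChIP, bulk RNA-seq after factor
depletion, and scRNA-seq are collected over a few conditions (here a
naive-ESC → day-1 → day-2 epiblast-like transition) and the question is
which transcription factors drive the transition and which genes they
directly control.

It is aimed at computational biologists who have peak calls, count
tables and motif occurrence lists in hand and want the downstream
statistics as tested, seeded, reusable functions rather than a chain of
one-off scripts.

## What it computes

* **Peak atlas** — replicate-concordant peaks (reciprocal overlap ≥ 50%
  of both lengths), a union atlas by single-linkage summit merging
  (distance < 100 bp), promoter/intragenic/intergenic partitioning, and
  signed nearest-TSS gene assignment.
* **Temporal dynamics** — CPM normalization; differential accessibility
  by a conditional negative-binomial exact test (shared robust
  method-of-moments dispersion) with CPM ≥ 4, fold and BH-q filters;
  per-feature z-scored profiles; fuzzy c-means (fuzzifier m, default 2)
  into fine clusters merged to broad temporal patterns by centroid
  correlation; binomial motif enrichment per cluster, z-normalized per
  motif.
* **Bivariate footprinting** — strand-aware aggregation of cut-site
  profiles around motif occurrences; per condition the flanking
  accessibility FA (mean flank cuts/bp) and footprint depth
  FPD = log2((flank + ε)/(interior + ε)); motifs classified on
  (ΔFA, ΔFPD) by a Tukey-halfspace-depth bagplot: bag = hull of the
  ⌈n/2⌉ deepest points, fence = bag ×3 about the depth median, points
  beyond the fence are the significant movers.
* **Single cells** — MAD-fence QC (library size both tails, detected
  genes low tail), mean-count gene filter, unit-centered size factors,
  mean-variance-trend HVG selection, binary co-expression scores
  (pooled z), JSI = 1 − JD² and Matthews-correlation co-expression
  matrices with reference-condition ordering, AUCell-style regulon AUC
  with Otsu activity thresholding, PC1 rank pseudotime, and pseudobulk
  aggregation.
* **Integration** — distance-binned hypergeometric concordance between
  accessibility clusters and expression clusters (exact tail over the
  gene universe, 8 bins spanning ±10–250 kb), direct-target calling
  (bound ∩ knockdown-responsive, down-in-knockdown = activated), and
  stage-marker overlap proportions.
* **Synthetic study** — seeded generators for every input (peak counts
  with four planted temporal archetypes, cut profiles with planted
  footprints, paired knockdown bulk with planted direct targets,
  single-cell NB counts with planted QC outliers, regulons and a 1-D
  trajectory), so the whole pipeline is testable end to end without any
  download.

## Worked example

Run the full synthetic study and every stage from the shell:

```
chromdyn simulate --seed 17 --out demo/
```

or drive the pieces from Python. Calling direct targets from the planted
knockdown experiment:

```python
from chromdyn.synthetic import SimulationConfig, simulate_knockdown
from chromdyn.dynamics import differential_expression
from chromdyn.integration import call_direct_targets

kd = simulate_knockdown(SimulationConfig(seed=17))
de = differential_expression(kd.counts, kd.pairs)   # fold > 1.2, p < 0.05, rescue rule
bound = list(kd.truth.index[kd.truth["bound"]])
targets, summary = call_direct_targets(bound, de)
print(summary)
print(targets.head(3))
```

prints

```
DirectTargetSummary(n_direct=78, n_activated=39, n_repressed=39, percent_activated=50)
        de_direction      class
gene_id
g0007     down_in_kd  activated
g0018     down_in_kd  activated
g0030     down_in_kd  activated
```

78 genes are both bound by the factor and responsive to its knockdown —
exactly the planted direct-target set (the generator plants 39 activated
and 39 repressed targets plus 50 bound-but-unresponsive genes that the
intersection correctly rejects). A gene *down* in the knockdown is
classified *activated*: depleting a factor lowers the genes it
activates. At genome-wide study scale, the same summary arithmetic turns
207 direct targets with 135 activated into 65% activated.

Recovering the planted temporal archetypes from the accessibility
counts:

```python
from chromdyn.synthetic import SimulationConfig, simulate_accessibility
from chromdyn.dynamics import cpm_normalize, zscore_profiles, fuzzy_cmeans, merge_clusters
from sklearn.metrics import adjusted_rand_score

_, counts, truth, _ = simulate_accessibility(SimulationConfig(seed=17))
z = zscore_profiles(cpm_normalize(counts))
clusters = merge_clusters(fuzzy_cmeans(z, c=12, seed=17), target_K=4)
print(round(adjusted_rand_score(truth, clusters.merged_label), 4))
```

prints `0.9958`: twelve fuzzy clusters merged to four broad patterns
reassemble the planted up-up / down-down / transient-up / transient-down
archetypes almost perfectly.

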