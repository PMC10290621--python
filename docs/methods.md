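# Methods notes

## Scope and data model

`canprio` prioritizes mouse ECG-phenotype genes into neuropsychiatric
candidates by how they are expressed across central-autonomic-network (CAN)
brain regions. All stages operate on plain-text inputs: an expression-energy
TSV (genes × regions, optionally with replicate `experiment_id` rows), a CAN
region CSV with `feedforward`/`feedback` role tags, GMT gene-set libraries,
and a per-gene phenotype TSV. The canonical in-memory containers are pandas
DataFrames wrapped in thin dataclasses that enforce the format invariants
(unique identifiers, non-negative finite energies, closed role and phenotype
vocabularies).

## Ingestion

A gene may have several ISH experiments. The collapse rule keeps the
experiment with the **largest total energy** across regions, ties broken by
the lexicographically smallest experiment id. This is deterministic and
favors high-signal experiments; nothing in the upstream data dictates a
particular rule, so the choice is recorded here rather than hidden. Missing
whitelist genes are reported (`retained + missing = requested`), never
imputed; a row that cannot be standardized later (zero variance across the
CAN regions) is dropped with a log entry because both the clustering and the
SVM stages require complete, non-degenerate rows. Regions are identified by
id; acronyms are display-only.

## Biclustering

Rows are z-scored with the sample (n−1) standard deviation. Linkage is Ward's
minimum-variance criterion on Euclidean distances between z-scored profiles,
in the "ward.D2" height convention (equivalently: classical Ward on the raw
observations, as implemented by `scipy.cluster.hierarchy.linkage(method="ward")`);
two singletons merge at their Euclidean distance, and in general a merge sits
at `sqrt(2·ΔSS)`. The test suite checks this against a brute-force
agglomerator that exhaustively picks the merge minimizing the
within-cluster sum-of-squares increase (all fixtures with ≤ 8 items, 1e-9).

Cluster counts are selected per axis by the mean silhouette width of the
hierarchical cuts for k = 2..10 (Euclidean distances, ties to the smallest
k). Cutting removes the k−1 highest merges (`scipy.cluster.hierarchy.cut_tree`)
and labels run 1..k in order of first appearance along the dendrogram's leaf
ordering, which makes label assignment reproducible. k_max is clamped to
n−1 because the silhouette is undefined for singleton-only partitions.

Gene-cluster naming is a deterministic post-hoc step: a cluster whose mean
z-score over feedforward-role regions is at least its mean over
feedback-role regions is named FF-ANS, otherwise FB-ANS, with numeric
suffixes if several clusters share a name.

## mSVM-RFE

Observations are regions labelled by region cluster; features are genes.
Per repeat, each class's regions are shuffled and dealt round-robin into
`n_folds` folds with a pointer that runs continuously across classes, so both
per-class occupancy and total fold sizes differ by at most one (47 regions /
4 folds gives sizes 12, 12, 12, 11). Every (n_folds − 1)-subset of folds is a
training set; defaults (4 folds × 50 repeats) give 200 runs. A class with a
single member is rejected because a held-out fold could then lose the class
entirely.

The ranking criterion is the standard linear SVM-RFE statistic: fit all
one-vs-one soft-margin linear SVMs (C = 0.01) and score each feature by the
sum of squared weights across the pairwise classifiers. Each iteration
removes `min(max(1, ceil(0.10 · n_remaining)), n_remaining − 15)` features —
the clamp makes every run land exactly on the 15-feature stop condition (418
features terminate in 30 iterations). Score ties are broken by removing the
lexicographically larger gene id, which makes runs fully deterministic.
Features are not re-scaled per training fold: they enter already row-z-scored,
so an extra per-fold standardization would only perturb the scale slightly
while breaking the one-to-one correspondence with the clustered matrix.

Aggregation: selection frequency (number of runs whose final 15 contain the
gene) descending, then mean elimination step descending, then gene id. For
the mean step, a survivor counts as `(total iterations + 1)` — i.e. better
than any eliminated feature — while the per-run record keeps the
conventional 0 for survivors. The conservation law
`Σ_genes frequency = n_runs × stop_n` holds for every configuration and is
asserted in the tests.

## Enrichment

For each term: p = P(X ≥ k), X ~ Hypergeom(N, K, n), where the universe N
defaults to the library's gene union intersected with the clustered gene set
(a web service's implicit background is not reproducible, so the universe is
explicit and configurable). Only the over-representation tail is computed;
rank-deviation composite scores used by some web services require their
precomputed background ranks and are out of scope. Adjustment is
Benjamini–Hochberg across the library's terms. Gene symbols are case-folded
to upper case; no ortholog mapping. The implementation
(`scipy.stats.hypergeom.sf`) is verified against an exact Fraction-arithmetic
tail enumeration (≤ 1e-12 relative, N ≤ 200) and against the closed-form
full-overlap case 1/C(20,5) = 1/15504.

## Phenotype tables

ECG phenotype cells follow the curated-table dialect: parameters accumulate
until an arrow, which assigns its direction to all of them ("HR, RR ↑" means
both increased); "(F)"/"(M)" after an arrow restricts those tokens to one
sex; "No" means no phenotype. The parameter vocabulary is closed (HR, HRV,
rMSSD, RR, PQ, PR, ST, QTc, QRS, QTc dispersion, HR_TTE, LVIDd, LVIDs) and
unknown names are parse errors, so transcription mistakes surface loudly.
Filtering rules that matter for the candidate counts:

* sex-specific tokens count under the default `any` matching (a male-only HR
  increase satisfies an HR-up criterion);
* the HRV criterion also matches rMSSD tokens, because rMSSD is a vagally
  mediated HRV statistic (this widens nothing in the packaged table: both
  HRV-decreased genes also carry a plain HRV token);
* NPD status is the literal string "Limited or no NPD annotations" — the
  classification is data, not inference. Of the 11 HR-increased genes in the
  packaged table, 7 carry that literal annotation; the count is computed,
  not asserted, because the annotation column and published prose summaries
  of it are not perfectly consistent.

The 32-gene candidate table is a versioned data file
(`canprio/data/ff_ans_candidates.tsv`), so corrections are data changes, not
code changes. One transcription decision is worth noting: the *Fbxl16* ECG
cell in the source material contained a typographically duplicated token
(the echocardiography heart rate marked both up and down); it is transcribed
here as `HR ↑, HR_TTE ↓`, the only reading consistent with the published
total of eleven HR-increased candidates.

## Synthetic data

The generator emulates ISH expression energies as log-normal:
`E = exp(base + pattern + N(0, noise_sd))`, hence strictly positive and
right-skewed. Planted structure has three layers:

* **region classes** (contiguous, sizes differing by ≤ 1) — the clusters the
  region axis should recover;
* **gene clusters** — each cluster is "on" (+`signal` in log-mean) across a
  contiguous "home" subset of the region classes, emulating
  feedforward-type vs feedback-type expression programs; with one gene
  cluster the home set is all classes and non-informative genes are exactly
  flat;
* **informative genes** — a subset carrying an extra bump
  (+`informative_signal`, default `signal`) in exactly one region class
  inside their cluster's home set; these are the class-discriminative
  features the SVM stage should recover.

One integer seed fans out to named substreams (matrix, phenotypes, GMT), so
each artifact regenerates independently and byte-identically. Companion
artifacts: a region list tagging the first cluster's home classes as
feedforward, a Bernoulli HR-up/HRV-down phenotype table, and a random GMT
library with one planted term equal to a designated query set.

What the generator does **not** emulate: spatial autocorrelation between
neighboring brain structures, heavy-tailed per-gene dynamic ranges,
correlated replicate noise, or realistic gene-set topology. Passing the
recovery tests therefore shows the algorithms are implemented correctly and
behave as designed on data matching their assumptions — not that the
full-scale biological results would reproduce on a different atlas snapshot.

A geometric limitation worth stating: a matrix cannot simultaneously present
a dominant 2-cluster gene structure and 7 silhouette-optimal region classes
to flat hierarchical cuts — whichever scale (home patterns vs per-class
bumps) dominates the distances wins on *both* axes, because the silhouette
criterion prefers the scale with the larger between/within ratio. The
recovery tests therefore target each planted layer in a regime where it is
identifiable: gene-cluster recovery (adjusted Rand index 1) on bump-free
matrices, and region-count recovery (k = 7 in ≥ 18/20 seeds at
signal/noise = 5) on fully informative block-diagonal matrices. Exactly
noise-free matrices are avoided for silhouette selection, since duplicate
rows make the criterion degenerate (any split into identical-point groups
scores 1).

## Problem sizes and determinism

Test and demonstration runs use reduced problem sizes chosen to exercise
every code path while keeping the suite fast: 40–100 genes, 24–47 regions,
2–10 fold-plan repeats (the stochastic RFE recovery property uses 30
samples / 3 classes / 100 features / 10 informative genes, signal 3,
noise 0.3, with 10 repeats = 40 runs per seed, over 20 seeds). The analytic
properties (fold counts, the 418 → 15 elimination schedule, conservation)
are scale-exact and are also exercised at the full-scale parameters. All
randomness flows from explicit integer seeds; an identical pipeline config
and seed produces a byte-identical `summary.json` (wall-clock timing is kept
out of the serialized summary for exactly this reason).

## Known limitations

* Full-scale counts (418 genes with expression data, 212/206 gene-cluster
  split, 99 hub genes with a 55/44 partition, term-level enrichment
  p-values) depend on a pinned atlas snapshot and library versions that are
  not redistributable here; the pipeline accepts those inputs when supplied.
* The silhouette criterion is applied to both axes; if the gene axis of real
  data has no silhouette-stable split, the chosen gene k reflects that.
* Weight-based RFE is the only implemented elimination criterion;
  accuracy-based variants would require held-out evaluation inside each run
  and are deliberately out of scope.
* The enrichment stage reports the Fisher/hypergeometric statistic only, so
  its p-values are comparable across libraries but not identical to web
  services that blend rank-deviation composites.
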