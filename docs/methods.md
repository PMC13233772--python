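# Methods

`castate` reconstructs a published analysis style for the Ca²⁺-signaling
transcriptome: restrict single-cell UMI counts to a curated panel of
Ca²⁺-signaling genes, factorize them with a hierarchical gamma-Poisson
model, cluster cells into Ca²⁺ states on their factor-score profiles, refine
those states, and evaluate them against matched random-gene nulls and
functional-group enrichment. This note documents the model, the parameter
choices, the synthetic data the tests rely on, and the numerical decisions a
maintainer would want spelled out.

## The factorization model

Counts follow a hierarchical gamma-Poisson (HPF) model. For cell *i*, gene
*j*, factor *k*:

    xi_i     ~ Gamma(a', a'/b')        cell capacity (depth)
    theta_ik ~ Gamma(a, xi_i)          cell loadings
    eta_j    ~ Gamma(c', c'/d')        gene capacity
    beta_jk  ~ Gamma(c, eta_j)         gene loadings
    y_ij     ~ Poisson(sum_k theta_ik beta_jk)

Inference is mean-field CAVI with gamma variational factors and a
multinomial allocation of each nonzero count across factors. The allocation
is treated as an explicit variational parameter, so every update (allocation,
cell loadings, gene loadings, capacities) is an exact coordinate-ascent step
and the ELBO is non-decreasing; the trace is recorded per sweep and asserted
monotone in the tests. The allocation and its two sufficient statistics are
computed in a single numba pass over the nonzeros, so a 2,000 x 800 fit at
K = 8 takes a few seconds on one CPU.

Hyperparameters: loading shapes `a = c = 0.3` (the conventional sparse
default for this model family), capacity shapes `a' = c' = 1.0`. The
capacity prior means `b'`, `d'` are set from the data so that the prior
expected rate matches the empirical mean count, split symmetrically between
cells and genes. All are exposed on `HPFHyperparameters`.

Convergence: relative ELBO change below `tol = 1e-5` for 10 consecutive
sweeps, at most 500 sweeps. A minimum of 30 sweeps is enforced before the
convergence check: early sweeps climb slowly out of the near-symmetric
initialization, and on deeper matrices a relative-change rule alone can
mistake that plateau for convergence and return a degenerate flat fit.
During K-selection scans the per-fit budget is lighter (150 sweeps,
`tol = 1e-4`, patience 5): selection needs the coverage statistic, not a
fully polished fit.

## Model-size selection (top-m coverage rule)

For each candidate K (averaged over 3 independently seeded fits), compute
each cell's normalized factor profile and the share captured by its top
`m = 4` factors; the selected K is the largest candidate whose mean share is
at least `coverage = 0.70`. Candidates default to the even values 4-16: the
coverage statistic changes slowly in K, so a coarse scan locates the knee at
half the cost of a unit-step scan. Coverage is empirically non-increasing in
K near and above the knee; well below the true K the statistic is less
informative (a merged fit can concentrate or spread mass unpredictably), so
the rule is read as "largest satisfying K", not as a monotone search.

## State graph and clustering

Cells are compared by the square root of the base-2 Jensen-Shannon
divergence between normalized factor profiles — a metric bounded in [0, 1].
The kNN graph (k = 15 for clustering) is built exactly (brute-force
distances, chunked) for the sizes this package targets. The "information
radius" prunes edges above the 85th percentile of all kNN edge distances;
the percentile is computed globally with linear interpolation (type-7).
A per-cell radius mode (each cell prunes at the 85th percentile of its own
k distances) is available behind `radius_mode="per-cell"`, since the
published description admits both readings. Ties at the radius are kept.

Leiden runs on the modularity objective with resolution 1.5 (2.5 in the
human preset) and edge weights `1 - distance`; unweighted mode is available
because the original description does not state weighting. Clusters below 20
cells are dropped as outliers. Labels are canonicalized by decreasing
cluster size so identical partitions yield identical label strings. A
correlation metric (`1 - Pearson r` of profiles) is provided for the
EMX1+ re-clustering variant.

## Refinement

Two rules, in order:

1. **Purity removal.** For each (cell type, state) pair with `n_tc` cells of
   type *t* in state *c* and `n_t` cells of that type overall, the pair's
   cells are removed when `n_tc < 15` OR `n_tc / n_t < 0.10`. The table is
   evaluated once, on the pre-refinement counts — re-iterating could cascade
   and is not part of the procedure. An AND variant is exposed.
2. **Small-state merging.** States under 250 cells merge, smallest first,
   into their nearest dendrogram sibling: state centroids are taken in a
   10-dimensional UMAP of the profile geometry (the pairwise Jensen-Shannon
   matrix is passed to UMAP as a precomputed metric), an average-linkage
   dendrogram is built on Euclidean centroid distances, and the sibling is
   the state with the smallest cophenetic distance (ties: larger state, then
   lexicographic label). Merging repeats to a fixed point.

Both rules only remove or relabel; a removed cell is never re-assigned.
Every action is recorded in an ordered provenance list (JSON-lines on disk)
that replays deterministically.

The 2-D visualization embedding uses the same geometry with a k = 50
neighborhood and no radius pruning, seeded and deterministic.

## Cell-gene scores and downstream operations

The Poisson rate matrix is `cell_scores @ gene_scores.T`; z-normalization is
per gene with the population SD, constant columns mapping to zero.
State-defining genes are ranked by mean reconstructed rate within the state
(ties broken lexicographically), top 50 by default. Gene-set scores subtract
an expression-matched control: genes are binned by mean log-normalized
expression into 25 bins and 50 controls are drawn per set gene from its bin;
scores binarize at cutoff 1. Radial-glia calling combines a positive
(HES1/NES/SOX2) and a negative (BCAN/NHLH1) set; the default requires
positive = 1 AND negative = 0, with a positive-only mode because the
published definition is ambiguous on the intersection. Differential
expression is a two-sided Wilcoxon rank-sum on log-normalized values (exact
for small tie-free groups, normal approximation otherwise) with
Benjamini-Hochberg control; significance requires adjusted p < alpha and
|log2 FC| above the caller's threshold (1 for compartments, 0.5 for
subclusters). Gene kinetic trends are row-normalized to sum to 1 and
clustered by complete linkage on cosine distances.

Log-normalization throughout is counts-per-10k followed by log1p.

## Diagnostics

* **Matched random genes** — one background gene per panel gene, uniform
  from the pool whose raw mean count lies within ±10% of the panel gene's,
  excluding panel members and genes expressed in fewer than 10 cells; an
  empty pool widens the interval in +5% steps with a warning.
* **LISI** — per cell, Gaussian neighbor weights calibrated by binary search
  to a perplexity of 30 (the reference implementation's default); the score
  is the inverse Simpson index of the weight-aggregated label distribution.
* **Neighbor-voting AUROC** — per functional group (≥ 5 genes), a cell-cell
  Spearman correlation network on log-normalized counts restricted to the
  group, row rank-normalized; 3-fold stratified cross-validation hides test
  labels and votes by mean connectivity to labeled training cells; AUROC per
  label, fold-averaged. Groups whose state-averaged AUROC exceeds 0.55 are
  flagged for reporting.
* **Factor redundancy** — pairwise normalized mutual information between
  quantile-binned (10 bins) factor cell scores; constant factors are defined
  as NMI 0 with a warning.
* **Cell-cycle factor flagging** — Pearson correlation between factor cell
  scores and log-normalized marker expression (TOP2A, MKI67, BIRC5 by
  default); a factor is flagged at max-r ≥ 0.3 (the published account says
  only "high correlation", so the threshold is exposed) and can be dropped
  from the model before clustering.

## Synthetic data

The generator draws from exactly the hierarchical structure the model
assumes: per-factor gamma gene loadings with planted marker genes
up-weighted 8x (marker loadings are drawn bounded away from zero so a
planted marker cannot be silent), per-cell loadings whose expected mix
follows a group usage vector (Dirichlet-like, concentration exposed),
per-cell lognormal depth, Poisson emission. Optional blocks: lineage cells
interpolating usage between two groups; a cell-cycle-like confounder factor
with dedicated non-panel marker genes (TOP2A/MKI67/BIRC5 naming) whose
expression correlates with the confounder loading by construction; and
unstructured background genes mean-matched to the panel genes, used as the
sampling pool for random-gene nulls.

Named fixtures (all generated at test time; nothing is shipped as data):

* `six_state` — 2,000 cells x 800 panel genes (+1,200 background genes),
  K_true = 8, six groups of ~333 cells at 2,000 panel UMIs per cell. Each
  group leaves a distinct pair of factors nearly unused (weight 0.04) and
  spreads the rest roughly evenly (~0.15), with anti-symmetric ±20% tilts
  so every factor's usage column is unique. This layout is deliberate: the
  top-4 coverage rule is only informative when cells genuinely spread their
  scores over more than four factors, and factor recovery is only
  well-posed when no two factors share a usage pattern. Groups remain well
  separated because any two differ in at least two off factors.
* `lineage` — three branches interpolating from one progenitor group.
* `cycling` — two groups plus the confounder factor and its markers.
* `impure` — five states (1,200/1,000/800/400/240 cells) with hand-planted
  (cell type, state) crossings: four blocks at exactly 9% of their type
  (fraction rule), two blocks of 14 cells (count rule), two 20% control
  blocks that must survive, and one boundary block of exactly 15 cells;
  state E (240 cells) sits below the merge threshold. The planted table is
  exported so tests can verify removals by enumeration.

What the generator does **not** emulate: ambient RNA, doublets, batch or
donor effects, over-dispersion beyond the gamma mixing (a negative-binomial
variant exists for robustness checks only), or spliced/unspliced layers.
Passing tests therefore demonstrate correctness of the procedure under the
model's own assumptions, not robustness to the full messiness of real
atlases.

## Problem sizes and runtime

The test suite and the acceptance script run on one CPU. The expensive
pieces are the K-selection scan on `six_state` (seven candidate K values x
3 restarts, a few minutes) and the end-to-end pipeline runs (about two
minutes each, dominated by UMAP on the 2,000-cell distance matrix). All
randomness flows from named substreams of one master seed; identical seeds
give byte-identical state labels, which the determinism checks assert.

## Known limitations

* Exact kNN and precomputed-distance UMAP bound practical size to ~20k
  cells; larger inputs would need approximate neighbors (flagged in graph
  metadata but not implemented).
* The coverage rule's behavior well below the true K is not monotone; the
  implementation returns the largest satisfying candidate, which is the
  intended reading, but a scan whose candidates are all far below the true
  K will silently select its top candidate.
* Purity removal assumes cell-type labels are trustworthy; there is no
  mechanism for uncertain or missing type labels beyond dropping the rule.
* The Wilcoxon exact path requires tie-free values and group sizes <= 8 per
  scipy's implementation; sparse count data with ties always takes the
  tie-corrected normal approximation.
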