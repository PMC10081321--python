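# Methods

This note documents the models, conventions and numerical choices behind
`coexqc`, in the spirit of a package methods appendix: what is computed,
what was genuinely open and how it was decided, and what a green test does
and does not establish.

## Expression input and QC

Matrices are gene-by-cell, raw counts or CPM.  QC (applied to counts only)
removes doublet-flagged cells first, then keeps cells with a mitochondrial
read fraction strictly below 0.5 and a detected-gene count in the inclusive
interval [200, 6000].  The bounds are read literally: "less than" is
strict, "between a and b" is inclusive.  Mitochondrial genes are recognised
by identifier prefix (default `MT-`) and the fraction is computed on raw
counts before normalization.  Duplicate gene identifiers are resolved by
keeping the row with the larger total count — deterministic, and it retains
the informative row.  CPM scales each cell to a total of 1e6; all-zero
cells stay zero.

Harmonization fits every dataset to a fixed gene universe (typically the
GO-annotated genes, supplied as a file for reproducibility rather than
fetched live): universe genes missing from a dataset become all-zero rows,
dataset genes outside the universe are dropped and counted.  This gives all
networks an identical index, the precondition for aggregation and for
preserved-co-expression comparisons.

## Networks

Spearman correlation across cells, computed as Pearson on within-gene ranks
with average ties.  Correlations involving zero-variance genes (including
zero-padded universe genes) are set to 0 — a neutral value that lands them
in the low tied mass after standardization instead of propagating NaNs; the
choice is ours, the upstream procedure being silent on it.

Rank standardization jointly ranks **all** entries of the symmetric matrix
(diagonal included, ties averaged) and divides by the maximum rank.
Ranking the full symmetric matrix preserves symmetry automatically; the
diagonal is forced to 1 afterwards.  Whether the original procedure ranks
with or without the diagonal is unstated; including it perturbs off-diagonal
values only through the shared divisor, which cancels in every AUROC the
package computes (AUROCs are rank-based, hence invariant to any strictly
monotone transform of the weights).

Aggregation is the element-wise mean; provenance (`n_cells`, `n_datasets`)
is summed.  Everything is dense `float64`; at the ~19k-gene scale of a GO
universe one matrix is ~2.9 GB, so operations are written to need at most
one full matrix resident plus row-level workspace.

## Marker statistics

The AUROC is computed from the Mann-Whitney identity
`AUROC = (R0 - n0(n0+1)/2) / (n0 n1)` with average-rank ties, which equals
pair counting with ties at ½ (verified exactly against a brute-force oracle
in the tests).  An empty class raises rather than returning a sentinel.

Differential expression is one-vs-rest per cell type:
`log2FC = log2((mean_in + 1)/(mean_out + 1))` on CPM (the 1-CPM pseudocount
is our transparent substitute for an upstream package's internals, exposed
as a parameter), expression AUROC as above, one-sided (greater-in-type)
normal-approximate rank-sum p with tie correction and continuity
correction, BH-adjusted within each dataset × cell type.  Meta-ranking
orders genes by recurrence of DE calls (log2 FC ≥ 4, FDR ≤ 0.05) across
datasets, then mean AUROC, then ascending gene id; all ties everywhere are
broken by gene id for bit-reproducibility.  The aggregate-expression
predictor sums CPM values of the marker genes per cell (a flag allows raw
counts) and scores target-vs-rest with the same AUROC.

## Module scores (neighbor voting)

Members of a set are split into `n_folds = 3` seeded folds.  Per fold,
every gene's vote is the sum of its network weights to the remaining
labeled members divided by its total weight (degree normalization controls
hub bias); the AUROC of held-out members versus non-members is averaged
over folds.  With folds equal to the member count this reduces exactly to
leave-one-out voting (tested).  Set genes missing from the network are
dropped with a log message; a set needs ≥ 3 usable members.  GO-style
collections are filtered to 10–1000 members after namespace intersection.

## Preserved co-expression

Positives for gene A are its top-k (default 10) reference partners,
excluding A itself; ties at the k-th value are cut lexicographically at
exactly k (an "include all tied" alternative is a flag).  Candidates are
all non-self genes ranked by test co-expression with A; the query gene is
excluded from both sides, since the diagonal would otherwise inflate every
score.  A gene whose test row is entirely tied is scored 0.5 and flagged
uninformative.  Set scores are exact member means; the global score is the
mean over all scored genes.  The percentile report uses mid-rank:
`100 · (#below + ½·#ties)/n`.

Term-level significance: with population mean and SD taken over all scored
genes, `Z = (mu_term − mu_pop)/(SD_pop/√n)`, left/right normal tails
(`p_L + p_R = 1` exactly), BH per tail over terms with 20–250 members,
significance at FDR ≤ 1e-4.  The z-test is closed-form (no Monte Carlo)
and matches hand arithmetic to 1e-12 in the tests.

The permutation correlation test permutes the pairing of one vector 10,000
times and reports `#{|rho*| ≥ |rho|}/n_perm` — deliberately the uncorrected
count, which can be 0; the (b+1)/(B+1) variant is available by flag.
Spearman is the default coefficient, Pearson by flag.  Group comparisons
use the exact rank-sum distribution when the smaller group has ≤ 8
observations and no ties, otherwise the continuity-corrected normal
approximation.  Enrichment is upper-tail hypergeometric over terms of
10–1000 universe-intersected members, with reporting restricted to 20–500.

## Clustering evaluation

The marker submatrix orders genes within each set by descending mean
intra-set co-expression.  "Consensus" k-means is defined here (the cited
heatmap tool's internal rule is undocumented): k-means is repeated with
seeded single initializations, the run-frequency co-clustering matrix is
computed, and the reported partition is the run agreeing best with the
modal (≥ 0.5) co-clustering pattern — deterministic under a seed and
faithful to the spirit of repeated-k-means consensus.  ARI is computed
against the grouping of genes by marker set.  Ward clustering uses
Euclidean distances on co-expression rows; leaf order places the subtree
containing the smaller original index first, so it is library-independent.

## Synthetic data

`simulate_dataset` draws gamma-Poisson (negative binomial) counts.
Relative rates per cell are lognormal base abundances × the cell's program
activities (gamma, mean 1, sd 0.7, shared by all genes of a program within
a cell — this induces within-program co-expression in *every* cell type) ×
a 32-fold elevation of the cell's own program (this induces DE).  Defaults:
5 types × 300 cells, 2,000 genes, 50 markers/type, 5,000 counts/cell,
dispersion 0.3 — a small but realistically noisy droplet-style experiment;
fold 32 comfortably clears the log2 FC ≥ 4 threshold after the pseudocount,
as a strong planted marker should.  The generator does **not** model batch
effects, ambient RNA or doublets, so green recovery tests establish
correctness of the statistics, not robustness to those artefacts.

`simulate_network_pair` plants modules (blocks of mutually elevated
weights) in a reference and rebuilds a test network from per-gene
neighborhoods: each gene elevates its top-k reference partners with
probability `p`, otherwise k random partners, with elevated entries
max-symmetrized.  Retained genes use an order-preserving additive boost of
the reference values, so at `p = 1` every gene scores exactly 1; retention
draws are coupled across `p` under one seed, so the score is strictly
increasing in `p` within a seed and the calibration sweep is not at the
mercy of Monte-Carlo noise.

## Degenerate inputs and numerical conventions

Asymmetry beyond 1e-8 is an error for network constructors; correlations
are clipped to [-1, 1] and symmetrized as `(C + Cᵀ)/2` to cancel BLAS
summation-order noise.  AUROC with an empty class, empty reference
distributions, constant vectors in the permutation test, and a
zero-variance score population in the z-test all raise informative errors
rather than returning sentinels.  All randomness flows through explicit
`numpy.random.default_rng` seeds; no global state.

## Known limitations

- The DE internals (pseudocount, one-sidedness, tie handling) are declared
  substitutes for an upstream marker package and may reorder genes near
  thresholds relative to it.
- Genome-wide scoring loops per gene (O(n² log n) total); fine to ~20k
  genes on one core, but no out-of-core path is provided.
- The package ships no real-tissue reference network; users supply their
  own serialized reference (HDF5) for fidelity scoring.
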