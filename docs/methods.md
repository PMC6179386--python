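# Methods

This note documents the statistical procedures implemented in `coanet`, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where the procedure admitted more than one reasonable reading.

## Protein quantification

Input is either protein-level abundance matrices or PSM-level tables (one row
per peptide-spectrum match, one reporter intensity per time point). PSM
channels are divided by the same PSM's t = 0 intensity; the protein ratio per
time point is the median of its PSM ratios (midpoint median for even counts).
PSMs with a non-positive t = 0 intensity are rejected with a warning. Proteins
must be supported by strictly more than `psm_min` PSMs (default 10) to enter
network construction. Cross-condition comparisons are restricted to the
proteome shared by all conditions. The relative-abundance score of a protein
in a stimulated condition is the sum over all time points of (condition −
baseline); the signed sum is the default because candidates are selected for
induction, and an absolute-value mode is available
(`relative_abundance(..., mode="absolute")`).

## Co-abundance networks

For each condition, pairwise Pearson correlations of the time-point profiles
form a complete weighted graph. Significance is assessed by permutation:
per realization every protein's profile vector is shuffled over the time-point
order and the correlations recomputed; the empirical p-value is
P\* = r₍>₎/N, the fraction of N = 300 permutations whose correlation strictly
exceeds the observed one, and Q\* is the Benjamini–Hochberg adjustment of the
upper-triangle P\* values. Edges require r ≥ r_threshold (0.90, ties
included) **and** Q\* ≤ q_max (0.01).

Numerical and procedural details:

* **Permutation scheme.** One member of each pair takes the shuffled profile
  per realization (equivalent under exchangeability to shuffling both; a flag
  switches to both-shuffled). With six time points only 720 distinct
  orderings exist, so permutations are Monte-Carlo sampled with replacement.
  Permuted correlations are clipped to [−1, 1] so floating-point excess can
  never "beat" a mathematically perfect observed correlation.
* **Resolution limit.** The smallest non-zero P\* is 1/300 ≈ 0.0033. With
  thousands of simultaneous pairs, a pair with a single exceeding permutation
  typically receives Q\* > 0.01 and is dropped even at r ≈ 0.98; in planted-
  module simulations the r ≥ 0.90 criterion alone recovers ≈ 100% of module
  pairs while the FDR gate costs 10–20% of them. This is inherent to the
  permutation budget, not a defect, and the tests assert both quantities
  separately.
* **P\* uses strict ">"** as defined; a conservative (r₍>₎+1)/(N+1) mode is
  available but off by default. Zero-variance profiles yield undefined
  correlations, recorded as r = 0 with a cleared validity flag (they keep
  their literal permutation count in P\* but are barred from edges by the
  mask and Q\* = 1).
* **Threshold selection.** The density sensitivity scan counts qualifying
  edges per candidate threshold; the selected value is the largest grid point
  whose density stays within a 5% relative tolerance of the density at the
  preceding grid point ("maintains the density"). The published default 0.90
  at 1% FDR is the shipped setting.
* **Alternatives.** Biweight midcorrelation follows the standard
  median/MAD weighting, u = (x − med)/(9·MAD), weights (1 − u²)² truncated at
  |u| ≥ 1 (verified against `pingouin` to 1e-15). At six time points bicor
  can deviate noticeably from Pearson on weakly correlated draws — the
  agreement tests use co-varying profiles. First-order partial correlation
  controls the baseline condition; since a first-order partial admits a
  single control vector per pair, the control for pair (x, y) is the
  element-wise mean of the two proteins' baseline profiles (option
  `control_mode="shared"` uses the condition-wide mean baseline profile
  instead).

## Network operations

Networks are simple undirected graphs whose edges carry a class (`ppi`,
`coabundance`, or `both`), evidence flags, an optional condition tag, and a
positive traversal weight. De-noising removes edges whose evidence is a
non-empty subset of {low-throughput, co-complex}; mixed-evidence edges
survive. Analyses operate on the largest connected component (ties broken by
the lexicographically smallest member).

Superimposing a co-abundance network on the PPI takes the union of nodes and
edges; an edge present in both sources becomes class `both` with the
**minimum** of the two weights, so that with w_C < w_P the co-abundance
evidence dominates traversal — the choice that gives the context-specific
links their intended importance. The variant analysis that *removes*
significantly anti-correlated PPI edges (r ≤ −0.90 at Q\* ≤ 0.01) is provided
as `remove_negative_edges`; co-abundance-class edges are never touched by it.

Degree-preserving randomization bins every node by floor(log₂ degree)
(degree-0 nodes excluded; the base is configurable). Random *edges* draw both
endpoints uniformly from the bins of the template edge's endpoints, rejecting
self-loops and duplicates (1000 attempts, then the bins widen one level at a
time); random *nodes* draw one replacement per candidate from the candidate's
own bin.

## Prioritization

Distances are minimum-total-weight path costs (Dijkstra on the sparse
adjacency); with all weights equal they reduce exactly to BFS hop counts.
Scores:

* proximity PS(c) = Σ_s I(s)/(d_cs + 1), seeds weighted I(s) = 1, unreachable
  seeds contribute 0;
* kernel dk(c) = −ln[Σ_s e^{−(d_cs+1)}/|S|], lower is better;
* RWR: p ← (1 − ρ)Wp + ρe with column-normalized unweighted adjacency,
  uniform restart over seeds, L1 tolerance 1e-6. The restart probability is
  not standardized in the literature; the default ρ = 0.75 (common in gene
  prioritization) is exposed as a parameter;
* DADA: the RWR score divided by the uniform-restart RWR score, which cancels
  pure degree attraction; on regular graphs it reproduces the RWR ordering.
  Several degree-aware variants exist; the uniform-restart ratio is the one
  implemented, and whether the walks should use traversal weights is left at
  the unweighted default.

Ranks break score ties by protein identifier, making all outputs
deterministic; percentiles map rank 1 → 100 and rank n → 0. The weight-ratio
scan rebuilds the combined network for each candidate ratio w_C/w_P ∈ (0, 10]
and selects the ratio with the highest mean AUROC over a fixed k-fold
partition (ties → smallest ratio; ratio 0 would make co-abundance paths free
and is dropped with a warning).

## Evaluation

k = 7 folds partition the seed set (first folds absorb the remainder); the
identical partition is reused for every network variant, so fold AUROCs are
paired. Within a fold, training seeds drive the ranking and are excluded from
both the positives and the negatives of that fold's evaluation; held-out seeds
are the positives. AUROC uses the rank-sum formulation with average ranks, so
tied pairs count ½. The paired t-test (df = k − 1, two-tailed) compares
variants; zero variance of the fold differences flags the p-value undefined
rather than zero. The random-edge control adds |E_CoA| degree-matched random
edges per realization (default 20 realizations) and reports the fraction of
realizations with mean AUROC at least the observed one. Navigability compares
per-node mean hop distances to targets across network variants by two-sided
Mann–Whitney U (exact for tie-free samples ≤ 20, normal approximation with
tie correction otherwise) with Bonferroni correction over the pairs tested.

## Candidate selection

The rank cutoff N comes from the cross-validated ROC: held-out scores from
all folds are pooled, the Youden point (max TPR − FPR, ties → smallest
cutoff) is found on the pooled curve, and the pooled cutoff divided by the
fold count gives N. The triple filter intersects the top-N network-ranked
proteins with the top-500 by relative abundance — a protein qualifies if it is
top-500 at *any* single time point (default) or by total score — and the
top-500 by expression fold change, then removes known seed targets. The
combined score re-ranks each criterion *within* the filtered set (reading the
rank-normalization in R_comb = N(N_prior + N_abun + N_expr)/3 as
re-normalization to the candidate set), averages the three ranks, and breaks
ties by network rank then identifier.

Candidate-to-target closeness uses unweighted hop distances **on the enriched
network** (candidate–target paths may traverse both PPI and co-abundance
links, exactly as the candidate–target path subnetworks are drawn):
d_c is the candidate's mean distance to all reachable targets, D the mean of
d_c. The null redraws each candidate from its log-degree bin for n_real
realizations (default 1000); z = (D − D̄_r)/σ_Dr and p_emp = P(D_r < D), so a
*small* p means candidates sit closer than degree-matched random proteins.
Per-path-length histograms carry one-sided empirical p-values (fraction of
realizations with at least the observed count at that length), which is how
the over-representation of short path lengths is tested.

## Enrichment

Edge-overlap validation prunes the co-abundance network and a reference
interaction network to their shared proteins, forms the 2×2 table over all
unordered shared pairs, and reports the two-sided Fisher exact p
(minimum-likelihood rule), the sample odds ratio ad/bc (Haldane 0.5
correction, flagged, when a cell is zero) and the Woolf log-OR 95% CI.

The "top prioritized" set is cut where per-rank empirical p-values stay below
α = 0.01: null rankings come from degree-bin-matched random seed sets of the
original size (the spec leaves the randomization target open; seed-set
randomization is the reading implemented), p at rank r is the fraction of
realizations whose score at rank r is at least the observed score, and the
cutoff is the largest r with all positions ≤ r significant. The shipped
default is 10,000 realizations; the test suite and the acceptance script use
200 as their problem size. Note that with strongly localized seed sets the
observed score can dominate the null at *every* rank, in which case the top
set is the whole ranking — the downstream enrichment then uses the filtered
candidate list, which is always small.

Gene-set enrichment is the upper-tail hypergeometric test with BH adjustment
(significant at q ≤ 0.05); the universe defaults to all genes annotated in
the collection and may be overridden by the network node set. The pathway
network connects significant sets with edges weighted by the Jaccard index of
their memberships restricted to the top prioritized proteins, discarding
J < 0.1; node size attribute is −log₁₀ q.

## Synthetic data

The generator produces the complete study at desk scale, with ground truth:

| parameter | default | meaning |
|---|---|---|
| n_nodes / mean_degree | 2000 / 12 | preferential-attachment PPI (heavy-tailed degrees); duplication–divergence available |
| n_seeds / locality | 150 / 0.5 | seed targets; half grown as a BFS neighborhood, half uniform |
| modules | 6 × 30 | planted co-abundance modules, 3 active per stimulated condition |
| module_overlap_with_seeds | 0.6 | fraction of module members drawn from the seed set (spilling into seed neighbors when exhausted) |
| n_background | 340 | quantified proteins outside any module (proteome 520 of 2000) |
| time_points | 0, 8, 12, 24, 48, 72 h | six-point profiles, t = 0 ≡ 1 |
| noise_sd | 0.15 | i.i.d. log-noise sd (~15% CV, typical reporter-ion noise) |
| n_regulators | 10 per condition | non-seed members of active modules; top-decile fold changes and a dedicated true pathway |

Module members share a smooth latent log-trajectory (cumulative Gaussian
steps, normalized to unit sd so an "active" module always has real dynamics)
plus i.i.d. log-noise; profiles are exponentiated and normalized to t = 0.
The baseline condition leaves all modules flat; each stimulated condition
activates its own modules. The module–seed overlap draws from the seed set
itself — known targets participate in condition-specific co-regulation, which
is what lets co-abundance edges shorten paths between held-out and training
seeds; an overlap pool of seed *neighbors* only demonstrably removes the
downstream gain. PSM tables multiply each protein profile by a random base
intensity and log-normal channel noise of chosen CV, so cv = 0 round-trips
exactly through the median aggregation.

What the generator does **not** emulate: missing values and their mechanisms,
isotopic interference, protein inference/grouping, correlated (batch)
noise, biased interactome coverage, or any real biology in the pathway
annotations. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the assumed data-generating process, not that
the biological conclusions of any particular study transfer.

Everything derives from a single master seed via `numpy` SeedSequence
spawning; the truth record (module membership, regulators, seeds, parameters)
suffices to regenerate a scenario bit-identically, and the pipeline manifest
records per-stage derived seeds so full runs are byte-reproducible.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the default 2000-node scenario
for the planted-signal checks (one scenario per generator seed, 20 generator
seeds for the random-edge control), 300 permutations throughout, 20
random-edge and up to 1000 random-node realizations, and 200 realizations for
the per-rank empirical cutoff. These sizes are the package's reference
configuration for simulation studies; all of them are parameters.

## Known limitations

* The permutation budget (N = 300 on six time points) bounds attainable
  significance; see the resolution note above.
* The paired t-test at k = 7 has limited power for small AUROC gains; the
  degree-preserving random-edge control is the more sensitive check.
* DADA and RWR follow one published variant each; restart probability and
  weighting conventions differ across the literature.
* The Youden-based rank cutoff inherits ROC granularity; with few positives
  the cutoff can be coarse.
* First-order partial correlation with a per-pair mean-baseline control is an
  interpretation; a full multivariate control is out of scope.
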