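# coanet

Condition-specific **co-abundance network** enrichment of protein–protein
interaction (PPI) networks, and **network-proximity prioritization** of drug
target candidates.

Generic PPI interactomes aggregate interactions across all tissues and cell
states, which blurs the context a disease study actually cares about. `coanet`
implements a workflow that restores context: time-course proteomics measured
under defined stimulation conditions (for example classically and
alternatively activated macrophages) is turned into per-condition
*co-abundance* edges, these edges are superimposed on the literature PPI
network, and every protein is then ranked by its weighted network proximity to
a set of seed proteins (known drug targets). The ranking is validated by
cross-validation against degree-preserving random-edge nulls, reduced to a
short candidate list by combining network, proteomic and transcriptomic
evidence, and characterized by pathway enrichment.

## The model

**Co-abundance edges.** For each pair of proteins quantified in a condition
(abundance ratios at time points 0–72 h, each protein normalized to its t=0
channel and supported by >10 peptide-spectrum matches), the Pearson
correlation *r* of their profiles is compared with a permutation null in which
profile vectors are shuffled over the time order: the empirical p-value is
P\* = r₍>₎/N for N = 300 permutations, adjusted to Q\* by Benjamini–Hochberg.
An edge is kept when r ≥ 0.90 and Q\* ≤ 0.01 — the highest correlation that
maintains the network density at 1% FDR in a sensitivity scan. Biweight
midcorrelation and first-order partial correlation (controlling the baseline
condition) are available as robustness alternatives.

**Weighted proximity ranking.** Co-abundance links carry weight w_C and PPI
links w_P, so the network distance becomes
d\*₍cs₎ = Σ w_C·n_C + Σ w_P·n_P over the cheapest path, and the ratio
w_C/w_P < 1 lets the condition-specific edges dominate traversal (default
w_C/w_P = 0.4, the optimum of a cross-validated ratio scan). Each candidate
*c* is scored against the seed set *S* by the proximity score

    PS(c) = Σ_{s∈S} I(s) / (d_cs + 1),        I(s) = 1,

with kernel distance dk(c) = −ln[Σ_s e^{−(d_cs+1)}/|S|], random walk with
restart (RWR) and its degree-adjusted variant (DADA) as alternative scorers.

**Evaluation and selection.** Seven-fold cross-validation (training seeds
score, held-out seeds are positives, training seeds excluded from the
evaluation pool) yields paired fold AUROCs for the PPI network with and
without co-abundance edges; a paired t-test and 20 degree-preserving
random-edge realizations (endpoints drawn from logarithmic degree bins)
quantify the gain. The genome-wide ranking is cut at the ROC point maximizing
sensitivity + specificity, intersected with the top-500 proteins by relative
abundance versus baseline and the top-500 genes by expression fold change, and
re-ranked by R_comb = (N_prior + N_abun + N_expr)/3. The final list's average
hop distance to the targets is tested against degree-matched random proteins
(z-score and empirical p), and the top prioritized set is profiled by
hypergeometric pathway enrichment with a Jaccard pathway network.

A fully parameterized synthetic-scenario generator (scale-free PPI, planted
seed-overlapping co-abundance modules, planted regulators with top-decile fold
changes, PSM-level tables, GMT pathways) makes every stage testable without
any external data.

## Worked example

```python
from coanet import (
    generate_scenario, permutation_significance, build_coabundance_network,
    combine_networks, extract_lcc, kfold_split, cv_auroc,
)
import numpy as np
from scipy import stats

sc = generate_scenario(rng_seed=0)            # 2000-node PPI, 150 seeds,
ppi = extract_lcc(sc.network)                 # 520-protein time-course per condition

corr = permutation_significance(sc.abundance["ifng"], n_perm=300, rng_seed=7)
coa = build_coabundance_network(corr)         # r >= 0.90, Q* <= 0.01
combined = combine_networks(ppi, coa, w_ppi=1.0, w_coa=0.4)

folds = kfold_split(sc.seeds, k=7, rng_seed=0)
auroc_ppi = np.mean(cv_auroc(ppi, sc.seeds, folds))
auroc_coa = np.mean(cv_auroc(combined, sc.seeds, folds))
t, p = stats.ttest_rel(cv_auroc(combined, sc.seeds, folds),
                       cv_auroc(ppi, sc.seeds, folds))
print(f"co-abundance edges: {coa.number_of_edges()}")
print(f"AUROC  PPI {auroc_ppi:.3f} -> PPI+CoA {auroc_coa:.3f}  (paired-t p={p:.4f})")
```

Output:

```
co-abundance edges: 1448
AUROC  PPI 0.693 -> PPI+CoA 0.788  (paired-t p=0.0032)
```

The 1448 co-abundance edges are the condition-specific correlation structure
(the planted modules of the simulated study); adding them to the PPI at weight
0.4 raises the cross-validated recovery of held-out drug targets from AUROC
0.693 to 0.788, and the paired t-test over the seven shared folds shows the
gain is systematic rather than fold noise.

The same run end-to-end, from the command line:

```bash
coanet run-all --simulate --seed 0 --out-dir runs/demo
```

which writes every stage output (co-abundance edge lists, combined network,
rankings, evaluation JSON, candidate tables, proximity statistics, enrichment
tables) plus a provenance manifest; rerunning with the same seed reproduces
every file byte-for-byte.

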