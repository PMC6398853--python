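# crpclust

Bayesian nonparametric clustering of multivariate categorical survey
responses, built for the kind of question asked of household-panel data:
do respondents fall into robust groups with distinct patterns of concern,
and do those groups differ in an outcome such as party identification?

The package implements the full workflow as a Python library:

1. **Dirichlet-process mixture of categoricals.** A Chinese Restaurant
   Process (CRP) prior with concentration α over partitions of N
   respondents; per cluster and item dimension *d* (with *V_d* response
   options), a categorical likelihood with a symmetric Dirichlet(β) prior.
   Component parameters are integrated out, giving the closed-form
   Dirichlet-categorical predictive
   `F_k(o) = ∏_d (n_{k,d,o_d} + β) / (n_k + V_d β)`
   and the collapsed Gibbs seating rule
   `P(t_i = k) ∝ n_k · F_k(o_i)` (existing cluster) or `α · F_new(o_i)`
   (new cluster). Chains are burned in, thinned, and pooled across
   independent replicates.
2. **Consensus by median partition.** The consensus clustering minimizes
   the mean *transfer distance* (the minimum number of single-item moves
   between two partitions, computed by a linear-sum-assignment reduction
   over the cluster-overlap matrix) to all posterior draws, found by greedy
   local search.
3. **Stability and profiling.** Per consensus cluster: the mean Transfer
   Similarity `TS = 1 − TD/(N−1)` and Mirkin Similarity
   `MS = 1 − 2(c+d)/N²` of the cluster against the sub-partitions its
   members form across draws; per-item response frequencies; outcome
   frequencies and enrichment ratios against the whole sample.
4. **Synthetic survey generator.** SOEP-shaped data (13 categorical items:
   eleven 3-point concern items, one employment item with a
   "not applicable" level, one binary other-concerns indicator) with a
   known latent partition, Dirichlet-drawn cluster response profiles
   (concentration γ controls separation), and a cluster-conditional
   party-identification outcome dominated by a "none" category — so every
   stage is testable without access-restricted panel data.

## Worked example

`examples/03_simulate_and_cluster.py` simulates 150 respondents in three
well-separated latent groups, runs two independent Gibbs chains, and
condenses the 2 × 100 retained draws into a median partition:

```text
dataset: 150 respondents x 13 items; true cluster sizes [81, 48, 21]
retained 200 draws; cluster-count trace (last 10): [3, 3, 3, 3, 3, 3, 3, 3, 3, 3]
median partition sizes: [81, 48, 21]
recovery (transfer similarity vs truth): 1.000
```

The sampler settles at three clusters, the consensus partition reproduces
the generating one exactly (transfer similarity 1.0 means zero item moves
are needed, up to relabeling). `examples/04_stability_and_profiles.py`
adds the study-style report — chain agreement, per-cluster stability, and
outcome enrichment:

```text
consensus clusters (sizes): [55, 36, 29]
chain disagreement: 0 of 120 (0.0%)
  cluster 0 (n= 55): TS  1.00  MS  1.00
  ...
  cluster 1: most enriched outcome 'other' (x3.33, 5.6% vs 1.7% overall)
```

An enrichment ratio of x3.33 says that outcome category is 3.33 times more
frequent inside the cluster than in the full sample.

The other examples demonstrate the CRP prior's rich-gets-richer seating
probabilities (`01_crp_prior.py`) and the transfer-distance / similarity
calculus on a four-item worked example (`02_partition_distances.py`).

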