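# Methods

## Model

`crpclust` clusters N respondents with D-dimensional integer-coded
categorical responses under a Dirichlet-process mixture model. The prior
over partitions is the Chinese Restaurant Process: respondents arrive
sequentially, join an occupied table k with probability
`n_k / (N + α)` and found a new table with probability `α / (N + α)`.
The concentration α (default 1) controls the a-priori number of clusters;
under this prior the expected cluster count is `Σ_{i<N} α/(α+i)`, and
cluster sizes decay steeply ("rich gets richer").

Given its cluster, a respondent's D items are independent categoricals.
Each cluster-and-dimension probability vector carries a symmetric
Dirichlet(β) prior and is integrated out, so clusters are represented only
by count statistics `n_{k,d,v}` and the predictive probability of a
response vector *o* is the product of Dirichlet-categorical posterior
predictives

    F_k(o) = ∏_d (n_{k,d,o_d} + β) / (n_k + V_d β),

which for an empty cluster reduces to the uniform prior predictive
`∏_d 1/V_d`. β is not pinned down by the methodology this package follows;
the default β = 1 (uniform base measure) is the conventional uninformative
choice and is exposed in `SamplerConfig`.

States such as "not applicable" (e.g., employment-safety concerns of
respondents without employment) are modeled as an extra response category
of their dimension rather than as missing data, so every respondent has a
complete code vector.

## Sampling

Collapsed Gibbs: each sweep removes every respondent in ascending index
order (a seeded random scan is available) and reseats it with probability
proportional to `n_k F_k(o)` for occupied tables and `α F_new(o)` for a new
one. Seating probabilities are computed in log space with max-subtraction;
at D = 13 the raw products underflow for large clusters. Clusters emptied
by a removal are deleted immediately and ids compacted, keeping the
"occupied tables" set well defined.

Chains are initialized by seating respondents 0..N−1 sequentially with the
same likelihood-weighted rule (a prior-only initialization is available via
`init_with_likelihood=False`). The default protocol mirrors the full-scale
study setup: burn-in 500 sweeps, thinning 160, S = 2048 retained draws,
two independent chains pooled; each chain's generator is seeded from a
deterministically spawned child of the master seed, so runs are exactly
reproducible. A `prior_only` switch disables the likelihood, turning the
sweep into a sampler of the bare CRP — used for calibration tests against
the closed-form mean cluster count and the exact exchangeable partition
probability function.

## Consensus and stability

The consensus partition minimizes the mean transfer distance (TD) to the
retained draws. TD between two partitions is N minus the maximal total
cluster overlap under an optimal one-to-one matching of clusters, computed
by zero-padding the overlap matrix to square and solving the linear sum
assignment problem (`scipy.optimize.linear_sum_assignment`); the sign
convention negates overlaps for the minimizing solver. Ties among equally
optimal matchings do not affect TD.

The greedy search starts from the retained draw with the smallest mean TD
to all draws (deterministic; a seeded random start is available), cycles
over items in ascending order, tentatively places each item in every
existing cluster and one new cluster, accepts only strict improvements
(preventing cycles), and stops after a full cycle without improvement. The
result is canonicalized: clusters numbered by decreasing size, ties broken
by smallest member index. Two implementation accelerations do not change
the result: identical draws are deduplicated and weighted by multiplicity,
and each draw's overlap matrix is maintained incrementally across moves.
Greedy local search carries no global-optimality guarantee; on small
instances (N ≤ 6) the test suite compares it with exhaustive search over
all set partitions and observes it at or near the global optimum, and it
never ends worse than its starting candidate.

Per-cluster stability restricts every retained draw to the members of one
consensus cluster and compares the induced sub-partition with the single
block, reporting mean Transfer Similarity `1 − TD/(|C|−1)` and Mirkin
Similarity `1 − 2(c+d)/|C|²`. For singleton clusters TS is undefined (its
denominator vanishes) and is reported as null, with MS still computed.
Run disagreement between two chains is the TD between their per-chain
consensus partitions, reported as a count and a fraction of N.

## Synthetic data

The generator emulates the structure of a concern block in a German
household panel: 13 items (eleven 3-point concern scales, employment
safety with a fourth not-applicable level, a binary other-concerns
indicator) and a party-identification outcome with eight categories
dominated by "none" (base shares: none 50%, two larger parties 18%/14%,
five smaller options). Cluster labels come either from a CRP with
`alpha_gen` (size-decaying clusters) or from explicit weights; each
cluster's per-dimension response profile is drawn from a symmetric
Dirichlet(γ). Small γ pushes profiles toward corners: γ = 0.05 gives
well-separated clusters, the default γ = 0.1 moderately separated ones.
Each cluster's outcome distribution keeps the "none" share fixed and tilts
the party mass toward one seeded favorite (default tilt 0.25), mimicking
the qualitative pattern of a majority without identification plus clusters
with one over-represented party.

Items are conditionally independent given the cluster — exactly the
mixture's own likelihood assumption — so recovery tests are a fair check
of the inference machinery, not of robustness to model misspecification.
Real survey data differ in ways the generator does not emulate: items are
correlated within respondents beyond cluster membership, marginal
frequencies are not Dirichlet-symmetric, and cluster structure is not
literally categorical-mixture. Passing recovery tests therefore
demonstrates correctness of the sampler and consensus machinery, not that
real panel data contain equally clean clusters.

## Problem sizes and numerical choices

The test suite runs everything at desk scale: recovery uses n = 300
respondents in three clusters (weights 0.5/0.3/0.2, γ = 0.05) with
burn-in 500, thinning 5, and 200 retained draws per chain; the prior-only
calibration uses N = 100 with 500 retained draws. Exhaustive oracles cover
LSAP up to 7×7, transfer distance up to N = 7, and median-partition
optimality up to N = 6 (Bell-number enumeration). Probability
normalizations are asserted to 1e−10…1e−12; Monte-Carlo comparisons use
3–4 standard-error bands.

## Known limitations

- **Mixing across cluster number is slow.** Single-site Gibbs merges
  clusters easily but splits them only through a rare founding event
  followed by a growth race; measured escape times from a merged two-cluster
  state at n = 300 range from a single sweep to thousands. With two chains,
  a run can end with one chain still merged: the pooled median partition is
  usually still correct (the correct draws dominate), but per-chain
  consensus partitions then disagree substantially. Remedies outside this
  package's scope are split-merge moves or more chains; within scope, use a
  generous burn-in and inspect the per-chain cluster-count trace before
  trusting run agreement.
- No hyperparameter inference for α or β, no missing-data handling, no
  split-merge or other accelerated samplers, and no statistical tests on
  enrichment ratios (they are descriptive, with no over-representation
  cutoff).
- The greedy median is a local optimizer; its optimality gap is verified
  only on small instances.
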