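# Methods

## Data model

A web is an ordered species list plus an S × S matrix with entries in
{−1, 0, +1}. Entry (i, j) is the sign of the effect of species i (row) on
the growth rate of species j (column); the literature is not unanimous on
this orientation, but the marginal likelihood of any fixed partition is
transpose-invariant (transposition permutes blocks ij ↔ ji and the product
over blocks is unchanged), so scores and optimal groupings do not depend on
the convention. Diagonal self-effects are allowed and counted: with L
nonzero entries, the zero count is Z = S² − L over all S² cells, diagonal
included.

Unordered pairs of reciprocal signs classify interactions: (+,−) trophic,
(+,+) mutualism, (−,−) competition, (+,0) commensalism, (−,0) amensalism,
(0,0) none. Type filtering (`subnetwork_by_type`) zeroes both directed
entries of every pair outside the kept classes but never drops species;
reduction to the largest weakly connected component is a separate, explicit
step, so the two operations can be composed or omitted independently.

## Likelihood and marginal likelihood

Each ordered block (i, j) is a run of independent ternary cells:
present with probability c_ij and, given presence, positive with
probability π_ij. The blocked log-likelihood at the per-block MLEs
ĉ_ij = L_ij/(L_ij+Z_ij), π̂_ij = K_ij/L_ij uses the 0·ln 0 = 0 convention
(via `scipy.special.xlogy`), which makes empty and saturated blocks exact
and reproduces the two limits that anchor the model: one group recovers the
global Erdős–Rényi-style fit, and singleton groups give likelihood exactly
1 (every 1 × 1 block is fit perfectly — the reason raw likelihood cannot
select a model and the marginal likelihood is needed).

Integrating c_ij and π_ij out under independent uniform priors on [0, 1]
gives, per block, the Beta-integral closed form
K! Z! (L−K)! / [(1+L)(1+L+Z)!]. The printed layout of this expression is
typographically ambiguous about the denominator; the derivation fixes it as
(1+L)·(1+L+Z)! and the test suite confirms the closed form against
numerical double integration (`scipy.integrate.dblquad`) per block to
better than 1e−8 in log space. All factorials are computed as log-Gamma;
no prior over partitions is applied, so comparing marginal likelihoods is
comparing Bayes factors with equal model priors.

## Search

The sampler is a collapsed Gibbs sweep inside Metropolis-coupled MCMC:

- **Gibbs move.** Visit species in a seeded random order. For each, score
  membership in every current group plus one fresh group by the tempered
  log marginal likelihood and sample from the normalized exponentiated
  scores. Because rates are integrated out, the group count grows and
  shrinks freely; empty groups are pruned immediately. Moving one species
  changes only one row and one column of the block-count matrices, so all
  candidate scores are evaluated with O(g²) vectorized work per species.
- **Coupling.** Chains run at tempering exponents applied as powers of the
  marginal likelihood; defaults are 4 chains at (1, 0.8, 0.6, 0.4),
  5000 sweeps, each chain initialized from a random partition with at most
  min(5, S) groups. After every sweep one random adjacent pair proposes a
  state swap accepted with probability
  min(1, exp[(β_k − β_{k+1})(ln P_{k+1} − ln P_k)]). These sampler
  settings are this package's own reconstruction of a standard MC³ design;
  they are configurable through `SearchConfig`.
- **Output.** The best partition ever visited by any chain (the target is
  optimization, not posterior summarization), its log marginal likelihood
  recomputed directly on the returned partition, per-chain score traces and
  the non-decreasing best-so-far series. Identical seeds give bit-identical
  results; ties in enumeration are broken by canonical (first-appearance)
  label order.

`exhaustive_search` enumerates all set partitions via restricted growth
strings and is guarded at S ≤ 10 (Bell(10) = 115 975); it is the exact
oracle the stochastic search is tested against at S ≤ 7. The jackknife
removes one species at a time, refits, and reports MI/MI_max between the
refit grouping and the reference restricted to the surviving species; the
ratio is defined as 1 when both restricted partitions are single groups
(MI_max = 0), since the groupings then agree trivially.

## Partition comparison

Entropies and MI are in nats with the 0·ln 0 = 0 convention. MI is computed
from the joint count table and agrees with both the entropy form
H(A) + H(B) − H(A,B) and the direct double sum to 1e−12 (a property test).
MI_max is defined as min(H(A), H(B)) — the attainable ceiling when one
partition refines the other; definitions accounting for fixed marginals
exist, but the minimum-entropy bound is the one conserved by the
randomization scheme below and is used consistently for the jackknife and
recovery ratios.

The randomization test permutes both partitions' labels over species
independently each replicate, conserving every group's size and hence
MI_max, and reports the plain proportion of replicates with MI ≥ observed
(an optional (r+1)/(n+1) conservative estimator is off by default). The
default is 10⁶ replicates; tests and the ablation workflow use smaller,
explicitly passed counts. A ≥-comparison with 1e−12 slack absorbs float
jitter at exact ties.

## Synthetic data

`generate` draws each ordered cell independently: nonzero with the planted
block's connection probability, positive with its sign probability.
Diagonal cells are drawn like any other (consistent with Z = S² − L); an
`allow_self_interactions=False` switch zeroes them for ecological realism.
The planted-recovery study conditions are within-group connection 0.5
versus between-group 0.05 with uninformative signs (π = 0.5 everywhere) —
a strong but not saturated contrast at S = 60 with three equal groups.

What the generator does *not* emulate: degree heterogeneity within groups,
correlated reciprocal links (real trophic pairs are perfectly
anti-symmetric, generated cells are independent), broad group-size
distributions, and the mixed interaction-type composition of real webs.
Passing recovery tests therefore show the search and scoring machinery are
correct under the model's own assumptions, not that real webs satisfy
those assumptions.

The deterministic 10-species fixture is a three-tier food chain (4 basal,
3 consumers, 3 predators, each tier fully consumed by the next) plus
mutualisms between two basal species and all predators. Its entries are
frozen constants: enumeration proves the trophic-only optimum is the
three-tier grouping while the full-web optimum splits the basal tier into
mutualist and non-mutualist halves — the nested-refinement behaviour the
fixture exists to exercise.

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to make every check exact or
statistically decisive at desk scale: quadrature cross-checks on 20 random
webs with S ≤ 5; search-vs-enumeration on 20 webs with S ≤ 7 at 150
sweeps; planted recovery on ten S = 60 webs at 50 sweeps (convergence is
observed within a handful of sweeps at this contrast); randomization
calibration on 800 independent partition pairs at N = 200 with 1000
replicates each, plus a 10⁴-replicate significance check. The package
defaults (5000 sweeps, 10⁶ replicates) are deliberately conservative for
real webs, where the landscape is rugged and p-values may be small.

Degenerate inputs are handled explicitly: empty networks are rejected by
the searches; single-species networks are fixed points of the Gibbs sweep;
π̂ is reported as 0 for empty blocks (the corresponding likelihood terms
are exactly zero); `mi_max = 0` comparisons define ratio 1 in the
jackknife.

## Limitations

- No degree correction or weighted links: entries are strictly ternary.
- The searches return a point estimate (best grouping), not co-clustering
  or consensus summaries; rerunning with different seeds is the intended
  robustness check alongside the jackknife.
- The randomization p-value is an estimate with Monte Carlo error
  ~ √(p(1−p)/n); at the default 10⁶ replicates this is negligible above
  p ≈ 10⁻⁵ but exact small p-values require more replicates.
- Species appearing in two ecological roles must be encoded as one node
  carrying the union of their interactions; the package does not duplicate
  nodes.
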