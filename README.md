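# signedgroups

Group-model analysis of **signed directed ecological interaction networks**.

Ecological communities are webs of feeding, mutualism, competition,
commensalism and amensalism. Encoding each pairwise effect as an entry of a
signed adjacency matrix `N` (`N[i, j] ∈ {-1, 0, +1}` is the sign of species
*i*'s effect on species *j*'s growth rate), this package finds the partition
of species into *ecologically equivalent* groups — species that interact in
the same way with the same kinds of partners — and quantifies how similar
two alternative groupings are.

## The model

The group model is a stochastic block model for signed digraphs. Given a
partition into *g* groups, each ordered group pair *(i, j)* has a connection
probability *c<sub>ij</sub>* and a probability *π<sub>ij</sub>* that a link
is positive. With per-block tallies *L<sub>ij</sub>* (links),
*K<sub>ij</sub>* (positive links) and *Z<sub>ij</sub>* (zeros),

P(N | c, π) = ∏<sub>ij</sub> c<sub>ij</sub><sup>L<sub>ij</sub></sup> π<sub>ij</sub><sup>K<sub>ij</sub></sup> (1−c<sub>ij</sub>)<sup>Z<sub>ij</sub></sup> (1−π<sub>ij</sub>)<sup>L<sub>ij</sub>−K<sub>ij</sub></sup>

which is maximized at ĉ<sub>ij</sub> = L<sub>ij</sub>/(L<sub>ij</sub>+Z<sub>ij</sub>),
π̂<sub>ij</sub> = K<sub>ij</sub>/L<sub>ij</sub>. For model selection across
partitions the rates are integrated out under uniform priors, giving the
closed-form marginal likelihood

P(N | G) = ∏<sub>ij</sub> K<sub>ij</sub>! Z<sub>ij</sub>! (L<sub>ij</sub>−K<sub>ij</sub>)! / [(1+L<sub>ij</sub>)(1+L<sub>ij</sub>+Z<sub>ij</sub>)!]

Ratios of marginal likelihoods are Bayes factors between groupings. The best
grouping is sought with a collapsed Gibbs sampler embedded in
Metropolis-coupled MCMC (several tempered chains exchanging states), with
exhaustive enumeration as an exact oracle for small webs. Partitions are
compared via Shannon entropy, mutual information (MI, in nats), the MI upper
bound min(H(A), H(B)), and a group-size-conserving randomization test.

## Worked example

Simulate a 45-species web from a planted three-group structure
(within-group connection probability 0.5, between 0.05), search for the
best grouping, and compare it to the truth:

```bash
signedgroups simulate --sizes 15,15,15 --seed 7 --out demo
signedgroups fit --network demo.network.tsv --sweeps 200 --seed 1 \
    --out-partition demo.best.tsv
signedgroups compare --partition-a demo.best.tsv \
    --partition-b demo.partition.tsv --reps 10000 --seed 2
```

prints

```
wrote 45 species, 405 links
best grouping: 3 groups, log marginal likelihood -1025.1186 nats
H_A     H_B     H_AB    MI      MI_max  p_value stars
1.098612        1.098612        1.098612        1.098612        1.098612        0       ***
```

The search recovers exactly three groups; both partitions have entropy
ln 3 ≈ 1.0986 nats, their MI equals its upper bound (the found grouping
matches the planted one perfectly), and none of the 10 000 size-conserving
shuffles reached the observed MI (p < 10⁻⁴, `***` = p < .001).

The same workflow runs on real webs from edge-list TSV
(`source  target  sign`) or labelled CSV matrices;
`signedgroups ablation-study` fits the full, trophic-only and
nontrophic-only variants of a web and writes all pairwise partition
comparisons with significance stars. As a library:

```python
import signedgroups as sg

net = sg.read_network("web.tsv", format="edge-list")
result = sg.mc3_search(sg.largest_weak_component(net), sg.SearchConfig(seed=0))
print(result.best_partition.n_groups, result.best_log_marginal)
```

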