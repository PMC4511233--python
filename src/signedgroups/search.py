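"""Partition search: tempered collapsed Gibbs sampling with chain coupling.

The sampler targets the marginal likelihood of the group model directly
(per-block rates are integrated out), so a Gibbs move reassigns one
species by scoring its membership in every current group plus one fresh
group and sampling from the normalized scores. Several chains run at
different temperatures -- the chain with tempering exponent beta targets
P(N | G)^beta, flattening the landscape for small beta -- and adjacent
chains periodically propose to swap states (Metropolis-coupled MCMC),
which lets hot chains ferry the cold chain out of local optima. The
deliverable is the best partition ever visited, not a posterior sample.

Exhaustive enumeration over all set partitions is provided as an exact
oracle for small networks, and a jackknife assesses how stable a grouping
is to removal of single species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .block_model import (
    Partition,
    canonicalize,
    log_marginal_likelihood,
    restrict_partition,
)
from .compare import mi_max, mutual_information
from .network import SignedNetwork, remove_species

__all__ = [
    "SearchConfig",
    "SearchResult",
    "JackknifeResult",
    "gibbs_sweep",
    "mc3_search",
    "exhaustive_search",
    "jackknife_stability",
]


@dataclass(frozen=True)
class SearchConfig:
    """Settings for the coupled-chain search.

    ``temperatures`` are the tempering exponents applied to the marginal
    likelihood, one per chain; the first (coldest) must be 1 and they
    must decrease strictly. ``init_groups`` caps the number of groups in
    each chain's random starting partition.
    """

    n_chains: int = 4
    temperatures: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4)
    n_sweeps: int = 5000
    seed: int | None = None
    max_groups: int | None = None
    record_every: int = 1
    init_groups: int = 5

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if len(self.temperatures) != self.n_chains:
            raise ValueError("need one tempering exponent per chain")
        if self.temperatures[0] != 1.0:
            raise ValueError("the cold chain must have exponent 1")
        if any(b <= 0 or b > 1 for b in self.temperatures):
            raise ValueError("exponents must lie in (0, 1]")
        if any(
            self.temperatures[i] <= self.temperatures[i + 1]
            for i in range(self.n_chains - 1)
        ):
            raise ValueError("exponents must decrease strictly with chain index")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")


@dataclass(frozen=True)
class SearchResult:
    """Best grouping found, its score, and per-chain score traces."""

    best_partition: Partition
    best_log_marginal: float
    traces: np.ndarray = field(repr=False)  # (n_chains, n_recorded)
    best_trace: np.ndarray = field(repr=False)  # best-so-far, non-decreasing
    seed: int | None = None


def _block_terms(L: np.ndarray, K: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Per-block log marginal contributions (vectorized)."""
    return (
        gammaln(K + 1.0)
        + gammaln(Z + 1.0)
        + gammaln(L - K + 1.0)
        - np.log1p(L)
        - gammaln(L + Z + 2.0)
    )


class _GibbsState:
    """Mutable chain state with incrementally maintained block counts.

    Moving one species only changes one row and one column of the count
    matrices, so candidate scores for all target groups are evaluated
    with O(g^2) vectorized work instead of re-tallying the S x S matrix.
    """

    def __init__(self, net: SignedNetwork, labels: np.ndarray, max_groups: int | None):
        self.nonzero = (net.signs != 0).astype(np.float64)
        self.positive = (net.signs == 1).astype(np.float64)
        self.n = net.n_species
        self.max_groups = max_groups if max_groups is not None else self.n
        self.labels = np.asarray(labels, dtype=np.int64).copy()
        self._rebuild()

    def _rebuild(self) -> None:
        uniq, self.labels = np.unique(self.labels, return_inverse=True)
        g = len(uniq)
        onehot = np.zeros((self.n, g))
        onehot[np.arange(self.n), self.labels] = 1.0
        self.L = onehot.T @ self.nonzero @ onehot
        self.K = onehot.T @ self.positive @ onehot
        self.sizes = onehot.sum(axis=0)

    def log_marginal(self) -> float:
        Z = np.outer(self.sizes, self.sizes) - self.L
        return float(_block_terms(self.L, self.K, Z).sum())

    def partition(self, species: tuple[str, ...]) -> Partition:
        return canonicalize(Partition(self.labels + 1, species))

    def sweep(self, beta: float, rng: np.random.Generator) -> None:
        for s in rng.permutation(self.n):
            self._move(int(s), beta, rng)

    def _move(self, s: int, beta: float, rng: np.random.Generator) -> None:
        g = len(self.sizes)
        a = self.labels[s]
        # tallies of s's links into each current group, excluding s itself
        w_row = self.nonzero[s].copy()
        w_col = self.nonzero[:, s].copy()
        p_row = self.positive[s].copy()
        p_col = self.positive[:, s].copy()
        self_nz, self_pos = w_row[s], p_row[s]
        w_row[s] = w_col[s] = p_row[s] = p_col[s] = 0.0
        row_L = np.bincount(self.labels, weights=w_row, minlength=g)
        col_L = np.bincount(self.labels, weights=w_col, minlength=g)
        row_K = np.bincount(self.labels, weights=p_row, minlength=g)
        col_K = np.bincount(self.labels, weights=p_col, minlength=g)

        # detach s from its group
        L, K, sizes = self.L, self.K, self.sizes
        L[a, :] -= row_L
        L[:, a] -= col_L
        K[a, :] -= row_K
        K[:, a] -= col_K
        L[a, a] -= self_nz
        K[a, a] -= self_pos
        sizes[a] -= 1

        # candidate slots: every current group, plus one fresh empty slot
        # unless detaching already emptied group a (which then serves as
        # the fresh slot) or the group cap is reached
        if sizes[a] > 0 and g < self.max_groups:
            G = g + 1
            L = np.pad(L, ((0, 1), (0, 1)))
            K = np.pad(K, ((0, 1), (0, 1)))
            sizes = np.append(sizes, 0.0)
            row_L = np.append(row_L, 0.0)
            col_L = np.append(col_L, 0.0)
            row_K = np.append(row_K, 0.0)
            col_K = np.append(col_K, 0.0)
        else:
            G = g

        Zbase = np.outer(sizes, sizes) - L
        t_old = _block_terms(L, K, Zbase)
        base_total = t_old.sum()
        # contribution of row b + column b (counting (b,b) once) before adding s
        old_bc = t_old.sum(axis=1) + t_old.sum(axis=0) - np.diag(t_old)

        # after adding s to candidate b, row b of L becomes L[b,:] + row_L,
        # so the matrix L + row_L[None,:] holds every candidate's new row b
        # at its row b (off-diagonal cells; (b,b) is handled separately)
        Lr = L + row_L[None, :]
        Kr = K + row_K[None, :]
        Zr = (sizes + 1.0)[:, None] * sizes[None, :] - Lr
        t_row = _block_terms(Lr, Kr, Zr)
        Lc = L + col_L[:, None]
        Kc = K + col_K[:, None]
        Zc = sizes[:, None] * (sizes + 1.0)[None, :] - Lc
        t_col = _block_terms(Lc, Kc, Zc)
        Ld = np.diag(L) + row_L + col_L + self_nz
        Kd = np.diag(K) + row_K + col_K + self_pos
        Zd = (sizes + 1.0) ** 2 - Ld
        t_diag = _block_terms(Ld, Kd, Zd)
        new_bc = (
            t_row.sum(axis=1)
            - np.diag(t_row)
            + t_col.sum(axis=0)
            - np.diag(t_col)
            + t_diag
        )
        totals = base_total - old_bc + new_bc

        logits = beta * (totals - totals.max())
        probs = np.exp(logits)
        probs /= probs.sum()
        b = int(rng.choice(G, p=probs))

        # attach s to slot b
        L[b, :] += row_L
        L[:, b] += col_L
        K[b, :] += row_K
        K[:, b] += col_K
        L[b, b] += self_nz
        K[b, b] += self_pos
        sizes[b] += 1
        self.labels[s] = b
        self.L, self.K, self.sizes = L, K, sizes
        if np.any(sizes == 0):
            self._compact()

    def _compact(self) -> None:
        alive = np.flatnonzero(self.sizes > 0)
        remap = -np.ones(len(self.sizes), dtype=np.int64)
        remap[alive] = np.arange(len(alive))
        self.labels = remap[self.labels]
        self.L = self.L[np.ix_(alive, alive)]
        self.K = self.K[np.ix_(alive, alive)]
        self.sizes = self.sizes[alive]


def gibbs_sweep(
    net: SignedNetwork,
    part: Partition,
    exponent: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> Partition:
    """One collapsed Gibbs sweep over all species at a tempering exponent.

    Each species, in a random order, is reassigned to an existing group
    or a fresh one with probability proportional to the tempered marginal
    likelihood of the resulting partition. Returns a canonical partition.
    """
    if not 0 < exponent <= 1:
        raise ValueError("tempering exponent must lie in (0, 1]")
    if part.n_species != net.n_species:
        raise ValueError("partition does not describe this network")
    rng = np.random.default_rng(rng)
    state = _GibbsState(net, canonicalize(part).assignment - 1, max_groups=None)
    state.sweep(exponent, rng)
    return state.partition(net.species)


def _random_partition(n: int, max_g: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, max(1, min(max_g, n)), size=n)


def mc3_search(net: SignedNetwork, config: SearchConfig | None = None) -> SearchResult:
    """Metropolis-coupled Gibbs search for the best-scoring partition.

    Runs ``n_chains`` tempered chains; after every sweep one adjacent
    pair of chains proposes a state exchange with the standard tempered
    acceptance ratio. The best partition ever visited by any chain is
    returned; given a seed, results are bit-reproducible.
    """
    if net.n_species == 0:
        raise ValueError("cannot search an empty network")
    config = config or SearchConfig()
    rng = np.random.default_rng(config.seed)
    chains = [
        _GibbsState(
            net,
            _random_partition(net.n_species, config.init_groups, rng),
            config.max_groups,
        )
        for _ in range(config.n_chains)
    ]
    betas = config.temperatures

    best_labels = chains[0].labels.copy()
    best_score = chains[0].log_marginal()
    for state in chains[1:]:
        score = state.log_marginal()
        if score > best_score:
            best_score, best_labels = score, state.labels.copy()

    n_rec = config.n_sweeps // config.record_every
    traces = np.empty((config.n_chains, n_rec))
    best_trace = np.empty(n_rec)
    rec = 0
    for sweep in range(1, config.n_sweeps + 1):
        scores = []
        for state, beta in zip(chains, betas):
            state.sweep(beta, rng)
            score = state.log_marginal()
            scores.append(score)
            if score > best_score:
                best_score = score
                best_labels = state.labels.copy()
        if config.n_chains > 1:
            k = int(rng.integers(config.n_chains - 1))
            log_ratio = (betas[k] - betas[k + 1]) * (scores[k + 1] - scores[k])
            if np.log(rng.random()) < min(0.0, log_ratio):
                chains[k], chains[k + 1] = chains[k + 1], chains[k]
        if sweep % config.record_every == 0:
            traces[:, rec] = scores
            best_trace[rec] = best_score
            rec += 1

    best = canonicalize(Partition(best_labels + 1, net.species))
    # score the returned partition directly so the contract is exact
    return SearchResult(
        best_partition=best,
        best_log_marginal=log_marginal_likelihood(net, best),
        traces=traces[:, :rec],
        best_trace=best_trace[:rec],
        seed=config.seed,
    )


def _set_partitions(n: int):
    """Yield all set partitions of range(n) as restricted growth strings."""
    labels = np.zeros(n, dtype=np.int64)
    maxes = np.zeros(n, dtype=np.int64)
    yield labels.copy()
    while True:
        i = n - 1
        while i > 0 and labels[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxes[i] = max(maxes[i - 1], labels[i])
        for j in range(i + 1, n):
            labels[j] = 0
            maxes[j] = maxes[i]
        yield labels.copy()


def exhaustive_search(net: SignedNetwork, max_species: int = 10) -> SearchResult:
    """Exact maximizer of the marginal likelihood by full enumeration.

    Feasible only for small networks (Bell(10) = 115975 partitions); ties
    are broken toward the lexicographically first restricted-growth
    string, i.e. the canonical enumeration order.
    """
    n = net.n_species
    if n == 0:
        raise ValueError("cannot search an empty network")
    if n > max_species:
        raise ValueError(f"exhaustive search limited to S <= {max_species}, got {n}")
    best_labels = None
    best_score = -np.inf
    for labels in _set_partitions(n):
        score = log_marginal_likelihood(net, Partition(labels + 1))
        if score > best_score:
            best_score = score
            best_labels = labels
    best = canonicalize(Partition(best_labels + 1, net.species))
    return SearchResult(
        best_partition=best,
        best_log_marginal=log_marginal_likelihood(net, best),
        traces=np.empty((0, 0)),
        best_trace=np.array([best_score]),
        seed=None,
    )


@dataclass(frozen=True)
class JackknifeResult:
    """Per-species MI / MI_max ratios after single-species deletion."""

    species: tuple[str, ...]
    ratios: np.ndarray
    mean: float
    std: float


def jackknife_stability(
    net: SignedNetwork,
    reference: Partition,
    config: SearchConfig | None = None,
) -> JackknifeResult:
    """Robustness of a grouping to removal of individual species.

    For each species the network is refit without it and the found
    partition is compared, via MI / MI_max, against the reference
    grouping restricted to the surviving species. Ratios near 1 mean the
    group structure does not hinge on any single species.
    """
    if net.n_species < 3:
        raise ValueError("jackknife needs at least 3 species")
    if reference.n_species != net.n_species:
        raise ValueError("reference partition does not describe this network")
    config = config or SearchConfig()
    reference = Partition(reference.assignment, net.species)
    base_seed = config.seed if config.seed is not None else 0
    ratios = np.empty(net.n_species)
    for i, label in enumerate(net.species):
        sub = remove_species(net, {label})
        cfg = SearchConfig(
            n_chains=config.n_chains,
            temperatures=config.temperatures,
            n_sweeps=config.n_sweeps,
            seed=base_seed + 7919 * (i + 1),
            max_groups=config.max_groups,
            record_every=config.record_every,
            init_groups=config.init_groups,
        )
        found = mc3_search(sub, cfg).best_partition
        ref_restricted = restrict_partition(reference, sub.species)
        bound = mi_max(found, ref_restricted)
        if bound == 0.0:
            # both partitions are degenerate (single group): perfect agreement
            ratios[i] = 1.0
        else:
            ratios[i] = mutual_information(found, ref_restricted) / bound
    return JackknifeResult(
        species=net.species,
        ratios=ratios,
        mean=float(ratios.mean()),
        std=float(ratios.std(ddof=1)),
    )
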