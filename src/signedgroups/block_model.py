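"""Group (stochastic block) model for signed directed networks.

Under a partition of the S species into g groups, every ordered group pair
(i, j) has a connection probability c_ij (any link from a member of i to a
member of j) and a sign probability pi_ij (that such a link is +1). The
likelihood of the observed sign matrix given per-block rates is a product
of Bernoulli terms over all S^2 cells; maximizing it per block gives
c_ij = L_ij / (L_ij + Z_ij) and pi_ij = K_ij / L_ij. Integrating the rates
out under independent uniform priors gives the closed-form marginal
likelihood

    prod_ij  K_ij! Z_ij! (L_ij - K_ij)!  /  [ (1 + L_ij) (1 + L_ij + Z_ij)! ]

which is the model-selection score used throughout the package: partitions
with higher marginal likelihood group species into fewer, more
"ecologically equivalent" roles without overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .network import SignedNetwork

__all__ = [
    "Partition",
    "BlockCounts",
    "block_counts",
    "mle_rates",
    "log_likelihood_mle",
    "log_marginal_likelihood",
    "log_marginal_from_counts",
    "log_bayes_factor",
    "canonicalize",
    "restrict_partition",
    "read_partition",
    "write_partition",
]


@dataclass(frozen=True)
class Partition:
    """Assignment of each species to a group.

    ``assignment`` holds one integer group label per species; labels are
    arbitrary until :func:`canonicalize` relabels them 1..g in order of
    first appearance. ``species`` optionally carries the labels of the
    network the partition describes, enabling species-aware restriction
    and file io.
    """

    assignment: np.ndarray = field(repr=True)
    species: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.assignment, dtype=np.int64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("assignment must be a non-empty 1-D integer sequence")
        object.__setattr__(self, "assignment", arr)
        arr.setflags(write=False)
        if self.species is not None:
            spp = tuple(str(s) for s in self.species)
            if len(spp) != arr.size:
                raise ValueError(
                    f"{len(spp)} species labels but {arr.size} assignments"
                )
            object.__setattr__(self, "species", spp)

    @property
    def n_species(self) -> int:
        return int(self.assignment.size)

    @property
    def n_groups(self) -> int:
        return int(np.unique(self.assignment).size)

    def group_sizes(self) -> np.ndarray:
        """Sizes of the groups, in canonical (first-appearance) order."""
        _, counts = np.unique(canonicalize(self).assignment, return_counts=True)
        return counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return (
            np.array_equal(self.assignment, other.assignment)
            and self.species == other.species
        )

    def __hash__(self) -> int:
        return hash((self.assignment.tobytes(), self.species))


def canonicalize(part: Partition) -> Partition:
    """Relabel groups 1..g in order of first appearance.

    Empty labels disappear; any model score is invariant because the
    blocks are merely permuted.
    """
    labels: dict[int, int] = {}
    out = np.empty_like(part.assignment)
    for i, lab in enumerate(part.assignment):
        out[i] = labels.setdefault(int(lab), len(labels) + 1)
    return Partition(out, part.species)


@dataclass(frozen=True)
class BlockCounts:
    """Per-ordered-block link tallies under a partition.

    ``L[i, j]`` counts nonzero cells from group i to group j, ``K[i, j]``
    the +1 cells among them, and ``Z[i, j]`` the zero cells; diagonal
    blocks include the matrix diagonal, so L_ij + Z_ij = n_i n_j always.
    """

    L: np.ndarray
    K: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("L", "K", "Z"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            object.__setattr__(self, name, arr)
        if not (self.L.shape == self.K.shape == self.Z.shape):
            raise ValueError("L, K, Z must share a g x g shape")
        if np.any(self.K > self.L) or np.any(self.K < 0) or np.any(self.Z < 0):
            raise ValueError("counts must satisfy 0 <= K_ij <= L_ij and Z_ij >= 0")


def _membership(net: SignedNetwork, part: Partition) -> np.ndarray:
    if part.n_species != net.n_species:
        raise ValueError(
            f"partition describes {part.n_species} species but network has {net.n_species}"
        )
    canon = canonicalize(part)
    g = canon.n_groups
    onehot = np.zeros((net.n_species, g), dtype=np.int64)
    onehot[np.arange(net.n_species), canon.assignment - 1] = 1
    return onehot


def block_counts(net: SignedNetwork, part: Partition) -> BlockCounts:
    """Tally L, K and Z for every ordered group pair."""
    m = _membership(net, part)
    nonzero = (net.signs != 0).astype(np.int64)
    positive = (net.signs == 1).astype(np.int64)
    L = m.T @ nonzero @ m
    K = m.T @ positive @ m
    sizes = m.sum(axis=0)
    Z = np.outer(sizes, sizes) - L
    return BlockCounts(L, K, Z)


def mle_rates(counts: BlockCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-block maximum-likelihood rates (c_hat, pi_hat).

    c_hat_ij = L_ij / (L_ij + Z_ij); pi_hat_ij = K_ij / L_ij, reported as
    0 for empty blocks (the corresponding likelihood terms vanish anyway).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(counts.L + counts.Z > 0, counts.L / np.maximum(counts.L + counts.Z, 1), 0.0)
        pi = np.where(counts.L > 0, counts.K / np.maximum(counts.L, 1), 0.0)
    return c, pi


def log_likelihood_mle(net: SignedNetwork, part: Partition) -> float:
    """Log blocked likelihood at the per-block MLE rates, in nats.

    Uses the 0 ln 0 = 0 convention; always <= 0, and exactly 0 when every
    species is its own group (each 1 x 1 block is explained perfectly).
    """
    counts = block_counts(net, part)
    c, pi = mle_rates(counts)
    ll = (
        xlogy(counts.L, c)
        + xlogy(counts.K, pi)
        + xlogy(counts.Z, 1.0 - c)
        + xlogy(counts.L - counts.K, 1.0 - pi)
    )
    return float(ll.sum())


def log_marginal_from_counts(L, K, Z) -> float:
    """Log marginal likelihood from block tallies (vectorized over blocks).

    Each block contributes ln[K! Z! (L-K)!] - ln(1+L) - ln[(1+L+Z)!],
    the Beta-integral of the Bernoulli likelihood under uniform priors
    on both rates. Factorials go through log-Gamma to avoid overflow.
    """
    L = np.asarray(L, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    term = (
        gammaln(K + 1.0)
        + gammaln(Z + 1.0)
        + gammaln(L - K + 1.0)
        - np.log1p(L)
        - gammaln(L + Z + 2.0)
    )
    return float(np.sum(term))


def log_marginal_likelihood(net: SignedNetwork, part: Partition) -> float:
    """Log marginal (integrated) likelihood of the network under a partition."""
    counts = block_counts(net, part)
    return log_marginal_from_counts(counts.L, counts.K, counts.Z)


def log_bayes_factor(net: SignedNetwork, part1: Partition, part2: Partition) -> float:
    """Log Bayes factor ln B = ln P(N | G1) - ln P(N | G2).

    Positive values favour ``part1``; antisymmetric in its two partition
    arguments.
    """
    return log_marginal_likelihood(net, part1) - log_marginal_likelihood(net, part2)


def restrict_partition(part: Partition, keep_species) -> Partition:
    """Restrict a species-labelled partition to an ordered subset of species.

    The surviving assignments are canonicalized, so the group count may
    shrink if a group loses all members.
    """
    if part.species is None:
        raise ValueError("partition carries no species labels to restrict by")
    keep_species = [str(s) for s in keep_species]
    index = {s: i for i, s in enumerate(part.species)}
    unknown = [s for s in keep_species if s not in index]
    if unknown:
        raise KeyError(f"unknown species labels: {unknown}")
    sub = part.assignment[[index[s] for s in keep_species]]
    return canonicalize(Partition(sub, tuple(keep_species)))


# ---------------------------------------------------------------------------
# partition io: TSV with columns `species  group`
# ---------------------------------------------------------------------------

def read_partition(path) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    missing = {"species", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"partition file is missing columns: {sorted(missing)}")
    return Partition(df["group"].to_numpy(dtype=np.int64), tuple(df["species"]))


def write_partition(part: Partition, path) -> None:
    if part.species is None:
        species = [f"sp{i + 1}" for i in range(part.n_species)]
    else:
        species = list(part.species)
    pd.DataFrame({"species": species, "group": part.assignment}).to_csv(
        path, sep="\t", index=False
    )
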