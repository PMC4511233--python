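"""Planted-partition generators and small deterministic fixtures.

Networks are drawn from the generative reading of the group model: given
group sizes, a g x g connection-probability matrix C and a g x g
positive-sign probability matrix P, every ordered cell (i, j) is
independently nonzero with probability C[g(i), g(j)] and, if nonzero,
positive with probability P[g(i), g(j)]. Diagonal cells are generated
like any other by default, matching the model's Z = S^2 - L accounting;
a switch disables self-interactions for ecological realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .block_model import Partition
from .network import SignedNetwork

__all__ = ["PlantedModel", "generate", "box1_fixture", "fig1_style_fixture"]


@dataclass(frozen=True)
class PlantedModel:
    """Planted block structure: sizes plus per-block rate matrices."""

    group_sizes: tuple[int, ...]
    C: np.ndarray
    P: np.ndarray
    seed: int | None = None
    allow_self_interactions: bool = True

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.group_sizes)
        if not sizes or any(s < 1 for s in sizes):
            raise ValueError("group sizes must be positive")
        object.__setattr__(self, "group_sizes", sizes)
        g = len(sizes)
        for name in ("C", "P"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (g, g):
                raise ValueError(f"{name} must be {g}x{g}, got {arr.shape}")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} entries must be probabilities in [0, 1]")
            object.__setattr__(self, name, arr)

    @property
    def n_species(self) -> int:
        return sum(self.group_sizes)


def generate(
    model: PlantedModel, rng: np.random.Generator | int | None = None
) -> tuple[SignedNetwork, Partition]:
    """Draw one signed network from a planted model, with its true partition."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    else:
        rng = np.random.default_rng(rng)
    sizes = model.group_sizes
    s = model.n_species
    membership = np.repeat(np.arange(len(sizes)), sizes)
    c_cell = model.C[np.ix_(membership, membership)]
    p_cell = model.P[np.ix_(membership, membership)]
    present = rng.random((s, s)) < c_cell
    positive = rng.random((s, s)) < p_cell
    signs = np.where(present, np.where(positive, 1, -1), 0).astype(np.int8)
    if not model.allow_self_interactions:
        np.fill_diagonal(signs, 0)
    species = tuple(f"sp{i + 1}" for i in range(s))
    return SignedNetwork(species, signs), Partition(membership + 1, species)


def box1_fixture() -> tuple[Partition, Partition]:
    """The worked five-species example: A = (1,2,1,2,1), B = (alpha, beta, gamma, beta, beta).

    Greek labels in B are encoded as 1, 2, 3 in order of appearance. Used
    to pin down the entropy and joint-count arithmetic exactly.
    """
    species = ("s1", "s2", "s3", "s4", "s5")
    a = Partition(np.array([1, 2, 1, 2, 1]), species)
    b = Partition(np.array([1, 2, 3, 2, 2]), species)
    return a, b


# Ten-species fixture: a three-tier food chain (4 basal, 3 consumers,
# 3 top predators; each tier fully consumed by the next) plus mutualisms
# between the first two basal species and all top predators. Filtering to
# trophic pairs leaves the clean three-tier structure; the full network
# splits the basal group into mutualist and non-mutualist halves.
_FIG1_SPECIES = ("b1", "b2", "b3", "b4", "c1", "c2", "c3", "t1", "t2", "t3")
_FIG1_TRUE_GROUPS = np.array([1, 1, 2, 2, 3, 3, 3, 4, 4, 4])


def fig1_style_fixture() -> tuple[SignedNetwork, Partition]:
    """Deterministic 10-species network whose full-model optimum refines
    its trophic-only optimum (one group splits into two subgroups)."""
    n = len(_FIG1_SPECIES)
    idx = {s: i for i, s in enumerate(_FIG1_SPECIES)}
    signs = np.zeros((n, n), dtype=np.int8)

    def eats(consumer: str, resource: str) -> None:
        signs[idx[resource], idx[consumer]] = 1
        signs[idx[consumer], idx[resource]] = -1

    def mutualists(x: str, y: str) -> None:
        signs[idx[x], idx[y]] = 1
        signs[idx[y], idx[x]] = 1

    for c in ("c1", "c2", "c3"):
        for b in ("b1", "b2", "b3", "b4"):
            eats(c, b)
    for t in ("t1", "t2", "t3"):
        for c in ("c1", "c2", "c3"):
            eats(t, c)
    for b in ("b1", "b2"):
        for t in ("t1", "t2", "t3"):
            mutualists(b, t)

    return (
        SignedNetwork(_FIG1_SPECIES, signs),
        Partition(_FIG1_TRUE_GROUPS, _FIG1_SPECIES),
    )
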