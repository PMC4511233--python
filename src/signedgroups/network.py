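"""Signed directed interaction networks.

A community interaction web is stored as an ordered list of species labels
plus an S x S matrix with entries in {-1, 0, +1}: entry (i, j) is the sign
of the effect of species i (row) on the growth rate of species j (column).
Feeding, mutualism, competition, commensalism and amensalism are all
expressible as unordered pairs of such signed effects.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SignedNetwork",
    "PairType",
    "read_network",
    "write_network",
    "classify_pair",
    "pair_type_census",
    "subnetwork_by_type",
    "remove_species",
    "largest_weak_component",
]

_VALID_SIGNS = frozenset({-1, 0, 1})


class PairType(enum.Enum):
    """Interaction class of an unordered species pair, by its sign pair.

    The six classes exhaust every unordered combination of two signs drawn
    from {-1, 0, +1}; ``NONE`` is the absent interaction (0, 0).
    """

    TROPHIC = "trophic"          # (+, -): consumer-resource
    MUTUALISM = "mutualism"      # (+, +)
    COMPETITION = "competition"  # (-, -)
    COMMENSALISM = "commensalism"  # (+, 0)
    AMENSALISM = "amensalism"    # (-, 0)
    NONE = "none"                # (0, 0)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: nontrophic = every interacting class except consumer-resource pairs
NONTROPHIC_TYPES = frozenset(
    {PairType.MUTUALISM, PairType.COMPETITION, PairType.COMMENSALISM, PairType.AMENSALISM}
)


@dataclass(frozen=True)
class SignedNetwork:
    """An ordered species list plus a square signed adjacency matrix.

    Parameters
    ----------
    species
        Unique, order-stable string labels (length S).
    signs
        S x S integer matrix with entries in {-1, 0, +1}. Entry (i, j) is
        the sign of species i's effect on species j's growth rate.
        Diagonal entries (self effects) are allowed.
    """

    species: tuple[str, ...]
    signs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        signs = np.asarray(self.signs, dtype=np.int8)
        object.__setattr__(self, "signs", signs)
        object.__setattr__(self, "species", tuple(str(s) for s in self.species))
        if signs.ndim != 2 or signs.shape[0] != signs.shape[1]:
            raise ValueError(f"sign matrix must be square, got shape {signs.shape}")
        if len(self.species) != signs.shape[0]:
            raise ValueError(
                f"{len(self.species)} species labels but matrix is {signs.shape[0]}x{signs.shape[0]}"
            )
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        if not set(np.unique(signs)).issubset(_VALID_SIGNS):
            bad = sorted(set(np.unique(signs)) - _VALID_SIGNS)
            raise ValueError(f"sign entries must be in {{-1, 0, +1}}; found {bad}")
        signs.setflags(write=False)

    # -- derived counts -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_links(self) -> int:
        """L: number of nonzero entries (directed links, diagonal included)."""
        return int(np.count_nonzero(self.signs))

    @property
    def n_positive(self) -> int:
        """K: number of +1 entries."""
        return int(np.sum(self.signs == 1))

    @property
    def n_zeros(self) -> int:
        """Z = S^2 - L: number of zero cells, diagonal included."""
        return self.n_species**2 - self.n_links

    def index_of(self, label: str) -> int:
        try:
            return self.species.index(label)
        except ValueError:
            raise KeyError(f"unknown species label: {label!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return self.species == other.species and np.array_equal(self.signs, other.signs)

    def __hash__(self) -> int:
        return hash((self.species, self.signs.tobytes()))

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph view with a ``sign`` attribute on each edge."""
        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        rows, cols = np.nonzero(self.signs)
        for i, j in zip(rows, cols):
            g.add_edge(self.species[i], self.species[j], sign=int(self.signs[i, j]))
        return g


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------

def read_network(path, format: str = "edge-list", species=None) -> SignedNetwork:
    """Read a signed network from a text file.

    ``edge-list``: tab-separated with header ``source  target  sign``;
    signs are +1 / -1 integers and absent edges default to 0. ``matrix``:
    comma-separated square matrix with a label header row and labels in
    the first column.

    Parameters
    ----------
    path
        File to read.
    format
        ``"edge-list"`` or ``"matrix"``.
    species
        Optional explicit species order for edge lists; needed to include
        isolated species, otherwise labels are collected from the edges in
        order of first appearance.
    """
    if format == "edge-list":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        missing = {"source", "target", "sign"} - set(df.columns)
        if missing:
            raise ValueError(f"edge list is missing columns: {sorted(missing)}")
        if species is None:
            labels: list[str] = []
            for lab in itertools.chain(df["source"], df["target"]):
                if lab not in labels:
                    labels.append(lab)
        else:
            labels = [str(s) for s in species]
        idx = {lab: i for i, lab in enumerate(labels)}
        signs = np.zeros((len(labels), len(labels)), dtype=np.int8)
        seen: dict[tuple[int, int], int] = {}
        for src, tgt, sign in zip(df["source"], df["target"], df["sign"]):
            sign = int(sign)
            if sign not in (-1, 1):
                raise ValueError(f"edge sign must be +1 or -1, got {sign}")
            if src not in idx or tgt not in idx:
                raise ValueError(f"edge ({src}, {tgt}) uses a label outside the species list")
            key = (idx[src], idx[tgt])
            if key in seen and seen[key] != sign:
                raise ValueError(f"conflicting duplicate edge ({src}, {tgt}): signs {seen[key]} and {sign}")
            seen[key] = sign
            signs[key] = sign
        return SignedNetwork(tuple(labels), signs)
    if format == "matrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("matrix row labels must equal column labels (same order)")
        return SignedNetwork(tuple(str(s) for s in df.index), df.to_numpy(dtype=int))
    raise ValueError(f"unknown format: {format!r} (expected 'edge-list' or 'matrix')")


def write_network(net: SignedNetwork, path, format: str = "edge-list") -> None:
    """Write a network to ``path``; exact round trip with :func:`read_network`.

    Edge lists record only nonzero entries, so isolated species must be
    re-supplied on reading via the ``species`` argument.
    """
    if format == "edge-list":
        rows, cols = np.nonzero(net.signs)
        df = pd.DataFrame(
            {
                "source": [net.species[i] for i in rows],
                "target": [net.species[j] for j in cols],
                "sign": [int(net.signs[i, j]) for i, j in zip(rows, cols)],
            }
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "matrix":
        df = pd.DataFrame(net.signs, index=list(net.species), columns=list(net.species))
        df.to_csv(path)
    else:
        raise ValueError(f"unknown format: {format!r} (expected 'edge-list' or 'matrix')")


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------

_PAIR_TABLE = {
    frozenset({1, -1}): PairType.TROPHIC,
    frozenset({1}): PairType.MUTUALISM,
    frozenset({-1}): PairType.COMPETITION,
    frozenset({1, 0}): PairType.COMMENSALISM,
    frozenset({-1, 0}): PairType.AMENSALISM,
    frozenset({0}): PairType.NONE,
}


def classify_pair(sign_ij: int, sign_ji: int) -> PairType:
    """Classify an unordered pair of reciprocal signs into an interaction type.

    (+,-) is trophic (consumer-resource), (+,+) mutualism, (-,-) competition,
    (+,0) commensalism, (-,0) amensalism and (0,0) no interaction. The result
    is symmetric in its two arguments.
    """
    for s in (sign_ij, sign_ji):
        if s not in _VALID_SIGNS:
            raise ValueError(f"sign must be in {{-1, 0, +1}}, got {s}")
    return _PAIR_TABLE[frozenset({int(sign_ij), int(sign_ji)})]


def pair_type_census(net: SignedNetwork) -> dict[PairType, int]:
    """Count unordered off-diagonal species pairs by interaction type.

    Every pair i < j is counted exactly once; the counts over all six
    classes (including ``NONE``) sum to S(S-1)/2.
    """
    census = {pt: 0 for pt in PairType}
    s = net.signs
    for i in range(net.n_species):
        for j in range(i + 1, net.n_species):
            census[classify_pair(int(s[i, j]), int(s[j, i]))] += 1
    return census


def subnetwork_by_type(net: SignedNetwork, keep: set[PairType]) -> SignedNetwork:
    """Keep only interactions whose unordered-pair class is in ``keep``.

    Both directed entries of a retained pair survive; everything else is
    zeroed. Species are never dropped, and diagonal self-effects are kept
    unconditionally (they are not part of any unordered pair).
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep set must be non-empty")
    signs = np.array(net.signs, dtype=np.int8)
    for i in range(net.n_species):
        for j in range(i + 1, net.n_species):
            if classify_pair(int(signs[i, j]), int(signs[j, i])) not in keep:
                signs[i, j] = 0
                signs[j, i] = 0
    return SignedNetwork(net.species, signs)


def remove_species(net: SignedNetwork, labels) -> SignedNetwork:
    """Induced subnetwork after deleting ``labels``, preserving species order."""
    labels = set(labels)
    unknown = labels - set(net.species)
    if unknown:
        raise KeyError(f"unknown species labels: {sorted(unknown)}")
    keep = [i for i, s in enumerate(net.species) if s not in labels]
    return SignedNetwork(
        tuple(net.species[i] for i in keep), net.signs[np.ix_(keep, keep)]
    )


def largest_weak_component(net: SignedNetwork) -> SignedNetwork:
    """Induced subnetwork on the largest weakly connected component.

    Connectivity ignores both edge direction and sign. Ties between
    equal-sized components are broken toward the one containing the
    smallest species index.
    """
    if net.n_species == 0:
        raise ValueError("empty network has no components")
    graph = net.to_networkx()
    index = {s: i for i, s in enumerate(net.species)}
    components = [sorted(index[s] for s in comp) for comp in nx.weakly_connected_components(graph)]
    best = max(components, key=lambda c: (len(c), -c[0]))
    keep_labels = set(net.species) - {net.species[i] for i in best}
    return remove_species(net, keep_labels)
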