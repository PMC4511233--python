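"""End-to-end ablation workflow: fit groupings to a web and its
interaction-type ablations, then compare every pair of partitions.

Each variant of the input web (all interactions, trophic-only,
nontrophic-only, or with a species class removed) is reduced to its
largest weakly connected component, fit with the coupled-chain search,
and written out; all resulting partitions are then compared pairwise on
their common species, with significance stars at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .block_model import Partition, restrict_partition, write_partition
from .compare import ComparisonResult, compare
from .network import (
    PairType,
    SignedNetwork,
    largest_weak_component,
    remove_species,
    subnetwork_by_type,
)
from .search import SearchConfig, mc3_search

__all__ = ["Ablation", "RunConfig", "run_ablation_study", "significance_stars", "restrict_partition"]

TROPHIC_ONLY = frozenset({PairType.TROPHIC})
NONTROPHIC_ONLY = frozenset(
    {PairType.MUTUALISM, PairType.COMPETITION, PairType.COMMENSALISM, PairType.AMENSALISM}
)


@dataclass(frozen=True)
class Ablation:
    """One network variant: keep only some interaction types and/or drop species."""

    name: str
    keep_types: frozenset[PairType] | None = None
    drop_species: tuple[str, ...] = ()

    def apply(self, net: SignedNetwork) -> SignedNetwork:
        out = net
        if self.keep_types is not None:
            out = subnetwork_by_type(out, set(self.keep_types))
        if self.drop_species:
            out = remove_species(out, set(self.drop_species))
        return out


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full ablation study run."""

    ablations: tuple[Ablation, ...] = (
        Ablation("all"),
        Ablation("trophic", keep_types=TROPHIC_ONLY),
        Ablation("nontrophic", keep_types=NONTROPHIC_ONLY),
    )
    search: SearchConfig = field(default_factory=SearchConfig)
    n_randomizations: int = 10_000
    compare_on: tuple[str, ...] | None = None
    seed: int | None = None


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def run_ablation_study(
    net: SignedNetwork, config: RunConfig, out_dir: str | Path
) -> dict[str, object]:
    """Fit every ablation variant and compare all resulting partitions.

    Writes one partition TSV per variant, a pairwise ``comparisons.tsv``
    with MI, MI_max, p-values and stars, and a JSON run log recording the
    seed, scores and any component extraction applied.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base_seed = config.seed if config.seed is not None else (config.search.seed or 0)

    partitions: dict[str, Partition] = {}
    log: dict[str, object] = {"seed": base_seed, "variants": {}}
    for i, ablation in enumerate(config.ablations):
        variant = ablation.apply(net)
        component = largest_weak_component(variant)
        extracted = component.n_species < variant.n_species
        cfg = SearchConfig(
            n_chains=config.search.n_chains,
            temperatures=config.search.temperatures,
            n_sweeps=config.search.n_sweeps,
            seed=base_seed + 104729 * i,
            max_groups=config.search.max_groups,
            record_every=config.search.record_every,
            init_groups=config.search.init_groups,
        )
        result = mc3_search(component, cfg)
        partitions[ablation.name] = result.best_partition
        write_partition(result.best_partition, out_dir / f"partition_{ablation.name}.tsv")
        log["variants"][ablation.name] = {
            "n_species": component.n_species,
            "component_extracted": extracted,
            "n_groups": result.best_partition.n_groups,
            "log_marginal": result.best_log_marginal,
            "seed": cfg.seed,
        }

    names = list(partitions)
    rows = []
    for i, a_name in enumerate(names):
        for b_name in names[i + 1 :]:
            pa, pb = partitions[a_name], partitions[b_name]
            common = [s for s in pa.species if s in set(pb.species)]
            if config.compare_on is not None:
                wanted = set(config.compare_on)
                common = [s for s in common if s in wanted]
            if not common:
                raise ValueError(f"no common species between {a_name!r} and {b_name!r}")
            ra = restrict_partition(pa, common)
            rb = restrict_partition(pb, common)
            result: ComparisonResult = compare(
                ra, rb, n_reps=config.n_randomizations, rng=base_seed + 15485863
            )
            rows.append(
                {
                    "partition_a": a_name,
                    "partition_b": b_name,
                    "n_common_species": len(common),
                    "H_A": result.H_A,
                    "H_B": result.H_B,
                    "H_AB": result.H_AB,
                    "MI": result.MI,
                    "MI_max": result.MI_max,
                    "p_value": result.p_value,
                    "stars": significance_stars(result.p_value),
                }
            )
    comparisons = pd.DataFrame(rows)
    comparisons.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return {"partitions": partitions, "comparisons": comparisons, "log": log}
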