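"""Abundance and occupancy measures over a species x site count matrix.

Two spatial scales: the archipelago (all sites) and single islands
(their sites only).  Local abundance per species is the mean over its
*occupied* sites — the sum of all its individuals divided by the number
of sites where it occurs — so species absent from a domain carry no row
rather than a zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd

__all__ = ["Domain", "summarize", "richness_by_category"]


@dataclass(frozen=True)
class Domain:
    """A spatial scope: the whole archipelago or one island.

    ``site_island`` maps every site code to its island code; the domain
    restricts the matrix to its own sites.
    """

    site_island: Mapping[str, str]
    scope: str = "archipelago"  # "archipelago" or "island:<code>"

    @property
    def sites(self) -> list[str]:
        if self.scope == "archipelago":
            return sorted(self.site_island)
        island = self.island
        return sorted(s for s, i in self.site_island.items() if i == island)

    @property
    def islands(self) -> list[str]:
        if self.scope == "archipelago":
            return sorted(set(self.site_island.values()))
        return [self.island]

    @property
    def island(self) -> str | None:
        if self.scope.startswith("island:"):
            return self.scope.split(":", 1)[1]
        return None

    def __post_init__(self) -> None:
        if self.scope != "archipelago" and not self.scope.startswith("island:"):
            raise ValueError(f"bad scope {self.scope!r}")
        if not self.site_island:
            raise ValueError("empty domain")
        if self.island is not None and self.island not in set(
            self.site_island.values()
        ):
            raise ValueError(f"unknown island {self.island!r}")


def summarize(matrix: pd.DataFrame, domain: Domain) -> pd.DataFrame:
    """Per-species abundance/occupancy summary within a domain.

    ``matrix`` is species x site (integer counts).  Returns one row per
    species *present* in the domain with columns: total_individuals,
    occupied_sites, total_sites, mean_site_abundance, occupancy_sites,
    occupied_islands, total_islands, occupancy_islands.
    """
    sites = domain.sites
    if not any(s in matrix.columns for s in sites):
        raise ValueError("domain has no sites in the matrix")
    # sites sampled but empty of species carry zero columns
    sub = matrix.reindex(columns=sites, fill_value=0)
    present = sub.sum(axis=1) > 0
    sub = sub.loc[present]
    occ_sites = (sub > 0).sum(axis=1)
    total = sub.sum(axis=1)
    islands_of = pd.Series({s: domain.site_island[s] for s in sites})
    occupied_islands = (
        (sub > 0)
        .T.groupby(islands_of)
        .any()
        .sum(axis=0)
    )
    n_sites = len(sites)
    n_islands = len(domain.islands)
    out = pd.DataFrame(
        {
            "total_individuals": total,
            "occupied_sites": occ_sites,
            "total_sites": n_sites,
            "mean_site_abundance": total / occ_sites,
            "occupancy_sites": occ_sites / n_sites,
            "occupied_islands": occupied_islands,
            "total_islands": n_islands,
            "occupancy_islands": occupied_islands / n_islands,
        }
    )
    out.index.name = "species"
    return out


def richness_by_category(
    matrix: pd.DataFrame,
    traits: pd.DataFrame,
    domain: Domain,
    category: str = "dispersal",
    grouping: Literal["site", "island"] = "site",
) -> pd.DataFrame:
    """Per-site (or per-island) species richness split by a trait column.

    Species missing from ``traits`` count under ``unknown``.  Column sums
    per unit equal total richness of the unit.
    """
    sites = domain.sites
    cat = traits.set_index("species")[category] if len(traits) else pd.Series(dtype=object)
    cat = cat.reindex(matrix.index).fillna("unknown")
    present = matrix.reindex(columns=sites, fill_value=0) > 0
    if grouping == "island":
        islands_of = pd.Series({s: domain.site_island[s] for s in sites})
        present = present.T.groupby(islands_of).any().T
    out = present.groupby(cat).sum().T
    out.index.name = grouping
    out.columns.name = category
    return out.astype(int)
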