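"""Species trait categorization: dispersal ability and niche breadth.

Dispersal is a family-level lookup (ballooning vs non-ballooning —
passive aerial dispersal on silk is strongly conserved within spider
families, so a published family table suffices).  Niche breadth
(laurel-forest specialist vs non-specialist) uses a two-step procedure:
an expert panel first (consensus, else majority, of at least
``min_voters`` votes), then a quantitative fallback that thresholds the
percentage of a species' occupied 500 x 500 m grid cells lying in
habitat, at a quantile of the expert-classified specialists'
percentages.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HabitatOccupancyRecord",
    "ballooning_lookup",
    "expert_step",
    "habitat_threshold",
    "quantile_step",
    "classify_niche",
    "build_trait_table",
]

SPECIALIST = "specialist"
NON_SPECIALIST = "non-specialist"
UNCATEGORIZED = "uncategorized"
ABSTAIN = "abstain"


@dataclass(frozen=True)
class HabitatOccupancyRecord:
    """Occupied-cell summary for one species: how many 500 x 500 m cells
    it occupies archipelago-wide and what percentage are habitat."""

    species: str
    n_cells: int
    pct_habitat: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.pct_habitat <= 100.0:
            raise ValueError("pct_habitat must be in [0, 100]")


def ballooning_lookup(family: str, table: Mapping[str, str]) -> str:
    """Family-level dispersal category; ``unknown`` if the family is
    absent from the lookup table."""
    return table.get(family, "unknown")


def expert_step(
    votes: pd.DataFrame, min_voters: int = 2
) -> dict[str, str | None]:
    """First classification step: the expert panel.

    ``votes`` has columns (species, expert, vote) with votes in
    {specialist, non-specialist, abstain}.  Species with fewer than
    ``min_voters`` non-abstaining votes, or with a tied vote, map to
    ``None`` (deferred to the quantitative step).
    """
    out: dict[str, str | None] = {}
    for species, grp in votes.groupby("species"):
        cast = [v for v in grp["vote"] if v != ABSTAIN]
        if len(cast) < min_voters:
            out[species] = None
            continue
        tally = Counter(cast)
        (top, n_top), *rest = tally.most_common()
        if rest and rest[0][1] == n_top:
            out[species] = None  # tie
        else:
            out[species] = top
    return out


def habitat_threshold(
    expert_specialist_pcts: Sequence[float], q: float = 0.50
) -> float:
    """Quantile of the expert-classified specialists' habitat
    percentages, used as the step-2 cut-off.

    Linear interpolation between order statistics (R type 7 / numpy
    default).
    """
    if len(expert_specialist_pcts) == 0:
        raise ValueError("need at least one expert-classified specialist")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    return float(np.quantile(np.asarray(expert_specialist_pcts, float), q))


def quantile_step(
    records: Iterable[HabitatOccupancyRecord],
    threshold: float,
    specialist_at_threshold: bool = True,
) -> dict[str, str]:
    """Second step: threshold on per-species habitat percentage.

    Species at or above the threshold are specialists (``>=`` keeps
    100%-habitat species from being dropped; set
    ``specialist_at_threshold=False`` for a strict ``>``).
    """
    out: dict[str, str] = {}
    for rec in records:
        above = (
            rec.pct_habitat >= threshold
            if specialist_at_threshold
            else rec.pct_habitat > threshold
        )
        out[rec.species] = SPECIALIST if above else NON_SPECIALIST
    return out


def classify_niche(
    species: Sequence[str],
    votes: pd.DataFrame,
    habitat: Iterable[HabitatOccupancyRecord],
    q: float = 0.50,
    min_voters: int = 2,
) -> pd.DataFrame:
    """Run both steps and return (species, niche, niche_source).

    Each species gets exactly one of: an expert category, a quantile
    category (if the experts deferred and distribution records exist),
    or ``uncategorized``.
    """
    habitat = list(habitat)
    by_species = {r.species: r for r in habitat}
    expert = expert_step(votes, min_voters=min_voters)
    specialist_pcts = [
        by_species[sp].pct_habitat
        for sp, cat in expert.items()
        if cat == SPECIALIST and sp in by_species
    ]
    thr = habitat_threshold(specialist_pcts, q) if specialist_pcts else None
    rows = []
    for sp in species:
        cat = expert.get(sp)
        if cat is not None:
            rows.append((sp, cat, "expert"))
        elif sp in by_species and thr is not None:
            rows.append(
                (sp, quantile_step([by_species[sp]], thr)[sp], "quantile")
            )
        else:
            rows.append((sp, UNCATEGORIZED, "none"))
    return pd.DataFrame(rows, columns=["species", "niche", "niche_source"])


def build_trait_table(
    species_families: Mapping[str, str],
    family_table: Mapping[str, str],
    votes: pd.DataFrame,
    habitat: Iterable[HabitatOccupancyRecord],
    q: float = 0.50,
    min_voters: int = 2,
) -> pd.DataFrame:
    """Full trait table: dispersal + niche per species.

    ``species_families`` maps species -> taxonomic family; every species
    in it gets a row, so the table always covers the count matrix.
    """
    niche = classify_niche(
        list(species_families), votes, habitat, q=q, min_voters=min_voters
    ).set_index("species")
    rows = []
    for sp, fam in species_families.items():
        rows.append(
            (
                sp,
                ballooning_lookup(fam, family_table),
                niche.loc[sp, "niche"],
                niche.loc[sp, "niche_source"],
            )
        )
    return pd.DataFrame(
        rows, columns=["species", "dispersal", "niche", "niche_source"]
    )
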