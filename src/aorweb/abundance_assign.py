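"""Extrapolate species (PBS) abundances to unsequenced individuals.

Only a few individuals per parataxonomic unit (PU) per site are
sequenced; the rest inherit a species identity by site-level
proportional assignment.  If every sequenced member of a PU belongs to
one species, the whole PU does.  Otherwise the unsequenced remainder at
each site is split according to the proportions observed among the
sequenced individuals at that site, using largest-remainder
apportionment so that integer counts are conserved exactly (naive
per-quota rounding can create or destroy individuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd

__all__ = [
    "PUCountTable",
    "UnresolvedSiteError",
    "largest_remainder",
    "assign_counts",
    "merge_assignments",
    "to_matrix",
]

FallbackPolicy = Literal["island", "global", "strict"]


class UnresolvedSiteError(ValueError):
    """A multi-species PU has no sequenced individuals at a site and the
    fallback policy is strict."""


@dataclass
class PUCountTable:
    """All collected individuals per (pu, site), plus the sequenced subset
    with species identities.

    Parameters
    ----------
    counts : DataFrame with columns (pu, site, n) — every individual
        collected, sequenced or not.
    sequenced : DataFrame with columns (pu, site, pbs, n) — the sequenced
        individuals only.
    site_island : optional mapping site -> island, needed for the
        island-level fallback.
    """

    counts: pd.DataFrame
    sequenced: pd.DataFrame
    site_island: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts[["pu", "site", "n"]].copy()
        self.sequenced = self.sequenced[["pu", "site", "pbs", "n"]].copy()
        if (self.counts["n"] < 0).any() or (self.sequenced["n"] < 0).any():
            raise ValueError("counts must be non-negative")
        seq_tot = (
            self.sequenced.groupby(["pu", "site"])["n"].sum().rename("seq")
        )
        merged = (
            self.counts.set_index(["pu", "site"])["n"]
            .to_frame()
            .join(seq_tot, how="outer")
            .fillna(0)
        )
        bad = merged[merged["seq"] > merged["n"]]
        if len(bad):
            raise ValueError(
                f"sequenced exceeds collected at {list(bad.index[:5])}"
            )


def largest_remainder(proportions: Mapping[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` integer units by ``proportions``.

    Quotas ``p_i * total`` are floored; leftover units go to the largest
    fractional remainders, ties broken by key (ascending).  The result
    always sums to ``total``.
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    psum = sum(proportions.values())
    if psum <= 0:
        raise ValueError("proportions must sum to a positive value")
    quotas = {k: v / psum * total for k, v in proportions.items()}
    out = {k: int(q) for k, q in quotas.items()}
    leftover = total - sum(out.values())
    by_frac = sorted(
        quotas, key=lambda k: (-(quotas[k] - out[k]), k)
    )
    for k in by_frac[:leftover]:
        out[k] += 1
    return out


def _proportions(seq: pd.DataFrame) -> dict[str, float]:
    tot = seq["n"].sum()
    return {row.pbs: row.n / tot for row in seq.itertuples()}


def assign_counts(
    table: PUCountTable, fallback: FallbackPolicy = "island"
) -> pd.DataFrame:
    """Assign every collected individual to a species.

    Returns a long-format DataFrame (pbs, site, n) whose per-(pu, site)
    totals equal the input counts exactly.  Sequenced individuals keep
    their own identities; only the unsequenced remainder is apportioned.

    For a multi-species PU with no sequenced individuals at a site, the
    ``fallback`` policy decides which proportions to borrow: ``island``
    uses the PU's sequenced individuals on the same island (then global),
    ``global`` pools across all sites, ``strict`` raises
    :class:`UnresolvedSiteError`.
    """
    if fallback not in ("island", "global", "strict"):
        raise ValueError(f"unknown fallback policy {fallback!r}")
    seq = table.sequenced
    pbs_per_pu = seq.groupby("pu")["pbs"].nunique()
    missing = set(table.counts["pu"]) - set(pbs_per_pu.index)
    if missing:
        raise ValueError(
            f"PUs with no sequenced individuals anywhere: {sorted(missing)}"
        )

    rows: list[tuple[str, str, int]] = []
    for rec in table.counts.itertuples():
        pu, site, n_total = rec.pu, rec.site, int(rec.n)
        pu_seq = seq[seq["pu"] == pu]
        if pbs_per_pu[pu] == 1:
            rows.append((pu_seq["pbs"].iloc[0], site, n_total))
            continue
        here = pu_seq[pu_seq["site"] == site]
        n_seq_here = int(here["n"].sum())
        n_unseq = n_total - n_seq_here
        # sequenced individuals keep their identities
        for r in here.itertuples():
            rows.append((r.pbs, site, int(r.n)))
        if n_unseq == 0:
            continue
        if n_seq_here > 0:
            props = _proportions(here.groupby("pbs", as_index=False)["n"].sum())
        elif fallback == "strict":
            raise UnresolvedSiteError(
                f"PU {pu!r} maps to multiple species but has no sequenced "
                f"individuals at site {site!r}"
            )
        else:
            props = None
            if fallback == "island" and table.site_island:
                island = table.site_island.get(site)
                island_sites = {
                    s for s, isl in table.site_island.items() if isl == island
                }
                near = pu_seq[pu_seq["site"].isin(island_sites)]
                if len(near):
                    props = _proportions(
                        near.groupby("pbs", as_index=False)["n"].sum()
                    )
            if props is None:  # global pool
                props = _proportions(
                    pu_seq.groupby("pbs", as_index=False)["n"].sum()
                )
        alloc = largest_remainder(props, n_unseq)
        rows.extend((pbs, site, k) for pbs, k in alloc.items() if k > 0)

    out = (
        pd.DataFrame(rows, columns=["pbs", "site", "n"])
        .groupby(["pbs", "site"], as_index=False)["n"]
        .sum()
    )
    return out


def merge_assignments(
    species_long: pd.DataFrame,
    assignments,
) -> pd.DataFrame:
    """Reconcile a species x site count table with delimitation output.

    Species flagged ``REMOVED_INCOMPLETE_SORTING`` are dropped; nothing
    else changes (PUs merged into one PBS already share a pbs id by the
    time counts are assigned).  ``assignments`` is the list of
    :class:`~aorweb.seq_delim.PBSAssignment`.
    """
    from .seq_delim import PBSStatus

    known = {a.pbs_id for a in assignments}
    unknown = set(species_long["pbs"]) - known
    if unknown:
        raise ValueError(f"unknown pbs ids: {sorted(unknown)}")
    removed = {
        a.pbs_id
        for a in assignments
        if a.status == PBSStatus.REMOVED_INCOMPLETE_SORTING
    }
    out = species_long[~species_long["pbs"].isin(removed)].reset_index(drop=True)
    return out


def to_matrix(long: pd.DataFrame) -> pd.DataFrame:
    """Long (pbs, site, n) -> wide species x site integer matrix."""
    return (
        long.pivot_table(index="pbs", columns="site", values="n", fill_value=0)
        .astype(int)
        .sort_index()
    )
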