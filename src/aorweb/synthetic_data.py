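"""Synthetic community data with the structure the pipeline assumes.

Every input the analysis chain consumes can be generated here:
species-structured COI alignments whose within/between-species
divergences straddle the delimitation threshold, parataxonomic labels
with controllable split/lump errors, a site x species count matrix in
which occupancy is a logistic function of log mean abundance with
category-specific intercepts and slopes, expert votes with a flip rate,
habitat-cell occupancy records, and pure-birth trees carrying Brownian
traits.  A fixed seed gives identical output on every run.

Sequence evolution uses the Kimura two-parameter process exactly: for a
branch of expected length d substitutions/site with transition/
transversion rate ratio kappa, each site mutates independently with the
closed-form K2P transition and transversion probabilities, so pairwise
K2P distance estimates are unbiased for the branch-length sums.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .seq_delim import SequenceRecord

__all__ = [
    "SimConfig",
    "sim_sequences",
    "sim_pu_labels",
    "sim_metacommunity",
    "recovery_table",
    "sim_votes",
    "sim_habitat",
    "sim_tree_and_trait",
    "write_dataset",
]

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
# index arithmetic: A=0 C=1 G=2 T=3; transition partner of i
_TS_PARTNER = np.array([2, 3, 0, 1])
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Defaults mirror a Canary-Islands-style laurel-forest spider survey:
    123 species across 4 islands with a 14/7/6/4 site pattern, COI
    length 658, an intraspecific/interspecific divergence gap straddling
    the 6.8% threshold, lognormal mean site abundance, and
    dispersal-category-specific occupancy curves with the intercepts and
    slopes of the fitted archipelago AOR (ballooning -2.0816/1.5101,
    non-ballooning -2.9312/1.9871).
    """

    seed: int = 0
    n_species: int = 123
    mean_individuals: float = 6.0  # sequenced individuals/species, >=2
    seq_length: int = 658
    intra_divergence: float = 0.01
    inter_divergence: float = 0.12
    ts_tv_ratio: float = 3.0
    pu_split_rate: float = 0.0
    pu_lump_rate: float = 0.0
    n_islands: int = 4
    sites_per_island: tuple[int, ...] = (14, 7, 6, 4)
    abundance_log_mean: float = 1.2
    abundance_log_sd: float = 1.1
    # occupancy ~ logistic(intercept + slope * log abundance), per category
    occupancy_coefs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ballooning": (-2.0816, 1.5101),
            "non-ballooning": (-2.9312, 1.9871),
        }
    )
    # which trait drives occupancy: "dispersal", "niche", or "both"
    # (for "both", occupancy_coefs is keyed "dispersal|niche")
    coef_on: str = "dispersal"
    p_ballooning: float = 0.51
    p_specialist: float = 0.36
    n_experts: int = 5
    expert_error: float = 0.0
    expert_abstain: float = 0.0
    birth_rate: float = 1.0
    bm_sigma2: float = 1.0

    def __post_init__(self) -> None:
        if self.intra_divergence >= self.inter_divergence:
            raise ValueError(
                "intra-species divergence target must be below the "
                "inter-species target"
            )
        for name in ("pu_split_rate", "pu_lump_rate", "p_ballooning",
                     "p_specialist", "expert_error", "expert_abstain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.sites_per_island) != self.n_islands:
            raise ValueError("sites_per_island length must equal n_islands")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, salt])
        )

    @property
    def site_island(self) -> dict[str, str]:
        out = {}
        k = 0
        for i, n_sites in enumerate(self.sites_per_island):
            island = f"I{i + 1}"
            for _ in range(n_sites):
                k += 1
                out[f"S{k:02d}"] = island
        return out


def _k2p_site_probs(d: float, kappa: float) -> tuple[float, float]:
    """Probability of a site showing a transition (P) or a transversion
    (Q, both types together) after expected distance d."""
    bt = d / (kappa + 2.0)
    at = kappa * bt
    p = 0.25 + 0.25 * math.exp(-4.0 * bt) - 0.5 * math.exp(-2.0 * (at + bt))
    q = 0.5 - 0.5 * math.exp(-4.0 * bt)
    return p, q


def _evolve(seq: np.ndarray, d: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    p, q = _k2p_site_probs(d, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    ts = u < p
    out[ts] = _TS_PARTNER[seq[ts]]
    tv = (u >= p) & (u < p + q)
    which = rng.integers(0, 2, size=int(tv.sum()))
    out[tv] = _TV_PARTNERS[seq[tv], which]
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def sim_sequences(
    cfg: SimConfig,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Simulate one aligned COI fragment per individual.

    Species ancestors radiate from a common root with branch length
    inter_divergence/2 each (so between-species pairs sit near the inter
    target); individuals hang off their species ancestor at
    intra_divergence/2 (within-species pairs near the intra target).
    Returns the records (PU label = true species unless relabelled by
    :func:`sim_pu_labels`) and the individual -> true species map.
    """
    rng = cfg.rng(salt=1)
    sites = list(cfg.site_island)
    islands = cfg.site_island
    root = rng.integers(0, 4, size=cfg.seq_length)
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    for s in range(cfg.n_species):
        species = f"SP{s + 1:03d}"
        anc = _evolve(root, cfg.inter_divergence / 2.0, cfg.ts_tv_ratio, rng)
        n_ind = 2 + rng.poisson(max(cfg.mean_individuals - 2.0, 0.0))
        for i in range(n_ind):
            ind = f"{species}_{i + 1:02d}"
            seq = _evolve(anc, cfg.intra_divergence / 2.0, cfg.ts_tv_ratio, rng)
            site = sites[rng.integers(0, len(sites))]
            records.append(
                SequenceRecord(
                    individual_id=ind,
                    sequence=_to_str(seq),
                    pu=species.replace("SP", "PU"),
                    site=site,
                    island=islands[site],
                    family=f"FAM{s % 10 + 1:02d}",
                )
            )
            truth[ind] = species
    return records, truth


def sim_pu_labels(
    records: Sequence[SequenceRecord],
    truth: Mapping[str, str],
    cfg: SimConfig,
) -> list[SequenceRecord]:
    """Inject parataxonomic labelling error.

    With probability ``pu_split_rate`` a species' individuals are split
    across two PU labels (over-splitting by the parataxonomist); with
    probability ``pu_lump_rate`` a species shares its PU label with the
    next species (under-splitting / cryptic pair).
    """
    rng = cfg.rng(salt=2)
    species = sorted(set(truth.values()))
    pu_of = {sp: sp.replace("SP", "PU") for sp in species}
    split = {sp for sp in species if rng.random() < cfg.pu_split_rate}
    lumped: dict[str, str] = {}
    for a, b in zip(species[::2], species[1::2]):
        if rng.random() < cfg.pu_lump_rate:
            lumped[b] = pu_of[a]
    out = []
    for r in records:
        sp = truth[r.individual_id]
        pu = lumped.get(sp, pu_of[sp])
        if sp in split and rng.random() < 0.5:
            pu = pu + "b"
        out.append(
            SequenceRecord(
                individual_id=r.individual_id,
                sequence=r.sequence,
                pu=pu,
                site=r.site,
                island=r.island,
                family=r.family,
            )
        )
    return out


def sim_metacommunity(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site x species counts plus the true trait table.

    Per species: dispersal and niche categories are independent draws;
    mean site abundance lambda is lognormal; each site is occupied
    independently with probability logistic(intercept_c + slope_c *
    log(lambda)) where c is the species' ``coef_on`` category; counts at
    occupied sites are zero-truncated Poisson(lambda), so occupancy and
    abundance stay separable (occupied means at least one individual).

    Returns (counts long DataFrame with columns species/site/n, traits
    DataFrame with species/dispersal/niche/lambda).
    """
    rng = cfg.rng(salt=3)
    sites = list(cfg.site_island)
    rows = []
    traits = []
    for s in range(cfg.n_species):
        species = f"SP{s + 1:03d}"
        dispersal = (
            "ballooning" if rng.random() < cfg.p_ballooning else "non-ballooning"
        )
        niche = (
            "specialist" if rng.random() < cfg.p_specialist else "non-specialist"
        )
        lam = float(
            rng.lognormal(cfg.abundance_log_mean, cfg.abundance_log_sd)
        )
        if cfg.coef_on == "dispersal":
            cat = dispersal
        elif cfg.coef_on == "niche":
            cat = niche
        elif cfg.coef_on == "both":
            cat = f"{dispersal}|{niche}"
        else:
            raise ValueError(f"unknown coef_on {cfg.coef_on!r}")
        intercept, slope = cfg.occupancy_coefs[cat]
        p_occ = 1.0 / (1.0 + math.exp(-(intercept + slope * math.log(lam))))
        occupied = rng.random(len(sites)) < p_occ
        for site, occ in zip(sites, occupied):
            if not occ:
                continue
            # zero-truncated Poisson via inverse-cdf shift
            n = int(rng.poisson(lam))
            while n == 0:
                n = int(rng.poisson(lam))
            rows.append((species, site, n))
        traits.append((species, dispersal, niche, lam))
    counts = pd.DataFrame(rows, columns=["species", "site", "n"])
    truth = pd.DataFrame(
        traits, columns=["species", "dispersal", "niche", "lambda"]
    )
    return counts, truth


def recovery_table(cfg: SimConfig) -> pd.DataFrame:
    """Species table for parameter-recovery checks.

    Unlike a field survey, the simulation knows every species — including
    those that happened to occupy zero sites — and each species' true
    mean abundance.  Regressing occupancy (including zeros) on the true
    log abundance avoids the truncation that conditioning on observed
    species would induce, so fitted coefficients are directly comparable
    to the generator's.
    """
    counts, traits = sim_metacommunity(cfg)
    occ = counts.groupby("species")["site"].nunique()
    tab = traits.set_index("species")
    tab["occupied_sites"] = occ.reindex(tab.index).fillna(0).astype(int)
    tab["total_sites"] = len(cfg.site_island)
    tab["log_abundance"] = np.log(tab["lambda"])
    return tab.reset_index()


def sim_votes(true_niche: Mapping[str, str], cfg: SimConfig) -> pd.DataFrame:
    """Expert votes: each expert either abstains or reports the true
    niche category, flipped with probability ``expert_error``."""
    rng = cfg.rng(salt=4)
    flip = {"specialist": "non-specialist", "non-specialist": "specialist"}
    rows = []
    for sp in sorted(true_niche):
        for e in range(cfg.n_experts):
            if rng.random() < cfg.expert_abstain:
                vote = "abstain"
            elif rng.random() < cfg.expert_error:
                vote = flip[true_niche[sp]]
            else:
                vote = true_niche[sp]
            rows.append((sp, f"expert{e + 1}", vote))
    return pd.DataFrame(rows, columns=["species", "expert", "vote"])


def sim_habitat(true_niche: Mapping[str, str], cfg: SimConfig) -> pd.DataFrame:
    """Habitat-cell records: specialists concentrate in habitat cells
    (Beta(8,1) percentages), non-specialists spread out (Beta(2,4))."""
    rng = cfg.rng(salt=5)
    rows = []
    for sp in sorted(true_niche):
        if true_niche[sp] == "specialist":
            pct = 100.0 * rng.beta(8.0, 1.0)
        else:
            pct = 100.0 * rng.beta(2.0, 4.0)
        n_cells = 1 + int(rng.lognormal(2.5, 1.0))
        rows.append((sp, n_cells, round(pct, 1)))
    return pd.DataFrame(rows, columns=["species", "n_cells", "pct_habitat"])


def sim_tree_and_trait(
    cfg: SimConfig, n_tips: int | None = None
) -> tuple[dendropy.Tree, dict[str, float]]:
    """Pure-birth (Yule) ultrametric tree plus a Brownian trait.

    Speciation waiting times are exponential with rate (birth_rate x
    number of extant lineages); the clock runs one extra waiting period
    after the last split so terminal branches have positive length.  The
    trait diffuses from 0 at the root with variance bm_sigma2 per unit
    time.
    """
    rng = cfg.rng(salt=6)
    n = n_tips if n_tips is not None else cfg.n_species
    if n < 2:
        raise ValueError("need at least 2 tips")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.birth_time = 0.0
    tree.seed_node.order = 0
    active = [tree.seed_node]
    t = 0.0
    n_created = 1
    while len(active) < n:
        t += rng.exponential(1.0 / (cfg.birth_rate * len(active)))
        idx = rng.integers(0, len(active))
        parent = active.pop(idx)
        parent.split_time = t
        for _ in range(2):
            child = parent.new_child()
            child.birth_time = t
            child.order = n_created
            n_created += 1
            active.append(child)
    t += rng.exponential(1.0 / (cfg.birth_rate * n))
    for i, leaf in enumerate(sorted(active, key=lambda nd: nd.order)):
        leaf.taxon = taxa.new_taxon(label=f"SP{i + 1:03d}")
    for nd in tree.preorder_node_iter():
        end = getattr(nd, "split_time", t)
        nd.edge.length = end - nd.birth_time
    # Brownian trait along branches
    trait: dict[str, float] = {}
    values = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        parent_val = values[id(nd.parent_node)]
        step = rng.normal(0.0, math.sqrt(cfg.bm_sigma2 * nd.edge.length))
        values[id(nd)] = parent_val + step
        if nd.is_leaf():
            trait[nd.taxon.label] = values[id(nd)]
    return tree, trait


def write_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a full synthetic dataset as plain-text files.

    FASTA + metadata CSV (sequences), counts CSV, votes CSV, habitat
    CSV, Newick tree, trait CSV and a truth.json; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = sim_sequences(cfg)
    records = sim_pu_labels(records, truth, cfg)
    counts, traits = sim_metacommunity(cfg)
    votes = sim_votes(dict(zip(traits["species"], traits["niche"])), cfg)
    habitat = sim_habitat(dict(zip(traits["species"], traits["niche"])), cfg)
    tree, trait = sim_tree_and_trait(cfg)

    paths = {}
    fasta = outdir / "sequences.fasta"
    with open(fasta, "w") as fh:
        for r in records:
            fh.write(f">{r.individual_id}\n{r.sequence}\n")
    paths["fasta"] = fasta
    meta = pd.DataFrame(
        [
            (r.individual_id, r.pu, r.site, r.island, r.family)
            for r in records
        ],
        columns=["individual_id", "pu", "site", "island", "family"],
    )
    for name, df in (
        ("metadata", meta),
        ("counts", counts),
        ("votes", votes),
        ("habitat", habitat),
        ("traits", traits),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    newick = outdir / "tree.nwk"
    tree.write(path=str(newick), schema="newick")
    paths["tree"] = newick
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "individual_species": truth,
                "bm_trait": trait,
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(cfg).items()
                    if not isinstance(v, Mapping)
                },
            },
            fh,
            indent=1,
        )
    paths["truth"] = truth_path
    return paths
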