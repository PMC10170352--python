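"""Distance-threshold species delimitation from COI barcodes.

Individuals arrive pre-aligned, each labelled with a parataxonomic unit
(PU) assigned from external morphology in the field.  Delimitation
proceeds in four steps: Kimura two-parameter (K2P) pairwise distances,
UPGMA clustering, a flat cut of the dendrogram at a maximum
intraspecific divergence threshold (default 6.8%) yielding *lineages*,
and a rule cascade that reconciles lineages with PU labels into
presumed biological species (PBS).

The rule cascade mirrors standard parataxonomy-plus-barcoding practice:

1. a lineage holding every individual of exactly one PU is one PBS;
2. a PU that segregates across lineages is flagged for human revision
   (assignment error or contamination) — never auto-resolved;
3. several PUs in one lineage with no morphological distinction merge
   into one PBS;
4. morphologically distinct PUs that are each monophyletic within the
   lineage are split into one PBS each;
5. morphologically distinct PUs without mtDNA segregation are removed
   as putative incomplete lineage sorting / gene flow.

Morphological distinctness is user-declared input (it came from experts,
not from sequence data).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SequenceRecord",
    "PairwiseComparison",
    "Dendrogram",
    "DendrogramNode",
    "LineageSummary",
    "PBSAssignment",
    "PBSStatus",
    "DelimitationConfig",
    "SaturatedDistanceError",
    "NoOverlapError",
    "k2p_distance",
    "pairwise_distances",
    "upgma",
    "cut_lineages",
    "summarize_lineages",
    "infer_pbs",
    "delimit",
]

#: transitions are purine<->purine and pyrimidine<->pyrimidine swaps
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class NoOverlapError(ValueError):
    """No site at which both sequences carry an unambiguous base."""


class SaturatedDistanceError(ValueError):
    """The K2P log arguments are non-positive; the distance is undefined."""


@dataclass(frozen=True)
class SequenceRecord:
    """One individual's aligned COI sequence plus field metadata.

    A trailing ``x`` on the PU label marks a type II PU (distinct within
    its plot but hard to cross-reference between plots).
    """

    individual_id: str
    sequence: str
    pu: str
    site: str
    island: str
    family: str = ""

    def __post_init__(self) -> None:
        if not self.pu or not self.site or not self.island:
            raise ValueError(
                f"record {self.individual_id!r}: pu/site/island must be non-empty"
            )

    @property
    def type_ii(self) -> bool:
        return self.pu.endswith("x")


@dataclass(frozen=True)
class PairwiseComparison:
    """Site-pattern proportions and the K2P distance for one pair.

    ``p`` and ``q`` are the transition and transversion proportions over
    the ``n_sites`` alignment columns that survive pairwise deletion.
    """

    p: float
    q: float
    n_sites: int
    d: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    return arr


def k2p_distance(a: str, b: str) -> PairwiseComparison:
    """Kimura two-parameter distance between two aligned sequences.

    Sites where either sequence has a gap or an ambiguous base are
    dropped (pairwise deletion).  With transition proportion ``p`` and
    transversion proportion ``q``,

        d = -1/2 ln(1 - 2p - q) - 1/4 ln(1 - 2q)

    Raises
    ------
    NoOverlapError
        if no site has unambiguous bases in both sequences.
    SaturatedDistanceError
        if ``1 - 2p - q <= 0`` or ``1 - 2q <= 0``.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal sequence lengths: {len(a)} vs {len(b)}")
    xa, xb = _encode(a), _encode(b)
    valid = np.isin(xa, (b"A", b"C", b"G", b"T")) & np.isin(
        xb, (b"A", b"C", b"G", b"T")
    )
    n = int(valid.sum())
    if n == 0:
        raise NoOverlapError("no comparable sites after pairwise deletion")
    xa, xb = xa[valid], xb[valid]
    diff = xa != xb
    pur_a = (xa == b"A") | (xa == b"G")
    pur_b = (xb == b"A") | (xb == b"G")
    transitions = int((diff & (pur_a == pur_b)).sum())
    transversions = int((diff & (pur_a != pur_b)).sum())
    p = transitions / n
    q = transversions / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError(
            f"saturated pair (p={p:.4f}, q={q:.4f}): K2P distance undefined"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    # exact zero for identical overlap, avoiding -0.0
    return PairwiseComparison(p=p, q=q, n_sites=n, d=abs(d))


def pairwise_distances(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Symmetric K2P distance matrix over ``records`` (zero diagonal).

    Any saturated pair aborts the computation; the error lists the
    offending individuals so they can be excluded as putative
    contamination rather than silently clamped.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    n = len(records)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(n), 2):
        try:
            d[i, j] = d[j, i] = k2p_distance(
                records[i].sequence, records[j].sequence
            ).d
        except SaturatedDistanceError:
            saturated.append((records[i].individual_id, records[j].individual_id))
    if saturated:
        raise SaturatedDistanceError(f"saturated pairs: {saturated}")
    return d


# ---------------------------------------------------------------------------
# UPGMA dendrogram
# ---------------------------------------------------------------------------


@dataclass
class DendrogramNode:
    """Node of a UPGMA merge tree; ``height`` is the average inter-cluster
    distance at which its two children merged (0 for tips)."""

    height: float
    label: str | None = None  # tip label, None for internal nodes
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_tip(self) -> bool:
        return self.children is None

    def tips(self) -> list[str]:
        if self.is_tip:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        stack = [self]
        res: list[str] = []
        while stack:
            node = stack.pop()
            if node.is_tip:
                res.append(node.label)  # type: ignore[arg-type]
            else:
                stack.extend(node.children)  # type: ignore[arg-type]
        return res


class Dendrogram:
    """Rooted ultrametric merge tree over individuals.

    Merge heights are in distance units (substitutions/site): the
    cophenetic distance between two tips is the height of the node at
    which they first join.
    """

    def __init__(self, root: DendrogramNode):
        self.root = root
        self._index: dict[str, int] = {
            lab: i for i, lab in enumerate(sorted(root.tips()))
        }

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self._index)

    def cophenetic(self, a: str, b: str) -> float:
        """Merge height at which tips ``a`` and ``b`` first join."""
        if a == b:
            return 0.0
        node = self.root
        while True:
            if node.is_tip:
                raise KeyError(f"{a!r}/{b!r} not found under a common node")
            left, right = node.children  # type: ignore[misc]
            lt, rt = set(left.tips()), set(right.tips())
            if a in lt and b in lt:
                node = left
            elif a in rt and b in rt:
                node = right
            elif (a in lt and b in rt) or (a in rt and b in lt):
                return node.height
            else:
                raise KeyError(f"tips {a!r}, {b!r} not both in dendrogram")

    def cophenetic_matrix(self) -> tuple[np.ndarray, list[str]]:
        labels = self.tip_labels
        n = len(labels)
        mat = np.zeros((n, n))

        def fill(node: DendrogramNode) -> list[str]:
            if node.is_tip:
                return [node.label]  # type: ignore[list-item]
            left, right = node.children  # type: ignore[misc]
            lt, rt = fill(left), fill(right)
            for x in lt:
                for y in rt:
                    i, j = self._index[x], self._index[y]
                    mat[i, j] = mat[j, i] = node.height
            return lt + rt

        fill(self.root)
        return mat, labels

    def newick(self) -> str:
        """Newick string; branch lengths are half the height differences,
        so the patristic tip-to-tip path equals the cophenetic distance."""

        def fmt(node: DendrogramNode, parent_height: float) -> str:
            bl = (parent_height - node.height) / 2.0
            if node.is_tip:
                return f"{node.label}:{bl:.10g}"
            left, right = node.children  # type: ignore[misc]
            inner = ",".join(
                (fmt(left, node.height), fmt(right, node.height))
            )
            return f"({inner}):{bl:.10g}"

        root = self.root
        if root.is_tip:
            return f"{root.label}:0;"
        left, right = root.children  # type: ignore[misc]
        inner = ",".join((fmt(left, root.height), fmt(right, root.height)))
        return f"({inner});"


def upgma(dist: np.ndarray, labels: Sequence[str]) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    At each step the pair of clusters with the smallest average pairwise
    distance merges, at a node whose height is that average.  Ties are
    broken deterministically: among tied pairs, the one whose
    lexicographically smallest member id is least wins (then the other
    cluster's smallest id).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / labels shape mismatch")
    if n < 1:
        raise ValueError("empty matrix")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0.0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")

    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(height=0.0, label=labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    mins = {i: labels[i] for i in range(n)}  # lexicographic min member id
    d = {
        (i, j): dist[i, j]
        for i, j in itertools.combinations(range(n), 2)
    }
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], *sorted((mins[kv[0][0]], mins[kv[0][1]]))),
        )
        (i, j), h = best
        node = DendrogramNode(
            height=h,
            children=(nodes[i], nodes[j])
            if mins[i] <= mins[j]
            else (nodes[j], nodes[i]),
        )
        active -= {i, j}
        for k in active:
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(next_id, k), max(next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        del d[(i, j)]
        nodes[next_id] = node
        sizes[next_id] = sizes[i] + sizes[j]
        mins[next_id] = min(mins[i], mins[j])
        active.add(next_id)
        next_id += 1
    return Dendrogram(nodes[next_id - 1])


# ---------------------------------------------------------------------------
# Lineages and PBS inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DelimitationConfig:
    """Threshold and the human-supplied revision inputs.

    ``morph_distinct`` holds unordered PU pairs declared morphologically
    distinct by expert revision; ``exclusions`` lists individual ids
    removed as contamination during the rule-2 revision loop.
    """

    divergence_threshold: float = 0.068
    morph_distinct: frozenset[frozenset[str]] = frozenset()
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.divergence_threshold <= 0:
            raise ValueError("divergence_threshold must be > 0")

    @staticmethod
    def make(
        divergence_threshold: float = 0.068,
        morph_distinct: Iterable[tuple[str, str]] = (),
        exclusions: Iterable[str] = (),
    ) -> "DelimitationConfig":
        return DelimitationConfig(
            divergence_threshold=divergence_threshold,
            morph_distinct=frozenset(frozenset(p) for p in morph_distinct),
            exclusions=frozenset(exclusions),
        )

    def distinct(self, pu_a: str, pu_b: str) -> bool:
        return frozenset((pu_a, pu_b)) in self.morph_distinct


def _subtree_for(node: DendrogramNode, members: set[str]) -> DendrogramNode:
    """Smallest node whose tip set contains ``members``."""
    while not node.is_tip:
        left, right = node.children  # type: ignore[misc]
        if members <= set(left.tips()):
            node = left
        elif members <= set(right.tips()):
            node = right
        else:
            return node
    return node


def cut_lineages(
    tree: Dendrogram, cfg: DelimitationConfig
) -> list[list[str]]:
    """Flat cut of the dendrogram at the divergence threshold.

    Lineages are the maximal subtrees whose internal merge heights are
    all <= ``cfg.divergence_threshold``; each is returned as a sorted
    list of individual ids, and the list of lineages is sorted by first
    member.
    """
    t = cfg.divergence_threshold
    lineages: list[list[str]] = []

    def descend(node: DendrogramNode) -> None:
        if node.is_tip or node.height <= t:
            lineages.append(sorted(node.tips()))
        else:
            for child in node.children:  # type: ignore[union-attr]
                descend(child)

    descend(tree.root)
    return sorted(lineages, key=lambda m: m[0])


@dataclass(frozen=True)
class LineageSummary:
    """PU composition of one lineage.

    ``inclusion`` maps each PU present to the fraction of that PU's
    individuals (alignment-wide) falling in this lineage; ``monophyletic``
    flags whether the PU's members form a clade within the lineage's
    subtree (trivially true when the lineage holds a single PU).
    """

    lineage_id: str
    members: tuple[str, ...]
    pu_composition: frozenset[str]
    inclusion: Mapping[str, float]
    monophyletic: Mapping[str, bool]


def _is_clade(sub: DendrogramNode, members: set[str]) -> bool:
    node = _subtree_for(sub, members)
    return set(node.tips()) == members


def summarize_lineages(
    partition: Sequence[Sequence[str]],
    records: Sequence[SequenceRecord],
    tree: Dendrogram,
) -> list[LineageSummary]:
    """Per-lineage PU composition, inclusion proportions and monophyly."""
    pu_of = {r.individual_id: r.pu for r in records}
    pu_totals: dict[str, int] = {}
    for r in records:
        pu_totals[r.pu] = pu_totals.get(r.pu, 0) + 1
    out: list[LineageSummary] = []
    for idx, members in enumerate(partition):
        mset = set(members)
        sub = _subtree_for(tree.root, mset)
        pus = sorted({pu_of[m] for m in members})
        inclusion = {
            pu: sum(1 for m in members if pu_of[m] == pu) / pu_totals[pu]
            for pu in pus
        }
        mono = {
            pu: _is_clade(sub, {m for m in members if pu_of[m] == pu})
            for pu in pus
        }
        out.append(
            LineageSummary(
                lineage_id=f"L{idx + 1:03d}",
                members=tuple(sorted(members)),
                pu_composition=frozenset(pus),
                inclusion=inclusion,
                monophyletic=mono,
            )
        )
    return out


class PBSStatus(str, Enum):
    CLEAN = "CLEAN"
    MERGED_PUS = "MERGED_PUS"
    SPLIT_PU_REVISED = "SPLIT_PU_REVISED"
    REMOVED_INCOMPLETE_SORTING = "REMOVED_INCOMPLETE_SORTING"


@dataclass(frozen=True)
class PBSAssignment:
    """One presumed biological species (or a removal record)."""

    pbs_id: str
    constituents: tuple[tuple[str, str], ...]  # (pu, lineage_id) pairs
    members: tuple[str, ...]
    status: PBSStatus


def infer_pbs(
    summaries: Sequence[LineageSummary],
    records: Sequence[SequenceRecord],
    cfg: DelimitationConfig,
) -> list[PBSAssignment]:
    """Apply the PU-vs-lineage rule cascade (see module docstring).

    Individuals listed in ``cfg.exclusions`` are dropped before the
    rules run (the human revision step for PUs that segregate across
    lineages); any PU that still segregates is flagged
    ``SPLIT_PU_REVISED`` on each of its PBS rather than auto-resolved.
    """
    pu_of = {r.individual_id: r.pu for r in records}
    # lineage occurrence count per PU, after exclusions
    lineages_of_pu: dict[str, set[str]] = {}
    kept: dict[str, list[str]] = {}
    for s in summaries:
        members = [m for m in s.members if m not in cfg.exclusions]
        kept[s.lineage_id] = members
        for m in members:
            lineages_of_pu.setdefault(pu_of[m], set()).add(s.lineage_id)

    out: list[PBSAssignment] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"PBS{counter:03d}"

    for s in summaries:
        members = kept[s.lineage_id]
        if not members:
            continue
        pus = sorted({pu_of[m] for m in members})
        split_flag = any(len(lineages_of_pu[pu]) > 1 for pu in pus)

        def emit(pu_list: list[str], mem: list[str], status: PBSStatus) -> None:
            out.append(
                PBSAssignment(
                    pbs_id=new_id() if status != PBSStatus.REMOVED_INCOMPLETE_SORTING
                    else f"REMOVED_{s.lineage_id}",
                    constituents=tuple((pu, s.lineage_id) for pu in pu_list),
                    members=tuple(sorted(mem)),
                    status=status,
                )
            )

        if len(pus) == 1:
            status = (
                PBSStatus.SPLIT_PU_REVISED if split_flag else PBSStatus.CLEAN
            )
            emit(pus, members, status)
            continue

        distinct_pairs = [
            (a, b)
            for a, b in itertools.combinations(pus, 2)
            if cfg.distinct(a, b)
        ]
        if not distinct_pairs:
            # rule 3: no morphological differences -> single merged PBS
            emit(pus, members, PBSStatus.MERGED_PUS)
            continue
        distinct_pus = sorted({p for pair in distinct_pairs for p in pair})
        if all(s.monophyletic.get(pu, False) for pu in distinct_pus):
            # rule 4: each morph-distinct PU is a clade -> one PBS each;
            # non-distinct companions merge with nothing here, they get
            # their own PBS too (still phylogenetically structured)
            for pu in pus:
                mem = [m for m in members if pu_of[m] == pu]
                emit([pu], mem, PBSStatus.CLEAN if not split_flag
                     else PBSStatus.SPLIT_PU_REVISED)
        else:
            # rule 5: morph-distinct PUs without mtDNA segregation
            emit(pus, members, PBSStatus.REMOVED_INCOMPLETE_SORTING)
    return out


def delimit(
    records: Sequence[SequenceRecord],
    cfg: DelimitationConfig | None = None,
) -> tuple[Dendrogram, list[LineageSummary], list[PBSAssignment]]:
    """Full chain: distances -> UPGMA -> threshold cut -> rules."""
    cfg = cfg or DelimitationConfig()
    ids = [r.individual_id for r in records]
    dist = pairwise_distances(records)
    tree = upgma(dist, ids)
    partition = cut_lineages(tree, cfg)
    summaries = summarize_lineages(partition, records, tree)
    assignments = infer_pbs(summaries, records, cfg)
    return tree, summaries, assignments
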