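"""Readers and writers for the pipeline's file formats.

All formats are plain text: FASTA (Biopython), CSV/TSV tables (pandas)
and Newick trees (dendropy, via :mod:`aorweb.phylo_signal`).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .seq_delim import LineageSummary, PBSAssignment, SequenceRecord

__all__ = [
    "read_alignment",
    "write_lineage_table",
    "write_pbs_table",
]


def read_alignment(
    fasta_path: str | Path, metadata_path: str | Path
) -> list[SequenceRecord]:
    """Join a FASTA of aligned sequences with its metadata CSV.

    The CSV needs columns individual_id, pu, site, island and optionally
    family; every FASTA record must have a metadata row and sequences
    must share one alignment length.
    """
    meta = pd.read_csv(metadata_path, dtype=str).set_index("individual_id")
    records = []
    lengths = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta.index:
            raise KeyError(f"no metadata for sequence {rec.id!r}")
        row = meta.loc[rec.id]
        seq = str(rec.seq).upper()
        lengths.add(len(seq))
        records.append(
            SequenceRecord(
                individual_id=rec.id,
                sequence=seq,
                pu=row["pu"],
                site=row["site"],
                island=row["island"],
                family=row.get("family", "") or "",
            )
        )
    if len(lengths) > 1:
        raise ValueError(f"unequal alignment lengths: {sorted(lengths)}")
    return records


def write_lineage_table(
    summaries: Sequence[LineageSummary], path: str | Path
) -> pd.DataFrame:
    """Lineage summary as a tidy TSV: one row per (lineage, PU)."""
    rows = [
        (
            s.lineage_id,
            pu,
            len([m for m in s.members]),
            s.inclusion[pu],
            s.monophyletic[pu],
        )
        for s in summaries
        for pu in sorted(s.pu_composition)
    ]
    df = pd.DataFrame(
        rows,
        columns=["lineage", "pu", "lineage_size", "inclusion", "monophyletic"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def write_pbs_table(
    assignments: Sequence[PBSAssignment], path: str | Path
) -> pd.DataFrame:
    rows = [
        (a.pbs_id, ";".join(f"{pu}@{lin}" for pu, lin in a.constituents),
         len(a.members), a.status.value)
        for a in assignments
    ]
    df = pd.DataFrame(rows, columns=["pbs", "constituents", "n", "status"])
    df.to_csv(path, sep="\t", index=False)
    return df
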