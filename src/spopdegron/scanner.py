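"""Degron scanning of protein sequences.

Slides a :class:`~spopdegron.motifs.DegronConsensus` along protein
sequences and reports every anchor coordinate at which all constrained
positions are satisfied.  Unconstrained (X) flanks may hang off either
terminus: the biology constrains only the contacted residues, and requiring
the full window in-bounds would miss near-terminal degrons.  All
overlapping matches are reported; downstream filtering is left to the user.

Coordinates are 1-based inclusive and honor a per-record
``first_residue_number``, so printed peptide numbering (e.g. a MyD88
fragment spanning residues 125-141) carries through to match coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence

import pandas as pd
from Bio import SeqIO

from .motifs import AA20, DegronConsensus

__all__ = [
    "SequenceRecord",
    "DegronMatch",
    "scan_sequence",
    "scan_fasta",
    "read_fasta",
    "matches_to_table",
    "write_matches",
    "read_matches",
    "TSV_COLUMNS",
]

TSV_COLUMNS = [
    "sequence_id",
    "motif",
    "anchor",
    "span_start",
    "span_end",
    "window",
    "q_position_residue",
]


@dataclass
class SequenceRecord:
    """A protein sequence with an explicit numbering origin.

    Lowercase input is uppercased and ``*`` terminators stripped at
    construction; other non-standard letters are retained but can never
    satisfy a constrained motif position.
    """

    id: str
    residues: str
    description: str = ""
    first_residue_number: int = 1

    def __post_init__(self):
        self.residues = self.residues.upper().replace("*", "")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.first_residue_number < 1:
            raise ValueError(f"record {self.id!r}: first_residue_number must be >= 1")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, coordinate: int) -> str:
        """Residue at a 1-based coordinate in the record's own numbering."""
        i = coordinate - self.first_residue_number
        if not 0 <= i < len(self.residues):
            raise IndexError(f"coordinate {coordinate} outside record {self.id!r}")
        return self.residues[i]


@dataclass
class DegronMatch:
    """One scanner hit, anchored at the +1 coordinate of the motif."""

    sequence_id: str
    motif_name: str
    anchor: int
    span_start: int
    span_end: int
    window: str
    per_position: dict

    @property
    def q_position_residue(self) -> str:
        """Residue at signed index -4 (the Q-motif glutamine in long degrons)."""
        return self.per_position.get(-4, "")


def scan_sequence(record: SequenceRecord, consensus: DegronConsensus) -> List[DegronMatch]:
    """All matches of ``consensus`` in ``record``, sorted by anchor.

    A match exists at anchor coordinate ``a`` when every constrained
    position ``p`` falls inside the sequence and its residue belongs to the
    allowed set.  The span covers the outermost constrained positions; the
    reported window covers every motif position that intersects the
    sequence, truncating X-only overhangs.
    """
    seq = record.residues
    n = len(seq)
    first = record.first_residue_number
    constrained = consensus.constrained
    if not constrained:
        constrained = consensus.positions  # fully-X motif: window must fit
    offsets = [(p.offset, p.allowed) for p in constrained]
    lo_off = min(off for off, _ in offsets)
    hi_off = max(off for off, _ in offsets)
    matches = []
    # i is the 0-based string index of the +1 anchor
    for i in range(-lo_off, n - hi_off):
        if all(seq[i + off] in allowed for off, allowed in offsets):
            anchor = first + i
            per_position = {
                p.index: seq[i + p.offset]
                for p in consensus.positions
                if 0 <= i + p.offset < n
            }
            window = "".join(per_position[k] for k in sorted(per_position))
            matches.append(
                DegronMatch(
                    sequence_id=record.id,
                    motif_name=consensus.name,
                    anchor=anchor,
                    span_start=anchor + lo_off,
                    span_end=anchor + hi_off,
                    window=window,
                    per_position=per_position,
                )
            )
    return matches


def read_fasta(path, first_residue_number: int = 1) -> List[SequenceRecord]:
    """Read a (multi-record, line-wrapped) FASTA file into records."""
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq),
                    description=rec.description,
                    first_residue_number=first_residue_number,
                )
            )
    except (OSError, ValueError) as exc:
        raise IOError(f"failed to parse FASTA {path} (near record {len(records) + 1}): {exc}")
    return records


def scan_fasta(
    path,
    motifs: Sequence[DegronConsensus],
    first_residue_number: int = 1,
) -> pd.DataFrame:
    """Scan every FASTA record against every motif; returns the match table.

    Records are processed in file order and motifs in the given order, so
    the output is deterministic.
    """
    records = read_fasta(path, first_residue_number)
    matches = []
    for record in records:
        for motif in motifs:
            matches.extend(scan_sequence(record, motif))
    return matches_to_table(matches)


def matches_to_table(matches: Iterable[DegronMatch]) -> pd.DataFrame:
    rows = [
        {
            "sequence_id": m.sequence_id,
            "motif": m.motif_name,
            "anchor": m.anchor,
            "span_start": m.span_start,
            "span_end": m.span_end,
            "window": m.window,
            "q_position_residue": m.q_position_residue,
        }
        for m in matches
    ]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_matches(matches, path, format: str = "tsv") -> None:
    """Write a match table as TSV (1-based inclusive) or BED (0-based
    half-open, converted from the span)."""
    table = matches if isinstance(matches, pd.DataFrame) else matches_to_table(matches)
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        header = "# degron matches; coordinates 1-based inclusive\n"
        try:
            with open(path, "w") as fh:
                fh.write(header)
                table.to_csv(fh, sep="\t", index=False)
        except OSError as exc:
            raise IOError(f"cannot write {path}: {exc}")
    elif fmt == "bed":
        try:
            with open(path, "w") as fh:
                fh.write('track name="degron_matches" description="0-based half-open spans"\n')
                for _, row in table.iterrows():
                    fh.write(
                        f"{row.sequence_id}\t{row.span_start - 1}\t{row.span_end}\t"
                        f"{row.motif}\t0\t+\n"
                    )
        except OSError as exc:
            raise IOError(f"cannot write {path}: {exc}")
    else:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'bed'")


def read_matches(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_matches` (round-trip)."""
    return pd.read_csv(path, sep="\t", comment="#")
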