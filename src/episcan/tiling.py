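"""Tiling of a protein sequence into overlapping peptides.

A peptide array for epitope mapping covers a protein with fixed-length
windows advanced by a constant step, so consecutive peptides share
``window - step`` residues.  If the last full window stops short of the
C-terminus, one additional truncated tile anchored at the next start
position is emitted so the terminus is covered; a tile that would be wholly
contained in its predecessor is never produced.  Coordinates are 1-based
inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio import SeqIO

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


def validate_sequence(sequence: str) -> str:
    """Upper-case and check a sequence against the canonical 20-letter alphabet."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("sequence must be non-empty")
    bad = set(seq) - CANONICAL_AA
    if bad:
        raise ValueError(
            f"non-canonical residue(s) {sorted(bad)}; only the 20 standard "
            "amino acids are supported"
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identified by ``id`` with a canonical amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideTile:
    """One array element: 1-based inclusive span on the parent protein."""

    index: int
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("tile span does not match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def residues(self) -> str:
        return f"{self.start}–{self.end}"


def read_fasta(path, record_id: str | None = None) -> ProteinRecord:
    """Read a protein from FASTA; first record unless ``record_id`` is given."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    return ProteinRecord(id=rec.id, sequence=str(rec.seq))


def tile_sequence(
    protein: ProteinRecord, window: int = 20, step: int = 10
) -> list[PeptideTile]:
    """Tile ``protein`` into ``window``-mers advanced by ``step`` residues.

    Starts run 1, 1+step, 1+2*step, ...; every tile whose full window fits
    is full length.  If the final full tile ends before the last residue L,
    one truncated tile is appended at the next start with end = L.

    Raises
    ------
    ValueError
        If the window exceeds the sequence length or step/window are
        inconsistent.
    """
    L = len(protein.sequence)
    if not (1 <= step <= window):
        raise ValueError("require 1 <= step <= window")
    if window > L:
        raise ValueError(f"window {window} exceeds sequence length {L}")

    tiles: list[PeptideTile] = []
    start = 1
    while start + window - 1 <= L:
        end = start + window - 1
        tiles.append(
            PeptideTile(len(tiles) + 1, start, end, protein.sequence[start - 1:end])
        )
        start += step
    if tiles[-1].end < L:
        # truncated terminal tile; start <= previous end + 1, so never a gap
        tiles.append(
            PeptideTile(len(tiles) + 1, start, L, protein.sequence[start - 1:L])
        )
    return tiles


def reassemble(tiles: Iterable[PeptideTile]) -> str:
    """Concatenate tiles with overlaps removed; inverse of :func:`tile_sequence`."""
    seq = ""
    for t in sorted(tiles, key=lambda t: t.index):
        overlap = len(seq) - (t.start - 1)
        if overlap < 0 or seq[t.start - 1:] != t.sequence[:overlap]:
            raise ValueError(f"tile {t.index} does not overlap consistently")
        seq += t.sequence[overlap:]
    return seq
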