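"""FASTA reading/writing and sequence curation.

Curation mirrors the preprocessing used for transporter benchmark sets:
sequences containing characters outside the 20 canonical amino-acid
letters are dropped (ambiguity codes B/Z/J/X and the rare U/O count as
illegal, since every downstream encoder indexes exactly 20 residue
types), as are sequences shorter than a minimum length (default 50).
Redundancy removal (CD-HIT at 60% identity) is expected to have been run
upstream; this module accepts its output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Default minimum sequence length retained by curation.
MIN_LENGTH_DEFAULT = 50


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence: identifier plus canonical residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read raw (id, residue-string) records from a FASTA file.

    Residue strings are uppercased but not validated; pass the records
    through :func:`curate` to obtain :class:`ProteinSequence` objects.
    Raises :class:`FastaParseError` for an empty file or content before
    the first header, naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first "
                    f"FASTA header ('>')"
                )
            break
        else:
            raise FastaParseError(f"{path}: empty file, no FASTA records")
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FastaParseError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(records: Iterable[tuple[str, str] | ProteinSequence],
                path: str | Path) -> None:
    """Write records (raw pairs or ProteinSequence) to a FASTA file."""
    out = []
    for rec in records:
        if isinstance(rec, ProteinSequence):
            rid, res = rec.id, rec.residues
        else:
            rid, res = rec
        out.append(SeqRecord(Seq(res), id=rid, description=""))
    SeqIO.write(out, str(Path(path)), "fasta")


def curate(
    records: Iterable[tuple[str, str]],
    min_length: int = MIN_LENGTH_DEFAULT,
) -> tuple[list[ProteinSequence], list[tuple[str, str]]]:
    """Filter raw records into validated sequences plus a rejection list.

    A record is rejected with reason ``illegal_character`` if it contains
    any character outside the canonical 20-letter alphabet, or with
    reason ``too_short`` if its length is below ``min_length``. Curation
    never raises on content; every input record lands in exactly one of
    the two output lists.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept: list[ProteinSequence] = []
    rejected: list[tuple[str, str]] = []
    for rid, residues in records:
        residues = residues.upper()
        if set(residues) - _AA_SET or not residues:
            rejected.append((rid, "illegal_character"))
        elif len(residues) < min_length:
            rejected.append((rid, "too_short"))
        else:
            kept.append(ProteinSequence(rid, residues))
    if rejected:
        logger.info(
            "curation rejected %d of %d records",
            len(rejected), len(rejected) + len(kept),
        )
    return kept, rejected
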