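"""PSI-BLAST ASCII PSSM parsing and validation.

A position-specific scoring matrix produced with ``psiblast
-out_ascii_pssm`` carries, per sequence position, 20 integer log-odds
scores followed by 20 weighted observed percentages and two per-position
statistics. Only the log-odds block is used here: it is the "original
PSSM profile" convention of the POSSUM descriptor suite, and the input
to both PSSM-composition and k-separated-bigrams encoders. Scores are
held as floats since downstream arithmetic is real-valued; no
normalisation is applied by default (an optional logistic squashing is
available for experimentation but is off in reproduction mode).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import ProteinSequence

logger = logging.getLogger(__name__)

#: Fixed PSI-BLAST column order of the 20 score columns.
PSSM_COLUMNS = ("A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
                "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V")


class PssmParseError(ValueError):
    """Raised when an ascii PSSM file cannot be parsed."""


@dataclass
class PssmProfile:
    """An L x 20 log-odds score matrix aligned to a protein sequence."""

    sequence_id: str
    residues: str
    scores: np.ndarray  # shape (L, 20), columns in PSSM_COLUMNS order
    column_order: tuple[str, ...] = field(default=PSSM_COLUMNS)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"{self.sequence_id}: scores must be L x 20, "
                f"got {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.residues):
            raise ValueError(
                f"{self.sequence_id}: {self.scores.shape[0]} score rows for "
                f"{len(self.residues)} residues"
            )
        if tuple(self.column_order) != PSSM_COLUMNS:
            raise ValueError("column_order must be the PSI-BLAST order")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def sigmoid_scaled(self) -> "PssmProfile":
        """Return a copy with scores mapped through 1/(1+e^-x).

        Off the default path; raw log-odds feed the encoders.
        """
        return PssmProfile(self.sequence_id, self.residues,
                           1.0 / (1.0 + np.exp(-self.scores)))


def parse_ascii_pssm(path: str | Path, sequence_id: str | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a profile.

    Takes the first 20 numeric columns (log-odds) of each matrix row and
    reconstructs the residue string from the row labels; trailing
    statistics lines are ignored. Raises :class:`PssmParseError`, naming
    the line, for a missing header, a malformed row, or a non-numeric
    score.
    """
    path = Path(path)
    if sequence_id is None:
        sequence_id = path.stem
    lines = path.read_text().splitlines()

    header_idx = None
    n_cols = 0
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(len(t) == 1 and t.isalpha() for t in toks):
            header_idx = i
            n_cols = len(toks)
            if tuple(toks[:20]) != PSSM_COLUMNS:
                raise PssmParseError(
                    f"{path}: line {i + 1}: unexpected column letters "
                    f"{toks[:20]} (PSI-BLAST order required)"
                )
            break
    if header_idx is None:
        raise PssmParseError(f"{path}: no PSSM column header line found")

    residues: list[str] = []
    rows: list[list[float]] = []
    expected_pos = 1
    in_matrix = False
    for i in range(header_idx + 1, len(lines)):
        lineno = i + 1
        toks = lines[i].split()
        if not toks:
            if in_matrix:
                break
            continue
        if not toks[0].lstrip("-").isdigit():
            if in_matrix:
                break
            raise PssmParseError(
                f"{path}: line {lineno}: expected matrix row, got {lines[i]!r}"
            )
        if len(toks) < 2 or not (len(toks[1]) == 1 and toks[1].isalpha()):
            raise PssmParseError(
                f"{path}: line {lineno}: matrix row missing residue letter"
            )
        pos = int(toks[0])
        if pos != expected_pos:
            raise PssmParseError(
                f"{path}: line {lineno}: position {pos}, expected {expected_pos}"
            )
        numeric = toks[2:]
        # score block (n_cols values) optionally followed by the two
        # per-position statistics columns
        if len(numeric) not in (n_cols, n_cols + 2):
            raise PssmParseError(
                f"{path}: line {lineno}: {len(numeric)} numeric fields, "
                f"expected {n_cols} (or {n_cols + 2} with statistics)"
            )
        try:
            row = [float(v) for v in numeric[:20]]
        except ValueError as exc:
            raise PssmParseError(
                f"{path}: line {lineno}: non-numeric score ({exc})"
            ) from None
        residues.append(toks[1].upper())
        rows.append(row)
        expected_pos += 1
        in_matrix = True

    if not rows:
        raise PssmParseError(f"{path}: matrix block is empty")
    return PssmProfile(sequence_id, "".join(residues), np.array(rows))


def write_ascii_pssm(profile: PssmProfile, path: str | Path) -> None:
    """Serialise a profile in the ``-out_ascii_pssm`` text layout.

    The log-odds block round-trips losslessly through
    :func:`parse_ascii_pssm`; the percentage block is written as zeros
    and the statistics footer uses placeholder constants.
    """
    path = Path(path)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "           " + "  ".join(PSSM_COLUMNS) + "   "
        + "   ".join(PSSM_COLUMNS),
    ]
    for i, (res, row) in enumerate(zip(profile.residues, profile.scores), 1):
        scores = " ".join(f"{int(v) if float(v).is_integer() else v:>3}" for v in row)
        pcts = " ".join("  0" for _ in range(20))
        lines.append(f"{i:>5} {res}   {scores}  {pcts}  0.00 0.00")
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1347     0.3192",
        "Standard Gapped      0.0410     0.2670",
        "PSI Ungapped         0.1347     0.3192",
        "PSI Gapped           0.0410     0.2670",
        "",
    ]
    Path(path).write_text("\n".join(lines))


def check_alignment(profile: PssmProfile, seq: ProteinSequence) -> bool:
    """True iff the profile's residues and id match the sequence.

    Mismatches are logged with the first differing position; never
    raises.
    """
    if profile.sequence_id != seq.id:
        logger.warning("id mismatch: profile %r vs sequence %r",
                       profile.sequence_id, seq.id)
        return False
    if len(profile.residues) != len(seq.residues):
        logger.warning("%s: length mismatch: profile L=%d, sequence L=%d",
                       seq.id, len(profile.residues), len(seq.residues))
        return False
    for i, (a, b) in enumerate(zip(profile.residues, seq.residues), 1):
        if a != b:
            logger.warning("%s: residue mismatch at position %d: "
                           "profile %s vs sequence %s", seq.id, i, a, b)
            return False
    return True


def load_pssm_directory(
    seqs: list[ProteinSequence],
    pssm_dir: str | Path,
    strict: bool = True,
) -> tuple[dict[str, PssmProfile], list[str]]:
    """Load ``<pssm_dir>/<id>.pssm`` for each sequence.

    In strict mode a missing or misaligned profile raises; in lenient
    mode the sequence id is returned in the dropped list with a logged
    warning.
    """
    pssm_dir = Path(pssm_dir)
    profiles: dict[str, PssmProfile] = {}
    dropped: list[str] = []
    for seq in seqs:
        fp = pssm_dir / f"{seq.id}.pssm"
        if not fp.exists():
            if strict:
                raise FileNotFoundError(f"no PSSM profile for {seq.id}: {fp}")
            logger.warning("dropping %s: no PSSM file", seq.id)
            dropped.append(seq.id)
            continue
        prof = parse_ascii_pssm(fp, sequence_id=seq.id)
        if not check_alignment(prof, seq):
            if strict:
                raise ValueError(f"PSSM/sequence mismatch for {seq.id}")
            dropped.append(seq.id)
            continue
        profiles[seq.id] = prof
    return profiles, dropped
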