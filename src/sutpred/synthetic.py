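"""Synthetic two-class protein benchmarks: sequences, PSSMs, labels.

The generator emulates the shape of a curated transporter benchmark
(default 306 positives / 729 negatives, the imbalance regime the
balancer targets) with a tunable class signal in [0, 1]:

* **composition signal** — positive sequences draw residues from
  p_pos = (1 - s) * u + s * bias_pos and negatives from the mirrored
  bias, where the two bias distributions concentrate on complementary
  halves of the alphabet; this is what the 188D/CTD encoders see.
* **profile signal** — each synthetic PSSM row is integer noise on
  [-3, 3], plus a boost of round(7 s) on the true residue's column and
  round(2 s) on two class-specific marker columns; this is what the
  PSSM-composition and bigram encoders see.

At s = 0 the classes are identically distributed (no accidental
signal); discriminability rises monotonically with s. Sequences are
i.i.d. — no homology structure, motifs or length/class correlation —
so results on these benchmarks exercise the pipeline mechanics, not
biological realism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .pssm import PSSM_COLUMNS, PssmProfile, write_ascii_pssm
from .sequence_io import AMINO_ACIDS, ProteinSequence, write_fasta

logger = logging.getLogger(__name__)

_COL_INDEX = {a: i for i, a in enumerate(PSSM_COLUMNS)}

# complementary alphabet halves carrying the compositional bias
_POS_BIAS_RESIDUES = "ACDEFGHIKL"
_NEG_BIAS_RESIDUES = "MNPQRSTVWY"
# class-specific PSSM marker columns
_POS_MARKERS = ("W", "Y")
_NEG_MARKERS = ("P", "Q")

NOISE_LOW, NOISE_HIGH = -3, 3
TRUE_RESIDUE_BOOST = 7
MARKER_BOOST = 2


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults mirror the 306/729 training regime."""

    n_pos: int = 306
    n_neg: int = 729
    length_range: tuple[int, int] = (50, 120)
    signal: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if not (50 <= lo <= hi):
            raise ValueError("length_range must satisfy 50 <= min <= max")
        if not 0 <= self.signal <= 1:
            raise ValueError("signal must be in [0, 1]")


def _class_distribution(signal: float, positive: bool) -> np.ndarray:
    bias = np.zeros(20)
    residues = _POS_BIAS_RESIDUES if positive else _NEG_BIAS_RESIDUES
    for a in residues:
        bias[AMINO_ACIDS.index(a)] = 1.0 / len(residues)
    uniform = np.full(20, 1.0 / 20)
    return (1 - signal) * uniform + signal * bias


def generate_sequences(cfg: SynthConfig) -> tuple[list[ProteinSequence], list[int]]:
    """Draw labelled sequences; positives first. Deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    seqs: list[ProteinSequence] = []
    labels: list[int] = []
    alphabet = np.array(list(AMINO_ACIDS))
    for label, count in ((1, cfg.n_pos), (0, cfg.n_neg)):
        p = _class_distribution(cfg.signal, positive=bool(label))
        tag = "pos" if label else "neg"
        for i in range(count):
            L = int(rng.integers(lo, hi + 1))
            residues = "".join(rng.choice(alphabet, size=L, p=p))
            seqs.append(ProteinSequence(f"{tag}_{i:04d}", residues))
            labels.append(label)
    return seqs, labels


def generate_pssms(
    seqs: list[ProteinSequence],
    labels: list[int],
    signal: float,
    seed: int,
) -> dict[str, PssmProfile]:
    """Synthesize an integer PSSM per sequence.

    Per position: uniform integer noise on [-3, 3] everywhere, plus
    round(7 * signal) on the column of the position's true residue and
    round(2 * signal) on the two class-specific marker columns, clipped
    to [-10, 10]. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    true_boost = round(TRUE_RESIDUE_BOOST * signal)
    marker_boost = round(MARKER_BOOST * signal)
    profiles: dict[str, PssmProfile] = {}
    for seq, label in zip(seqs, labels):
        L = len(seq)
        scores = rng.integers(NOISE_LOW, NOISE_HIGH + 1, size=(L, 20)).astype(float)
        rows = np.arange(L)
        true_cols = np.array([_COL_INDEX[a] for a in seq.residues])
        scores[rows, true_cols] += true_boost
        for m in (_POS_MARKERS if label else _NEG_MARKERS):
            scores[:, _COL_INDEX[m]] += marker_boost
        np.clip(scores, -10, 10, out=scores)
        profiles[seq.id] = PssmProfile(seq.id, seq.residues, scores)
    return profiles


def make_benchmark(
    cfg: SynthConfig,
    out_dir: str | Path,
    force: bool = False,
) -> Path:
    """Write a self-contained benchmark bundle.

    Layout: ``sequences.fasta``, ``labels.tsv`` (id, label),
    ``pssm/<id>.pssm`` and ``manifest.json`` recording the config, so a
    replay of the manifest's seed reproduces the bundle byte for byte.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty "
                              f"(use force=True to overwrite)")
    (out_dir / "pssm").mkdir(parents=True, exist_ok=True)

    seqs, labels = generate_sequences(cfg)
    profiles = generate_pssms(seqs, labels, cfg.signal, cfg.seed + 1)

    write_fasta(seqs, out_dir / "sequences.fasta")
    with open(out_dir / "labels.tsv", "w") as fh:
        fh.write("id\tlabel\n")
        for seq, label in zip(seqs, labels):
            fh.write(f"{seq.id}\t{label}\n")
    for seq in seqs:
        write_ascii_pssm(profiles[seq.id], out_dir / "pssm" / f"{seq.id}.pssm")
    manifest = {"config": asdict(cfg), "n_sequences": len(seqs),
                "format_version": 1}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("benchmark bundle written to %s (%d pos / %d neg)",
                out_dir, cfg.n_pos, cfg.n_neg)
    return out_dir
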