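"""Protein feature encoders: 188D CTD, PSSM composition, k-separated bigrams.

Three descriptor families represent each protein:

* **188D** — 20 amino-acid frequencies plus, for each of 8
  physicochemical properties, group Composition (3), cross-group
  Transition frequencies (3) and positional Distribution quantiles (15):
  20 + 8 x 21 = 188 values. Purely sequence-based.
* **PSSM composition** (400) — PSSM rows grouped by the residue observed
  at each position are summed per residue type and divided by the
  sequence length L.
* **k-separated-bigrams-PSSM** (400 per k) — T[m, n](k) =
  sum_i N[i, m] * N[i + k, n] over i = 1..L-k, capturing residue-pair
  transition tendencies at sequence separation k; k = 1 (adjacent
  positions) is the default.

All encoders are pure functions of their inputs and emit vectors with a
fixed, named schema; amino-acid frequency order is alphabetical, PSSM
blocks follow the PSI-BLAST column order.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .containers import LabeledFeatureMatrix
from .pssm import PSSM_COLUMNS, PssmProfile
from .properties import DEFAULT_GROUPINGS, PropertyGrouping
from .sequence_io import AMINO_ACIDS, ProteinSequence

logger = logging.getLogger(__name__)

#: Valid feature-set members, in fixed concatenation order.
FEATURE_SETS = ("d188", "pssm_comp", "kbigrams")

#: Quantiles of the distribution descriptor: first, 25, 50, 75, 100%.
_DIST_QUANTILES = (0.0, 0.25, 0.50, 0.75, 1.0)

_COL_INDEX = {a: i for i, a in enumerate(PSSM_COLUMNS)}


def aac(seq: ProteinSequence) -> np.ndarray:
    """Amino-acid composition: F_i = N_i / L, alphabetical order, sums to 1."""
    counts = np.array([seq.residues.count(a) for a in AMINO_ACIDS], dtype=float)
    return counts / len(seq)


def _group_indices(seq: ProteinSequence, g: PropertyGrouping) -> np.ndarray:
    lut = {}
    for gi, letters in enumerate(g.groups):
        for a in letters:
            lut[a] = gi
    return np.array([lut[a] for a in seq.residues], dtype=int)


def ctd_composition(seq: ProteinSequence, g: PropertyGrouping) -> np.ndarray:
    """Fraction of residues in each of the property's 3 groups (sums to 1)."""
    gi = _group_indices(seq, g)
    return np.bincount(gi, minlength=3).astype(float) / len(seq)


def ctd_transition(seq: ProteinSequence, g: PropertyGrouping) -> np.ndarray:
    """Cross-group adjacency frequencies T(i1,i2) = (N(i1,i2)+N(i2,i1))/(L-1).

    Three values for the unordered group pairs (1,2), (2,3), (3,1),
    counting adjacent residue pairs that cross the two groups in either
    order.
    """
    L = len(seq)
    if L < 2:
        raise ValueError("transition needs L >= 2 (denominator L - 1)")
    gi = _group_indices(seq, g)
    a, b = gi[:-1], gi[1:]
    out = np.zeros(3)
    for j, (g1, g2) in enumerate(((0, 1), (1, 2), (2, 0))):
        out[j] = np.sum(((a == g1) & (b == g2)) | ((a == g2) & (b == g1)))
    return out / (L - 1)


def ctd_distribution(seq: ProteinSequence, g: PropertyGrouping) -> np.ndarray:
    """Positional distribution: for each group, the sequence positions of
    its first, 25%, 50%, 75% and last occurrence, as fractions of L.

    The q-quantile occurrence is the ceil(q * n)-th of the group's n
    occurrences (1-based); a group absent from the sequence contributes
    five zeros. Within a group the five values are non-decreasing.
    """
    L = len(seq)
    gi = _group_indices(seq, g)
    out = np.zeros(15)
    for group in range(3):
        positions = np.flatnonzero(gi == group) + 1  # 1-based
        n = len(positions)
        if n == 0:
            continue
        for qi, q in enumerate(_DIST_QUANTILES):
            occ = max(1, math.ceil(q * n))
            out[group * 5 + qi] = positions[occ - 1] / L
    return out


def encode_188d(
    seq: ProteinSequence,
    groupings: Sequence[PropertyGrouping] = DEFAULT_GROUPINGS,
) -> np.ndarray:
    """188D vector: AAC (20) + per property [C (3), T (3), D (15)]."""
    if len(groupings) != 8:
        raise ValueError(f"188D requires exactly 8 property groupings, "
                         f"got {len(groupings)}")
    parts = [aac(seq)]
    for g in groupings:
        parts += [ctd_composition(seq, g), ctd_transition(seq, g),
                  ctd_distribution(seq, g)]
    return np.concatenate(parts)


def schema_188d(groupings: Sequence[PropertyGrouping] = DEFAULT_GROUPINGS) -> list[str]:
    names = [f"aac_{a}" for a in AMINO_ACIDS]
    for g in groupings:
        names += [f"{g.name}_comp_g{i + 1}" for i in range(3)]
        names += [f"{g.name}_trans_g{a}{b}" for a, b in ((1, 2), (2, 3), (3, 1))]
        for i in range(3):
            names += [f"{g.name}_dist_g{i + 1}_q{int(q * 100)}"
                      for q in _DIST_QUANTILES]
    return names


def pssm_composition(profile: PssmProfile) -> np.ndarray:
    """400-value PSSM composition: per residue type, the sum of that
    type's PSSM rows divided by L; blocks concatenated in PSI-BLAST
    column order. Residue types absent from the sequence give an
    all-zero block.
    """
    L = profile.length
    out = np.zeros((20, 20))
    for i, res in enumerate(profile.residues):
        out[_COL_INDEX[res]] += profile.scores[i]
    return (out / L).ravel()


def schema_pssm_composition() -> list[str]:
    return [f"pssmcomp_{a}_{b}" for a in PSSM_COLUMNS for b in PSSM_COLUMNS]


def k_separated_bigrams(profile: PssmProfile, k: int = 1) -> np.ndarray:
    """k-separated bigram transform of the PSSM:
    T[m, n](k) = sum_{i=1..L-k} N[i, m] * N[i+k, n], flattened row-major
    (T[1,1], T[1,2], ..., T[20,20]).

    For k >= L the sum is empty and the 400 values are all zero (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    N = profile.scores
    L = profile.length
    if k >= L:
        logger.warning("%s: k=%d >= L=%d, bigram block is all zeros",
                       profile.sequence_id, k, L)
        return np.zeros(400)
    return (N[:-k].T @ N[k:]).ravel()


def schema_k_bigrams(k: int) -> list[str]:
    return [f"kbigram{k}_{a}_{b}" for a in PSSM_COLUMNS for b in PSSM_COLUMNS]


def encode_dataset(
    seqs: Sequence[ProteinSequence],
    labels: Mapping[str, int] | Sequence[int],
    feature_set: Iterable[str] = ("kbigrams",),
    profiles: Mapping[str, PssmProfile] | None = None,
    k_list: Sequence[int] = (1,),
    groupings: Sequence[PropertyGrouping] = DEFAULT_GROUPINGS,
) -> LabeledFeatureMatrix:
    """Encode a labeled sequence set into a feature matrix.

    ``feature_set`` selects any non-empty subset of
    {"d188", "pssm_comp", "kbigrams"}; selected encoders are
    concatenated in that fixed order. PSSM-based features require a
    profile for every sequence (strict; missing ids raise listing the
    offenders). ``k_list`` appends one 400-wide bigram block per k.
    """
    fs = [f for f in FEATURE_SETS if f in set(feature_set)]
    unknown = set(feature_set) - set(FEATURE_SETS)
    if unknown:
        raise ValueError(f"unknown feature set member(s): {sorted(unknown)}")
    if not fs:
        raise ValueError("feature_set must name at least one encoder")
    needs_pssm = "pssm_comp" in fs or "kbigrams" in fs
    if needs_pssm:
        if profiles is None:
            raise ValueError("PSSM-based features selected but no profiles given")
        missing = [s.id for s in seqs if s.id not in profiles]
        if missing:
            raise ValueError(f"missing PSSM profiles for: {missing}")
    if isinstance(labels, Mapping):
        y = [labels[s.id] for s in seqs]
    else:
        y = list(labels)
        if len(y) != len(seqs):
            raise ValueError("labels length must match sequence count")

    schema: list[str] = []
    if "d188" in fs:
        schema += schema_188d(groupings)
    if "pssm_comp" in fs:
        schema += schema_pssm_composition()
    if "kbigrams" in fs:
        for k in k_list:
            schema += schema_k_bigrams(k)

    rows = []
    for seq in seqs:
        parts = []
        if "d188" in fs:
            parts.append(encode_188d(seq, groupings))
        if "pssm_comp" in fs:
            parts.append(pssm_composition(profiles[seq.id]))
        if "kbigrams" in fs:
            for k in k_list:
                parts.append(k_separated_bigrams(profiles[seq.id], k))
        rows.append(np.concatenate(parts))

    X = np.vstack(rows)
    logger.info("encoded %d sequences -> %d features (%s)",
                len(seqs), X.shape[1], "+".join(fs))
    return LabeledFeatureMatrix(X, np.array(y), [s.id for s in seqs], schema)
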