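"""Borderline-SMOTE oversampling for the minority class.

Implements Borderline-SMOTE1: each minority point is classified by the
number m' of majority points among its k nearest neighbours in the full
data set (Euclidean distance) — m' = k marks *noise*, k/2 <= m' < k
marks *danger* (near the class boundary), m' < k/2 marks *safe*. Only
danger points spawn synthetic samples, each a random linear
interpolation p + r (q - p), r ~ U[0, 1], toward one of p's k nearest
minority neighbours, until the minority class reaches full parity with
the majority class. Distances are computed on raw features by default
(an optional standardisation flag is available); nearest-neighbour ties
break toward the lowest row index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .containers import LabeledFeatureMatrix

logger = logging.getLogger(__name__)

#: id prefix marking oversampled rows, used by leak checks downstream.
SYNTHETIC_ID_PREFIX = "synthetic|"


@dataclass(frozen=True)
class ParentRecord:
    """Provenance of one synthetic row: parents p, q and the draw r."""

    synthetic_id: str
    p_id: str
    q_id: str
    r: float


def _knn_indices(X: np.ndarray, query: np.ndarray, k: int,
                 exclude_self: np.ndarray | None = None) -> np.ndarray:
    """Indices of the k nearest rows of X to each query row.

    ``exclude_self`` gives, per query, the row index of X that is the
    query itself (excluded from its own neighbourhood). Distance ties
    resolve to the lowest row index (stable sort on (distance, index)).
    """
    d = cdist(query, X)
    if exclude_self is not None:
        d[np.arange(len(query)), exclude_self] = np.inf
    # lexsort on (index, distance): stable lowest-index tie-break
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def classify_minority_points(
    data: LabeledFeatureMatrix,
    k: int = 5,
    standardize: bool = False,
) -> dict[str, np.ndarray]:
    """Partition minority-class row indices into safe / danger / noise.

    For each minority point, m' counts majority points among its k
    nearest neighbours over the whole data set (itself excluded):
    m' == k -> noise; k/2 <= m' < k -> danger; m' < k/2 -> safe.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= data.n_samples:
        raise ValueError(f"k={k} must be < number of samples ({data.n_samples})")
    neg, pos = data.class_counts()
    if neg == 0 or pos == 0:
        raise ValueError("both classes must be non-empty")
    minority_label = 1 if pos <= neg else 0
    minority_idx = np.flatnonzero(data.y == minority_label)

    X = data.X
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    nn = _knn_indices(X, X[minority_idx], k, exclude_self=minority_idx)
    m_prime = (data.y[nn] != minority_label).sum(axis=1)

    noise = minority_idx[m_prime == k]
    danger = minority_idx[(m_prime >= k / 2) & (m_prime < k)]
    safe = minority_idx[m_prime < k / 2]
    return {"safe": safe, "danger": danger, "noise": noise}


def borderline_smote(
    data: LabeledFeatureMatrix,
    k: int = 5,
    seed: int = 0,
    standardize: bool = False,
) -> tuple[LabeledFeatureMatrix, list[ParentRecord]]:
    """Oversample the minority class to full parity with the majority.

    Returns the balanced matrix (original rows first, unchanged,
    followed by synthetic rows with tagged ids) and a parent log
    recording (p, q, r) for every synthetic row. Deterministic for a
    given (data, k, seed).

    If the minority class is already at or above parity the input is
    returned unchanged. If no danger points exist, parents are drawn
    from all non-noise minority points instead (plain-SMOTE fallback,
    logged).
    """
    neg, pos = data.class_counts()
    if neg == 0 or pos == 0:
        raise ValueError("both classes must be non-empty")
    minority_label = 1 if pos <= neg else 0
    n_min = min(neg, pos)
    n_maj = max(neg, pos)
    if n_min < 2:
        raise ValueError("minority class must have >= 2 samples")
    if n_min >= n_maj:
        logger.info("classes already balanced (%d/%d); no-op", neg, pos)
        return data, []

    parts = classify_minority_points(data, k=k, standardize=standardize)
    parent_pool = parts["danger"]
    if len(parent_pool) == 0:
        logger.warning("no danger points; falling back to all non-noise "
                       "minority points (plain SMOTE)")
        parent_pool = np.concatenate([parts["safe"], parts["danger"]])
        if len(parent_pool) == 0:
            parent_pool = parts["noise"]

    minority_idx = np.flatnonzero(data.y == minority_label)
    X = data.X
    Xdist = X
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xdist = (X - X.mean(axis=0)) / sd

    # k nearest *minority* neighbours of each parent candidate
    k_nb = min(k, len(minority_idx) - 1)
    if k_nb < k:
        logger.warning("clamping neighbour k from %d to %d (minority size %d)",
                       k, k_nb, len(minority_idx))
    pos_in_min = {int(g): j for j, g in enumerate(minority_idx)}
    nb = _knn_indices(
        Xdist[minority_idx],
        Xdist[parent_pool],
        k_nb,
        exclude_self=np.array([pos_in_min[int(p)] for p in parent_pool]),
    )  # indices into minority_idx

    need = n_maj - n_min
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(parent_pool))

    new_rows = np.empty((need, data.n_features))
    new_ids: list[str] = []
    log: list[ParentRecord] = []
    for s in range(need):
        pi = order[s % len(parent_pool)]
        p_idx = int(parent_pool[pi])
        q_idx = int(minority_idx[nb[pi, rng.integers(k_nb)]])
        r = float(rng.uniform())
        new_rows[s] = X[p_idx] + r * (X[q_idx] - X[p_idx])
        sid = f"{SYNTHETIC_ID_PREFIX}{s}|{data.ids[p_idx]}"
        new_ids.append(sid)
        log.append(ParentRecord(sid, data.ids[p_idx], data.ids[q_idx], r))

    balanced = LabeledFeatureMatrix(
        np.vstack([X, new_rows]),
        np.concatenate([data.y, np.full(need, minority_label, dtype=int)]),
        list(data.ids) + new_ids,
        list(data.schema),
    )
    logger.info("Borderline-SMOTE: %d/%d -> %d/%d (%d synthetic rows from "
                "%d parent points)", n_min, n_maj, n_maj, n_maj, need,
                len(parent_pool))
    return balanced, log


def is_synthetic_id(sample_id: str) -> bool:
    return sample_id.startswith(SYNTHETIC_ID_PREFIX)
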