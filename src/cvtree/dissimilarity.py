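"""Cosine correlation and dissimilarity between composition vectors.

For two genomes A and B with composition vectors a_A, a_B the correlation
is the cosine

    C(A,B) = sum_s a_A(s) a_B(s) / (||a_A|| ||a_B||)  in [-1, 1]

and the dissimilarity is D(A,B) = (1 - C) / 2 in [0, 1]. The dot product
runs over the intersection of stored peptides (absent components are zero
under default storage); each norm is over the vector's full stored set.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .composition import CompositionVector
from .errors import DegenerateDataError, UsageError
from .io import DistMatrix

__all__ = ["correlation", "dissimilarity", "distance_matrix"]


def correlation(a: CompositionVector, b: CompositionVector) -> float:
    """Cosine correlation C(A,B) of two composition vectors."""
    if a.K != b.K:
        raise UsageError(f"mismatched K: {a.K} != {b.K}")
    for v in (a, b):
        if v.norm == 0.0:
            raise DegenerateDataError(
                f"zero-norm composition vector for {v.genome_id or '<unnamed>'}"
            )
    # sorted-code intersection; absent components are zero
    _, ia, ib = np.intersect1d(
        a.codes, b.codes, assume_unique=True, return_indices=True
    )
    dot = float(np.dot(a.values[ia], b.values[ib]))
    return dot / (a.norm * b.norm)


def dissimilarity(a: CompositionVector, b: CompositionVector) -> float:
    """D(A,B) = (1 - C(A,B)) / 2, in [0, 1]."""
    d = (1.0 - correlation(a, b)) / 2.0
    # guard against floating-point excursions just outside [0, 1]
    return min(1.0, max(0.0, d))


def distance_matrix(
    vectors: Sequence[CompositionVector],
    labels: Sequence[str] | None = None,
) -> DistMatrix:
    """Assemble the full pairwise dissimilarity matrix.

    Label order is preserved from the input; labels default to the
    vectors' genome ids.
    """
    if labels is None:
        labels = [v.genome_id for v in vectors]
    labels = list(labels)
    if len(labels) != len(vectors):
        raise UsageError("labels and vectors differ in length")
    if len(vectors) < 3:
        raise UsageError("need at least 3 vectors for a distance matrix")
    if len(set(labels)) != len(labels):
        raise UsageError("duplicate labels")
    K = vectors[0].K
    for lab, v in zip(labels, vectors):
        if v.K != K:
            raise UsageError(f"genome {lab!r}: K={v.K} differs from {K}")
        if v.norm == 0.0:
            raise DegenerateDataError(f"genome {lab!r}: zero-norm vector")
    n = len(vectors)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dissimilarity(vectors[i], vectors[j])
            values[i, j] = values[j, i] = d
    return DistMatrix(labels=labels, values=values)
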