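"""Edit-distance core: Levenshtein distance and the Levenshtein Similarity Index.

The Levenshtein distance (LD) between two symbol sequences is the minimal
number of single-symbol insertions, deletions and substitutions turning one
into the other (all unit cost; no transpositions).  The Levenshtein
similarity index (LSI) normalizes it by the longer sequence's length and
reports a similarity:

    LSI(a, b) = 1 − LD(a, b) / max(|a|, |b|)

so 1 means identical and 0 means maximally different.  Symbols are opaque,
hashable tokens (unit labels for phrase strings, integer theme IDs for song
strings).  Distances for clustering are 1 − LSI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import SimilarityMatrix

__all__ = [
    "levenshtein",
    "lsi",
    "similarity_matrix",
    "median_string",
    "within_set_similarity",
    "MedianStringResult",
    "LevenshteinSimilarity",
]


def _encode_pair(a: Sequence[Hashable], b: Sequence[Hashable]):
    codes: dict[Hashable, int] = {}
    ea = tuple(codes.setdefault(s, len(codes)) for s in a)
    eb = tuple(codes.setdefault(s, len(codes)) for s in b)
    return ea, eb


def _lev_coded(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    # two-row DP over integer-coded symbols; O(|a|·|b|) time, O(|b|) space
    if len(a) < len(b):
        a, b = b, a
    lb = len(b)
    if lb == 0:
        return len(a)
    prev = list(range(lb + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * lb
        pj = prev[0]
        for j in range(1, lb + 1):
            d = pj + (ca != b[j - 1])
            pj = prev[j]
            up = pj + 1
            if up < d:
                d = up
            left = cur[j - 1] + 1
            if left < d:
                d = left
            cur[j] = d
        prev = cur
    return prev[lb]


def levenshtein(a: Sequence[Hashable], b: Sequence[Hashable]) -> int:
    """Minimal unit-cost edit count between two symbol sequences."""
    ea, eb = _encode_pair(tuple(a), tuple(b))
    return _lev_coded(ea, eb)


def lsi(a: Sequence[Hashable], b: Sequence[Hashable]) -> float:
    """Levenshtein similarity index: 1 − LD / max(|a|, |b|), in [0, 1].

    Undefined (raises ValueError) when both sequences are empty.
    """
    a, b = tuple(a), tuple(b)
    m = max(len(a), len(b))
    if m == 0:
        raise ValueError("LSI is undefined for two empty sequences")
    return 1.0 - levenshtein(a, b) / m


def _pairwise_lsi(seqs: list[tuple[int, ...]]) -> np.ndarray:
    n = len(seqs)
    out = np.ones((n, n))
    lens = [len(s) for s in seqs]
    for i in range(n):
        si, li = seqs[i], lens[i]
        for j in range(i + 1, n):
            v = 1.0 - _lev_coded(si, seqs[j]) / max(li, lens[j])
            out[i, j] = out[j, i] = v
    return out


def _encode_all(strings: Sequence[Sequence[Hashable]]) -> list[tuple[int, ...]]:
    codes: dict[Hashable, int] = {}
    return [tuple(codes.setdefault(s, len(codes)) for s in seq) for seq in strings]


def similarity_matrix(
    strings: Sequence[Sequence[Hashable]],
    labels: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """All-pairs LSI matrix over a collection of symbol sequences."""
    strings = [tuple(s) for s in strings]
    if len(strings) < 2:
        raise ValueError("need at least 2 strings for a similarity matrix")
    for k, s in enumerate(strings):
        if not s:
            name = labels[k] if labels is not None else str(k)
            raise ValueError(f"string {name!r} is empty")
    if labels is None:
        labels = [str(i) for i in range(len(strings))]
    values = _pairwise_lsi(_encode_all(strings))
    return SimilarityMatrix(list(labels), values)


@dataclass(frozen=True)
class MedianStringResult:
    """The set member most similar to all others under summed pairwise LSI."""

    index: int
    string: tuple
    score: float
    within_set_similarity: float


def median_string(strings: Sequence[Sequence[Hashable]]) -> MedianStringResult:
    """Pick the member whose summed pairwise LSI to the rest is largest.

    Ties break to the smallest input index.  A singleton set returns its only
    member with score 0 and within-set similarity 1 by convention.
    """
    strings = [tuple(s) for s in strings]
    if not strings:
        raise ValueError("median string of an empty collection is undefined")
    if len(strings) == 1:
        return MedianStringResult(0, strings[0], 0.0, 1.0)
    sims = _pairwise_lsi(_encode_all(strings))
    np.fill_diagonal(sims, 0.0)
    sums = sims.sum(axis=1)
    # ties break to the smallest input index; the tolerance keeps the rule
    # stable under float summation order (exact ties can differ by an ulp)
    top = sums.max()
    idx = int(np.flatnonzero(sums >= top - 1e-9 * max(1.0, abs(top)))[0])
    n = len(strings)
    within = float(sums.sum() / (n * (n - 1)))
    return MedianStringResult(idx, strings[idx], float(sums[idx]), within)


def within_set_similarity(strings: Sequence[Sequence[Hashable]]) -> float:
    """Mean off-diagonal pairwise LSI of a set (requires >= 2 members)."""
    strings = [tuple(s) for s in strings]
    if len(strings) < 2:
        raise ValueError("within-set similarity needs at least 2 strings")
    sims = _pairwise_lsi(_encode_all(strings))
    n = len(strings)
    iu = np.triu_indices(n, k=1)
    return float(sims[iu].mean())


class LevenshteinSimilarity(BaseEstimator, TransformerMixin):
    """Pairwise LSI transformer over collections of symbol sequences.

    ``fit`` stores the reference collection; ``transform(Y)`` returns the
    rectangular LSI matrix between ``Y`` and the reference (so
    ``fit_transform(X)`` is the square all-pairs matrix).  Fits into sklearn
    pipelines that consume precomputed similarity/affinity matrices.

    Parameters
    ----------
    as_distance : bool, default False
        Return 1 − LSI instead of LSI.
    """

    def __init__(self, as_distance: bool = False):
        self.as_distance = as_distance

    def fit(self, X, y=None):
        X = [tuple(s) for s in X]
        if any(not s for s in X):
            raise ValueError("empty sequences are not allowed")
        self.reference_ = X
        return self

    def transform(self, Y):
        if not hasattr(self, "reference_"):
            raise ValueError("LevenshteinSimilarity instance is not fitted yet")
        Y = [tuple(s) for s in Y]
        if any(not s for s in Y):
            raise ValueError("empty sequences are not allowed")
        out = np.empty((len(Y), len(self.reference_)))
        for i, a in enumerate(Y):
            for j, b in enumerate(self.reference_):
                out[i, j] = lsi(a, b)
        return 1.0 - out if self.as_distance else out

    def fit_transform(self, X, y=None):
        # square case: exploit symmetry
        self.fit(X)
        vals = _pairwise_lsi(_encode_all(self.reference_))
        return 1.0 - vals if self.as_distance else vals
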