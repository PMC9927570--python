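"""Entropy-based scores for single variants and variant pairs.

All quantities are plug-in (maximum-likelihood) estimates in bits, with the
convention 0*log2(1/0) = 0 and no pseudocounts:

* H(C): entropy of the binary phenotype;
* H(C|A): conditional entropy given one genotype variable;
* I(A;C) = H(C) - H(C|A): mutual information of a variant and the phenotype;
* I(A,B;C): joint mutual information, treating the ordered genotype pair as
  one composite variable with up to nine categories;
* IG(A;B;C) = I(A,B;C) - I(A;C) - I(B;C): the pairwise synergy ("information
  gain"). Positive IG means the pair explains the phenotype beyond its
  parts; negative IG indicates redundancy. Both are returned as-is.

Missing genotypes are handled by pairwise-complete deletion: subjects
missing any variable involved in a score are dropped from that score only.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .data import MISSING, Dataset, PhenotypeVector

__all__ = [
    "PairScores",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "joint_mutual_information",
    "pairwise_information_gain",
    "all_pairs_information_gain",
]


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Entropy (bits) of the empirical distribution given by ``counts``."""
    n = counts.sum()
    if n == 0:
        raise ValueError("entropy of an empty sample is undefined")
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _as_labels(labels) -> np.ndarray:
    if isinstance(labels, PhenotypeVector):
        return labels.labels
    return np.asarray(labels, dtype=np.int64)


def entropy(labels) -> float:
    """H(C) in bits for a binary phenotype vector."""
    y = _as_labels(labels)
    if y.size == 0:
        raise ValueError("entropy of an empty phenotype is undefined")
    return _entropy_from_counts(np.bincount(y, minlength=2))


def _complete(y: np.ndarray, *genos: np.ndarray) -> tuple[np.ndarray, ...]:
    mask = np.ones(len(y), dtype=bool)
    for g in genos:
        mask &= g != MISSING
    if not mask.any():
        raise ValueError("no complete observations after dropping missing genotypes")
    return (y[mask],) + tuple(g[mask] for g in genos)


def conditional_entropy(labels, genotypes) -> float:
    """H(C|A) in bits; rows with missing genotypes are dropped."""
    y = _as_labels(labels)
    a = np.asarray(genotypes, dtype=np.int64)
    if len(y) != len(a):
        raise ValueError("labels and genotypes must have equal length")
    y, a = _complete(y, a)
    # H(C|A) = H(A,C) - H(A)
    joint = np.bincount(a * 2 + y, minlength=6)
    marg_a = np.bincount(a, minlength=3)
    return _entropy_from_counts(joint) - _entropy_from_counts(marg_a)


def mutual_information(genotypes, labels) -> float:
    """I(A;C) = H(C) - H(C|A) in bits, on pairwise-complete rows."""
    y = _as_labels(labels)
    a = np.asarray(genotypes, dtype=np.int64)
    y, a = _complete(y, a)
    joint = np.bincount(a * 2 + y, minlength=6)
    return (
        _entropy_from_counts(np.bincount(y, minlength=2))
        + _entropy_from_counts(np.bincount(a, minlength=3))
        - _entropy_from_counts(joint)
    )


def joint_mutual_information(genotypes_a, genotypes_b, labels) -> float:
    """I(A,B;C) in bits, with (a, b) as one composite 9-category variable."""
    y = _as_labels(labels)
    a = np.asarray(genotypes_a, dtype=np.int64)
    b = np.asarray(genotypes_b, dtype=np.int64)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("all vectors must have equal length")
    y, a, b = _complete(y, a, b)
    ab = a * 3 + b
    joint = np.bincount(ab * 2 + y, minlength=18)
    return (
        _entropy_from_counts(np.bincount(y, minlength=2))
        + _entropy_from_counts(np.bincount(ab, minlength=9))
        - _entropy_from_counts(joint)
    )


def pairwise_information_gain(genotypes_a, genotypes_b, labels) -> float:
    """IG(A;B;C) = I(A,B;C) - I(A;C) - I(B;C), in bits (may be negative).

    All three terms are computed on the same pairwise-complete subject set so
    the decomposition is self-consistent.
    """
    y = _as_labels(labels)
    a = np.asarray(genotypes_a, dtype=np.int64)
    b = np.asarray(genotypes_b, dtype=np.int64)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("all vectors must have equal length")
    y, a, b = _complete(y, a, b)
    return (
        joint_mutual_information(a, b, y)
        - mutual_information(a, y)
        - mutual_information(b, y)
    )


@dataclasses.dataclass
class PairScores:
    """Symmetric matrix of pairwise information-gain values (bits).

    The diagonal is NaN (self-pairs are undefined).
    """

    variant_ids: list[str]
    ig: np.ndarray

    def __post_init__(self) -> None:
        self.ig = np.asarray(self.ig, dtype=float)
        m = len(self.variant_ids)
        if self.ig.shape != (m, m):
            raise ValueError("ig matrix shape must match variant_ids")

    def pair(self, a: str, b: str) -> float:
        i = self.variant_ids.index(a)
        j = self.variant_ids.index(b)
        if i == j:
            raise ValueError("self-pairs have no information gain")
        return float(self.ig[i, j])

    def iter_pairs(self):
        """Yield (variant_a, variant_b, ig) over the upper triangle."""
        m = len(self.variant_ids)
        for i in range(m):
            for j in range(i + 1, m):
                yield self.variant_ids[i], self.variant_ids[j], float(self.ig[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.iter_pairs()), columns=["variant_a", "variant_b", "information_gain"]
        )

    def top_pair(self) -> tuple[str, str, float]:
        """The unordered pair with maximum information gain."""
        masked = np.where(np.isnan(self.ig), -np.inf, self.ig)
        iu = np.triu_indices(len(self.variant_ids), k=1)
        k = int(np.argmax(masked[iu]))
        i, j = iu[0][k], iu[1][k]
        return self.variant_ids[i], self.variant_ids[j], float(self.ig[i, j])


def all_pairs_information_gain(dataset: Dataset) -> PairScores:
    """Score every unordered variant pair by IG(A;B;C).

    For complete data the per-variant terms are cached; pairs with missing
    genotypes fall back to pairwise-complete recomputation of all terms.
    """
    codes = dataset.genotypes.codes
    y = dataset.phenotype.labels
    dataset.phenotype.require_both_classes()
    m = codes.shape[1]
    if m < 2:
        raise ValueError("at least two variants are required")
    ig = np.full((m, m), np.nan)

    any_missing = (codes == MISSING).any(axis=0)
    h_c = _entropy_from_counts(np.bincount(y, minlength=2))
    # cache I(A;C) for complete columns
    mi_single = np.empty(m)
    for j in range(m):
        if any_missing[j]:
            mi_single[j] = np.nan
        else:
            joint = np.bincount(codes[:, j] * 2 + y, minlength=6)
            mi_single[j] = (
                h_c
                + _entropy_from_counts(np.bincount(codes[:, j], minlength=3))
                - _entropy_from_counts(joint)
            )

    for i, j in itertools.combinations(range(m), 2):
        a, b = codes[:, i], codes[:, j]
        if any_missing[i] or any_missing[j]:
            val = pairwise_information_gain(a, b, y)
        else:
            ab = a * 3 + b
            joint_mi = (
                h_c
                + _entropy_from_counts(np.bincount(ab, minlength=9))
                - _entropy_from_counts(np.bincount(ab * 2 + y, minlength=18))
            )
            val = joint_mi - mi_single[i] - mi_single[j]
        ig[i, j] = ig[j, i] = val
    return PairScores(list(dataset.variant_ids), ig)
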