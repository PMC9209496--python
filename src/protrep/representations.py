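"""Classical sequence-vector baselines: bag of k-mers with TFIDF, and
amino-acid frequencies.

The bag-of-k-mers representation counts every overlapping length-k
substring of a protein and lays the counts out in alphabetical k-mer
order, giving a 20^k-dimensional vector (k=2 -> 400, k=3 -> 8,000,
k=4 -> 160,000). A smoothed TFIDF reweighting then accentuates rare
k-mers. Counts are held sparse internally; the dense 20^k contract is
exposed at the module surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import TfidfTransformer

from .io import CANONICAL_AA, ProteinRecord, RepresentationMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KmerSpec:
    """k-mer size and alphabet; vector dimension is ``|alphabet| ** k``."""

    k: int = 3
    alphabet: str = CANONICAL_AA

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet letters must be unique")

    @property
    def dim(self) -> int:
        return len(self.alphabet) ** self.k

    def kmer_names(self) -> list[str]:
        """All k-mers in alphabetical (= column) order."""
        from itertools import product

        return ["".join(t) for t in product(sorted(self.alphabet), repeat=self.k)]


def _kmer_indices(sequence: str, spec: KmerSpec) -> np.ndarray:
    """Column indices of each valid k-mer window (ambiguous windows skipped)."""
    order = {a: i for i, a in enumerate(sorted(spec.alphabet))}
    codes = np.array([order.get(c, -1) for c in sequence], dtype=np.int64)
    n = len(codes) - spec.k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    base = len(spec.alphabet)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for offset in range(spec.k):
        window = codes[offset : offset + n]
        valid &= window >= 0
        idx = idx * base + window
    return idx[valid]


def kmer_counts(r: ProteinRecord, spec: KmerSpec = KmerSpec()) -> np.ndarray:
    """Dense count vector over all k-mers in alphabetical order.

    Overlapping occurrences are counted; any window containing a
    non-alphabet (ambiguity) letter contributes nothing. A sequence
    shorter than k yields the zero vector with a logged warning.
    """
    if len(r.sequence) < spec.k:
        logger.warning("sequence %s shorter than k=%d; zero k-mer vector", r.id, spec.k)
        return np.zeros(spec.dim)
    idx = _kmer_indices(r.sequence, spec)
    counts = np.zeros(spec.dim)
    np.add.at(counts, idx, 1.0)
    return counts


def kmer_count_matrix(records: Sequence[ProteinRecord],
                      spec: KmerSpec = KmerSpec()) -> sp.csr_matrix:
    """Sparse (n_proteins, 20^k) count matrix, rows in record order."""
    indptr = [0]
    indices: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for r in records:
        if len(r.sequence) < spec.k:
            logger.warning("sequence %s shorter than k=%d; zero row", r.id, spec.k)
            cols = np.empty(0, dtype=np.int64)
        else:
            cols = _kmer_indices(r.sequence, spec)
        uniq, cnt = np.unique(cols, return_counts=True)
        indices.append(uniq)
        data.append(cnt.astype(np.float64))
        indptr.append(indptr[-1] + len(uniq))
    return sp.csr_matrix(
        (np.concatenate(data) if data else [], np.concatenate(indices) if indices else [],
         np.array(indptr)),
        shape=(len(records), spec.dim),
    )


@dataclass
class TfidfModel:
    """Fitted smoothed-IDF weights: idf(t) = ln((1+n)/(1+df(t))) + 1,
    rows L2-normalized on transform (the convention of sklearn's
    TfidfTransformer, which backs this model)."""

    _transformer: TfidfTransformer

    @property
    def idf_weights(self) -> np.ndarray:
        return self._transformer.idf_


def fit_tfidf(counts: sp.spmatrix | np.ndarray) -> TfidfModel:
    """Fit smoothed TFIDF weights on a reference count corpus."""
    counts = sp.csr_matrix(counts)
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("counts must be nonnegative")
    transformer = TfidfTransformer(norm="l2", smooth_idf=True, sublinear_tf=False)
    transformer.fit(counts)
    return TfidfModel(transformer)


def transform_tfidf(model: TfidfModel, counts: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Apply fitted TFIDF weights; rows come back L2-normalized."""
    return model._transformer.transform(sp.csr_matrix(counts))


def aa_frequencies(r: ProteinRecord) -> np.ndarray:
    """20-vector of canonical residue frequencies (sums to 1).

    Ambiguity letters are ignored; a sequence with no canonical residue
    is an error.
    """
    order = {a: i for i, a in enumerate(CANONICAL_AA)}
    counts = np.zeros(20)
    for c in r.sequence:
        i = order.get(c)
        if i is not None:
            counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(f"sequence {r.id} has no canonical residues")
    return counts / total


class KmerTfidfVectorizer(BaseEstimator, TransformerMixin):
    """Bag-of-k-mers counts with smoothed TFIDF weighting.

    Parameters
    ----------
    k : int, default 3
        k-mer length; output dimension is ``20 ** k``.
    alphabet : str
        Ordered residue alphabet (canonical 20 by default).

    Attributes
    ----------
    idf_ : ndarray of shape (20**k,)
        Fitted inverse-document-frequency weights.
    """

    def __init__(self, k: int = 3, alphabet: str = CANONICAL_AA):
        self.k = k
        self.alphabet = alphabet

    def fit(self, X: Sequence[ProteinRecord], y=None) -> "KmerTfidfVectorizer":
        spec = KmerSpec(self.k, self.alphabet)
        self._spec = spec
        self._tfidf = fit_tfidf(kmer_count_matrix(X, spec))
        self.idf_ = self._tfidf.idf_weights
        return self

    def transform(self, X: Sequence[ProteinRecord]) -> sp.csr_matrix:
        if not hasattr(self, "_tfidf"):
            raise RuntimeError("KmerTfidfVectorizer must be fitted before transform")
        return transform_tfidf(self._tfidf, kmer_count_matrix(X, self._spec))

    def to_matrix(self, X: Sequence[ProteinRecord]) -> RepresentationMatrix:
        dense = np.asarray(self.transform(X).todense())
        return RepresentationMatrix([r.id for r in X], dense, "kmer-tfidf")


class AAFrequencyVectorizer(BaseEstimator, TransformerMixin):
    """Stateless amino-acid frequency representation (20 dimensions)."""

    def fit(self, X: Sequence[ProteinRecord], y=None) -> "AAFrequencyVectorizer":
        return self

    def transform(self, X: Sequence[ProteinRecord]) -> np.ndarray:
        return np.vstack([aa_frequencies(r) for r in X])

    def to_matrix(self, X: Sequence[ProteinRecord]) -> RepresentationMatrix:
        return RepresentationMatrix([r.id for r in X], self.transform(X), "aa-freq")


def kmer_tfidf_matrix(records: Sequence[ProteinRecord], k: int = 3,
                      fit_records: Sequence[ProteinRecord] | None = None
                      ) -> RepresentationMatrix:
    """One-call k-mer TFIDF representation (fit on ``fit_records`` or on
    ``records`` themselves)."""
    vec = KmerTfidfVectorizer(k=k).fit(fit_records if fit_records is not None else records)
    return vec.to_matrix(records)


def aa_frequency_matrix(records: Sequence[ProteinRecord]) -> RepresentationMatrix:
    return AAFrequencyVectorizer().to_matrix(records)
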