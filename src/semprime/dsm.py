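"""Distributional semantic spaces of the LSA and HAL families.

This module builds word vectors from a tokenized corpus along the two
classic count-based routes:

* **LSA-type** — a word-by-document count matrix: each cell records how
  often a word occurs in a document.  Document co-occurrence captures
  syntagmatic (associative) relations.
* **HAL-type** — a word-by-word count matrix: two *content* words
  co-occur when they appear within a window of ``w`` content words
  inside the same sentence.  Local co-occurrence captures paradigmatic
  (semantic) relations.

Both matrices are reweighted with positive pointwise mutual information
(PPMI) and reduced to ``k`` dimensions with a truncated singular value
decomposition; word vectors are the rows of ``U_k @ diag(s_k)``, which
preserves the row geometry of the weighted matrix at full rank.  Word
similarity is the cosine of the angle between two word vectors; for all
similarity-band logic negative cosines are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd, svd_flip

__all__ = [
    "Token",
    "TokenizedCorpus",
    "VocabularyTable",
    "CooccurrenceCounts",
    "WeightedMatrix",
    "SemanticSpace",
    "build_vocabulary",
    "count_word_by_document",
    "count_word_by_word",
    "ppmi_transform",
    "svd_reduce",
    "cosine_similarity",
    "build_space",
    "EmptyCorpusError",
    "DegenerateMatrixError",
    "MissingWordError",
    "UndefinedSimilarityError",
]

# Matrices at or below this minimum dimension are decomposed with a full
# dense SVD (exact); larger ones use a seeded randomized SVD.
_DENSE_SVD_MAX = 600


class EmptyCorpusError(ValueError):
    """The corpus contains no tokens."""


class DegenerateMatrixError(ValueError):
    """A count matrix with zero total count cannot be PPMI-weighted."""


class MissingWordError(KeyError):
    """A queried word is not represented in the space/vocabulary."""


class UndefinedSimilarityError(ValueError):
    """Cosine similarity is undefined for an all-zero word vector."""


class Token(NamedTuple):
    form: str
    is_content: bool = True


# A sentence is a list of Tokens; a document is a list of sentences.
Sentence = list
Document = list


@dataclass
class TokenizedCorpus:
    """An ordered collection of documents, each a list of sentences."""

    documents: list

    def __post_init__(self) -> None:
        for d, doc in enumerate(self.documents):
            for s, sent in enumerate(doc):
                if len(sent) == 0:
                    raise ValueError(f"empty sentence {s} in document {d}")
                for tok in sent:
                    if not tok.form:
                        raise ValueError(f"empty token form in document {d}")

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for doc in self.documents for s in doc)

    def iter_sentences(self) -> Iterable[tuple[int, list]]:
        """Yield (document index, sentence) pairs in corpus order."""
        for d, doc in enumerate(self.documents):
            for sent in doc:
                yield d, sent


@dataclass
class VocabularyTable:
    """The ``cap`` most frequent surface forms, ranked 1..n.

    Ranks follow non-increasing raw frequency; frequency ties are broken
    lexicographically so that the table is a pure function of the corpus.
    """

    words: list
    counts: np.ndarray
    cap: int
    index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {w: i for i, w in enumerate(self.words)}
        if len(self.index) != len(self.words):
            raise ValueError("duplicate words in vocabulary")
        if len(self.words) > self.cap:
            raise ValueError("vocabulary exceeds its size cap")

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def rank(self, word: str) -> int:
        """1-based frequency rank."""
        try:
            return self.index[word] + 1
        except KeyError:
            raise MissingWordError(word) from None


@dataclass
class CooccurrenceCounts:
    """Sparse non-negative integer co-occurrence counts.

    ``columns`` is ``"documents"`` for word-by-document counts and
    ``"words"`` for (symmetric, zero-diagonal) word-by-word counts.
    """

    matrix: sp.csr_matrix
    vocab: VocabularyTable
    columns: str  # "documents" | "words"

    def __post_init__(self) -> None:
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("negative co-occurrence count")


@dataclass
class WeightedMatrix:
    """PPMI-weighted counts; same shape and labels as the source counts."""

    matrix: sp.csr_matrix
    vocab: VocabularyTable
    columns: str


def build_vocabulary(corpus: TokenizedCorpus, cap: int) -> VocabularyTable:
    """Count raw token frequencies and keep the ``cap`` most frequent forms."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    counts: dict = {}
    for _, sent in corpus.iter_sentences():
        for tok in sent:
            counts[tok.form] = counts.get(tok.form, 0) + 1
    if not counts:
        raise EmptyCorpusError("cannot build a vocabulary from an empty corpus")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:cap]
    words = [w for w, _ in ordered]
    return VocabularyTable(
        words=words, counts=np.array([c for _, c in ordered], dtype=np.int64), cap=cap
    )


def count_word_by_document(
    corpus: TokenizedCorpus, vocab: VocabularyTable
) -> CooccurrenceCounts:
    """Word-by-document occurrence counts; out-of-vocabulary tokens are ignored."""
    rows, cols = [], []
    for d, sent in corpus.iter_sentences():
        for tok in sent:
            i = vocab.index.get(tok.form)
            if i is not None:
                rows.append(i)
                cols.append(d)
    shape = (len(vocab), corpus.n_documents)
    mat = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)), shape=shape
    ).tocsr()
    return CooccurrenceCounts(matrix=mat, vocab=vocab, columns="documents")


def count_word_by_word(
    corpus: TokenizedCorpus, vocab: VocabularyTable, window: int
) -> CooccurrenceCounts:
    """Windowed word-by-word counts over content tokens.

    Within each sentence, non-content tokens are dropped first; every
    ordered pair of remaining tokens at distance <= ``window`` adds one
    count to both (a, b) and (b, a).  Pairs never cross a sentence
    boundary, increments are flat (no distance decay), and pairs of two
    tokens of the *same* word are skipped so the diagonal stays zero.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    # Flatten content tokens into one id array with sentence ids so all
    # window offsets can be handled with array slices.
    ids, sent_ids = [], []
    for s, (_, sent) in enumerate(corpus.iter_sentences()):
        for tok in sent:
            if tok.is_content:
                i = vocab.index.get(tok.form)
                if i is not None:
                    ids.append(i)
                    sent_ids.append(s)
    ids_arr = np.asarray(ids, dtype=np.int64)
    sent_arr = np.asarray(sent_ids, dtype=np.int64)
    n = len(vocab)
    rows, cols = [], []
    for d in range(1, window + 1):
        if len(ids_arr) <= d:
            break
        a, b = ids_arr[:-d], ids_arr[d:]
        ok = (sent_arr[:-d] == sent_arr[d:]) & (a != b)
        rows.append(a[ok])
        cols.append(b[ok])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        data = np.ones(len(r), dtype=np.int64)
        upper = sp.coo_matrix((data, (r, c)), shape=(n, n))
        mat = (upper + upper.T).tocsr()
    else:
        mat = sp.csr_matrix((n, n), dtype=np.int64)
    return CooccurrenceCounts(matrix=mat, vocab=vocab, columns="words")


def ppmi_transform(counts: CooccurrenceCounts) -> WeightedMatrix:
    """Positive pointwise mutual information weighting.

    cell(w, c) = max(0, ln(n_wc * N / (n_w. * n_.c))), with the marginals
    taken from the count matrix itself and natural logarithms.  Cells with
    a zero count stay exactly zero.
    """
    mat = counts.matrix.tocoo()
    total = float(mat.sum())
    if total <= 0:
        raise DegenerateMatrixError("all-zero count matrix")
    row_marg = np.asarray(counts.matrix.sum(axis=1)).ravel().astype(float)
    col_marg = np.asarray(counts.matrix.sum(axis=0)).ravel().astype(float)
    with np.errstate(divide="ignore"):
        pmi = np.log(mat.data.astype(float) * total) - np.log(
            row_marg[mat.row] * col_marg[mat.col]
        )
    np.maximum(pmi, 0.0, out=pmi)
    out = sp.coo_matrix((pmi, (mat.row, mat.col)), shape=mat.shape).tocsr()
    out.eliminate_zeros()
    return WeightedMatrix(matrix=out, vocab=counts.vocab, columns=counts.columns)


def svd_reduce(
    weighted: WeightedMatrix, k: int, seed: int, model: str = "custom"
) -> "SemanticSpace":
    """Reduce a weighted matrix to a k-dimensional space by truncated SVD.

    Word vectors are ``U_k @ diag(s_k)``; the effective dimensionality is
    ``min(k, rank)``.  Small matrices are decomposed exactly (dense
    LAPACK); larger ones use a seeded randomized SVD, so the space is
    reproducible bit-for-bit given (matrix, k, seed).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_rows, n_cols = weighted.matrix.shape
    if k > max(n_rows, n_cols):
        raise ValueError(f"k={k} exceeds both matrix dimensions {weighted.matrix.shape}")
    if min(n_rows, n_cols) <= _DENSE_SVD_MAX or k >= min(n_rows, n_cols):
        dense = np.asarray(weighted.matrix.todense(), dtype=float)
        u, s, vt = np.linalg.svd(dense, full_matrices=False)
        u, vt = svd_flip(u, vt)
    else:
        u, s, vt = randomized_svd(
            weighted.matrix.astype(float),
            n_components=min(k, min(n_rows, n_cols)),
            n_iter=7,
            random_state=seed,
        )
    if s.size and s[0] > 0:
        rank = int(np.sum(s > s[0] * max(n_rows, n_cols) * np.finfo(float).eps))
    else:
        rank = 0
    eff_k = max(1, min(k, rank)) if rank else 1
    vectors = u[:, :eff_k] * s[:eff_k]
    meta = {
        "model": model,
        "k_requested": k,
        "k": eff_k,
        "weighting": "ppmi",
        "seed": seed,
        "columns": weighted.columns,
    }
    return SemanticSpace(
        words=list(weighted.vocab.words),
        vectors=np.ascontiguousarray(vectors),
        singular_values=s[:eff_k].copy(),
        meta=meta,
        frequencies=weighted.vocab.counts.copy(),
    )


@dataclass
class SemanticSpace:
    """Words-by-k real-valued vectors plus model metadata."""

    words: list
    vectors: np.ndarray
    singular_values: np.ndarray
    meta: dict
    frequencies: np.ndarray = None  # raw corpus counts, aligned with words
    index: dict = field(default_factory=dict, repr=False)
    _units: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.words) != self.vectors.shape[0]:
            raise ValueError("one vector per word required")
        if not self.index:
            self.index = {w: i for i, w in enumerate(self.words)}
        if np.any(np.diff(self.singular_values) > 1e-9):
            raise ValueError("singular values must be non-increasing")

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def _unit_vectors(self) -> np.ndarray:
        """Row-normalized vectors; zero rows stay zero."""
        if self._units is None:
            norms = np.linalg.norm(self.vectors, axis=1)
            safe = np.where(norms > 0, norms, 1.0)
            self._units = self.vectors / safe[:, None]
        return self._units

    def _row(self, word: str) -> int:
        try:
            return self.index[word]
        except KeyError:
            raise MissingWordError(word) from None

    def cosine(self, w1: str, w2: str) -> float:
        """Cosine of the angle between the vectors of w1 and w2, in [-1, 1]."""
        i, j = self._row(w1), self._row(w2)
        units = self._unit_vectors()
        for w, r in ((w1, i), (w2, j)):
            if not np.any(self.vectors[r]):
                raise UndefinedSimilarityError(f"zero vector for {w!r}")
        return float(np.clip(units[i] @ units[j], -1.0, 1.0))

    def clamped_cosine(self, w1: str, w2: str) -> float:
        """Cosine with negative values clamped to zero (band/class logic)."""
        return max(0.0, self.cosine(w1, w2))

    def clamped_cosines_to(self, target: str) -> np.ndarray:
        """Clamped cosine of every vocabulary word to ``target``.

        Words with an all-zero vector get NaN (similarity undefined).
        """
        i = self._row(target)
        units = self._unit_vectors()
        if not np.any(self.vectors[i]):
            raise UndefinedSimilarityError(f"zero vector for {target!r}")
        sims = units @ units[i]
        np.clip(sims, 0.0, 1.0, out=sims)
        zero = ~np.any(self.vectors != 0, axis=1)
        sims[zero] = np.nan
        return sims

    def words_in_similarity_band(
        self,
        target: str,
        lo: float,
        hi: float,
        predicate: Callable[[str], bool] | None = None,
        include_hi: bool = False,
    ) -> list:
        """All words u != target with clamped cosine in [lo, hi).

        With ``include_hi=True`` the upper bound is included (used for the
        top similarity class, which is closed at 1).  Words whose cosine is
        undefined (zero vector) are never returned.  Order follows the
        space's vocabulary order, hence is deterministic given the space.
        """
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("require 0 <= lo < hi <= 1")
        sims = self.clamped_cosines_to(target)
        t = self._row(target)
        out = []
        for j, c in enumerate(sims):
            if j == t or np.isnan(c):
                continue
            in_band = (lo <= c < hi) or (include_hi and c == hi)
            if in_band and (predicate is None or predicate(self.words[j])):
                out.append(self.words[j])
        return out


def cosine_similarity(space: "SemanticSpace", w1: str, w2: str) -> float:
    """Module-level convenience for :meth:`SemanticSpace.cosine`."""
    return space.cosine(w1, w2)


def build_space(
    corpus: TokenizedCorpus,
    model: str,
    k: int,
    seed: int,
    vocab_cap: int = 100_000,
    window: int = 3,
) -> SemanticSpace:
    """End-to-end space construction: counts -> PPMI -> truncated SVD.

    ``model`` is ``"lsa"`` (word-by-document) or ``"hal"`` (word-by-word
    with the given content-word window).
    """
    vocab = build_vocabulary(corpus, vocab_cap)
    if model == "lsa":
        counts = count_word_by_document(corpus, vocab)
    elif model == "hal":
        counts = count_word_by_word(corpus, vocab, window)
    else:
        raise ValueError(f"unknown model {model!r} (expected 'lsa' or 'hal')")
    weighted = ppmi_transform(counts)
    space = svd_reduce(weighted, k, seed, model=model)
    space.meta["window"] = window if model == "hal" else None
    space.meta["vocab_cap"] = vocab_cap
    return space
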