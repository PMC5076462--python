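"""Semantic-space construction: counts, PPMI, SVD, cosine queries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semprime.dsm import (
    DegenerateMatrixError,
    EmptyCorpusError,
    MissingWordError,
    SemanticSpace,
    Token,
    TokenizedCorpus,
    UndefinedSimilarityError,
    build_vocabulary,
    count_word_by_document,
    count_word_by_word,
    ppmi_transform,
    svd_reduce,
)
from tests.conftest import sentence


def corpus_of(*docs):
    return TokenizedCorpus(documents=[[sentence(s) for s in doc] for doc in docs])


def space_from_vectors(words, vectors):
    vectors = np.asarray(vectors, dtype=float)
    sv = np.linalg.svd(vectors, compute_uv=False)
    return SemanticSpace(words=list(words), vectors=vectors,
                         singular_values=sv, meta={})


class TestVocabulary:
    def test_counts_and_ranks(self):
        vocab = build_vocabulary(corpus_of(["a a b"]), cap=10)
        assert vocab.words == ["a", "b"]
        assert vocab.counts.tolist() == [2, 1]
        assert vocab.rank("a") == 1 and vocab.rank("b") == 2

    def test_cap_truncates(self):
        vocab = build_vocabulary(corpus_of(["a a b"]), cap=1)
        assert vocab.words == ["a"]

    def test_ties_break_lexicographically(self):
        vocab = build_vocabulary(corpus_of(["zeta beta zeta beta alpha"]), cap=10)
        assert vocab.words == ["beta", "zeta", "alpha"]

    def test_empty_corpus_rejected(self):
        with pytest.raises(EmptyCorpusError):
            build_vocabulary(TokenizedCorpus(documents=[]), cap=5)

    def test_matches_brute_force_tally(self, rng):
        words = [f"w{i}" for i in range(30)]
        sentences = [
            " ".join(rng.choice(words, size=rng.integers(1, 12)))
            for _ in range(200)
        ]
        corpus = corpus_of(sentences)
        tally = {}
        for s in sentences:
            for w in s.split():
                tally[w] = tally.get(w, 0) + 1
        vocab = build_vocabulary(corpus, cap=50)
        expected = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        assert vocab.words == [w for w, _ in expected]
        assert vocab.counts.tolist() == [c for _, c in expected]


class TestWordByDocument:
    def test_two_documents(self):
        corpus = corpus_of(["x x"], ["y"])
        vocab = build_vocabulary(corpus, cap=10)
        counts = count_word_by_document(corpus, vocab)
        dense = counts.matrix.toarray()
        x, y = vocab.index["x"], vocab.index["y"]
        assert dense[x].tolist() == [2, 0]
        assert dense[y].tolist() == [0, 1]

    def test_oov_tokens_ignored(self):
        corpus = corpus_of(["x"], ["zzz zzz"])
        vocab = build_vocabulary(corpus_of(["x"]), cap=10)
        counts = count_word_by_document(corpus, vocab)
        assert counts.matrix.toarray()[:, 1].sum() == 0

    def test_matches_per_document_tally(self, rng):
        words = [f"w{i}" for i in range(12)]
        docs = [
            [" ".join(rng.choice(words, size=rng.integers(1, 8)))
             for _ in range(rng.integers(1, 4))]
            for _ in range(20)
        ]
        corpus = corpus_of(*docs)
        vocab = build_vocabulary(corpus, cap=100)
        dense = count_word_by_document(corpus, vocab).matrix.toarray()
        for d, doc in enumerate(docs):
            tokens = " ".join(doc).split()
            for w in vocab.words:
                assert dense[vocab.index[w], d] == tokens.count(w)


def window_pairs_oracle(sentences, vocab, window):
    """O(n^2) enumeration of content-token pairs within the window."""
    n = len(vocab)
    out = np.zeros((n, n), dtype=int)
    for toks in sentences:
        ids = [vocab.index[t.form] for t in toks
               if t.is_content and t.form in vocab.index]
        for i in range(len(ids)):
            for j in range(i + 1, min(i + window + 1, len(ids))):
                if ids[i] != ids[j]:
                    out[ids[i], ids[j]] += 1
                    out[ids[j], ids[i]] += 1
    return out


class TestWordByWord:
    def test_window_three_spans_sentence(self):
        corpus = corpus_of(["a b c d"])
        vocab = build_vocabulary(corpus, cap=10)
        dense = count_word_by_word(corpus, vocab, window=3).matrix.toarray()
        i = vocab.index
        assert dense[i["a"], i["d"]] == 1
        assert dense[i["a"], i["b"]] == 1
        assert np.array_equal(dense, dense.T)
        assert np.all(np.diag(dense) == 0)

    def test_single_token_sentence(self):
        corpus = corpus_of(["solo"])
        vocab = build_vocabulary(corpus, cap=10)
        assert count_word_by_word(corpus, vocab, 3).matrix.nnz == 0

    def test_no_pairs_across_sentences(self):
        corpus = corpus_of(["a b", "c d"])
        vocab = build_vocabulary(corpus, cap=10)
        dense = count_word_by_word(corpus, vocab, 3).matrix.toarray()
        i = vocab.index
        assert dense[i["b"], i["c"]] == 0

    def test_non_content_tokens_excluded(self):
        doc = [[Token("a"), Token("the", is_content=False), Token("b")]]
        corpus = TokenizedCorpus(documents=[doc])
        vocab = build_vocabulary(corpus, cap=10)
        dense = count_word_by_word(corpus, vocab, window=1).matrix.toarray()
        i = vocab.index
        # "the" is dropped first, so a-b are at content distance 1
        assert dense[i["a"], i["b"]] == 1
        assert dense[i["the"]].sum() == 0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        data=st.lists(
            st.lists(st.integers(0, 7), min_size=1, max_size=25),
            min_size=1, max_size=6,
        ),
        window=st.integers(1, 4),
    )
    def test_matches_pair_enumeration_oracle(self, data, window):
        docs = [[" ".join(f"w{i}" for i in s) for s in data]]
        corpus = corpus_of(*docs)
        vocab = build_vocabulary(corpus, cap=100)
        dense = count_word_by_word(corpus, vocab, window).matrix.toarray()
        sentences = [s for _, s in corpus.iter_sentences()]
        assert np.array_equal(dense, window_pairs_oracle(sentences, vocab, window))


def ppmi_oracle(counts):
    """Cell-by-cell probability-ratio computation."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    out = np.zeros_like(counts)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            if counts[i, j] > 0:
                p_ij = counts[i, j] / total
                p_i = counts[i].sum() / total
                p_j = counts[:, j].sum() / total
                out[i, j] = max(0.0, np.log(p_ij / (p_i * p_j)))
    return out


def counts_from_dense(dense, symmetric=False):
    import scipy.sparse as sp

    from semprime.dsm import CooccurrenceCounts, VocabularyTable

    dense = np.asarray(dense)
    n = dense.shape[0]
    vocab = VocabularyTable(
        words=[f"w{i}" for i in range(n)],
        counts=np.maximum(dense.sum(axis=1), 1),
        cap=n,
    )
    return CooccurrenceCounts(
        matrix=sp.csr_matrix(dense),
        vocab=vocab,
        columns="words" if symmetric else "documents",
    )


class TestPPMI:
    def test_uniform_matrix_is_all_zero(self):
        w = ppmi_transform(counts_from_dense(np.ones((3, 4))))
        assert w.matrix.nnz == 0

    def test_diagonal_toy(self):
        w = ppmi_transform(counts_from_dense([[10, 0], [0, 10]]))
        dense = w.matrix.toarray()
        assert dense[0, 0] == pytest.approx(np.log(2), abs=1e-12)
        assert dense[0, 1] == 0 and dense[1, 0] == 0

    def test_zero_cells_stay_zero_and_nonnegative(self, rng):
        dense = rng.integers(0, 4, size=(15, 20))
        w = ppmi_transform(counts_from_dense(dense)).matrix.toarray()
        assert np.all(w >= 0)
        assert np.all(w[dense == 0] == 0)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DegenerateMatrixError):
            ppmi_transform(counts_from_dense(np.zeros((3, 3))))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), rows=st.integers(2, 50),
           cols=st.integers(2, 50))
    def test_matches_probability_oracle(self, seed, rows, cols):
        r = np.random.default_rng(seed)
        dense = r.integers(0, 5, size=(rows, cols)) * (r.random((rows, cols)) < 0.4)
        if dense.sum() == 0:
            dense[0, 0] = 1
        w = ppmi_transform(counts_from_dense(dense)).matrix.toarray()
        assert np.allclose(w, ppmi_oracle(dense), atol=1e-10)


def pairwise_cosines(mat):
    mat = np.asarray(mat, dtype=float)
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = mat / norms
    return unit @ unit.T


class TestSVDReduce:
    def test_diagonal_matrix(self):
        w = counts_from_dense(np.diag([3.0, 2.0, 1.0]))
        from semprime.dsm import WeightedMatrix

        weighted = WeightedMatrix(matrix=w.matrix.astype(float), vocab=w.vocab,
                                  columns="documents")
        space = svd_reduce(weighted, k=3, seed=0)
        assert np.allclose(space.singular_values, [3, 2, 1])
        assert np.allclose(pairwise_cosines(space.vectors),
                           pairwise_cosines(np.diag([3.0, 2.0, 1.0])), atol=1e-8)

    def test_full_rank_preserves_row_cosines(self, rng):
        dense = np.abs(rng.normal(size=(12, 18)))
        w = ppmi_transform(counts_from_dense((dense * 10).astype(int) + 1))
        space = svd_reduce(w, k=12, seed=0)
        got = pairwise_cosines(space.vectors)
        want = pairwise_cosines(w.matrix.toarray())
        assert np.allclose(got, want, atol=1e-8)

    def test_k1_collinear(self, rng):
        import scipy.sparse as sp

        from semprime.dsm import VocabularyTable, WeightedMatrix

        dense = np.abs(rng.normal(size=(6, 6))) + 0.1
        vocab = VocabularyTable(words=[f"w{i}" for i in range(6)],
                                counts=np.ones(6, dtype=int), cap=6)
        weighted = WeightedMatrix(matrix=sp.csr_matrix(dense), vocab=vocab,
                                  columns="documents")
        space = svd_reduce(weighted, k=1, seed=0)
        assert space.k == 1
        cos = pairwise_cosines(space.vectors)
        assert np.all(np.isin(np.round(cos, 6), [-1.0, 0.0, 1.0]))

    def test_k_larger_than_both_dims_rejected(self, rng):
        w = ppmi_transform(counts_from_dense(rng.integers(1, 5, (4, 5))))
        with pytest.raises(ValueError):
            svd_reduce(w, k=6, seed=0)

    def test_singular_values_non_increasing_and_reproducible(self, rng):
        dense = (rng.random((700, 650)) < 0.01) * rng.integers(1, 9, (700, 650))
        w = ppmi_transform(counts_from_dense(dense))
        a = svd_reduce(w, k=20, seed=42)
        b = svd_reduce(w, k=20, seed=42)
        assert np.all(np.diff(a.singular_values) <= 1e-9)
        assert np.array_equal(a.vectors, b.vectors)  # bit-for-bit


class TestCosineQueries:
    def test_self_cosine_is_one(self):
        s = space_from_vectors(["u", "v"], [[1.0, 2.0], [0.0, 1.0]])
        assert s.cosine("u", "u") == pytest.approx(1.0)

    def test_orthogonal_and_oblique(self):
        s = space_from_vectors(["x", "y", "d"], [[1, 0], [0, 1], [1, 1]])
        assert s.cosine("x", "y") == pytest.approx(0.0)
        assert s.cosine("x", "d") == pytest.approx(0.7071, abs=1e-4)
        assert s.cosine("d", "x") == s.cosine("x", "d")

    def test_missing_and_zero_vector_errors(self):
        s = space_from_vectors(["ok", "zero"], [[1, 0], [0, 0]])
        with pytest.raises(MissingWordError):
            s.cosine("absent", "ok")
        with pytest.raises(UndefinedSimilarityError):
            s.cosine("zero", "ok")

    def test_band_full_and_empty(self):
        s = space_from_vectors(
            ["t", "hi", "mid", "neg"],
            [[1, 0], [0.95, 0.31], [1, 1], [-1, 0.01]],
        )
        full = s.words_in_similarity_band("t", 0.0, 1.0)
        assert set(full) == {"hi", "mid", "neg"}  # neg clamps to 0
        assert s.words_in_similarity_band("t", 0.999, 1.0) == []

    def test_band_matches_exhaustive_scan(self, rng):
        vecs = rng.normal(size=(6, 4))
        words = [f"w{i}" for i in range(6)]
        s = space_from_vectors(words, vecs)
        for lo, hi in [(0.0, 0.3), (0.3, 0.7), (0.7, 1.0)]:
            got = s.words_in_similarity_band("w0", lo, hi)
            want = [
                w for w in words[1:]
                if lo <= max(0.0, s.cosine("w0", w)) < hi
            ]
            assert got == want

    def test_clamped_cosine_bounds(self, rng):
        vecs = rng.normal(size=(8, 3))
        s = space_from_vectors([f"w{i}" for i in range(8)], vecs)
        for i in range(8):
            for j in range(8):
                c = s.cosine(f"w{i}", f"w{j}")
                assert -1.0 <= c <= 1.0
                assert 0.0 <= s.clamped_cosine(f"w{i}", f"w{j}") <= 1.0
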