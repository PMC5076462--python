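"""Stimulus generation: pools, class assignment, prime sampling, blocks."""

import numpy as np
import pytest
from scipy import stats

from semprime.dsm import MissingWordError, SemanticSpace
from semprime.items import (
    GenerationFailureError,
    ItemPair,
    ItemSet,
    LexiconEntry,
    PoolExhaustedError,
    PRIME_CONSTRAINTS,
    SimilarityClassScheme,
    TARGET_CONSTRAINTS,
    assemble_blocks,
    assign_similarity_classes,
    frequency_class,
    generate_item_set,
    generate_nonwords,
    sample_prime,
    select_word_pool,
    verify_matching,
)


def entry(word, freq=1000, fclass=10, concrete=True):
    return LexiconEntry(word=word, frequency=freq, frequency_class=fclass,
                        length=len(word), is_concrete_noun=concrete)


def make_space(words, vectors):
    vectors = np.asarray(vectors, dtype=float)
    sv = np.sort(np.linalg.svd(vectors, compute_uv=False))[::-1]
    return SemanticSpace(words=list(words), vectors=vectors,
                        singular_values=sv, meta={})


def ring_space(n_words, seed=0):
    """Words on a half-circle: every cosine band is well populated."""
    rng = np.random.default_rng(seed)
    angles = np.sort(rng.uniform(0, np.pi, n_words))
    vectors = np.column_stack([np.cos(angles), np.sin(angles)])
    return make_space([f"word{i:03d}" for i in range(n_words)], vectors)


class TestScheme:
    def test_default_partition(self):
        s = SimilarityClassScheme.default()
        assert s.n_classes == 10
        assert s.edges[0] == 0.0 and s.edges[-1] == 1.0
        assert s.interval(0) == (0.0, 0.09, False)
        assert s.interval(9) == (0.81, 1.0, True)

    def test_class_of_boundaries(self):
        s = SimilarityClassScheme.default()
        assert s.class_of(0.0) == 0
        assert s.class_of(0.09) == 1  # half-open: 0.09 belongs to class 2's lo
        assert s.class_of(0.8099) == 8
        assert s.class_of(1.0) == 9

    def test_parse_round_trip(self):
        s = SimilarityClassScheme.parse("0:0.5:1")
        assert s.n_classes == 2

    @pytest.mark.parametrize("bad", ["0.1:1", "0:1.2", "0:0.5:0.4:1"])
    def test_invalid_schemes_rejected(self, bad):
        with pytest.raises(ValueError):
            SimilarityClassScheme.parse(bad)


class TestFrequencyClass:
    def test_leipzig_convention(self):
        assert frequency_class(1000, 1000) == 0
        assert frequency_class(1000, 1024000) == 10
        with pytest.raises(ValueError):
            frequency_class(0, 100)


class TestWordPool:
    def lexicon(self, n_eligible=300, n_other=50):
        lex = [entry(f"target{i:03d}") for i in range(n_eligible)]
        lex += [entry(f"xx{i}", fclass=2) for i in range(n_other)]
        return lex

    def test_exact_pool_split(self):
        targets, nw = select_word_pool(self.lexicon(), TARGET_CONSTRAINTS,
                                       n_pool=300, n_targets=200, seed=0)
        assert len(targets) == 200 and len(nw) == 100
        assert not set(targets) & set(nw)

    def test_empty_pool(self):
        targets, nw = select_word_pool(self.lexicon(), TARGET_CONSTRAINTS,
                                       n_pool=0, n_targets=0, seed=0)
        assert targets == [] and nw == []

    def test_deterministic_given_seed(self):
        lex = self.lexicon(10, 0)
        a = select_word_pool(lex, TARGET_CONSTRAINTS, 10, 7, seed=99)
        b = select_word_pool(lex, TARGET_CONSTRAINTS, 10, 7, seed=99)
        assert a == b

    def test_exhausted_pool_names_binding_constraint(self):
        lex = [entry(f"w{i:03d}", fclass=3) for i in range(300)]
        with pytest.raises(PoolExhaustedError, match="frequency class"):
            select_word_pool(lex, TARGET_CONSTRAINTS, 300, 200, seed=0)


class TestClassAssignment:
    def test_exact_equality_when_divisible(self):
        scheme = SimilarityClassScheme.default()
        targets = [f"t{i}" for i in range(200)]
        assignment = assign_similarity_classes(targets, scheme, seed=0)
        sizes = [list(assignment.values()).count(c) for c in range(10)]
        assert sizes == [20] * 10

    def test_empty_targets(self):
        assert assign_similarity_classes([], SimilarityClassScheme.default(), 0) == {}

    def test_pigeonhole_sizes(self):
        scheme = SimilarityClassScheme.parse("0:0.3:0.6:1")
        assignment = assign_similarity_classes([f"t{i}" for i in range(7)],
                                               scheme, seed=5)
        sizes = sorted(list(assignment.values()).count(c) for c in range(3))
        assert sizes == [2, 2, 3]

    def test_assignment_varies_with_seed(self):
        scheme = SimilarityClassScheme.default()
        targets = [f"t{i}" for i in range(50)]
        a = assign_similarity_classes(targets, scheme, seed=1)
        b = assign_similarity_classes(targets, scheme, seed=2)
        assert a != b


class TestSamplePrime:
    def setup_method(self):
        self.space = ring_space(60)
        self.scheme = SimilarityClassScheme.default()
        self.lexicon = {w: entry(w) for w in self.space.words}

    def test_forced_choice(self):
        target = self.space.words[0]
        candidates = self.space.words_in_similarity_band(target, 0.45, 0.54)
        excluded = set(self.space.words) - {candidates[0], target}
        got = sample_prime(target, 5, self.scheme, self.space, self.lexicon,
                           excluded, PRIME_CONSTRAINTS, seed=0)
        assert got == candidates[0]

    def test_empty_candidate_set(self):
        target = self.space.words[0]
        got = sample_prime(target, 5, self.scheme, self.space, self.lexicon,
                           set(self.space.words), PRIME_CONSTRAINTS, seed=0)
        assert got is None

    def test_missing_target(self):
        with pytest.raises(MissingWordError):
            sample_prime("absent", 0, self.scheme, self.space, self.lexicon,
                         set(), PRIME_CONSTRAINTS, seed=0)

    def test_draws_always_satisfy_constraints(self):
        rng = np.random.default_rng(7)
        target = self.space.words[30]
        for _ in range(300):
            ci = int(rng.integers(10))
            got = sample_prime(target, ci, self.scheme, self.space,
                               self.lexicon, {target}, PRIME_CONSTRAINTS, rng)
            if got is None:
                continue
            lo, hi, closed = self.scheme.interval(ci)
            c = self.space.clamped_cosine(got, target)
            assert (lo <= c < hi) or (closed and c == hi)
            assert PRIME_CONSTRAINTS.satisfied_by(self.lexicon[got])


class TestGenerateItemSet:
    def test_abundant_space_no_reassignment(self):
        space = ring_space(400)
        lexicon = [entry(w) for w in space.words]
        targets = space.words[::8][:40]
        scheme = SimilarityClassScheme.default()
        item_set = generate_item_set(targets, scheme, space, lexicon, seed=3)
        assert len(item_set.word_pairs) == 40
        assert item_set.reassignments == []
        assert sum(item_set.realized_allocation.values()) == 40
        words = [w for p in item_set.word_pairs for w in (p.prime, p.target)]
        assert len(words) == len(set(words))

    def test_empty_band_forces_reassignment(self):
        # two tight clusters: cosines are either ~1 or ~0, middle bands empty
        rng = np.random.default_rng(0)
        vecs = []
        for i in range(40):
            base = np.array([1.0, 0.0]) if i % 2 else np.array([0.0, 1.0])
            vecs.append(base + rng.normal(0, 0.01, 2))
        space = make_space([f"wd{i:02d}" for i in range(40)], vecs)
        lexicon = [entry(w) for w in space.words]
        scheme = SimilarityClassScheme.default()
        item_set = generate_item_set(["wd00"], scheme, space, lexicon, seed=1,
                                     max_reassignments=50)
        assert len(item_set.word_pairs) == 1
        # the target cannot stay in a middle class
        assert item_set.word_pairs[0].class_index in (0, 9) or \
            item_set.reassignments == []

    def test_generation_failure_lists_targets(self):
        space = make_space(["a", "b"], [[1.0, 0.0], [1.0, 0.0]])
        lexicon = [entry("a"), entry("b")]
        scheme = SimilarityClassScheme.parse("0:0.5:1")
        with pytest.raises(GenerationFailureError, match="a"):
            # only candidate "b" has cosine 1 with "a": class 0 is empty
            generate_item_set(["a"], SimilarityClassScheme.parse("0:0.5:1"),
                              space, lexicon, seed=0, max_reassignments=0)

    def test_deterministic(self):
        space = ring_space(300)
        lexicon = [entry(w) for w in space.words]
        targets = space.words[::10][:20]
        scheme = SimilarityClassScheme.default()
        a = generate_item_set(targets, scheme, space, lexicon, seed=11)
        b = generate_item_set(targets, scheme, space, lexicon, seed=11)
        assert [(p.prime, p.target, p.class_index) for p in a.word_pairs] == \
               [(p.prime, p.target, p.class_index) for p in b.word_pairs]


class TestNonwords:
    def test_empty(self):
        assert generate_nonwords(0, (4, 10), ["word"], set(), seed=0) == []

    def test_full_set_properties(self):
        refs = [f"ref{'a' * (i % 6)}" for i in range(200)]
        lexicon_words = set(refs)
        nw = generate_nonwords(100, (3, 10), refs, lexicon_words, seed=5)
        assert len(nw) == 100
        assert len(set(nw)) == 100
        assert not set(nw) & lexicon_words
        assert all(3 <= len(w) <= 10 for w in nw)

    def test_lengths_match_references(self):
        rng = np.random.default_rng(2)
        refs = ["".join(rng.choice(list("bcdlmn"), size=rng.integers(4, 10)))
                for _ in range(200)]
        nw = generate_nonwords(100, (4, 10), refs, set(refs), seed=9)
        t, p = stats.ttest_ind([len(w) for w in nw], [len(w) for w in refs])
        assert p > 0.05

    def test_deterministic(self):
        refs = ["haus", "baum", "tisch", "blume", "garten"]
        a = generate_nonwords(5, (4, 10), refs, set(refs), seed=77)
        b = generate_nonwords(5, (4, 10), refs, set(refs), seed=77)
        assert a == b


def build_item_set(word_pairs, nonword_pairs, scheme=None):
    scheme = scheme or SimilarityClassScheme.default()
    realized = {ci: 0 for ci in range(scheme.n_classes)}
    for p in word_pairs:
        realized[p.class_index] += 1
    return ItemSet(word_pairs=word_pairs, nonword_pairs=nonword_pairs,
                   scheme=scheme, planned_allocation=dict(realized),
                   realized_allocation=realized, reassignments=[])


class TestVerifyMatching:
    def pairs(self, rng, n=50, cosine=None, prime_len=None):
        scheme = SimilarityClassScheme.default()
        word_pairs, lexicon = [], []
        for i in range(n):
            c = cosine(i) if cosine else rng.uniform(0, 0.999)
            plen = prime_len(i, c) if prime_len else int(rng.integers(4, 10))
            prime = (f"p{i:03d}" + "x" * 10)[:plen]
            target = f"tgt{i:03d}"
            word_pairs.append(ItemPair(prime=prime, target=target, cosine=c,
                                       class_index=scheme.class_of(c),
                                       trial_type="word"))
            lexicon += [entry(prime), entry(target)]
        nonword_pairs = []
        for i in range(25):
            plen = int(rng.integers(4, 10))
            prime = ("q" * plen + str(i))[:plen]
            nonword_pairs.append(ItemPair(prime=prime, target=f"nw{i:03d}",
                                          cosine=float("nan"), class_index=-1,
                                          trial_type="nonword"))
            lexicon.append(entry(prime))
        return build_item_set(word_pairs, nonword_pairs), lexicon

    def test_degenerate_cosine_flagged_skipped(self, rng):
        item_set, lexicon = self.pairs(rng, cosine=lambda i: 0.5)
        report = verify_matching(item_set, lexicon)
        skipped = [c for c in report.checks if c.skipped]
        assert any(c.name.startswith("cosine") for c in skipped)

    def test_null_pass_rate_near_nominal(self):
        # identically-distributed groups: each check should pass ~95% of runs
        passes, reps = 0, 200
        for rep in range(reps):
            r = np.random.default_rng(rep)
            a = r.integers(4, 10, 100)
            b = r.integers(4, 10, 100)
            _, p = stats.ttest_ind(a, b, equal_var=False)
            passes += p > 0.05
        assert 0.90 <= passes / reps <= 0.99

    def test_planted_violation_flagged(self, rng):
        item_set, lexicon = self.pairs(
            rng, cosine=lambda i: i / 50.0,
            prime_len=lambda i, c: 4 + int(c * 5.99),  # length grows with cosine
        )
        report = verify_matching(item_set, lexicon)
        by_name = {c.name: c for c in report.checks}
        assert not by_name["cosine ~ prime_length"].passed
        assert not report.overall_pass


class TestAssembleBlocks:
    def make_items(self, n_words=200, n_nonwords=100):
        scheme = SimilarityClassScheme.default()
        rng = np.random.default_rng(0)
        wp = [ItemPair(prime=f"p{i:03d}", target=f"t{i:03d}",
                       cosine=float(rng.uniform(0, 0.999)),
                       class_index=0, trial_type="word")
              for i in range(n_words)]
        for i, p in enumerate(wp):
            wp[i] = ItemPair(prime=p.prime, target=p.target, cosine=p.cosine,
                             class_index=scheme.class_of(p.cosine),
                             trial_type="word")
        nwp = [ItemPair(prime=f"q{i:03d}", target=f"n{i:03d}",
                        cosine=float("nan"), class_index=-1,
                        trial_type="nonword") for i in range(n_nonwords)]
        return build_item_set(wp, nwp)

    def test_block_composition(self):
        plan = assemble_blocks(self.make_items(), 4, 50, 25, 8, seed=0)
        for block in plan.blocks:
            assert sum(p.trial_type == "word" for p in block) == 50
            assert sum(p.trial_type == "nonword" for p in block) == 25

    def test_latin_square_rows(self):
        plan = assemble_blocks(self.make_items(), 4, 50, 25, 4, seed=0)
        rows = plan.participant_orders
        assert all(sorted(r) == [0, 1, 2, 3] for r in rows)
        for pos in range(4):
            assert sorted(r[pos] for r in rows) == [0, 1, 2, 3]

    def test_every_item_in_exactly_one_block(self):
        items = self.make_items()
        plan = assemble_blocks(items, 4, 50, 25, 4, seed=1)
        seen = [p.target for block in plan.blocks for p in block]
        expected = [p.target for p in items.word_pairs + items.nonword_pairs]
        assert sorted(seen) == sorted(expected)

    def test_indivisible_counts_rejected(self):
        with pytest.raises(ValueError):
            assemble_blocks(self.make_items(199, 100), 4, 50, 25, 4, seed=0)

    def test_schedule_metadata(self):
        plan = assemble_blocks(self.make_items(), 4, 50, 25, 2, seed=0)
        assert plan.schedule == {"soa_ms": 1000, "timeout_ms": 3000,
                                 "feedback_ms": 1000}
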