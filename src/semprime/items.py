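"""Similarity-stratified stimulus generation for lexical-decision priming.

The generation procedure mirrors the pseudo-random item-construction
method used in cosine-controlled priming studies:

1. select a pool of medium-frequency concrete nouns and split it into
   targets and primes-for-nonword-trials;
2. partition [0, 1] into ten contiguous cosine-similarity classes and
   assign an equal number of targets to each class;
3. for every target, sample a prime uniformly from all words whose
   clamped cosine to the target falls in the assigned class and which
   satisfy length/frequency/concreteness constraints, re-assigning the
   target to a random other class when no candidate exists;
4. construct pronounceable nonword targets length-matched to the real
   targets;
5. verify that the stratification did not induce confounds (lengths and
   frequencies balanced across trial types, cosine uncorrelated with
   lengths and frequencies);
6. partition the items into blocks and balance block order across
   participants with a cyclic Latin square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dsm import SemanticSpace

__all__ = [
    "LexiconEntry",
    "SimilarityClassScheme",
    "Constraints",
    "TARGET_CONSTRAINTS",
    "PRIME_CONSTRAINTS",
    "ItemPair",
    "ItemSet",
    "MatchingCheck",
    "MatchingReport",
    "BlockPlan",
    "frequency_class",
    "select_word_pool",
    "assign_similarity_classes",
    "sample_prime",
    "generate_item_set",
    "generate_nonwords",
    "verify_matching",
    "generate_matched_item_set",
    "assemble_blocks",
    "PoolExhaustedError",
    "GenerationFailureError",
]

VOWELS = set("aeiouy")


class PoolExhaustedError(ValueError):
    """Not enough lexicon entries satisfy the pool constraints."""


class GenerationFailureError(RuntimeError):
    """Some targets could not receive a prime within the attempt budget."""

    def __init__(self, stuck_targets: list):
        self.stuck_targets = list(stuck_targets)
        super().__init__(
            f"no eligible prime found for {len(self.stuck_targets)} target(s): "
            f"{', '.join(self.stuck_targets)}"
        )


def frequency_class(freq: float, f_max: float) -> int:
    """Leipzig-style frequency class: round(log2(f_max / f)).

    Class 0 is the most frequent word; each further class is roughly a
    factor-two drop in frequency.
    """
    if freq <= 0 or f_max <= 0:
        raise ValueError("frequencies must be positive")
    return int(round(math.log2(f_max / freq)))


@dataclass(frozen=True)
class LexiconEntry:
    """One lexicon row: surface form plus the matching covariates."""

    word: str
    frequency: int
    frequency_class: int
    length: int
    is_concrete_noun: bool

    def __post_init__(self) -> None:
        if self.length != len(self.word):
            raise ValueError(f"length field must equal len({self.word!r})")
        if self.frequency_class < 0:
            raise ValueError("frequency_class must be >= 0")


@dataclass(frozen=True)
class SimilarityClassScheme:
    """Contiguous half-open intervals partitioning [0, 1].

    Class i is [edges[i], edges[i+1]); the last class is closed at 1 so
    the partition covers the full clamped-cosine range.
    """

    edges: tuple

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 2 or e[0] != 0.0 or e[-1] != 1.0:
            raise ValueError("edges must run from 0.0 to 1.0")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("edges must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.edges) - 1

    def interval(self, i: int) -> tuple:
        """(lo, hi, closed_top) for class ``i``."""
        if not 0 <= i < self.n_classes:
            raise IndexError(f"no similarity class {i}")
        return self.edges[i], self.edges[i + 1], i == self.n_classes - 1

    def class_of(self, cosine: float) -> int:
        """Index of the class containing a clamped cosine value."""
        if not 0.0 <= cosine <= 1.0:
            raise ValueError("clamped cosine must lie in [0, 1]")
        if cosine == 1.0:
            return self.n_classes - 1
        return int(np.searchsorted(self.edges, cosine, side="right") - 1)

    @classmethod
    def default(cls) -> "SimilarityClassScheme":
        """Ten classes: [0, .09), [.09, .18), ..., [.81, 1]."""
        edges = tuple(round(0.09 * i, 2) for i in range(10)) + (1.0,)
        return cls(edges=edges)

    @classmethod
    def parse(cls, text: str) -> "SimilarityClassScheme":
        """Parse a colon-separated edge list such as ``0:0.09:...:1``."""
        return cls(edges=tuple(float(x) for x in text.split(":")))


@dataclass(frozen=True)
class Constraints:
    """Lexical eligibility window for pool or prime selection."""

    min_length: int
    max_length: int
    min_freq_class: int
    max_freq_class: int
    concrete_noun: bool = True

    def satisfied_by(self, entry: LexiconEntry) -> bool:
        return (
            (not self.concrete_noun or entry.is_concrete_noun)
            and self.min_length <= entry.length <= self.max_length
            and self.min_freq_class <= entry.frequency_class <= self.max_freq_class
        )


# Experiment defaults: targets are concrete nouns, 4-9 letters, frequency
# class 10-15; primes may be one letter longer and one class wider on
# each side (4-10 letters, class 9-16).
TARGET_CONSTRAINTS = Constraints(4, 9, 10, 15)
PRIME_CONSTRAINTS = Constraints(4, 10, 9, 16)


@dataclass(frozen=True)
class ItemPair:
    """A prime-target pair; ``cosine`` is NaN for nonword trials."""

    prime: str
    target: str
    cosine: float
    class_index: int
    trial_type: str  # "word" | "nonword"

    def __post_init__(self) -> None:
        if self.trial_type not in ("word", "nonword"):
            raise ValueError(f"bad trial_type {self.trial_type!r}")
        if self.trial_type == "word":
            if self.prime == self.target:
                raise ValueError("prime must differ from target")
            if not 0.0 <= self.cosine <= 1.0:
                raise ValueError("word-trial cosine must be a clamped value in [0,1]")


@dataclass
class ItemSet:
    """The complete stimulus list of one experiment."""

    word_pairs: list
    nonword_pairs: list
    scheme: SimilarityClassScheme
    planned_allocation: dict
    realized_allocation: dict
    reassignments: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for p in self.word_pairs:
            for w in (p.prime, p.target):
                if w in seen:
                    raise ValueError(f"word {w!r} reused within the item material")
                seen.add(w)
            lo, hi, closed = self.scheme.interval(p.class_index)
            ok = lo <= p.cosine < hi or (closed and p.cosine == hi)
            if not ok:
                raise ValueError(
                    f"cosine {p.cosine:.3f} outside class {p.class_index} for "
                    f"{p.prime}-{p.target}"
                )


@dataclass(frozen=True)
class MatchingCheck:
    name: str
    statistic: float
    p_value: float
    passed: bool
    skipped: bool = False


@dataclass
class MatchingReport:
    checks: list
    alpha: float

    @property
    def overall_pass(self) -> bool:
        return all(c.passed for c in self.checks if not c.skipped)


@dataclass
class BlockPlan:
    """Item-to-block partition plus per-participant block orders."""

    blocks: list  # list of lists of ItemPair
    participant_orders: list  # Latin-square rows, one per participant
    participant_trials: list  # full per-participant trial sequences
    practice: list
    schedule: dict


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def select_word_pool(
    lexicon: list,
    target_constraints: Constraints,
    n_pool: int,
    n_targets: int,
    seed,
) -> tuple:
    """Sample the word pool and split it into targets and nonword-trial primes.

    Returns ``(targets, nonword_primes)``: a uniform sample without
    replacement of ``n_pool`` eligible words, of which ``n_targets`` become
    targets and the rest primes for the nonword trials.
    """
    if not 0 <= n_targets <= n_pool:
        raise ValueError("need 0 <= n_targets <= n_pool")
    rng = _as_rng(seed)
    eligible = [e.word for e in lexicon if target_constraints.satisfied_by(e)]
    if len(eligible) < n_pool:
        c = target_constraints
        by = {
            "concrete_noun": sum(e.is_concrete_noun for e in lexicon),
            f"length {c.min_length}-{c.max_length}": sum(
                c.min_length <= e.length <= c.max_length for e in lexicon
            ),
            f"frequency class {c.min_freq_class}-{c.max_freq_class}": sum(
                c.min_freq_class <= e.frequency_class <= c.max_freq_class
                for e in lexicon
            ),
        }
        binding = min(by, key=by.get)
        raise PoolExhaustedError(
            f"only {len(eligible)} of {n_pool} required words satisfy all pool "
            f"constraints; binding constraint: {binding} ({by[binding]} words)"
        )
    if n_pool == 0:
        return [], []
    pool = list(rng.choice(eligible, size=n_pool, replace=False))
    targets = pool[:n_targets]
    nonword_primes = pool[n_targets:]
    return targets, nonword_primes


def assign_similarity_classes(targets: list, scheme: SimilarityClassScheme, seed) -> dict:
    """Assign each target a similarity class, as equally as possible.

    Class sizes differ by at most one, with exact equality whenever the
    class count divides the target count; which targets land in which
    class is uniformly random given the seed.
    """
    if scheme.n_classes < 1:
        raise ValueError("scheme has no classes")
    rng = _as_rng(seed)
    if not targets:
        return {}
    order = list(rng.permutation(len(targets)))
    n, c = len(targets), scheme.n_classes
    base, extra = divmod(n, c)
    sizes = np.full(c, base, dtype=int)
    if extra:
        sizes[rng.choice(c, size=extra, replace=False)] += 1
    assignment = {}
    pos = 0
    for ci in range(c):
        for j in order[pos : pos + sizes[ci]]:
            assignment[targets[j]] = ci
        pos += sizes[ci]
    return assignment


def sample_prime(
    target: str,
    class_index: int,
    scheme: SimilarityClassScheme,
    space: SemanticSpace,
    lexicon_index: dict,
    excluded: set,
    prime_constraints: Constraints,
    seed,
):
    """Uniform draw from the eligible primes of one similarity class.

    The candidate set is the intersection of (i) words within the class's
    cosine band around the target, (ii) prime-eligible lexicon entries and
    (iii) words not yet used.  Returns ``None`` when the set is empty.
    """
    rng = _as_rng(seed)
    lo, hi, closed = scheme.interval(class_index)

    def eligible(word: str) -> bool:
        entry = lexicon_index.get(word)
        return (
            entry is not None
            and word not in excluded
            and prime_constraints.satisfied_by(entry)
        )

    candidates = space.words_in_similarity_band(
        target, lo, hi, predicate=eligible, include_hi=closed
    )
    if not candidates:
        return None
    return candidates[int(rng.integers(len(candidates)))]


def generate_item_set(
    targets: list,
    scheme: SimilarityClassScheme,
    space: SemanticSpace,
    lexicon: list,
    prime_constraints: Constraints = PRIME_CONSTRAINTS,
    seed=0,
    max_reassignments: int = 20,
    nonword_primes: list = (),
    nonword_targets: list = (),
    extra_excluded: set = frozenset(),
    provenance: dict | None = None,
) -> ItemSet:
    """Run the constrained prime-sampling loop over all targets.

    Every target gets a prime from its assigned class; when a class band
    holds no eligible candidate the target is re-assigned uniformly at
    random to another class, up to ``max_reassignments`` attempts per
    target.  Words are never reused across primes and targets.
    """
    rng = _as_rng(seed)
    lexicon_index = {e.word: e for e in lexicon}
    assignment = assign_similarity_classes(targets, scheme, rng)
    planned = {
        ci: sum(1 for t in targets if assignment[t] == ci)
        for ci in range(scheme.n_classes)
    }
    excluded = set(targets) | set(nonword_primes) | set(extra_excluded)
    word_pairs, reassignments, stuck = [], [], []
    for target in targets:
        ci = assignment[target]
        prime = sample_prime(
            target, ci, scheme, space, lexicon_index, excluded, prime_constraints, rng
        )
        attempts = 0
        while prime is None and attempts < max_reassignments:
            others = [c for c in range(scheme.n_classes) if c != ci]
            new_ci = others[int(rng.integers(len(others)))]
            reassignments.append((target, ci, new_ci))
            ci = new_ci
            prime = sample_prime(
                target, ci, scheme, space, lexicon_index, excluded, prime_constraints, rng
            )
            attempts += 1
        if prime is None:
            stuck.append(target)
            continue
        cos = space.clamped_cosine(prime, target)
        word_pairs.append(
            ItemPair(prime=prime, target=target, cosine=cos, class_index=ci,
                     trial_type="word")
        )
        excluded.add(prime)
    if stuck:
        raise GenerationFailureError(stuck)
    realized = {ci: 0 for ci in range(scheme.n_classes)}
    for p in word_pairs:
        realized[p.class_index] += 1
    nonword_pairs = [
        ItemPair(prime=pr, target=nw, cosine=float("nan"), class_index=-1,
                 trial_type="nonword")
        for pr, nw in zip(nonword_primes, nonword_targets)
    ]
    return ItemSet(
        word_pairs=word_pairs,
        nonword_pairs=nonword_pairs,
        scheme=scheme,
        planned_allocation=planned,
        realized_allocation=realized,
        reassignments=reassignments,
        provenance=dict(provenance or {}, seed=str(seed)),
    )


def _cv_pattern(word: str) -> str:
    return "".join("v" if ch.lower() in VOWELS else "c" for ch in word)


def generate_nonwords(
    n: int,
    length_range: tuple,
    reference_words: list,
    lexicon_words: set,
    seed,
    max_retries: int = 200,
) -> list:
    """Pronounceable-looking nonword strings, length-matched to references.

    Each nonword copies the consonant/vowel pattern of a sampled reference
    word and refills every slot with a random letter of the same class, so
    the length distribution matches the references and a two-sample t-test
    on lengths stays non-significant.  Collisions with lexicon words (and
    among nonwords) are rejected and resampled.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    rng = _as_rng(seed)
    lo, hi = length_range
    refs = [w for w in reference_words if lo <= len(w) <= hi]
    if not refs:
        raise ValueError("no reference word within the length range")
    if n <= len(refs):
        chosen = list(rng.choice(refs, size=n, replace=False))
    else:
        chosen = list(rng.choice(refs, size=n, replace=True))
    consonants = sorted(set("bcdfghklmnprstwz"))
    vowels = sorted("aeiou")
    out, used = [], set()
    for ref in chosen:
        pattern = _cv_pattern(ref)
        for _ in range(max_retries):
            letters = [
                vowels[int(rng.integers(len(vowels)))]
                if ch == "v"
                else consonants[int(rng.integers(len(consonants)))]
                for ch in pattern
            ]
            cand = "".join(letters)
            if cand not in lexicon_words and cand not in used:
                out.append(cand)
                used.add(cand)
                break
        else:
            raise RuntimeError(
                f"could not build a collision-free nonword for pattern {pattern!r}"
            )
    return out


def _ttest_check(name: str, a, b, alpha: float) -> MatchingCheck:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2 or (np.var(a) == 0 and np.var(b) == 0):
        return MatchingCheck(name, float("nan"), float("nan"), True, skipped=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return MatchingCheck(name, float(t), float(p), bool(p > alpha))


def _corr_check(name: str, x, y, alpha: float) -> MatchingCheck:
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 3 or np.var(x) == 0 or np.var(y) == 0:
        return MatchingCheck(name, float("nan"), float("nan"), True, skipped=True)
    r, p = stats.pearsonr(x, y)
    return MatchingCheck(name, float(r), float(p), bool(p > alpha))


def verify_matching(item_set: ItemSet, lexicon: list, alpha: float = 0.05) -> MatchingReport:
    """Diagnostic matching checks on a finished item set.

    Two-sample t-tests: nonword vs. real target lengths; word-trial vs.
    nonword-trial prime lengths and frequency classes.  Pearson
    correlations: cosine against target/prime length and frequency class.
    A check passes when its p-value exceeds ``alpha``; zero-variance
    checks are flagged as skipped.
    """
    idx = {e.word: e for e in lexicon}
    wp, nwp = item_set.word_pairs, item_set.nonword_pairs
    checks = [
        _ttest_check(
            "target_length: word vs nonword",
            [len(p.target) for p in wp],
            [len(p.target) for p in nwp],
            alpha,
        ),
        _ttest_check(
            "prime_length: word vs nonword trials",
            [idx[p.prime].length for p in wp],
            [idx[p.prime].length for p in nwp],
            alpha,
        ),
        _ttest_check(
            "prime_freq_class: word vs nonword trials",
            [idx[p.prime].frequency_class for p in wp],
            [idx[p.prime].frequency_class for p in nwp],
            alpha,
        ),
    ]
    cosines = [p.cosine for p in wp]
    for name, vals in [
        ("cosine ~ target_length", [len(p.target) for p in wp]),
        ("cosine ~ target_freq_class", [idx[p.target].frequency_class for p in wp]),
        ("cosine ~ prime_length", [idx[p.prime].length for p in wp]),
        ("cosine ~ prime_freq_class", [idx[p.prime].frequency_class for p in wp]),
    ]:
        checks.append(_corr_check(name, cosines, vals, alpha))
    return MatchingReport(checks=checks, alpha=alpha)


def generate_matched_item_set(
    targets: list,
    scheme: SimilarityClassScheme,
    space: SemanticSpace,
    lexicon: list,
    prime_constraints: Constraints = PRIME_CONSTRAINTS,
    seed=0,
    alpha: float = 0.05,
    max_regenerations: int = 10,
    require_planned_allocation: bool = False,
    **kwargs,
) -> tuple:
    """Regenerate-until-matched wrapper around :func:`generate_item_set`.

    Draws a fresh derived seed until :func:`verify_matching` passes or the
    retry budget is exhausted (the last set is then returned with its
    failing report).  With ``require_planned_allocation`` a draw is also
    retried when any target had to be re-assigned, so the realized
    class allocation equals the planned one.
    """
    rng = _as_rng(seed)
    item_set = report = None
    for _ in range(max_regenerations):
        sub_seed = int(rng.integers(2**31 - 1))
        item_set = generate_item_set(
            targets, scheme, space, lexicon, prime_constraints, sub_seed, **kwargs
        )
        report = verify_matching(item_set, lexicon, alpha)
        if report.overall_pass and not (
            require_planned_allocation and item_set.reassignments
        ):
            break
    return item_set, report


def assemble_blocks(
    item_set: ItemSet,
    n_blocks: int,
    words_per_block: int,
    nonwords_per_block: int,
    n_participant_orders: int,
    seed,
    practice: list = (),
) -> BlockPlan:
    """Partition items into blocks and balance block order across participants.

    Each block receives the configured number of word and nonword trials
    (a random partition); block order follows a cyclic Latin square over
    ``n_blocks``, recycled over participants, and the within-block trial
    order is re-randomized for every participant.
    """
    rng = _as_rng(seed)
    wp, nwp = list(item_set.word_pairs), list(item_set.nonword_pairs)
    if len(wp) != n_blocks * words_per_block:
        raise ValueError(
            f"{len(wp)} word pairs do not divide into {n_blocks} x {words_per_block}"
        )
    if len(nwp) != n_blocks * nonwords_per_block:
        raise ValueError(
            f"{len(nwp)} nonword pairs do not divide into "
            f"{n_blocks} x {nonwords_per_block}"
        )
    w_order = list(rng.permutation(len(wp)))
    n_order = list(rng.permutation(len(nwp)))
    blocks = []
    for b in range(n_blocks):
        block = [wp[i] for i in w_order[b * words_per_block : (b + 1) * words_per_block]]
        block += [
            nwp[i] for i in n_order[b * nonwords_per_block : (b + 1) * nonwords_per_block]
        ]
        blocks.append(block)
    orders, trials = [], []
    for p in range(n_participant_orders):
        row = tuple((p + j) % n_blocks for j in range(n_blocks))
        orders.append(row)
        seq = []
        for b in row:
            idx = rng.permutation(len(blocks[b]))
            seq.extend((b, blocks[b][i]) for i in idx)
        trials.append(seq)
    schedule = {"soa_ms": 1000, "timeout_ms": 3000, "feedback_ms": 1000}
    return BlockPlan(
        blocks=blocks,
        participant_orders=orders,
        participant_trials=trials,
        practice=list(practice),
        schedule=schedule,
    )
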