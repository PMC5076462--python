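"""Synthetic study material: lexicon, latent-category corpus, reaction times.

No raw reaction-time data is publicly deposited for cosine-controlled
priming studies, and building spaces from an 880-million-word corpus is
far outside desk scale.  This module therefore generates:

* a **lexicon** with Zipfian frequencies whose Leipzig-style frequency
  classes span the medium-frequency band used for stimulus selection
  (the most frequent entries are function words, exactly as in real
  frequency lists, so the class scale is anchored naturally);
* a **corpus** with latent-category co-occurrence structure: every
  content word belongs to one of ``C`` categories arranged on a ring,
  each document has a latent ring position, and every content token
  draws its category from a wrapped Gaussian kernel around that
  position (then a word frequency-proportionally within the category),
  interleaved with function words.  Kernel overlap makes
  between-category similarity fall off smoothly with ring distance, so
  derived spaces produce cosines covering all ten similarity classes;
* **trial-level reaction times** under the same linear mixed model the
  analysis assumes: fixed effects of cosine and of prime/target length
  and frequency, correlated by-subject random effects (intercept plus
  cosine, target-length and target-frequency slopes), by-item random
  intercepts, log-normal residuals, plus error trials and slow-outlier
  responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dsm import Token, TokenizedCorpus
from .items import (
    BlockPlan,
    ItemSet,
    LexiconEntry,
    PRIME_CONSTRAINTS,
    TARGET_CONSTRAINTS,
    frequency_class,
)
from .util import derive_seed

__all__ = [
    "GeneratorConfig",
    "CorpusPlan",
    "SimulationParams",
    "generate_lexicon",
    "corpus_plan",
    "generate_corpus",
    "simulate_experiment",
]

_CONSONANTS = sorted("bdfghklmnprstvz")
_VOWELS = sorted("aeiou")

# Content-word length distribution (letters -> probability); mass is
# concentrated on the 4-9 letter range that stimulus selection needs,
# with a thin tail of longer nouns.
_LENGTH_DIST = {3: 0.035, 4: 0.155, 5: 0.185, 6: 0.185, 7: 0.165, 8: 0.135,
                9: 0.115, 10: 0.015, 11: 0.007, 12: 0.003}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic lexicon + corpus generator.

    The token budget is ``n_documents * sentences_per_document *
    tokens_per_sentence``; lexicon frequencies are a Zipf law over the
    whole vocabulary (function words first) scaled to that budget, so the
    realized corpus approximates the lexicon counts.
    """

    vocab_size: int = 1000          # content words
    n_categories: int = 40          # latent categories on a ring
    zipf_exponent: float = 0.12     # power-law decay across the content band
    n_documents: int = 900
    sentences_per_document: int = 25
    tokens_per_sentence: int = 80
    n_function_words: int = 12      # non-content; most frequent entries
    near_synonym_fraction: float = 0.05
    seed: int = 0
    # width (ring units) of the wrapped Gaussian kernel from which each
    # token's category is drawn around its document's latent position;
    # wider kernels give smoother cosine decay with ring distance
    category_kernel_sigma: float = 2.5
    concrete_fraction: float = 0.78
    # closed-class head: the top function word is 2**head_anchor_log2
    # times as frequent as the top content word, anchoring the content
    # band across Leipzig frequency classes 10-11.  The default (None)
    # places the class-10/11 boundary at the median content frequency,
    # whatever the vocabulary size, so both classes are well populated
    # (the analysis model needs frequency-class variance).
    head_anchor_log2: float | None = None
    head_exponent: float = 2.5

    def anchor_log2(self) -> float:
        if self.head_anchor_log2 is not None:
            return self.head_anchor_log2
        return 10.5 - self.zipf_exponent * float(np.log2(self.vocab_size / 2))

    def __post_init__(self) -> None:
        if not self.vocab_size > self.n_categories >= 1:
            raise ValueError("require vocab_size > n_categories >= 1")
        if self.zipf_exponent < 0:
            raise ValueError("Zipf exponent must be >= 0")
        for name in ("n_documents", "sentences_per_document",
                     "tokens_per_sentence", "n_function_words"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.near_synonym_fraction <= 1.0:
            raise ValueError("near_synonym_fraction must be in [0, 1]")

    @property
    def total_tokens(self) -> int:
        return (self.n_documents * self.sentences_per_document
                * self.tokens_per_sentence)


def _pronounceable(rng: np.random.Generator, length: int) -> str:
    """A consonant-vowel alternating letter string of the given length."""
    letters = []
    for i in range(length):
        pool = _CONSONANTS if i % 2 == 0 else _VOWELS
        letters.append(pool[int(rng.integers(len(pool)))])
    return "".join(letters)


def _unique_word(rng, length, taken, max_tries=1000) -> str:
    for _ in range(max_tries):
        w = _pronounceable(rng, length)
        if w not in taken:
            taken.add(w)
            return w
    raise RuntimeError(f"could not generate a fresh word of length {length}")


def generate_lexicon(
    config: GeneratorConfig,
    min_target_pool: int = 300,
    min_prime_pool: int = 500,
) -> list:
    """Build the synthetic lexicon (function words first, then content words).

    Content frequencies follow a power law with exponent
    ``zipf_exponent`` across ranks 1..V; function words form a much
    steeper head (exponent ``head_exponent``) whose top count is
    ``2**head_anchor_log2`` times the top content count, so the whole
    content band sits around Leipzig frequency class 10 — the
    medium-frequency band stimulus selection draws from — while staying
    frequent enough for estimable vectors, mirroring how class-10-15
    words of a corpus-scale space are still high-count words.  The sum
    of all frequencies is scaled to the corpus token budget.  Lengths
    and concreteness are assigned independently of frequency so that
    stimulus matching can succeed.  Raises if fewer than
    ``min_target_pool`` entries satisfy the target constraints or fewer
    than ``min_prime_pool`` the prime constraints.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "lexicon"))
    F, V = config.n_function_words, config.vocab_size
    content_w = np.arange(1, V + 1, dtype=float) ** -config.zipf_exponent
    func_w = (2.0 ** config.anchor_log2()) * (
        np.arange(1, F + 1, dtype=float) ** -config.head_exponent
    )
    weights = np.concatenate([func_w, content_w])
    freqs = np.maximum(1, np.round(weights / weights.sum()
                                   * config.total_tokens)).astype(int)
    f_max = int(freqs[0])
    lengths = np.array(list(_LENGTH_DIST), dtype=int)
    probs = np.array(list(_LENGTH_DIST.values()))
    probs = probs / probs.sum()
    taken: set = set()
    entries = []
    for i in range(F):
        length = int(rng.integers(2, 4))
        word = _unique_word(rng, length, taken)
        entries.append(LexiconEntry(
            word=word, frequency=int(freqs[i]),
            frequency_class=frequency_class(freqs[i], f_max),
            length=length, is_concrete_noun=False,
        ))
    content_lengths = rng.choice(lengths, size=V, p=probs)
    concrete = rng.random(V) < config.concrete_fraction
    for j in range(V):
        word = _unique_word(rng, int(content_lengths[j]), taken)
        entries.append(LexiconEntry(
            word=word, frequency=int(freqs[F + j]),
            frequency_class=frequency_class(freqs[F + j], f_max),
            length=int(content_lengths[j]), is_concrete_noun=bool(concrete[j]),
        ))
    n_target = sum(TARGET_CONSTRAINTS.satisfied_by(e) for e in entries)
    n_prime = sum(PRIME_CONSTRAINTS.satisfied_by(e) for e in entries)
    if n_target < min_target_pool or n_prime < min_prime_pool:
        raise ValueError(
            f"lexicon too sparse for stimulus selection: {n_target} "
            f"target-eligible (need {min_target_pool}), {n_prime} "
            f"prime-eligible (need {min_prime_pool}); increase vocab_size "
            f"or adjust the Zipf exponent"
        )
    return entries


@dataclass
class CorpusPlan:
    """Latent structure behind a generated corpus (for inspection/tests)."""

    category_of: dict            # content word -> category index
    synonym_pairs: list          # planted near-synonym word pairs
    category_mass: np.ndarray    # total frequency per category


def corpus_plan(config: GeneratorConfig, lexicon: list) -> CorpusPlan:
    """Assign content words to ring categories and plant near-synonym pairs.

    Deterministic given the config seed; :func:`generate_corpus` uses the
    same plan internally, so tests can recover the planted structure.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "corpus-plan"))
    content = [e for e in lexicon if not _is_function(e, config)]
    C = config.n_categories
    cats = rng.integers(0, C, size=len(content))
    # plant near-synonym pairs among words frequent enough for their
    # vectors to be estimable (top half of the content frequency range)
    n_pairs = int(round(config.near_synonym_fraction * len(content) / 2))
    order = np.argsort([-e.frequency for e in content])
    eligible = order[: max(2 * n_pairs, len(content) // 2)]
    pairs = []
    if n_pairs:
        chosen = rng.choice(eligible, size=2 * n_pairs, replace=False)
        for a, b in zip(chosen[::2], chosen[1::2]):
            cats[b] = cats[a]
            pairs.append((content[a].word, content[b].word))
    mass = np.zeros(C)
    for e, c in zip(content, cats):
        mass[c] += e.frequency
    return CorpusPlan(
        category_of={e.word: int(c) for e, c in zip(content, cats)},
        synonym_pairs=pairs,
        category_mass=mass,
    )


def _is_function(entry: LexiconEntry, config: GeneratorConfig) -> bool:
    # function words are generated first with lengths 2-3 and the top
    # frequency ranks; identify them by concreteness=False plus length<4
    return (not entry.is_concrete_noun) and entry.length < 4


def generate_corpus(
    config: GeneratorConfig, lexicon: list, plan: CorpusPlan | None = None
) -> TokenizedCorpus:
    """Sample the token stream and assemble it into documents and sentences.

    Each document gets a latent position on the category ring; every
    content token draws its category from a wrapped Gaussian kernel
    (width ``category_kernel_sigma``, mass-weighted so word counts track
    the lexicon frequencies) around that position, then a word
    frequency-proportionally within the category.  Each token slot is a
    function word with probability ``function_token_share``.
    """
    if plan is None:
        plan = corpus_plan(config, lexicon)
    rng = np.random.default_rng(derive_seed(config.seed, "corpus-tokens"))
    C = config.n_categories
    func = [e for e in lexicon if _is_function(e, config)]
    content = [e for e in lexicon if not _is_function(e, config)]
    func_words = np.array([e.word for e in func], dtype=object)
    func_p = np.array([e.frequency for e in func], dtype=float)
    func_p /= func_p.sum()
    # per-category word lists and within-category frequency distributions
    cat_words: list = [[] for _ in range(C)]
    cat_freqs: list = [[] for _ in range(C)]
    for e in content:
        c = plan.category_of[e.word]
        cat_words[c].append(e.word)
        cat_freqs[c].append(e.frequency)
    cat_words = [np.array(w, dtype=object) for w in cat_words]
    cat_cum = []
    for f in cat_freqs:
        arr = np.array(f, dtype=float)
        cat_cum.append(np.cumsum(arr) / arr.sum() if arr.size else arr)
    mass = plan.category_mass / plan.category_mass.sum()

    D = config.n_documents
    spd, tps = config.sentences_per_document, config.tokens_per_sentence
    total = config.total_tokens

    # per-center category distributions: wrapped Gaussian kernel around
    # the center, mass-weighted so marginal word counts track the lexicon
    ring = np.arange(C)
    dist = np.abs(ring[None, :] - ring[:, None])
    dist = np.minimum(dist, C - dist)
    kernel = np.exp(-(dist.astype(float) ** 2)
                    / (2.0 * config.category_kernel_sigma**2))
    weighted = kernel * np.maximum(mass, 1e-12)[None, :]
    weighted /= weighted.sum(axis=1, keepdims=True)
    cat_given_center_cum = np.cumsum(weighted, axis=1)

    # document-level latent ring positions
    centers = rng.integers(0, C, size=D)

    # token-level draws; the function-word share of slots follows the
    # lexicon's frequency masses so realized counts track the targets
    func_share = float(sum(e.frequency for e in func)) / (
        sum(e.frequency for e in func) + sum(e.frequency for e in content)
    )
    doc_of = np.repeat(np.arange(D), spd * tps)
    is_func = rng.random(total) < func_share
    forms = np.empty(total, dtype=object)
    n_func = int(is_func.sum())
    forms[is_func] = rng.choice(func_words, size=n_func, p=func_p)
    content_idx = np.flatnonzero(~is_func)
    tok_center = centers[doc_of[content_idx]]
    u = rng.random(content_idx.size)
    tok_cat = np.empty(content_idx.size, dtype=int)
    for k in range(C):
        m = tok_center == k
        if m.any():
            tok_cat[m] = np.searchsorted(cat_given_center_cum[k], u[m],
                                         side="right")
    tok_cat = np.minimum(tok_cat, C - 1)
    for c in range(C):
        sel = content_idx[tok_cat == c]
        if sel.size == 0 or cat_cum[c].size == 0:
            continue
        draws = np.searchsorted(cat_cum[c], rng.random(sel.size), side="right")
        draws = np.minimum(draws, len(cat_words[c]) - 1)
        forms[sel] = cat_words[c][draws]
    # any content slot of an empty category falls back to a function word
    empty = np.array([f is None for f in forms])
    if empty.any():
        forms[empty] = rng.choice(func_words, size=int(empty.sum()), p=func_p)
        is_func = is_func | empty

    documents = []
    pos = 0
    for _ in range(D):
        doc = []
        for _ in range(spd):
            sent = [
                Token(form=forms[pos + t], is_content=not is_func[pos + t])
                for t in range(tps)
            ]
            doc.append(sent)
            pos += tps
        documents.append(doc)
    return TokenizedCorpus(documents=documents)


def _default_subject_cov() -> np.ndarray:
    sd = np.array([0.12, 0.04, 0.004, 0.004])
    return np.diag(sd**2)


@dataclass
class SimulationParams:
    """Generative parameters of the trial-level reaction-time model.

    All fixed effects are on the natural-log RT (ms) scale; the cosine
    effect default of -0.05 sits within the range reported for priming
    studies of this design, and the intercept is chosen so that the
    median simulated RT is about 600 ms.  The by-subject random-effect
    covariance is over (intercept, cosine slope, target-length slope,
    target-frequency slope).
    """

    beta0: float = 6.20
    beta_cos: float = -0.05
    beta_len_target: float = 0.01
    beta_freq_target: float = 0.01
    beta_len_prime: float = 0.002
    beta_freq_prime: float = 0.002
    subject_cov: np.ndarray = field(default_factory=_default_subject_cov)
    sigma_item: float = 0.04
    sigma_resid: float = 0.18
    p_error: float = 0.017
    p_outlier: float = 0.004
    outlier_range: tuple = (1500.0, 3000.0)
    n_subjects: int = 44
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.subject_cov, dtype=float)
        if cov.shape != (4, 4) or not np.allclose(cov, cov.T):
            raise ValueError("subject_cov must be a symmetric 4x4 matrix")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ValueError("subject_cov must be positive semi-definite")
        for name in ("sigma_item", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_error", "p_outlier"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def simulate_experiment(
    blocks: BlockPlan,
    items: ItemSet,
    params: SimulationParams,
    lexicon: list,
) -> pd.DataFrame:
    """Simulate one lexical-decision experiment; returns the trial table.

    Word trials follow
    ``logRT = b0 + b_cos*cos + b_lT*lenT + b_fT*fcT + b_lP*lenP + b_fP*fcP
    + S_j . (1, cos, lenT, fcT) + I_i + eps`` with ``S_j ~ MVN(0, Sigma_S)``,
    ``I_i ~ N(0, sigma_I^2)`` and ``eps ~ N(0, sigma_e^2)``; nonword trials
    share the intercept, subject/item intercepts and residual noise but
    carry no covariate effects.  Each trial is flagged as an error with
    probability ``p_error``; with probability ``p_outlier`` its RT is
    replaced by a uniform draw from the outlier range.
    """
    rng = np.random.default_rng(params.seed)
    idx = {e.word: e for e in lexicon}
    all_pairs = items.word_pairs + items.nonword_pairs
    item_ids = {p.target: i for i, p in enumerate(all_pairs)}
    cov = np.asarray(params.subject_cov, dtype=float)
    try:
        root = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:  # PSD but singular: eigenvalue square root
        vals, vecs = np.linalg.eigh(cov)
        root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    S = rng.standard_normal((params.n_subjects, 4)) @ root.T
    I = rng.normal(0.0, params.sigma_item, size=len(all_pairs))
    rows = []
    n_orders = len(blocks.participant_trials)
    for j in range(params.n_subjects):
        seq = blocks.participant_trials[j % n_orders]
        for block_id, pair in seq:
            i = item_ids[pair.target]
            if pair.trial_type == "word":
                t_entry, p_entry = idx[pair.target], idx[pair.prime]
                z = np.array([1.0, pair.cosine, t_entry.length,
                              t_entry.frequency_class])
                mu = (
                    params.beta0
                    + params.beta_cos * pair.cosine
                    + params.beta_len_target * t_entry.length
                    + params.beta_freq_target * t_entry.frequency_class
                    + params.beta_len_prime * p_entry.length
                    + params.beta_freq_prime * p_entry.frequency_class
                    + S[j] @ z
                )
                cov = (pair.cosine, t_entry.length, t_entry.frequency_class,
                       p_entry.length, p_entry.frequency_class)
            else:
                p_entry = idx[pair.prime]
                mu = params.beta0 + S[j, 0]
                cov = (np.nan, len(pair.target), np.nan,
                       p_entry.length, p_entry.frequency_class)
            log_rt = mu + I[i] + rng.normal(0.0, params.sigma_resid)
            rt = float(np.exp(log_rt))
            if rng.random() < params.p_outlier:
                rt = float(rng.uniform(*params.outlier_range))
            error = rng.random() < params.p_error
            rows.append((
                f"s{j:03d}", f"i{i:03d}", pair.prime, pair.target,
                pair.trial_type, block_id, rt,
                "error" if error else "correct",
                cov[0], cov[1], cov[2], cov[3], cov[4],
            ))
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "item", "prime", "target", "trial_type", "block",
            "rt_ms", "accuracy", "cosine", "target_length",
            "target_freq_class", "prime_length", "prime_freq_class",
        ],
    )
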