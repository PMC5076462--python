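"""Shared fixtures: toy corpora and one default-scale synthetic study."""

import numpy as np
import pytest

from semprime.dsm import Token, TokenizedCorpus, build_space
from semprime.items import (
    PRIME_CONSTRAINTS,
    TARGET_CONSTRAINTS,
    SimilarityClassScheme,
    select_word_pool,
)
from semprime.simulate import GeneratorConfig, generate_corpus, generate_lexicon


def sentence(text, noncontent=()):
    return [Token(form=w, is_content=w not in noncontent) for w in text.split()]


@pytest.fixture
def toy_corpus():
    """Two tiny documents with a function word."""
    return TokenizedCorpus(
        documents=[
            [sentence("the cat sat on the mat", noncontent={"the", "on"}),
             sentence("a cat ate fish", noncontent={"a"})],
            [sentence("dogs chase cats")],
        ]
    )


@pytest.fixture(scope="session")
def study():
    """Default-scale synthetic study: lexicon, corpus, both spaces, pool.

    Session-scoped because building the 1.8M-token corpus and two
    300-dimensional spaces takes ~15 s; all default-condition tests
    share it.
    """
    cfg = GeneratorConfig(seed=7)
    lexicon = generate_lexicon(cfg)
    corpus = generate_corpus(cfg, lexicon)
    spaces = {
        model: build_space(corpus, model=model, k=300, seed=3)
        for model in ("lsa", "hal")
    }
    targets, nonword_primes = select_word_pool(
        lexicon, TARGET_CONSTRAINTS, 300, 200, seed=1
    )
    return {
        "config": cfg,
        "lexicon": lexicon,
        "corpus": corpus,
        "spaces": spaces,
        "targets": targets,
        "nonword_primes": nonword_primes,
        "scheme": SimilarityClassScheme.default(),
    }


@pytest.fixture(scope="session")
def study_items(study):
    """A generated item set (HAL space) at the full design size."""
    from semprime.items import generate_item_set, generate_nonwords

    nonwords = generate_nonwords(
        100, (4, 10), study["targets"], {e.word for e in study["lexicon"]},
        seed=31,
    )
    return generate_item_set(
        study["targets"], study["scheme"], study["spaces"]["hal"],
        study["lexicon"], PRIME_CONSTRAINTS, seed=2,
        nonword_primes=study["nonword_primes"], nonword_targets=nonwords,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
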