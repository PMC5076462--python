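"""Readers, writers, space persistence, run configuration and the pipeline.

All artifact formats are plain text:

* corpus — UTF-8, one sentence per line, blank line between documents,
  whitespace-separated tokens; tokens prefixed with ``~`` are
  non-content (function words);
* lexicon / item lists / trial tables — TSV;
* semantic space — a directory with ``vocab.tsv``, ``vectors.tsv``,
  ``singular_values.tsv`` and a ``meta`` key-value file carrying model
  metadata plus a checksum of the vectors file for integrity checks;
* block plans and the run manifest — JSON.

:func:`run_pipeline` orchestrates the full study: synthetic lexicon and
corpus, LSA and HAL spaces, stimulus generation for both experiments,
trial simulation, preprocessing, the per-experiment and pooled mixed
model analyses, and a manifest with all derived seeds and artifact
checksums.  Every stochastic stage derives its seed from the master
seed plus the stage name, so a rerun with the same configuration
reproduces every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis as ana
from .dsm import SemanticSpace, Token, TokenizedCorpus, build_space
from .items import (
    BlockPlan,
    ItemPair,
    ItemSet,
    LexiconEntry,
    PRIME_CONSTRAINTS,
    TARGET_CONSTRAINTS,
    SimilarityClassScheme,
    assemble_blocks,
    generate_matched_item_set,
    generate_nonwords,
    select_word_pool,
)
from .simulate import (
    GeneratorConfig,
    SimulationParams,
    generate_corpus,
    generate_lexicon,
    simulate_experiment,
)
from .util import derive_seed

__all__ = [
    "NONCONTENT_PREFIX",
    "read_corpus",
    "write_corpus",
    "read_lexicon",
    "write_lexicon",
    "write_item_set",
    "read_item_set",
    "write_blocks",
    "read_blocks",
    "write_trials",
    "read_trials",
    "save_space",
    "load_space",
    "SpaceIntegrityError",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("semprime")

NONCONTENT_PREFIX = "~"


class SpaceIntegrityError(RuntimeError):
    """A persisted space directory is incomplete or corrupted."""


# ---------------------------------------------------------------------------
# corpus

def write_corpus(corpus: TokenizedCorpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d, doc in enumerate(corpus.documents):
            if d:
                fh.write("\n")
            for sent in doc:
                fh.write(
                    " ".join(
                        t.form if t.is_content else NONCONTENT_PREFIX + t.form
                        for t in sent
                    )
                    + "\n"
                )


def read_corpus(path) -> TokenizedCorpus:
    """Parse a corpus file; malformed lines raise with their line number."""
    documents, current = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                if current:
                    documents.append(current)
                    current = []
                continue
            sent = []
            for raw in line.split():
                if raw == NONCONTENT_PREFIX:
                    raise ValueError(
                        f"{path}:{lineno}: bare non-content marker with no token"
                    )
                if raw.startswith(NONCONTENT_PREFIX):
                    sent.append(Token(form=raw[len(NONCONTENT_PREFIX):],
                                      is_content=False))
                else:
                    sent.append(Token(form=raw, is_content=True))
            current.append(sent)
    if current:
        documents.append(current)
    return TokenizedCorpus(documents=documents)


# ---------------------------------------------------------------------------
# lexicon

def write_lexicon(lexicon: list, path) -> None:
    df = pd.DataFrame(
        [(e.word, e.frequency, e.frequency_class, e.length,
          int(e.is_concrete_noun)) for e in lexicon],
        columns=["word", "frequency", "frequency_class", "length",
                 "is_concrete_noun"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_lexicon(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        LexiconEntry(
            word=str(r.word), frequency=int(r.frequency),
            frequency_class=int(r.frequency_class), length=int(r.length),
            is_concrete_noun=bool(r.is_concrete_noun),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# items and blocks

def write_item_set(item_set: ItemSet, lexicon: list, path) -> None:
    """Item list TSV with the covariates stimulus matching controls."""
    idx = {e.word: e for e in lexicon}
    rows = []
    for p in item_set.word_pairs + item_set.nonword_pairs:
        prime = idx[p.prime]
        target = idx.get(p.target)  # nonword targets have no lexicon entry
        rows.append((
            p.prime, p.target, p.trial_type,
            "" if np.isnan(p.cosine) else repr(p.cosine),
            p.class_index, prime.length, prime.frequency_class,
            target.length if target else len(p.target),
            target.frequency_class if target else "",
        ))
    pd.DataFrame(
        rows,
        columns=["prime", "target", "trial_type", "cosine", "class_index",
                 "prime_length", "prime_freq_class", "target_length",
                 "target_freq_class"],
    ).to_csv(path, sep="\t", index=False)


def read_item_set(path, scheme: SimilarityClassScheme | None = None) -> ItemSet:
    scheme = scheme or SimilarityClassScheme.default()
    df = pd.read_csv(path, sep="\t")
    word_pairs, nonword_pairs = [], []
    for r in df.itertuples():
        pair = ItemPair(
            prime=str(r.prime), target=str(r.target),
            cosine=float(r.cosine) if pd.notna(r.cosine) else float("nan"),
            class_index=int(r.class_index), trial_type=str(r.trial_type),
        )
        (word_pairs if pair.trial_type == "word" else nonword_pairs).append(pair)
    realized = {ci: 0 for ci in range(scheme.n_classes)}
    for p in word_pairs:
        realized[p.class_index] += 1
    return ItemSet(
        word_pairs=word_pairs, nonword_pairs=nonword_pairs, scheme=scheme,
        planned_allocation=dict(realized), realized_allocation=realized,
        reassignments=[], provenance={"source": str(path)},
    )


def write_blocks(plan: BlockPlan, path) -> None:
    payload = {
        "blocks": [[(p.prime, p.target) for p in block] for block in plan.blocks],
        "participant_orders": [list(o) for o in plan.participant_orders],
        "participant_trials": [
            [(b, p.prime, p.target) for b, p in seq]
            for seq in plan.participant_trials
        ],
        "practice": list(plan.practice),
        "schedule": plan.schedule,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_blocks(path, item_set: ItemSet) -> BlockPlan:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    by_key = {(p.prime, p.target): p
              for p in item_set.word_pairs + item_set.nonword_pairs}
    try:
        blocks = [[by_key[tuple(k)] for k in blk] for blk in payload["blocks"]]
        trials = [
            [(b, by_key[(pr, tg)]) for b, pr, tg in seq]
            for seq in payload["participant_trials"]
        ]
    except KeyError as err:
        raise ValueError(f"block plan references unknown item {err}") from None
    return BlockPlan(
        blocks=blocks,
        participant_orders=[tuple(o) for o in payload["participant_orders"]],
        participant_trials=trials,
        practice=payload["practice"],
        schedule=payload["schedule"],
    )


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# semantic spaces

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_space(space: SemanticSpace, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    freqs = (space.frequencies if space.frequencies is not None
             else np.zeros(len(space.words), dtype=int))
    with open(d / "vocab.tsv", "w", encoding="utf-8") as fh:
        fh.write("word\tfrequency\trank\n")
        for rank, (w, f) in enumerate(zip(space.words, freqs), start=1):
            fh.write(f"{w}\t{int(f)}\t{rank}\n")
    with open(d / "vectors.tsv", "w", encoding="utf-8") as fh:
        for w, vec in zip(space.words, space.vectors):
            fh.write(w + "\t" + "\t".join(repr(float(x)) for x in vec) + "\n")
    with open(d / "singular_values.tsv", "w", encoding="utf-8") as fh:
        fh.write("\n".join(repr(float(s)) for s in space.singular_values) + "\n")
    meta = dict(space.meta)
    meta["vectors_sha256"] = _sha256(d / "vectors.tsv")
    with open(d / "meta", "w", encoding="utf-8") as fh:
        for key in sorted(meta):
            fh.write(f"{key}={meta[key]}\n")


def load_space(directory) -> SemanticSpace:
    d = Path(directory)
    for name in ("vocab.tsv", "vectors.tsv", "singular_values.tsv", "meta"):
        if not (d / name).is_file():
            raise SpaceIntegrityError(f"missing {name} in {d}")
    meta = {}
    for line in (d / "meta").read_text(encoding="utf-8").splitlines():
        key, _, value = line.partition("=")
        meta[key] = value
    expected = meta.pop("vectors_sha256", None)
    if expected is not None and _sha256(d / "vectors.tsv") != expected:
        raise SpaceIntegrityError(f"vectors checksum mismatch in {d}")
    words, rows = [], []
    with open(d / "vectors.tsv", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            words.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    vocab = pd.read_csv(d / "vocab.tsv", sep="\t")
    sv = np.array([
        float(x)
        for x in (d / "singular_values.tsv").read_text().split()
    ])
    for key in ("k", "k_requested", "seed", "vocab_cap"):
        if key in meta and meta[key] != "None":
            meta[key] = int(meta[key])
    if meta.get("window") not in (None, "None"):
        meta["window"] = int(meta["window"])
    elif "window" in meta:
        meta["window"] = None
    return SemanticSpace(
        words=words,
        vectors=np.asarray(rows, dtype=float),
        singular_values=sv,
        meta=meta,
        frequencies=vocab["frequency"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline

@dataclass
class RunConfig:
    """Full parameterization of one end-to-end study run."""

    master_seed: int = 0
    output_dir: str = "semprime_run"
    log_level: str = "INFO"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    dims: int = 300
    window: int = 3
    vocab_cap: int = 100_000
    scheme: str = "0:0.09:0.18:0.27:0.36:0.45:0.54:0.63:0.72:0.81:1"
    n_pool: int = 300
    n_targets: int = 200
    n_nonwords: int = 100
    n_blocks: int = 4
    words_per_block: int = 50
    nonwords_per_block: int = 25
    n_subjects_exp1: int = 44
    n_subjects_exp2: int = 43
    simulation: SimulationParams = field(default_factory=SimulationParams)
    matching_alpha: float = 0.05

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.master_seed, stage)


def _augment_with_space_cosines(trials, item_set, spaces) -> pd.DataFrame:
    """Add per-space clamped-cosine columns (e.g. cosine_lsa, cosine_hal)."""
    out = trials.copy()
    for name, space in spaces.items():
        col = {}
        for p in item_set.word_pairs:
            col[p.target] = space.clamped_cosine(p.prime, p.target)
        out[f"cosine_{name}"] = out["target"].map(col)
    return out


def _fit_rows(report: ana.AnalysisReport) -> pd.DataFrame:
    rows = []
    for model, fit in (("baseline", report.baseline),
                       ("cosine", report.cosine_model)):
        for term in fit.params.index:
            rows.append((model, term, fit.params[term], fit.bse[term],
                         fit.tvalues[term]))
    return pd.DataFrame(rows, columns=["model", "term", "estimate", "se", "t"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole study and write all artifacts under the output dir.

    Returns a dict with the in-memory artifacts (spaces, item sets,
    trial tables, analysis reports) and writes TSV/JSON files plus a
    manifest with stage seeds and artifact checksums.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    logger.addHandler(log_handler)
    try:
        return _run_pipeline(config, out)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run_pipeline(config: RunConfig, out: Path) -> dict:
    scheme = SimilarityClassScheme.parse(config.scheme)
    gen_cfg = dataclasses.replace(config.generator,
                                  seed=config.stage_seed("generator"))

    logger.info("stage: lexicon + corpus")
    lexicon = generate_lexicon(gen_cfg, min_target_pool=config.n_pool,
                               min_prime_pool=config.n_pool)
    write_lexicon(lexicon, out / "lexicon.tsv")
    corpus = generate_corpus(gen_cfg, lexicon)
    write_corpus(corpus, out / "corpus.txt")

    logger.info("stage: semantic spaces")
    spaces = {}
    for model in ("lsa", "hal"):
        spaces[model] = build_space(
            corpus, model=model, k=config.dims,
            seed=config.stage_seed(f"space-{model}"),
            vocab_cap=config.vocab_cap, window=config.window,
        )
        save_space(spaces[model], out / f"space_{model}")

    logger.info("stage: stimulus pool")
    targets, nonword_primes = select_word_pool(
        lexicon, TARGET_CONSTRAINTS, config.n_pool, config.n_targets,
        seed=config.stage_seed("pool"),
    )
    lexicon_words = {e.word for e in lexicon}

    item_sets, block_plans, trial_tables = {}, {}, {}
    used_primes: set = set()
    for exp, model in (("exp1", "lsa"), ("exp2", "hal")):
        logger.info("stage: items %s (%s space)", exp, model)
        nonwords = generate_nonwords(
            config.n_nonwords, (4, 10), targets, lexicon_words,
            seed=config.stage_seed(f"nonwords-{exp}"),
        )
        item_set, matching = generate_matched_item_set(
            targets, scheme, spaces[model], lexicon, PRIME_CONSTRAINTS,
            seed=config.stage_seed(f"items-{exp}"),
            alpha=config.matching_alpha,
            nonword_primes=nonword_primes, nonword_targets=nonwords,
            extra_excluded=used_primes,
            provenance={"experiment": exp, "space": model},
        )
        if not matching.overall_pass:
            logger.warning("%s: matching checks not all passed", exp)
        used_primes |= {p.prime for p in item_set.word_pairs}
        item_sets[exp] = item_set
        write_item_set(item_set, lexicon, out / f"items_{exp}.tsv")

        plan = assemble_blocks(
            item_set, config.n_blocks, config.words_per_block,
            config.nonwords_per_block,
            n_participant_orders=max(config.n_subjects_exp1,
                                     config.n_subjects_exp2),
            seed=config.stage_seed(f"blocks-{exp}"),
        )
        block_plans[exp] = plan
        write_blocks(plan, out / f"blocks_{exp}.json")

        logger.info("stage: simulation %s", exp)
        n_subj = (config.n_subjects_exp1 if exp == "exp1"
                  else config.n_subjects_exp2)
        params = dataclasses.replace(
            config.simulation, n_subjects=n_subj,
            seed=config.stage_seed(f"simulate-{exp}"),
        )
        trials = simulate_experiment(plan, item_set, params, lexicon)
        trials = _augment_with_space_cosines(trials, item_set, spaces)
        trial_tables[exp] = trials
        write_trials(trials, out / f"trials_{exp}.tsv")

    logger.info("stage: analysis")
    reports, clean = {}, {}
    for exp in ("exp1", "exp2"):
        clean[exp], excl = ana.preprocess(trial_tables[exp])
        pd.DataFrame([dataclasses.asdict(excl)]).to_csv(
            out / f"exclusions_{exp}.tsv", sep="\t", index=False
        )
        for predictor in ("cosine_lsa", "cosine_hal"):
            reports[(exp, predictor)] = ana.run_experiment_analysis(
                clean[exp], predictor
            )
    for predictor in ("cosine_lsa", "cosine_hal"):
        reports[("pooled", predictor)] = ana.pooled_analysis(
            clean["exp1"], clean["exp2"], predictor
        )
    comparison = []
    for (scope, predictor), rep in reports.items():
        _fit_rows(rep).to_csv(out / f"fits_{scope}_{predictor}.tsv",
                              sep="\t", index=False)
        rep.item_means.to_csv(out / f"item_means_{scope}_{predictor}.tsv",
                              sep="\t", index=False)
        tab = rep.comparison_table()
        tab.insert(0, "scope", scope)
        tab.insert(1, "predictor", predictor)
        comparison.append(tab)
    pd.concat(comparison, ignore_index=True).to_csv(
        out / "model_comparison.tsv", sep="\t", index=False
    )

    manifest = {
        "config": json.loads(json.dumps(
            dataclasses.asdict(config), default=lambda o: str(o)
        )),
        "stage_seeds": {
            stage: config.stage_seed(stage)
            for stage in ["generator", "space-lsa", "space-hal", "pool",
                          "nonwords-exp1", "nonwords-exp2", "items-exp1",
                          "items-exp2", "blocks-exp1", "blocks-exp2",
                          "simulate-exp1", "simulate-exp2"]
        },
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.suffix in (".tsv", ".txt", ".json")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")
    return {
        "lexicon": lexicon,
        "corpus": corpus,
        "spaces": spaces,
        "item_sets": item_sets,
        "block_plans": block_plans,
        "trial_tables": trial_tables,
        "clean_tables": clean,
        "reports": reports,
        "manifest": manifest,
    }
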