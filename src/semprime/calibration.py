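"""Simulation-based calibration checks of the mixed-model analysis.

These routines close the loop between the generative reaction-time
model and the inferential pipeline: simulate experiments with a known
cosine effect (or none), run the exact analysis used on study data, and
measure type-I error of the likelihood-ratio test, bias of the cosine
estimate, and coverage of its Wald interval.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .analysis import (
    experiment_model_spec,
    likelihood_ratio_test,
    preprocess,
    wald_ci,
)
from .items import (
    GenerationFailureError,
    ItemSet,
    PRIME_CONSTRAINTS,
    TARGET_CONSTRAINTS,
    SimilarityClassScheme,
    assemble_blocks,
    generate_item_set,
    select_word_pool,
)
from .mixedlm import fit_mixedlm
from .simulate import SimulationParams, simulate_experiment
from .util import derive_seed

__all__ = [
    "subsample_items",
    "generate_item_replicates",
    "null_lrt_calibration",
    "recovery_calibration",
]


def generate_item_replicates(
    space,
    lexicon: list,
    k: int,
    seed: int,
    n_pool: int = 300,
    n_targets: int = 200,
    scheme: SimilarityClassScheme | None = None,
    max_attempts: int | None = None,
) -> list:
    """Independent stimulus samples for Monte-Carlo replication studies.

    Each replicate redraws the word pool and reruns constrained prime
    sampling with fresh seeds; generation failures (exhausted bands) are
    skipped, mirroring how a stuck stimulus list would be regenerated in
    practice.
    """
    scheme = scheme or SimilarityClassScheme.default()
    out, attempt = [], 0
    max_attempts = max_attempts or 3 * k
    while len(out) < k and attempt < max_attempts:
        s = derive_seed(seed, f"replicate-{attempt}")
        attempt += 1
        try:
            targets, _ = select_word_pool(
                lexicon, TARGET_CONSTRAINTS, n_pool, n_targets, seed=s)
            out.append(generate_item_set(
                targets, scheme, space, lexicon, PRIME_CONSTRAINTS, seed=s))
        except GenerationFailureError:
            continue
    if len(out) < k:
        raise RuntimeError(f"only {len(out)}/{k} item replicates generated")
    return out


def subsample_items(item_set: ItemSet, n_items: int, seed) -> ItemSet:
    """Class-stratified subsample of word pairs (keeps the cosine spread)."""
    rng = np.random.default_rng(seed)
    n_classes = item_set.scheme.n_classes
    if n_items % n_classes:
        raise ValueError("n_items must divide evenly over the classes")
    per_class = n_items // n_classes
    chosen = []
    for ci in range(n_classes):
        pool = [p for p in item_set.word_pairs if p.class_index == ci]
        if len(pool) < per_class:
            raise ValueError(f"class {ci} has only {len(pool)} pairs")
        idx = rng.choice(len(pool), size=per_class, replace=False)
        chosen.extend(pool[i] for i in idx)
    alloc = {ci: per_class for ci in range(n_classes)}
    return ItemSet(
        word_pairs=chosen, nonword_pairs=[], scheme=item_set.scheme,
        planned_allocation=alloc, realized_allocation=dict(alloc),
        reassignments=[], provenance=dict(item_set.provenance,
                                          subsampled=str(n_items)),
    )


def _simulate_once(item_set, lexicon, params, seed):
    plan = assemble_blocks(
        item_set, n_blocks=1, words_per_block=len(item_set.word_pairs),
        nonwords_per_block=0, n_participant_orders=params.n_subjects,
        seed=derive_seed(seed, "blocks"),
    )
    p = dataclasses.replace(params, seed=derive_seed(seed, "trials"))
    trials = simulate_experiment(plan, item_set, p, lexicon)
    clean, _ = preprocess(trials)
    return clean


def _as_item_sets(item_sets) -> list:
    if isinstance(item_sets, ItemSet):
        return [item_sets]
    return list(item_sets)


def null_lrt_calibration(
    item_sets,
    lexicon: list,
    n_reps: int,
    seed: int,
    n_subjects: int = 20,
    n_items: int = 100,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the cosine LRT under beta_cos = 0.

    Simulates ``n_reps`` experiments at reduced size, runs the
    baseline-vs-cosine model comparison on each, and reports the
    rejection rate at ``alpha`` (nominally ~0.05).  ``item_sets`` may be
    one ItemSet or several; replications rotate over them (and over
    fresh subsamples), so the stimulus sample varies across
    replications just as it would across real replication studies.
    """
    base_spec = experiment_model_spec("cosine", with_predictor_fixed=False)
    full_spec = experiment_model_spec("cosine", with_predictor_fixed=True)
    parents = _as_item_sets(item_sets)
    params = SimulationParams(beta_cos=0.0, n_subjects=n_subjects)
    p_values = []
    warm_b = warm_f = None
    for rep in range(n_reps):
        parent = parents[rep % len(parents)]
        items = subsample_items(parent, n_items,
                                derive_seed(seed, f"subsample-{rep}"))
        clean = _simulate_once(items, lexicon, params,
                               derive_seed(seed, f"null-{rep}"))
        base = fit_mixedlm(clean, base_spec, start=warm_b, polish=False)
        full = fit_mixedlm(clean, full_spec, start=warm_f, polish=False)
        warm_b, warm_f = base.theta, full.theta
        p_values.append(likelihood_ratio_test(base, full).p_value)
    p = np.array(p_values)
    return {
        "n_reps": n_reps,
        "rejection_rate": float(np.mean(p < alpha)),
        "p_values": p,
    }


def recovery_calibration(
    item_sets,
    lexicon: list,
    n_reps: int,
    seed: int,
    beta_cos: float = -0.05,
    n_subjects: int = 43,
    level: float = 0.95,
) -> dict:
    """Bias and Wald-CI coverage of the cosine estimate at study scale.

    ``item_sets`` may be one ItemSet or several; replications rotate
    over them so stimulus sampling variability enters the Monte-Carlo
    average, as it would across real replications.
    """
    full_spec = experiment_model_spec("cosine", with_predictor_fixed=True)
    parents = [
        s if not s.nonword_pairs else subsample_items(
            s, len(s.word_pairs), derive_seed(seed, f"strip-{i}"))
        for i, s in enumerate(_as_item_sets(item_sets))
    ]
    params = SimulationParams(beta_cos=beta_cos, n_subjects=n_subjects)
    estimates, covered = [], []
    warm = None
    for rep in range(n_reps):
        items = parents[rep % len(parents)]
        clean = _simulate_once(items, lexicon, params,
                               derive_seed(seed, f"recovery-{rep}"))
        fit = fit_mixedlm(clean, full_spec, start=warm, polish=False)
        warm = fit.theta
        est = float(fit.params["cosine"])
        ci = wald_ci(est, float(fit.bse["cosine"]), level)
        estimates.append(est)
        covered.append(ci.lower <= beta_cos <= ci.upper)
    est = np.array(estimates)
    return {
        "n_reps": n_reps,
        "true_beta": beta_cos,
        "mean_beta": float(est.mean()),
        "mc_se": float(est.std(ddof=1) / np.sqrt(n_reps)),
        "coverage": float(np.mean(covered)),
        "estimates": est,
    }
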