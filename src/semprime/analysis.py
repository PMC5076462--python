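"""Trial-level preprocessing and the mixed-model priming analysis.

The analysis asks whether distributional cosine similarity predicts
lexical-decision latencies.  Following standard practice for this
design:

* only word-target trials are analysed; subjects, then items, with
  error rates above 25% are removed, then error trials, then responses
  faster than 100 ms or slower than 1500 ms; log RTs are modelled;
* the baseline model regresses logRT on prime/target length and
  frequency with by-subject random intercepts and slopes (for cosine,
  target length and target frequency — note the cosine *random* slope
  is in the baseline) plus by-item random intercepts;
* the cosine model adds a fixed effect of cosine similarity; the two
  ML fits are compared with a likelihood-ratio test, and the cosine
  estimate is reported with a 95% Wald confidence interval;
* for pooled data from two experiments sharing targets, by-item
  intercepts are replaced by crossed by-prime and by-target intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import MixedLMFit, MixedLMSpec, RandomTerm, fit_mixedlm

__all__ = [
    "PreprocessConfig",
    "ExclusionReport",
    "LRTResult",
    "WaldCI",
    "AnalysisReport",
    "EmptyResultError",
    "preprocess",
    "fit_lmem",
    "likelihood_ratio_test",
    "wald_ci",
    "run_experiment_analysis",
    "pooled_analysis",
    "cosine_correlation",
    "experiment_model_spec",
    "pooled_model_spec",
]

#: fixed covariates of the baseline model, in the conventional order
BASELINE_FIXED = ("target_length", "target_freq_class",
                  "prime_length", "prime_freq_class")
#: by-subject random slopes (the cosine slope is present in the baseline)
SUBJECT_SLOPES = ("cosine", "target_length", "target_freq_class")


class EmptyResultError(ValueError):
    """A preprocessing step removed every remaining trial."""


@dataclass(frozen=True)
class PreprocessConfig:
    error_rate_threshold: float = 0.25
    rt_min_ms: float = 100.0
    rt_max_ms: float = 1500.0

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate_threshold < 1.0:
            raise ValueError("error_rate_threshold must be in (0, 1)")
        if not self.rt_min_ms < self.rt_max_ms:
            raise ValueError("rt_min_ms must be below rt_max_ms")


@dataclass
class ExclusionReport:
    """Counts and percentages for every preprocessing step."""

    n_input: int
    n_word_trials: int
    subjects_removed: list
    items_removed: list
    n_after_error_screen: int
    n_error_trials: int
    pct_error_trials: float
    n_rt_excluded: int
    pct_rt_excluded: float
    n_final: int


def preprocess(
    trials: pd.DataFrame, config: PreprocessConfig = PreprocessConfig()
) -> tuple:
    """Apply the exclusion pipeline and add the natural-log RT column.

    Order: keep word trials; drop subjects then items whose word-trial
    error rate exceeds the threshold; drop error trials; drop trials
    with RT outside [rt_min_ms, rt_max_ms] (percentage reported on the
    post-error base); append ``log_rt``.
    """
    n_input = len(trials)
    words = trials[trials["trial_type"] == "word"].copy()
    if words.empty:
        raise EmptyResultError("no word trials in the input")
    is_err = words["accuracy"] == "error"
    subj_rate = is_err.groupby(words["subject"]).mean()
    bad_subjects = sorted(subj_rate[subj_rate > config.error_rate_threshold].index)
    words = words[~words["subject"].isin(bad_subjects)]
    if words.empty:
        raise EmptyResultError("all subjects excluded by the error screen")
    is_err = words["accuracy"] == "error"
    item_rate = is_err.groupby(words["item"]).mean()
    bad_items = sorted(item_rate[item_rate > config.error_rate_threshold].index)
    words = words[~words["item"].isin(bad_items)]
    if words.empty:
        raise EmptyResultError("all items excluded by the error screen")
    n_screened = len(words)
    correct = words[words["accuracy"] == "correct"]
    n_err = n_screened - len(correct)
    if correct.empty:
        raise EmptyResultError("no correct trials left")
    in_range = correct[
        (correct["rt_ms"] >= config.rt_min_ms)
        & (correct["rt_ms"] <= config.rt_max_ms)
    ].copy()
    n_rt = len(correct) - len(in_range)
    if in_range.empty:
        raise EmptyResultError("no trials left after the RT screen")
    in_range["log_rt"] = np.log(in_range["rt_ms"].to_numpy(dtype=float))
    report = ExclusionReport(
        n_input=n_input,
        n_word_trials=int((trials["trial_type"] == "word").sum()),
        subjects_removed=bad_subjects,
        items_removed=bad_items,
        n_after_error_screen=n_screened,
        n_error_trials=n_err,
        pct_error_trials=100.0 * n_err / n_screened,
        n_rt_excluded=n_rt,
        pct_rt_excluded=100.0 * n_rt / len(correct),
        n_final=len(in_range),
    )
    return in_range.reset_index(drop=True), report


def experiment_model_spec(
    predictor: str = "cosine", with_predictor_fixed: bool = True
) -> MixedLMSpec:
    """Single-experiment model: by-subject slopes + by-item intercepts."""
    slopes = tuple(predictor if s == "cosine" else s for s in SUBJECT_SLOPES)
    fixed = BASELINE_FIXED + ((predictor,) if with_predictor_fixed else ())
    return MixedLMSpec(
        response="log_rt",
        fixed=fixed,
        random=(RandomTerm("subject", slopes), RandomTerm("item")),
    )


def pooled_model_spec(
    predictor: str = "cosine", with_predictor_fixed: bool = True
) -> MixedLMSpec:
    """Pooled model: crossed by-prime and by-target intercepts.

    Targets recur across experiments (with different primes), so item
    intercepts are replaced by separate prime and target intercepts; no
    by-target random slopes are included.
    """
    slopes = tuple(predictor if s == "cosine" else s for s in SUBJECT_SLOPES)
    fixed = BASELINE_FIXED + ((predictor,) if with_predictor_fixed else ())
    return MixedLMSpec(
        response="log_rt",
        fixed=fixed,
        random=(
            RandomTerm("subject", slopes),
            RandomTerm("prime"),
            RandomTerm("target"),
        ),
    )


def fit_lmem(table: pd.DataFrame, spec: MixedLMSpec, **kwargs) -> MixedLMFit:
    """ML fit of a crossed random-effects model (see :mod:`semprime.mixedlm`)."""
    return fit_mixedlm(table, spec, **kwargs)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of two nested ML fits."""

    chisq: float
    df: int
    p_value: float

    def __str__(self) -> str:
        return f"chi2({self.df}) = {self.chisq:.2f}, p = {self.p_value:.3f}"


def likelihood_ratio_test(reduced: MixedLMFit, full: MixedLMFit) -> LRTResult:
    """chi2 = 2 (logL_full - logL_reduced), df = parameter difference.

    Requires the reduced model to be nested in the full one and both to
    be ML fits of the same data.
    """
    if reduced.n_obs != full.n_obs:
        raise ValueError("fits are not on the same data")
    if not set(reduced.spec.fixed) <= set(full.spec.fixed):
        raise ValueError("models are not nested in their fixed effects")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("the full model has fewer parameters than the reduced")
    chisq = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0
    return LRTResult(chisq=chisq, df=df, p_value=p)


@dataclass(frozen=True)
class WaldCI:
    estimate: float
    se: float
    level: float
    lower: float
    upper: float


def wald_ci(estimate: float, se: float, level: float = 0.95) -> WaldCI:
    """estimate -/+ z * se with z the standard-normal quantile."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if se <= 0:
        raise ValueError("se must be positive")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    return WaldCI(estimate=float(estimate), se=float(se), level=level,
                  lower=float(estimate - z * se), upper=float(estimate + z * se))


@dataclass
class AnalysisReport:
    """Everything one model comparison produces."""

    predictor: str
    baseline: MixedLMFit
    cosine_model: MixedLMFit
    lrt: LRTResult
    ci: WaldCI
    item_means: pd.DataFrame
    prediction_curve: pd.DataFrame

    def comparison_table(self) -> pd.DataFrame:
        rows = []
        for name, fit in (("baseline", self.baseline),
                          (f"+{self.predictor}", self.cosine_model)):
            rows.append((name, fit.n_params, fit.loglik, fit.aic))
        out = pd.DataFrame(rows, columns=["model", "k", "logL", "AIC"])
        out.loc[1, "chisq"] = self.lrt.chisq
        out.loc[1, "df"] = self.lrt.df
        out.loc[1, "p"] = self.lrt.p_value
        return out


def _report(
    table: pd.DataFrame,
    predictor: str,
    base_spec: MixedLMSpec,
    full_spec: MixedLMSpec,
    **fit_kwargs,
) -> AnalysisReport:
    baseline = fit_mixedlm(table, base_spec, **fit_kwargs)
    cosine_model = fit_mixedlm(table, full_spec, start=baseline.theta,
                               **fit_kwargs)
    lrt = likelihood_ratio_test(baseline, cosine_model)
    ci = wald_ci(cosine_model.params[predictor], cosine_model.bse[predictor])
    item_means = (
        table.groupby("item")
        .agg(mean_rt=("rt_ms", "mean"), cosine=(predictor, "first"))
        .reset_index()
    )
    grid = pd.DataFrame({predictor: np.linspace(0.0, 1.0, 101)})
    for c in BASELINE_FIXED:
        grid[c] = table[c].mean()
    item_means["predicted_rt"] = np.exp(
        cosine_model.predict_fixed(
            item_means.rename(columns={"cosine": predictor}).assign(
                **{c: table[c].mean() for c in BASELINE_FIXED}
            )
        )
    )
    grid["predicted_rt"] = np.exp(cosine_model.predict_fixed(grid))
    return AnalysisReport(
        predictor=predictor,
        baseline=baseline,
        cosine_model=cosine_model,
        lrt=lrt,
        ci=ci,
        item_means=item_means,
        prediction_curve=grid,
    )


def run_experiment_analysis(
    trials: pd.DataFrame, predictor: str = "cosine", **fit_kwargs
) -> AnalysisReport:
    """Baseline vs. baseline+cosine comparison for one experiment.

    ``trials`` must be a preprocessed table (word trials, ``log_rt``
    column).  The predictor column holds the cosine similarity under
    test; the baseline already carries its by-subject random slope.
    """
    return _report(
        trials,
        predictor,
        experiment_model_spec(predictor, with_predictor_fixed=False),
        experiment_model_spec(predictor, with_predictor_fixed=True),
        **fit_kwargs,
    )


def pooled_analysis(
    trials_exp1: pd.DataFrame,
    trials_exp2: pd.DataFrame,
    predictor: str = "cosine",
    **fit_kwargs,
) -> AnalysisReport:
    """Pooled analysis of two experiments with crossed prime/target intercepts.

    Subject identifiers are made disjoint before concatenation; the
    random structure follows :func:`pooled_model_spec`.  The report's
    comparison table carries log-likelihood and AIC for both models.
    """
    a = trials_exp1.copy()
    b = trials_exp2.copy()
    a["subject"] = "e1_" + a["subject"].astype(str)
    b["subject"] = "e2_" + b["subject"].astype(str)
    pooled = pd.concat([a, b], ignore_index=True)
    return _report(
        pooled,
        predictor,
        pooled_model_spec(predictor, with_predictor_fixed=False),
        pooled_model_spec(predictor, with_predictor_fixed=True),
        **fit_kwargs,
    )


def cosine_correlation(cosines_a, cosines_b) -> float:
    """Pearson correlation between two cosine measures over the same pairs."""
    a = np.asarray(cosines_a, dtype=float)
    b = np.asarray(cosines_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("cosine collections differ in length")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(a, b)[0])
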