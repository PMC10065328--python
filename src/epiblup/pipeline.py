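"""Across-year evaluation pipeline: CV design, model variants, summaries.

The evaluation mirrors an across-season prediction protocol: a bivariate
model is trained on the complete source-year (e.g. 2017) data of the
target environment plus the target-year (2018) training folds, and
evaluated by the Pearson correlation between predicted genetic values and
the held-out target-year phenotypes (predictive ability), averaged over
5-fold cross-validation repeated 5 times.  For sERRBLUP, interaction
selection uses *only* the complete source-year data, never the
cross-validation folds, so target-year test phenotypes influence nothing
upstream of the fold fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import PhenotypeRecords, PredictorPanel
from .kernels import RelationshipKernel, errblup_kernel, gblup_kernel, serrblup_kernel
from .mixed_models import (
    fit_with_protocol,
    genomic_correlation,
    predict_blup,
    reml_univariate,
)
from .selection import EffectVarianceRanking, backsolve_effects, effect_variances, select_top

logger = logging.getLogger("epiblup")

__all__ = [
    "ModelSpec",
    "CVPlan",
    "EvaluationResult",
    "make_cv_plan",
    "run_evaluation",
    "serrblup_selection",
    "prediction_accuracy",
    "gain_regression",
    "phenotypic_correlation",
    "best_serrblup",
]

MODELS = ("uni_gblup_within", "uni_gblup_avg", "bi_gblup", "bi_errblup", "bi_serrblup")


@dataclass
class ModelSpec:
    model: str
    environment: str
    trait: str
    target_year: int
    source_year: int
    predictor_kind: str = "snp"
    q: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if (self.model == "bi_serrblup") != (self.q is not None):
            raise ValueError("q is required iff model is bi_serrblup")


@dataclass
class CVPlan:
    folds: int
    reps: int
    seed: int
    partitions: list  # per rep: list of `folds` line-id lists

    def fold_lines(self, rep: int, fold: int) -> list[str]:
        return self.partitions[rep][fold]


@dataclass
class EvaluationResult:
    spec: ModelSpec
    pa_per_fold: np.ndarray          # folds*reps values, NaN where skipped
    pa_mean: float
    accuracy_mean: float | None
    r_g_full: float | None           # genomic correlation from the full-data prefit
    pct_converged: float
    r_p: float | None                # phenotypic correlation between years
    pa_mean_converged: float = np.nan
    fold_converged: np.ndarray = field(default=None, repr=False)


def make_cv_plan(lines, folds: int = 5, reps: int = 5, seed: int = 0) -> CVPlan:
    """Random equal-split fold assignments, deterministic given seed.

    Each repetition is an independent random partition of the lines into
    ``folds`` subsets whose sizes differ by at most one.
    """
    lines = list(lines)
    if len(lines) < folds:
        raise ValueError(f"{len(lines)} lines cannot form {folds} folds")
    rng = np.random.default_rng(seed)
    sizes = np.full(folds, len(lines) // folds)
    sizes[: len(lines) % folds] += 1
    partitions = []
    for _ in range(reps):
        perm = rng.permutation(len(lines))
        out, start = [], 0
        for sz in sizes:
            out.append([lines[i] for i in perm[start : start + sz]])
            start += sz
        partitions.append(out)
    return CVPlan(folds=folds, reps=reps, seed=seed, partitions=partitions)


def serrblup_selection(
    panel: PredictorPanel,
    phenotypes: PhenotypeRecords,
    environment: str,
    trait: str,
    source_year: int,
    kernel: RelationshipKernel | None = None,
) -> EffectVarianceRanking:
    """Rank all pairwise interactions on the complete source-year data.

    Fits univariate ERRBLUP to the source-year phenotypes of the target
    environment, backsolves all pair effects, and fills effect variances.
    """
    k_err = kernel if kernel is not None else errblup_kernel(panel)
    y_src = phenotypes.series(source_year, environment, trait)
    y_src = y_src[y_src.index.isin(panel.line_ids)]
    fit = reml_univariate(y_src, k_err)
    ranking = backsolve_effects(panel, fit.g_hat.to_numpy(), k_err)
    return effect_variances(ranking)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def _build_kernel(spec: ModelSpec, panel: PredictorPanel, phenotypes: PhenotypeRecords):
    if spec.model in ("uni_gblup_within", "uni_gblup_avg", "bi_gblup"):
        return gblup_kernel(panel)
    if spec.model == "bi_errblup":
        return errblup_kernel(panel)
    ranking = serrblup_selection(
        panel, phenotypes, spec.environment, spec.trait, spec.source_year
    )
    return serrblup_kernel(panel, select_top(ranking, spec.q))


def run_evaluation(
    spec: ModelSpec,
    panel: PredictorPanel,
    blocks: PredictorPanel | None,
    phenotypes: PhenotypeRecords,
    plan: CVPlan,
    h2: float | None = None,
    kernel: RelationshipKernel | None = None,
) -> EvaluationResult:
    """Run one model variant through the full cross-validation design.

    ``kernel`` may be supplied to reuse a precomputed kernel (it must match
    ``spec``); otherwise it is built here.  Fold-level predictive abilities
    are NaN where a fold was skipped (fewer than 3 phenotyped test lines,
    or degenerate predictions); the mean is over computed folds.
    """
    pp = blocks if spec.predictor_kind == "block" else panel
    if pp is None:
        raise ValueError(f"no {spec.predictor_kind} panel supplied")
    recs = phenotypes.subset(environment=spec.environment, trait=spec.trait)
    recs = recs.subset(lines=pp.line_ids)
    k = kernel if kernel is not None else _build_kernel(spec, pp, recs)

    y_target = recs.series(spec.target_year, spec.environment, spec.trait)
    pa = np.full(plan.folds * plan.reps, np.nan)
    conv = np.zeros(plan.folds * plan.reps, dtype=bool)
    r_g_full = None
    prefit_components = None

    bivariate = spec.model.startswith("bi_")
    if bivariate:
        two_year = recs.frame[recs.frame["year"].isin([spec.source_year, spec.target_year])]
        prefit = fit_with_protocol(PhenotypeRecords(two_year), k, stage="prefit")
        prefit_components = prefit.components
        try:
            r_g_full = genomic_correlation(prefit)
        except ValueError:
            r_g_full = np.nan

    if spec.model == "uni_gblup_avg":
        y_avg = (
            recs.frame[recs.frame["year"].isin([spec.source_year, spec.target_year])]
            .groupby("line_id")["value"].mean()
        )

    for rep in range(plan.reps):
        for fold in range(plan.folds):
            i = rep * plan.folds + fold
            test_lines = [l for l in plan.fold_lines(rep, fold) if l in y_target.index]
            if len(test_lines) < 3:
                logger.info("fold %d/%d skipped: %d phenotyped test lines", rep, fold, len(test_lines))
                continue
            y_test = y_target.loc[test_lines].to_numpy(float)

            if spec.model == "uni_gblup_within":
                y_train = y_target.drop(index=test_lines, errors="ignore")
                fit = reml_univariate(y_train, k)
                g_pred = fit.g_hat.loc[test_lines].to_numpy(float)
                conv[i] = fit.converged
            elif spec.model == "uni_gblup_avg":
                y_train = y_avg.drop(index=test_lines, errors="ignore")
                fit = reml_univariate(y_train, k)
                g_pred = fit.g_hat.loc[test_lines].to_numpy(float)
                conv[i] = fit.converged
            else:
                fold_recs = recs.frame[
                    (recs.frame["year"] == spec.source_year)
                    | (
                        (recs.frame["year"] == spec.target_year)
                        & ~recs.frame["line_id"].isin(test_lines)
                    )
                ]
                fit = fit_with_protocol(
                    PhenotypeRecords(fold_recs), k, stage="cv_fold", init=prefit_components
                )
                g_pred = predict_blup(fit, k, spec.target_year, test_lines).to_numpy(float)
                conv[i] = fit.converged and not fit.fixed_fallback

            if np.std(g_pred) == 0 or np.std(y_test) == 0:
                logger.info("fold %d/%d skipped: degenerate predictions", rep, fold)
                continue
            pa[i] = _pearson(g_pred, y_test)

    computed = ~np.isnan(pa)
    pa_mean = float(np.nanmean(pa)) if computed.any() else np.nan
    pa_conv = float(np.nanmean(pa[conv & computed])) if (conv & computed).any() else np.nan
    r_p = None
    try:
        r_p = phenotypic_correlation(
            recs, spec.environment, spec.trait, spec.source_year, spec.target_year
        )
    except ValueError:
        r_p = np.nan
    return EvaluationResult(
        spec=spec,
        pa_per_fold=pa,
        pa_mean=pa_mean,
        accuracy_mean=None if h2 is None else prediction_accuracy(pa_mean, h2),
        r_g_full=r_g_full,
        pct_converged=float(conv[computed].mean()) if computed.any() else 0.0,
        r_p=r_p,
        pa_mean_converged=pa_conv,
        fold_converged=conv,
    )


def prediction_accuracy(pa: float, h2: float) -> float:
    """Predictive ability divided by the square root of trait heritability."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    return pa / float(np.sqrt(h2))


def gain_regression(results, predictor: str = "r_g"):
    """OLS of the gain (best minus baseline predictive ability) on a correlation.

    ``results`` is a sequence of (baseline, best) EvaluationResult pairs;
    ``predictor`` selects the genomic (``r_g``) or phenotypic (``r_p``)
    correlation of the *best* model.  Returns (slope, intercept, r_squared,
    pearson_r, p_value); the p-value is the two-sided t-test of the
    Pearson correlation.
    """
    if predictor not in ("r_g", "r_p"):
        raise ValueError("predictor must be 'r_g' or 'r_p'")
    if len(results) < 3:
        raise ValueError("need at least 3 result pairs")
    gains = np.array([best.pa_mean - base.pa_mean for base, best in results])
    x = np.array(
        [best.r_g_full if predictor == "r_g" else best.r_p for _, best in results],
        dtype=float,
    )
    if np.std(x) == 0:
        raise ValueError("constant predictor; regression undefined")
    fit = stats.linregress(x, gains)
    return (
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2),
        float(fit.rvalue), float(fit.pvalue),
    )


def phenotypic_correlation(
    records: PhenotypeRecords, environment: str, trait: str, year1: int, year2: int
) -> float:
    """Pearson correlation between the two years over commonly phenotyped lines."""
    a = records.series(year1, environment, trait)
    b = records.series(year2, environment, trait)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} lines phenotyped in both years")
    return _pearson(a.loc[common].to_numpy(float), b.loc[common].to_numpy(float))


def best_serrblup(results: dict[float, EvaluationResult]) -> tuple[float, EvaluationResult]:
    """Selection fraction maximizing mean predictive ability; ties -> larger q."""
    if not results:
        raise ValueError("no results")
    best_q = max(results, key=lambda q: (results[q].pa_mean, q))
    return best_q, results[best_q]
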