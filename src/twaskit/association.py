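"""Association testing of PTS against disease and clinical outcomes.

Each outcome (case-control status, spinal vs bulbar onset, age at onset,
survival) is tested by ordinary least squares with sex as a covariate.  The
variance explained by the score is the incremental R^2 of the full model
over the sex-only model.  For binary outcomes the observed-scale R^2 is
converted to the liability scale with the Lee et al. (2012)
ascertainment-corrected transformation, parameterised by the population
prevalence K and the sample case proportion P.  Per-platform estimates are
combined by fixed-effect inverse-variance-weighted (IVW) meta-analysis.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scoring import (PtsVector, WeightSet, build_weight_set, compute_pts,
                      standardize_expression, DEFAULT_THRESHOLD_GRID,
                      FeatureCorrelation)
from .simulate import ExpressionCohort

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult",
    "LiabilityParams",
    "fit_linear_assoc",
    "observed_to_liability_r2",
    "ivw_meta",
    "evaluate_all",
    "best_rows",
    "DEFAULT_PREVALENCE",
    "ONSET_PREVALENCE",
]

#: population lifetime prevalence used for the case-control liability
#: conversion (1 in 300).
DEFAULT_PREVALENCE = 1.0 / 300.0
#: nominal prevalence for the spinal-vs-bulbar onset conversion (0.5, an
#: arbitrary value that makes liability R^2 comparable across studies).
ONSET_PREVALENCE = 0.5

BINARY_OUTCOMES = ("case_control", "onset_site")
OUTCOMES = ("case_control", "onset_site", "onset_age", "survival")


@dataclasses.dataclass(frozen=True)
class LiabilityParams:
    """Population prevalence K and sample case proportion P."""

    K: float
    P: float

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0 or not 0.0 < self.P < 1.0:
            raise ValueError("K and P must lie strictly inside (0, 1)")


@dataclasses.dataclass(frozen=True)
class AssocResult:
    """One regression (or meta-analysis) of a PTS against an outcome."""

    outcome: str
    beta: float
    se: float
    p: float
    r2_observed: float
    n: int
    platform: str = "meta"
    r2_liability: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if self.r2_liability is not None and self.outcome not in BINARY_OUTCOMES:
            raise ValueError("liability R^2 only defined for binary outcomes")


def fit_linear_assoc(outcome: Sequence[float], pts: Sequence[float],
                     sex: Sequence[int], outcome_name: str = "outcome",
                     platform: str = "platform") -> AssocResult:
    """OLS of outcome on (intercept, sex, PTS); incremental R^2 for the PTS.

    Rows with any missing value are dropped; at least 10 complete
    observations are required.  A constant outcome or constant PTS raises
    an error naming the degenerate column.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(pts, dtype=float)
    s = np.asarray(sex, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x) & np.isfinite(s)
    y, x, s = y[ok], x[ok], s[ok]
    if len(y) < 10:
        raise ValueError("fewer than 10 complete observations")
    if np.ptp(y) == 0:
        raise ValueError(f"constant outcome column '{outcome_name}'")
    if np.ptp(x) == 0:
        raise ValueError("constant PTS column")
    covs = [np.ones_like(y)]
    if np.ptp(s) > 0:
        covs.append(s)
    else:
        logger.info("sex constant in %s/%s; dropped from design",
                    platform, outcome_name)
    x_red = np.column_stack(covs)
    x_full = np.column_stack(covs + [x])
    full = sm.OLS(y, x_full).fit()
    red = sm.OLS(y, x_red).fit()
    beta = float(full.params[-1])
    se = float(full.bse[-1])
    p = float(full.pvalues[-1])
    r2_inc = max(float(full.rsquared - red.rsquared), 0.0)
    return AssocResult(outcome_name, beta, se, p, r2_inc, int(len(y)),
                       platform=platform)


def observed_to_liability_r2(r2_obs: float, params: LiabilityParams) -> float:
    """Convert observed-scale R^2 to the liability scale (Lee et al. 2012).

    With t = Phi^-1(1-K), z = phi(t), m = z/K,
    C = [K(1-K)]^2 / [z^2 P(1-P)] and
    theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t), the liability-scale
    variance explained is ``C r2 / (1 + C theta r2)``.
    """
    if not 0.0 <= r2_obs < 1.0:
        raise ValueError("r2_obs must lie in [0, 1)")
    K, P = params.K, params.P
    t = stats.norm.ppf(1.0 - K)
    z = stats.norm.pdf(t)
    m = z / K
    C = (K * (1.0 - K)) ** 2 / (z * z * P * (1.0 - P))
    d = m * (P - K) / (1.0 - K)
    theta = d * (d - t)
    out = C * r2_obs / (1.0 + C * theta * r2_obs)
    return max(float(out), 0.0)


def ivw_meta(results: Sequence[AssocResult]) -> AssocResult:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    beta = sum(b_i / se_i^2) / sum(1 / se_i^2); se = sum(1/se_i^2)^(-1/2);
    p from the normal Z = beta/se.  A single study is returned unchanged
    (relabelled "meta").  The meta-level observed R^2 is the t^2/(t^2+df)
    approximation from the meta Z and pooled residual df.
    """
    if not results:
        raise ValueError("no results to meta-analyse")
    outcomes = {r.outcome for r in results}
    if len(outcomes) > 1:
        raise ValueError(f"mixed outcomes in meta-analysis: {outcomes}")
    n_pool = int(sum(r.n for r in results))
    if len(results) == 1:
        r = results[0]
        return dataclasses.replace(r, platform="meta")
    w = np.array([1.0 / r.se**2 for r in results])
    b = np.array([r.beta for r in results])
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    zstat = beta / se
    p = float(2.0 * stats.norm.sf(abs(zstat)))
    df = max(n_pool - 3, 1)
    r2 = float(zstat**2 / (zstat**2 + df))
    return AssocResult(results[0].outcome, beta, se, p, r2, n_pool,
                       platform="meta")


def _outcome_vectors(cohort: ExpressionCohort, outcome: str):
    ph = cohort.phenotypes
    if outcome == "case_control":
        return ph["case"], ph["sex"], ph.index
    cases = ph[ph["case"] == 1]
    return cases[outcome], cases["sex"], cases.index


def evaluate_all(
    cohorts: Sequence[ExpressionCohort],
    weight_sets: Iterable[WeightSet],
    prevalence: float = DEFAULT_PREVALENCE,
    onset_prevalence: float = ONSET_PREVALENCE,
    outcomes: Sequence[str] = OUTCOMES,
) -> pd.DataFrame:
    """Per-platform fits plus IVW meta for every weight set x outcome.

    Case-control is tested in the full cohort; clinical outcomes within
    cases only.  Binary outcomes additionally get a liability-scale R^2
    (K = ``prevalence`` for case-control, K = ``onset_prevalence`` for
    onset site; P is always the realized case proportion of the analysis
    sample).  Platforms where an outcome is degenerate are skipped with a
    log message.
    """
    z_expr = {c.platform: standardize_expression(c.expression)
              for c in cohorts}
    rows = []
    for ws in weight_sets:
        pts: dict[str, PtsVector] = {
            c.platform: compute_pts(z_expr[c.platform], ws) for c in cohorts}
        for outcome in outcomes:
            fits: list[AssocResult] = []
            fracs: list[tuple[int, float]] = []
            for cohort in cohorts:
                y, sex, idx = _outcome_vectors(cohort, outcome)
                score = pts[cohort.platform].scores.loc[idx]
                try:
                    fit = fit_linear_assoc(y, score, sex, outcome,
                                           cohort.platform)
                except ValueError as exc:
                    logger.info("skipping %s / %s: %s", cohort.platform,
                                outcome, exc)
                    continue
                if outcome in BINARY_OUTCOMES:
                    mask = np.isfinite(np.asarray(y, dtype=float))
                    frac = float(np.asarray(y, dtype=float)[mask].mean())
                    K = prevalence if outcome == "case_control" \
                        else onset_prevalence
                    r2_liab = _safe_liability(fit.r2_observed, K, frac)
                    fit = dataclasses.replace(fit, r2_liability=r2_liab)
                    fracs.append((fit.n, frac))
                fits.append(fit)
            if not fits:
                continue
            meta = ivw_meta(fits)
            if outcome in BINARY_OUTCOMES and fracs:
                n_tot = sum(n for n, _ in fracs)
                p_pool = sum(n * f for n, f in fracs) / n_tot
                K = prevalence if outcome == "case_control" \
                    else onset_prevalence
                meta = dataclasses.replace(
                    meta, r2_liability=_safe_liability(meta.r2_observed, K,
                                                       p_pool))
            for fit in fits + [meta]:
                rows.append({
                    "threshold": ws.threshold, "stratum": ws.stratum,
                    "coloc_only": ws.coloc_only, "n_genes": ws.n_genes,
                    "outcome": fit.outcome, "platform": fit.platform,
                    "beta": fit.beta, "se": fit.se, "p": fit.p,
                    "r2_observed": fit.r2_observed,
                    "r2_liability": fit.r2_liability, "n": fit.n,
                })
    return pd.DataFrame(rows)


def _safe_liability(r2_obs: float, K: float, P: float) -> float | None:
    if not 0.0 < P < 1.0:
        return None
    return observed_to_liability_r2(min(r2_obs, 1.0 - 1e-12),
                                    LiabilityParams(K, P))


def best_rows(assoc: pd.DataFrame) -> pd.DataFrame:
    """Best-threshold meta row per (stratum, coloc_only, outcome).

    "Best" maximises liability R^2 where defined and observed R^2
    otherwise.  Note this in-sample maximum over the threshold grid is
    optimistic; no out-of-sample correction is applied.
    """
    meta = assoc[assoc["platform"] == "meta"].copy()
    meta["r2_rank"] = meta["r2_liability"].fillna(meta["r2_observed"])
    idx = meta.groupby(["stratum", "coloc_only", "outcome"])["r2_rank"].idxmax()
    return meta.loc[idx].drop(columns="r2_rank").reset_index(drop=True)


def default_weight_sets(
    records: pd.DataFrame,
    corr: FeatureCorrelation,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    strata: Sequence[str] = ("all", "blood", "brain"),
    coloc_options: Sequence[bool] = (False, True),
    **kwargs,
) -> list[WeightSet]:
    """The full grid of weight sets: thresholds x strata x coloc filter."""
    out = []
    for stratum in strata:
        for coloc_only in coloc_options:
            for thr in threshold_grid:
                ws = build_weight_set(records, corr, thr, stratum=stratum,
                                      coloc_only=coloc_only, **kwargs)
                if ws.n_genes:
                    out.append(ws)
    return out
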