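"""Observed case-control differential expression and TWAS concordance.

Probe-level expression is averaged per gene and log2-transformed.
Differential expression within one platform is the Pearson (point-biserial)
correlation between case-control status and expression, with a two-sided
t-transform p-value and BH-FDR across genes.  Platforms are combined on
Fisher's z scale with variance 1/(n-3) by inverse-variance weighting.
Finally, meta-analytic observed directions are classified against the
TWAS-inferred direction (the sign of a gene's mean TWAS Z) as concordant
or discordant among significantly differentially expressed genes.
"""
from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ExpressionCohort
from .triage import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess_expression",
    "per_gene_case_control_correlation",
    "meta_diffexpr",
    "classify_concordance",
]


def preprocess_expression(probe_matrix: pd.DataFrame,
                          probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Average probes per gene, then log2.

    ``probe_map`` must cover every probe row; values must be positive
    before the log step or an error naming the offending coordinates is
    raised.
    """
    missing = [p for p in probe_matrix.index if p not in probe_map]
    if missing:
        raise ValueError(f"probes missing from probe map: {missing[:10]}")
    gene_means = probe_matrix.groupby(
        probe_matrix.index.map(lambda p: probe_map[p])).mean()
    bad = np.argwhere(gene_means.to_numpy() <= 0)
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"non-positive value at gene {gene_means.index[i]!r}, sample "
            f"{gene_means.columns[j]!r}: cannot log2-transform")
    return np.log2(gene_means)


def per_gene_case_control_correlation(
        cohort: ExpressionCohort) -> pd.DataFrame:
    """Per-gene Pearson r between case status and expression, with BH q.

    Requires at least 3 cases and 3 controls; constant genes are dropped
    with a warning.
    """
    status = cohort.phenotypes["case"].to_numpy(dtype=float)
    if (status == 1).sum() < 3 or (status == 0).sum() < 3:
        raise ValueError("need at least 3 cases and 3 controls")
    expr = cohort.expression.loc[:, cohort.phenotypes.index].to_numpy(
        dtype=float)
    n = len(status)
    sd_gene = expr.std(axis=1, ddof=0)
    keep = sd_gene > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} constant genes")
    expr = expr[keep]
    genes = cohort.expression.index[keep]

    sc = status - status.mean()
    ec = expr - expr.mean(axis=1, keepdims=True)
    r = (ec @ sc) / (n * sd_gene[keep] * sc.std(ddof=0))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df=n - 2), 1e-300, 1.0)
    out = pd.DataFrame({"gene_id": genes, "r": r, "p": p, "n": n,
                        "platform": cohort.platform})
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.reset_index(drop=True)


def meta_diffexpr(per_platform: Sequence[pd.DataFrame],
                  fisher_z: bool = True) -> pd.DataFrame:
    """IVW meta-analysis of per-platform correlations across genes.

    Default combines on Fisher's z scale with variance 1/(n-3) and
    back-transforms; ``fisher_z=False`` combines raw r with the same
    variance (a flat approximation).  Genes present on a single platform
    pass through unchanged.
    """
    stacked = pd.concat(per_platform, ignore_index=True)
    rows = []
    for gene, sub in stacked.groupby("gene_id"):
        if len(sub) == 1:
            row = sub.iloc[0]
            rows.append({"gene_id": gene, "r": float(row["r"]),
                         "p": float(row["p"]), "n": int(row["n"]),
                         "n_platforms": 1})
            continue
        ns = sub["n"].to_numpy(dtype=float)
        if (ns <= 3).any():
            raise ValueError(f"gene {gene}: platform n must exceed 3 for "
                             "the 1/(n-3) variance")
        rs = np.clip(sub["r"].to_numpy(dtype=float), -1 + 1e-12, 1 - 1e-12)
        est = np.arctanh(rs) if fisher_z else rs
        w = ns - 3.0
        combined = float((w * est).sum() / w.sum())
        se = float(w.sum() ** -0.5)
        z = combined / se
        p = float(np.clip(2.0 * stats.norm.sf(abs(z)), 1e-300, 1.0))
        r_meta = float(np.tanh(combined)) if fisher_z else combined
        rows.append({"gene_id": gene, "r": r_meta, "p": p,
                     "n": int(ns.sum()), "n_platforms": int(len(sub))})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def classify_concordance(twas_mean_z: Mapping[str, float],
                         meta: pd.DataFrame,
                         alpha: float = 0.05,
                         zero_tol: float = 1e-8) -> tuple[pd.DataFrame, dict]:
    """Compare TWAS-inferred and observed directions of effect.

    A gene with significant observed differential expression (q <= alpha)
    is ``concordant`` if the observed r and the TWAS mean Z share a sign,
    ``discordant`` otherwise; non-significant genes are
    ``not_significant``.  Genes whose mean TWAS Z is within ``zero_tol``
    of zero are ``unclassifiable``.  Returns the per-gene calls and a
    summary count dict.
    """
    rows = []
    for _, row in meta.iterrows():
        g = row["gene_id"]
        if g not in twas_mean_z:
            continue
        tz = float(twas_mean_z[g])
        if abs(tz) < zero_tol:
            call = "unclassifiable"
        elif row["q"] > alpha:
            call = "not_significant"
        elif np.sign(row["r"]) == np.sign(tz):
            call = "concordant"
        else:
            call = "discordant"
        rows.append({"gene_id": g,
                     "twas_sign": "+" if tz > 0 else ("-" if tz < 0 else "0"),
                     "observed_sign": "+" if row["r"] > 0 else "-",
                     "observed_significant": bool(row["q"] <= alpha),
                     "call": call})
    calls = pd.DataFrame(rows)
    summary = {
        "n_compared": int(len(calls)),
        "n_significant": int(calls["observed_significant"].sum())
        if len(calls) else 0,
        "n_concordant": int((calls["call"] == "concordant").sum())
        if len(calls) else 0,
        "n_discordant": int((calls["call"] == "discordant").sum())
        if len(calls) else 0,
    }
    return calls, summary
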