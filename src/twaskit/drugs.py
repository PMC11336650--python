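"""Directional drug-gene enrichment and ATC drug-class enrichment.

Drug-gene interactions are coded -1/0/+1 from a closed label vocabulary
(decreased / undirected / increased gene activity).  Two drug-level
statistics are provided:

* a signed concordance test: ``S = sum_g code_g * Z_g`` over a drug's
  directional interactions with measured (clumped) genes, standardized
  under the permutation null that reassigns the drug's codes to random
  measured genes.  The reported drug Z is sign-flipped so that positive
  means the drug pushes expression *against* the risk direction, i.e. is
  predicted to reduce disease risk.  Small instances are evaluated by
  exact enumeration of code-to-gene assignments; otherwise the closed-form
  mean/variance of sampling without replacement is used with a normal
  approximation.
* an unsigned rank-sum test: one-sided Mann-Whitney of the drug's member
  genes' chi-square-scale association values against all non-member genes.

ATC level-3 class enrichment compares drug statistics within a class to
all other tested drugs by Wilcoxon rank-sum (two-sided for the signed
statistic, one-sided "greater" for the unsigned), with BH-FDR across
classes.  Classes need at least 5 drugs with statistics to be tested.
"""
from __future__ import annotations

import itertools
import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import NEGATIVE_LABELS, POSITIVE_LABELS, UNDIRECTED_LABEL
from .triage import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "code_interactions",
    "filter_testable_drugs",
    "signed_drug_enrichment",
    "unsigned_drug_enrichment",
    "atc_enrichment",
    "LABEL_CODES",
]

LABEL_CODES: dict[str, int] = {
    **{lab: -1 for lab in NEGATIVE_LABELS},
    **{lab: +1 for lab in POSITIVE_LABELS},
    UNDIRECTED_LABEL: 0,
}

# permutation-null gates for the signed test: drugs with at most
# _PERM_MAX_CODES directional genes use the permutation null (exact
# enumeration up to _EXACT_MAX_ASSIGNMENTS assignments, Monte-Carlo
# permutation beyond); larger drugs use the closed-form normal
# approximation, which is adequate once the sum has enough terms.
_PERM_MAX_CODES = 8
_EXACT_MAX_ASSIGNMENTS = 50_000
_MC_PERMUTATIONS = 4000


def code_interactions(raw: pd.DataFrame) -> pd.DataFrame:
    """Attach -1/0/+1 codes to a drug-gene interaction table.

    ``raw`` needs columns ``drug_id, gene_id, label``.  Unknown labels are
    rejected with the offending row indices listed.
    """
    labels = raw["label"]
    unknown = ~labels.isin(LABEL_CODES)
    if unknown.any():
        bad = raw.loc[unknown, ["drug_id", "gene_id", "label"]]
        raise ValueError(
            "unknown interaction labels at rows "
            f"{bad.index.tolist()[:20]}: {sorted(set(bad['label']))}")
    out = raw.copy()
    out["code"] = labels.map(LABEL_CODES).astype(int)
    return out


def filter_testable_drugs(interactions: pd.DataFrame,
                          gene_stats: Mapping[str, float],
                          min_genes: int = 2) -> list[str]:
    """Drugs interacting with at least ``min_genes`` measured genes."""
    measured = set(gene_stats)
    sub = interactions[interactions["gene_id"].isin(measured)]
    counts = sub.groupby("drug_id")["gene_id"].nunique()
    return sorted(counts[counts >= min_genes].index)


def _exact_signed_p(z_universe: np.ndarray, codes: np.ndarray,
                    s_obs: float) -> tuple[float, float, float]:
    """Exact permutation null of S over all ordered code->gene assignments."""
    n, k = len(z_universe), len(codes)
    picks = np.fromiter(itertools.chain.from_iterable(
        itertools.permutations(range(n), k)), dtype=np.intp).reshape(-1, k)
    s_all = z_universe[picks] @ codes
    mu = float(s_all.mean())
    sd = float(s_all.std(ddof=0))
    dev = abs(s_obs - mu)
    p = float((np.abs(s_all - mu) >= dev - 1e-12).mean())
    return mu, sd, p


def _mc_signed_p(z_universe: np.ndarray, codes: np.ndarray, s_obs: float,
                 mu: float, rng: np.random.Generator) -> float:
    """Monte-Carlo permutation p for S when enumeration is infeasible."""
    n, k = len(z_universe), len(codes)
    picks = np.argpartition(rng.random((_MC_PERMUTATIONS, n)), k - 1,
                            axis=1)[:, :k]
    s_all = z_universe[picks] @ codes
    dev = abs(s_obs - mu)
    return float((1 + int((np.abs(s_all - mu) >= dev - 1e-12).sum()))
                 / (_MC_PERMUTATIONS + 1))


def signed_drug_enrichment(gene_z: Mapping[str, float],
                           interactions: pd.DataFrame,
                           min_genes: int = 2,
                           seed: int = 0) -> pd.DataFrame:
    """Signed concordance enrichment per drug against the permutation null.

    ``gene_z`` maps clumped (approximately independent) genes to signed
    association Z-scores.  Reported z is positive when the drug's
    interaction directions oppose the risk direction (predicted
    protective); p is two-sided; q is BH-FDR across drugs.  ``seed``
    drives the Monte-Carlo permutations used for drugs whose assignment
    space is too large to enumerate.
    """
    mc_rng = np.random.default_rng(seed)
    if "code" not in interactions.columns:
        interactions = code_interactions(interactions)
    universe_genes = sorted(gene_z)
    zu = np.array([gene_z[g] for g in universe_genes], dtype=float)
    n = len(zu)
    if n < 2:
        raise ValueError("need at least 2 measured genes")
    mu_z = zu.mean()
    # population variance of the measured-gene Z universe
    var_z = zu.var(ddof=0)

    testable = set(filter_testable_drugs(interactions, gene_z, min_genes))
    rows = []
    for drug, sub in interactions.groupby("drug_id"):
        if drug not in testable:
            continue
        sub = sub[sub["gene_id"].isin(gene_z)].drop_duplicates("gene_id")
        directional = sub[sub["code"] != 0]
        if directional.empty:
            logger.info("drug %s has no directional interactions; excluded "
                        "from the signed test", drug)
            continue
        codes = directional["code"].to_numpy(dtype=float)
        zg = np.array([gene_z[g] for g in directional["gene_id"]])
        s_obs = float(codes @ zg)
        k = len(codes)
        csum = codes.sum()
        csq = (codes**2).sum()
        mu = mu_z * csum
        var = var_z * (csq - (csum**2 - csq) / (n - 1))
        sd = math.sqrt(max(var, 0.0))
        z_std = (s_obs - mu) / sd if sd > 0 else 0.0
        if k <= _PERM_MAX_CODES and math.perm(n, k) <= _EXACT_MAX_ASSIGNMENTS:
            mu_e, sd_e, p = _exact_signed_p(zu, codes, s_obs)
            z_std = (s_obs - mu_e) / sd_e if sd_e > 0 else 0.0
        elif k <= _PERM_MAX_CODES:
            p = _mc_signed_p(zu, codes, s_obs, mu, mc_rng)
        else:
            p = float(2.0 * stats.norm.sf(abs(z_std))) if sd > 0 else 1.0
        rows.append({"drug_id": drug, "n_genes": int(len(sub)),
                     "s": s_obs, "z": -z_std, "p": max(p, 1e-300)})
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
    return result


def _rank_sum_p(group: np.ndarray, rest: np.ndarray,
                alternative: str) -> float:
    """Mann-Whitney p: exact when small and tie-free, else midrank normal
    approximation with continuity correction."""
    combined = np.concatenate([group, rest])
    tie_free = len(np.unique(combined)) == len(combined)
    method = "exact" if (tie_free and min(len(group), len(rest)) <= 8) \
        else "asymptotic"
    res = stats.mannwhitneyu(group, rest, alternative=alternative,
                             method=method)
    return float(res.pvalue)


def unsigned_drug_enrichment(gene_assoc: Mapping[str, float],
                             interactions: pd.DataFrame,
                             min_genes: int = 2) -> pd.DataFrame:
    """Unsigned enrichment: member vs non-member gene association ranks.

    ``gene_assoc`` maps genes to chi-square-scale association values (e.g.
    Z^2).  One-sided (greater) Mann-Whitney per drug; BH-FDR across drugs.
    """
    genes = sorted(gene_assoc)
    values = {g: float(gene_assoc[g]) for g in genes}
    testable = set(filter_testable_drugs(interactions, gene_assoc, min_genes))
    rows = []
    for drug, sub in interactions.groupby("drug_id"):
        if drug not in testable:
            continue
        members = sorted(set(sub["gene_id"]) & set(genes))
        non_members = [g for g in genes if g not in set(members)]
        if not non_members:
            raise ValueError(f"drug {drug} covers the whole gene universe; "
                             "no comparator genes")
        mvals = np.array([values[g] for g in members])
        nvals = np.array([values[g] for g in non_members])
        p = _rank_sum_p(mvals, nvals, "greater")
        rows.append({"drug_id": drug, "n_genes": len(members),
                     "p": max(p, 1e-300)})
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
    return result


def atc_enrichment(drug_results: pd.DataFrame,
                   atc_map: pd.DataFrame | Mapping[str, str],
                   min_drugs: int = 5,
                   sided: str | None = None,
                   restrict_first: bool = False) -> pd.DataFrame:
    """ATC level-3 class enrichment by Wilcoxon rank-sum with BH-FDR.

    Drugs are ranked on their signed ``z`` when present (two-sided test,
    direction summarised by the class median z) or on ``-log10(p)``
    otherwise (one-sided "greater").  ``atc_map`` maps drug -> atc3; a
    drug with several codes contributes to each unless ``restrict_first``.
    Classes with fewer than ``min_drugs`` tested drugs are skipped; a
    class containing every tested drug has no comparator and is an error.
    """
    if isinstance(atc_map, Mapping):
        atc_df = pd.DataFrame({"drug_id": list(atc_map),
                               "atc3": [atc_map[d] for d in atc_map]})
    else:
        atc_df = atc_map[["drug_id", "atc3"]].drop_duplicates()
    if restrict_first:
        atc_df = atc_df.sort_values("atc3").drop_duplicates("drug_id")

    signed = "z" in drug_results.columns
    if sided is None:
        sided = "two" if signed else "one"
    alternative = "two-sided" if sided == "two" else "greater"
    stat = drug_results.set_index("drug_id")["z"] if signed else \
        -np.log10(drug_results.set_index("drug_id")["p"])

    merged = atc_df[atc_df["drug_id"].isin(stat.index)]
    rows = []
    for atc, sub in merged.groupby("atc3"):
        drugs = sorted(set(sub["drug_id"]))
        if len(drugs) < min_drugs:
            continue
        group = stat.loc[drugs].to_numpy(dtype=float)
        rest = stat.drop(index=drugs).to_numpy(dtype=float)
        if len(rest) == 0:
            raise ValueError(f"ATC group {atc} contains every tested drug")
        p = _rank_sum_p(group, rest, alternative)
        rows.append({
            "atc3": atc, "n_drugs": len(drugs),
            "median_z": float(np.median(group)) if signed else np.nan,
            "p": max(p, 1e-300),
            "rank_stat": "z" if signed else "-log10(p)",
        })
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
        result = result.sort_values(["q", "p"]).reset_index(drop=True)
    return result
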