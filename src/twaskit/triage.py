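"""High-confidence gene triage from TWAS/SMR statistics and fine-mapping.

A gene is called a high-confidence disease association if it satisfies at
least one of three criteria:

* ``finemap`` — the gene body contains every variant of some 95 % credible
  set (an optional flanking window may be added);
* ``fusion_coloc`` — an FDR-significant fusion-style association that also
  colocalises, i.e. PP4 / (PP3 + PP4) strictly exceeds 0.8;
* ``smr_heidi`` — an FDR-significant SMR-style association whose HEIDI
  p-value strictly exceeds 0.05 (no evidence of heterogeneity/linkage).

FDR correction is Benjamini-Hochberg, applied across all panels within
each method stream separately; expression and protein records are pooled
within a method unless requested otherwise.
"""
from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "bh_fdr",
    "coloc_colocalised",
    "smr_colocalised",
    "credible_set_contained",
    "define_high_confidence",
]

COLOC_RATIO_CUT = 0.8
HEIDI_CUT = 0.05


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (order-preserving).

    Every input must lie in (0, 1]; offenders are reported by index.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    bad = np.flatnonzero(~((p > 0.0) & (p <= 1.0)))
    if bad.size:
        raise ValueError(f"p-values outside (0, 1] at indices {bad.tolist()}")
    return multipletests(p, method="fdr_bh")[1]


def coloc_colocalised(pp3: float, pp4: float) -> bool | None:
    """True iff PP4 / (PP3 + PP4) strictly exceeds 0.8.

    Returns ``None`` (not evaluable, distinct from False) when the
    posteriors are absent or sum to zero.
    """
    if pp3 is None or pp4 is None:
        return None
    if not (math.isfinite(pp3) and math.isfinite(pp4)):
        return None
    if pp3 < 0 or pp4 < 0:
        raise ValueError("posterior probabilities must be non-negative")
    total = pp3 + pp4
    if total == 0.0:
        return None
    return pp4 / total > COLOC_RATIO_CUT


def smr_colocalised(heidi_p: float) -> bool | None:
    """True iff the HEIDI p-value strictly exceeds 0.05; None if absent."""
    if heidi_p is None or not math.isfinite(heidi_p):
        return None
    if not 0.0 < heidi_p <= 1.0:
        raise ValueError("HEIDI p must lie in (0, 1]")
    return heidi_p > HEIDI_CUT


def credible_set_contained(gene: pd.Series | dict,
                           positions: Iterable[tuple[str, int]],
                           window_bp: int = 0) -> bool:
    """True iff every credible-set variant lies within the (flanked) gene.

    ``positions`` is an iterable of ``(chromosome, 1-based position)``; the
    containment interval is ``[start - window_bp, end + window_bp]``
    inclusive on the gene's chromosome.
    """
    positions = list(positions)
    if not positions:
        raise ValueError("credible set must be non-empty")
    chrom = str(gene["chrom"])
    lo = int(gene["start"]) - window_bp
    hi = int(gene["end"]) + window_bp
    return all(str(c) == chrom and lo <= int(p) <= hi for c, p in positions)


def _method_q(twas: pd.DataFrame, separate_molecules: bool) -> pd.Series:
    """BH q-values per method stream (optionally per molecule stream)."""
    q = pd.Series(np.nan, index=twas.index)
    keys = ["method", "molecule"] if separate_molecules else ["method"]
    for _, sub in twas.groupby(keys):
        q.loc[sub.index] = bh_fdr(sub["p"].to_numpy())
    return q


def define_high_confidence(
    twas: pd.DataFrame,
    credible_sets: pd.DataFrame | None,
    annotation: pd.DataFrame,
    fdr_alpha: float = 0.05,
    separate_molecules: bool = False,
    window_bp: int = 0,
) -> pd.DataFrame:
    """Apply the three high-confidence criteria to all genes.

    Parameters
    ----------
    twas
        association records with columns ``gene_id, method, p`` and, where
        available, ``pp3, pp4, heidi_p`` (and ``molecule`` if
        ``separate_molecules``).
    credible_sets
        long-format frame ``locus_id, chrom, pos`` (may be None/empty).
    annotation
        gene annotation ``gene_id, chrom, start, end``.

    Returns one row per gene appearing in ``twas`` or containing a credible
    set, with boolean criterion columns, the combined ``criteria`` string,
    ``high_confidence``, and the per-method minimum q-values.
    """
    twas = twas.reset_index(drop=True)
    q = _method_q(twas, separate_molecules)
    twas = twas.assign(q=q)

    is_fusion = twas["method"].eq("fusion")
    is_smr = twas["method"].eq("smr")
    ratio_ok = pd.Series(False, index=twas.index)
    if "pp3" in twas and "pp4" in twas:
        idx = twas.index[twas["pp3"].notna() & twas["pp4"].notna()]
        total = twas.loc[idx, "pp3"] + twas.loc[idx, "pp4"]
        good = idx[total > 0]
        ratio_ok.loc[good] = (twas.loc[good, "pp4"]
                              / total.loc[good]) > COLOC_RATIO_CUT
    fusion_hit = is_fusion & (twas["q"] <= fdr_alpha) & ratio_ok

    heidi_ok = pd.Series(False, index=twas.index)
    if "heidi_p" in twas:
        heidi_ok = twas["heidi_p"].notna() & (twas["heidi_p"] > HEIDI_CUT)
    smr_hit = is_smr & (twas["q"] <= fdr_alpha) & heidi_ok

    per_gene = pd.DataFrame({
        "fusion_coloc": fusion_hit.groupby(twas["gene_id"]).any(),
        "smr_heidi": smr_hit.groupby(twas["gene_id"]).any(),
        "q_fusion_min": twas.loc[is_fusion].groupby("gene_id")["q"].min(),
        "q_smr_min": twas.loc[is_smr].groupby("gene_id")["q"].min(),
    })

    # fine-mapping containment
    finemap_genes: set[str] = set()
    if credible_sets is not None and len(credible_sets):
        ann = annotation.set_index("gene_id")
        known = set(ann.index)
        missing = sorted(set(twas["gene_id"]) - known)
        if missing:
            logger.warning("%d genes absent from annotation; excluded from "
                           "the fine-mapping criterion: %s",
                           len(missing), missing[:10])
        for locus, sub in credible_sets.groupby("locus_id"):
            positions = list(zip(sub["chrom"].astype(str), sub["pos"]))
            chroms = {c for c, _ in positions}
            if len(chroms) > 1:
                continue
            chrom = chroms.pop()
            lo = min(p for _, p in positions)
            hi = max(p for _, p in positions)
            cand = ann[(ann["chrom"].astype(str) == chrom)
                       & (ann["start"] - window_bp <= lo)
                       & (ann["end"] + window_bp >= hi)]
            finemap_genes.update(cand.index)

    all_genes = sorted(set(per_gene.index) | finemap_genes)
    result = per_gene.reindex(all_genes)
    result[["fusion_coloc", "smr_heidi"]] = \
        result[["fusion_coloc", "smr_heidi"]].fillna(False).astype(bool)
    result["finemap"] = [g in finemap_genes for g in all_genes]
    crits = []
    for _, row in result.iterrows():
        met = [name for name in ("finemap", "fusion_coloc", "smr_heidi")
               if row[name]]
        crits.append(",".join(met))
    result["criteria"] = crits
    result["high_confidence"] = result["criteria"] != ""
    result.index.name = "gene_id"
    return result.reset_index()
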