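"""Calibration and recovery studies on the synthetic study generator.

These routines run the full method (weight-set construction, scoring,
liability-scale association, triage, drug/ATC enrichment, observed DE)
against simulations with known ground truth and summarise:

* **null calibration** — no signal genes, no liability variance explained:
  the best-threshold liability R^2 should be near zero, per-gene DE should
  make essentially no FDR discoveries, and drug/ATC p-values should be
  uniform;
* **parameter recovery** — a planted true score explaining 5 % of
  liability variance should be recovered by the estimated liability R^2 at
  the best threshold, and planted clinical effects should be recovered in
  sign;
* **triage recovery** — planted signal genes should be recalled with high
  sensitivity and low empirical FDR;
* **enrichment recovery** — the planted protective ATC class should be the
  top FDR-significant class.

Study sizes default to 1000 genes and 2000 cases + 2000 controls per
platform over 20 simulation replicates.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import best_rows, default_weight_sets, evaluate_all
from .config import SimConfig
from .diffexp import meta_diffexpr, per_gene_case_control_correlation
from .drugs import atc_enrichment, code_interactions, signed_drug_enrichment
from .scoring import build_weight_set
from .simulate import (simulate_cohorts, simulate_credible_sets,
                       simulate_drug_database, simulate_feature_correlation,
                       simulate_gene_annotation, simulate_twas_sumstats)
from .triage import define_high_confidence

__all__ = [
    "null_calibration_study",
    "recovery_study",
    "triage_recovery_study",
    "enrichment_recovery_study",
]


def _sub_seed(seed: int, i: int) -> int:
    return int((seed * 100_003 + i * 7919 + 17) % (2**31 - 1))


def _truth_weights(truth: pd.DataFrame) -> dict[str, float]:
    sig = truth[truth["is_signal"]]
    return dict(zip(sig["gene_id"], sig["true_z"]))


def null_calibration_study(seed: int, n_seeds: int = 20,
                           n_drugs: int = 1000) -> dict:
    """Fully null simulation: zero signal genes, zero liability variance.

    Returns the mean best-threshold case-control liability R^2, the mean
    number of per-gene DE discoveries at q < 0.05, and KS uniformity
    p-values for the pooled drug-level and ATC-level enrichment p-values.
    """
    best_r2 = []
    de_hits = []
    drug_ps: list[np.ndarray] = []
    atc_ps: list[np.ndarray] = []
    for i in range(n_seeds):
        cfg = SimConfig(n_signal_genes=0, target_liability_r2=0.0,
                        n_drugs=n_drugs, n_enriched_drugs=0,
                        seed=_sub_seed(seed, i))
        annotation = simulate_gene_annotation(cfg)
        twas, truth = simulate_twas_sumstats(cfg, annotation)
        corr = simulate_feature_correlation(cfg, annotation)
        cohorts = simulate_cohorts(cfg, annotation, {})

        weight_sets = default_weight_sets(twas, corr, strata=("all",),
                                          coloc_options=(False,))
        assoc = evaluate_all(cohorts, weight_sets,
                             outcomes=("case_control",))
        best = best_rows(assoc)
        best_r2.append(float(best["r2_liability"].iloc[0]))

        per_platform = [per_gene_case_control_correlation(c)
                        for c in cohorts]
        meta = meta_diffexpr(per_platform)
        de_hits.append(int((meta["q"] < 0.05).sum()))

        interactions = code_interactions(
            simulate_drug_database(cfg, truth)[0])
        gene_z = build_weight_set(twas, corr, threshold=1.0).weights
        drug_res = signed_drug_enrichment(gene_z, interactions)
        atc_res = atc_enrichment(drug_res, interactions[["drug_id", "atc3"]])
        drug_ps.append(drug_res["p"].to_numpy())
        atc_ps.append(atc_res["p"].to_numpy())

    drug_p = np.concatenate(drug_ps)
    atc_p = np.concatenate(atc_ps)
    return {
        "n_seeds": n_seeds,
        "best_liability_r2": best_r2,
        "mean_best_liability_r2": float(np.mean(best_r2)),
        "de_q05_hits": de_hits,
        "mean_de_q05_hits": float(np.mean(de_hits)),
        "drug_p_ks_p": float(stats.kstest(drug_p, "uniform").pvalue),
        "atc_p_ks_p": float(stats.kstest(atc_p, "uniform").pvalue),
        "n_drug_p": int(len(drug_p)),
        "n_atc_p": int(len(atc_p)),
    }


def recovery_study(seed: int, n_seeds: int = 20,
                   target_r2: float = 0.05) -> dict:
    """Planted-signal recovery of liability R^2 and clinical effect signs.

    Simulates cohorts whose true expression score explains ``target_r2``
    of liability variance, scores individuals with weight sets built from
    the simulated TWAS, and reports the best-threshold meta liability R^2
    plus sign agreement of the meta onset-age and survival effects with
    the planted directions.
    """
    r2s, age_sign_ok, surv_sign_ok = [], [], []
    for i in range(n_seeds):
        cfg = SimConfig(target_liability_r2=target_r2,
                        seed=_sub_seed(seed, i))
        annotation = simulate_gene_annotation(cfg)
        twas, truth = simulate_twas_sumstats(cfg, annotation)
        corr = simulate_feature_correlation(cfg, annotation)
        cohorts = simulate_cohorts(cfg, annotation, _truth_weights(truth))
        weight_sets = default_weight_sets(twas, corr, strata=("all",),
                                          coloc_options=(False,))
        assoc = evaluate_all(cohorts, weight_sets)
        best = best_rows(assoc)
        cc = best[best["outcome"] == "case_control"]
        r2s.append(float(cc["r2_liability"].iloc[0]))

        meta = assoc[assoc["platform"] == "meta"]
        # judge clinical signs at the best case-control threshold
        thr = float(cc["threshold"].iloc[0])
        at_thr = meta[meta["threshold"] == thr]
        age = at_thr[at_thr["outcome"] == "onset_age"]
        surv = at_thr[at_thr["outcome"] == "survival"]
        age_sign_ok.append(bool(len(age)) and
                           np.sign(age["beta"].iloc[0])
                           == np.sign(cfg.onset_age_beta))
        surv_sign_ok.append(bool(len(surv)) and
                            np.sign(surv["beta"].iloc[0])
                            == np.sign(cfg.survival_beta))
    return {
        "n_seeds": n_seeds,
        "target_liability_r2": target_r2,
        "liability_r2": r2s,
        "mean_liability_r2": float(np.mean(r2s)),
        "onset_age_sign_rate": float(np.mean(age_sign_ok)),
        "survival_sign_rate": float(np.mean(surv_sign_ok)),
    }


def triage_recovery_study(seed: int, n_seeds: int = 20) -> dict:
    """Sensitivity and empirical FDR of high-confidence triage."""
    sens, fdr = [], []
    for i in range(n_seeds):
        cfg = SimConfig(seed=_sub_seed(seed, i))
        annotation = simulate_gene_annotation(cfg)
        twas, truth = simulate_twas_sumstats(cfg, annotation)
        credsets, _ = simulate_credible_sets(cfg, annotation, truth)
        result = define_high_confidence(twas, credsets, annotation)
        called = set(result.loc[result["high_confidence"], "gene_id"])
        signal = set(truth.loc[truth["is_signal"], "gene_id"])
        tp = len(called & signal)
        sens.append(tp / len(signal))
        fdr.append((len(called) - tp) / len(called) if called else 0.0)
    return {
        "n_seeds": n_seeds,
        "sensitivity": sens,
        "mean_sensitivity": float(np.mean(sens)),
        "empirical_fdr": fdr,
        "mean_empirical_fdr": float(np.mean(fdr)),
    }


def enrichment_recovery_study(seed: int, n_seeds: int = 20) -> dict:
    """How often the planted protective ATC class is the top significant hit."""
    top_hits = []
    for i in range(n_seeds):
        cfg = SimConfig(seed=_sub_seed(seed, i))
        annotation = simulate_gene_annotation(cfg)
        twas, truth = simulate_twas_sumstats(cfg, annotation)
        corr = simulate_feature_correlation(cfg, annotation)
        interactions, drug_truth = simulate_drug_database(cfg, truth)
        interactions = code_interactions(interactions)
        gene_z = build_weight_set(twas, corr, threshold=1.0).weights
        drug_res = signed_drug_enrichment(gene_z, interactions)
        atc_res = atc_enrichment(drug_res, interactions[["drug_id", "atc3"]])
        top = atc_res.iloc[0]
        top_hits.append(bool(top["atc3"] == drug_truth["protective_atc"]
                             and top["q"] <= 0.05))
    return {
        "n_seeds": n_seeds,
        "top_hits": top_hits,
        "top_hit_rate": float(np.mean(top_hits)),
    }
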