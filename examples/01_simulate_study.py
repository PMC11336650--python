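"""Generate a synthetic TWAS-downstream study and inspect its ground truth.

Builds a small two-platform case-control study: gene annotation in 500 kb
correlation blocks, TWAS/SMR summary statistics with 15 planted signal
genes, expression cohorts under a liability-threshold model, and a drug
database with planted protective drugs.
"""
from twaskit import (SimConfig, simulate_cohorts, simulate_drug_database,
                     simulate_gene_annotation, simulate_twas_sumstats)

cfg = SimConfig(n_genes=300, n_signal_genes=15, n_cases=300, n_controls=300,
                target_liability_r2=0.05, seed=42)
annotation = simulate_gene_annotation(cfg)
twas, truth = simulate_twas_sumstats(cfg, annotation)
weights = dict(zip(truth.loc[truth.is_signal, "gene_id"],
                   truth.loc[truth.is_signal, "true_z"]))
cohorts = simulate_cohorts(cfg, annotation, weights)
drugs, drug_truth = simulate_drug_database(cfg, truth)

c = cohorts[0]
print(f"genes: {len(annotation)} on {annotation.chrom.nunique()} chromosomes")
print(f"TWAS records: {len(twas)} "
      f"({twas.panel.nunique()} panels x {twas.method.nunique()} methods)")
print(f"signal genes: {truth.is_signal.sum()}, "
      f"mean |Z| {twas[twas.gene_id.isin(weights)].z.abs().mean():.1f}")
frac = c.meta["n_pool_cases"] / c.meta["n_pool"]
print(f"platform_1: {c.expression.shape[0]} genes x "
      f"{c.expression.shape[1]} samples; pre-ascertainment case fraction "
      f"{frac:.4f} (population prevalence K = {cfg.prevalence_K:.4f})")
print(f"drugs: {drugs.drug_id.nunique()}; planted protective class "
      f"{drug_truth['protective_atc']} with "
      f"{len(drug_truth['enriched_drugs'])} drugs")
# The case fraction in the sampling pool matches K because case status is
# decided by thresholding the latent liability; the cohort itself is
# case-enriched by ascertainment only.
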