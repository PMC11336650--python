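"""Synthetic study generator with known ground truth.

Generates every input the downstream pipeline consumes:

* a gene annotation laid out in correlation blocks that each span less than
  one 500 kb window, with consecutive blocks more than a window apart;
* gene x panel x method TWAS/SMR-style summary statistics in which a known
  subset of signal genes carries large, sign-consistent Z-scores together
  with colocalisation posteriors (PP3/PP4) and HEIDI p-values;
* a block-diagonal predicted-expression correlation matrix over gene-panel
  features;
* case-control expression cohorts drawn under a liability-threshold model:
  an individual's liability is ``c * (sum_g w_g z_ig) + e`` with the scale
  ``c`` chosen so the true weighted-expression score explains a configured
  fraction of liability variance, a case being any individual whose
  (standardized) liability exceeds the prevalence threshold; cases are then
  oversampled to the target cohort size (ascertainment changes sampling
  only, never an individual's phenotype);
* fine-mapping 95 % credible sets (some fully contained in signal genes,
  some decoys spanning two genes);
* a directional drug-gene interaction table with level-3 ATC codes, in
  which a known set of drugs preferentially targets signal genes with a
  protective (risk-opposing) direction, concentrated in one ATC class.

All generators are pure functions of ``(config, seed)``: the same seed
yields byte-identical outputs.  Each stage uses its own deterministic
sub-stream, so adding a stage never perturbs earlier stages' draws.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig
from .scoring import FeatureCorrelation

__all__ = [
    "ExpressionCohort",
    "simulate_gene_annotation",
    "simulate_twas_sumstats",
    "simulate_feature_correlation",
    "simulate_expression_cohort",
    "simulate_cohorts",
    "simulate_credible_sets",
    "simulate_drug_database",
    "NEGATIVE_LABELS",
    "POSITIVE_LABELS",
    "UNDIRECTED_LABEL",
    "ATC3_CODES",
]

# closed drug-interaction label vocabulary
NEGATIVE_LABELS = ("DECREASED_EXPRESSION", "NEGATIVE_RESPONSE",
                   "OPPOSITE_RESPONSE")
POSITIVE_LABELS = ("INCREASED_EXPRESSION", "POSITIVE_RESPONSE")
UNDIRECTED_LABEL = "UNDIRECTED"

#: level-3 ATC (pharmacological subgroup) codes used by the generator; the
#: first is the class the protective planted drugs are concentrated in, the
#: second hosts deleterious planted drugs when configured.
ATC3_CODES = ("C08C", "N03A", "N06A", "N05A", "C07A", "A10B", "J01C",
              "L01X", "M01A", "R03A", "C09A", "B01A", "D07A", "G03B",
              "H02A", "P01B", "S01E", "V03A")

# per-stage sub-stream keys (never renumber: determinism contract)
_KEY_TWAS = 1
_KEY_DRUGS = 4
_KEY_CREDSETS = 5
_KEY_DROPOUT = 29
_KEY_COHORT_BASE = 30


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclasses.dataclass
class ExpressionCohort:
    """Observed expression for one platform plus per-sample phenotypes.

    ``expression`` is genes x samples on a log2-microarray-like scale;
    ``phenotypes`` is indexed by sample id with columns ``case`` (0/1),
    ``sex`` (0/1), and, for cases only, ``onset_site`` (1 = spinal),
    ``onset_age`` and ``survival``.
    """

    platform: str
    expression: pd.DataFrame
    phenotypes: pd.DataFrame
    meta: dict = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def simulate_gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Lay genes on chromosomes in well-separated correlation blocks.

    Each block of ``block_size`` genes spans strictly less than
    ``window_bp``; the gap between consecutive blocks exceeds ``window_bp``,
    so cross-block pairs never fall inside a window.  Layout is a pure
    function of the config (no randomness needed).

    Returns a frame with columns ``gene_id, chrom, start, end, block``
    (1-based inclusive coordinates; ``block`` is generator-internal).
    """
    footprint = max(config.window_bp // (config.block_size + 1), 2)
    gene_len = max(footprint // 2, 1)
    n_blocks = math.ceil(config.n_genes / config.block_size)
    blocks_per_chrom = 50
    block_span = (config.block_size - 1) * footprint + gene_len
    stride = block_span + config.window_bp + gene_len

    rows = []
    for b in range(n_blocks):
        chrom = str(b // blocks_per_chrom + 1)
        block_start = 1 + (b % blocks_per_chrom) * stride
        for i in range(config.block_size):
            g = b * config.block_size + i
            if g >= config.n_genes:
                break
            start = block_start + i * footprint
            rows.append((f"G{g:05d}", chrom, start, start + gene_len - 1, b))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "block"])


# ---------------------------------------------------------------------------
# TWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_twas_sumstats(
    config: SimConfig, annotation: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate gene x panel x method association records plus ground truth.

    Signal genes receive a true Z with magnitude centred at
    ``signal_z_mean`` and a random but panel-consistent sign; panel-level
    records add unit normal noise.  Null genes are standard normal.
    Two-sided p-values are computed exactly from the normal tail of Z.
    Fusion-style records carry coloc posteriors (PP4 skewed high for signal
    genes, low for null genes; PP3 a random fraction of the remaining
    mass); SMR-style records carry HEIDI p-values (uniform for signal
    genes; skewed small for a configured fraction of null genes).

    Returns ``(records, truth)`` where ``truth`` has one row per gene with
    ``is_signal`` and the generative ``true_z``.
    """
    rng = _rng(config.seed, _KEY_TWAS)
    genes = annotation["gene_id"].to_numpy()
    n = len(genes)

    is_signal = np.zeros(n, dtype=bool)
    if config.n_signal_genes:
        idx = rng.choice(n, size=config.n_signal_genes, replace=False)
        is_signal[idx] = True
    magnitude = np.clip(rng.normal(config.signal_z_mean, 1.0, size=n), 0.5,
                        None)
    sign = rng.choice([-1.0, 1.0], size=n)
    true_z = np.where(is_signal, sign * magnitude, 0.0)
    truth = pd.DataFrame({"gene_id": genes, "is_signal": is_signal,
                          "true_z": true_z})

    frames = []
    for method in ("fusion", "smr"):
        for panel, stratum in zip(config.panels, config.panel_strata):
            z = true_z + rng.standard_normal(n)
            if config.panel_sign_agreement < 1.0:
                flip = is_signal & (rng.random(n) >
                                    config.panel_sign_agreement)
                z = np.where(flip, -z, z)
            p = np.clip(2.0 * stats.norm.sf(np.abs(z)),
                        np.nextafter(0.0, 1.0), 1.0)
            if method == "fusion":
                pp4 = np.where(is_signal, rng.beta(20.0, 2.0, size=n),
                               rng.beta(2.0, 20.0, size=n))
                pp3 = rng.random(n) * (1.0 - pp4)
                heidi = np.full(n, np.nan)
            else:
                pp3 = np.full(n, np.nan)
                pp4 = np.full(n, np.nan)
                uniform = rng.random(n)
                small = rng.beta(1.0, 30.0, size=n)
                use_small = (~is_signal) & (rng.random(n) <
                                            config.null_heidi_small_frac)
                heidi = np.clip(np.where(use_small, small, uniform),
                                np.nextafter(0.0, 1.0), 1.0)
            frames.append(pd.DataFrame({
                "gene_id": genes,
                "panel": panel,
                "stratum": stratum,
                "method": method,
                "molecule": "expression",
                "z": z,
                "p": p,
                "pp3": pp3,
                "pp4": pp4,
                "heidi_p": heidi,
                "feature": np.char.add(np.char.add(genes.astype(str), "@"),
                                       panel),
            }))
    records = pd.concat(frames, ignore_index=True)
    return records, truth


# ---------------------------------------------------------------------------
# predicted-expression correlation
# ---------------------------------------------------------------------------

def _block_template(m: int, n_panels: int, within: float,
                    cross: float) -> np.ndarray:
    """Dense correlation template for one block of m genes x P panels."""
    size = m * n_panels
    mat = np.full((size, size), within)
    for g in range(m):
        sl = slice(g * n_panels, (g + 1) * n_panels)
        mat[sl, sl] = cross
    np.fill_diagonal(mat, 1.0)
    return mat


def simulate_feature_correlation(config: SimConfig,
                                 annotation: pd.DataFrame) -> FeatureCorrelation:
    """Block-diagonal feature correlation over gene x panel features.

    Same-gene cross-panel pairs get ``cross_panel_r``; different genes in
    the same block get ``within_block_r``; cross-block pairs are absent.
    The block template must be positive semi-definite (checked by
    eigendecomposition) or a ``ValueError`` is raised.
    """
    template = _block_template(config.block_size, config.n_panels,
                               config.within_block_r, config.cross_panel_r)
    min_eig = float(np.linalg.eigvalsh(template).min())
    if min_eig < -1e-8:
        raise ValueError(
            f"within_block_r={config.within_block_r} / cross_panel_r="
            f"{config.cross_panel_r} break positive semi-definiteness "
            f"(min eigenvalue {min_eig:.3g}) for block size "
            f"{config.block_size}")

    panels = config.panels
    entries: dict[tuple[str, str], float] = {}
    for _, sub in annotation.groupby("block"):
        feats = [f"{g}@{p}" for g in sub["gene_id"] for p in panels]
        gene_of = [g for g in sub["gene_id"] for _ in panels]
        for a in range(len(feats)):
            for b in range(a + 1, len(feats)):
                r = (config.cross_panel_r if gene_of[a] == gene_of[b]
                     else config.within_block_r)
                if r != 0.0:
                    entries[(feats[a], feats[b])] = r
    return FeatureCorrelation(entries, window_bp=config.window_bp)


# ---------------------------------------------------------------------------
# expression cohorts under the liability-threshold model
# ---------------------------------------------------------------------------

def _gene_blocks(config: SimConfig, annotation: pd.DataFrame):
    """Per-block gene index arrays and the Cholesky of the block correlation."""
    chols: dict[int, np.ndarray] = {}
    blocks = []
    pos = {g: i for i, g in enumerate(annotation["gene_id"])}
    for _, sub in annotation.groupby("block"):
        idx = np.array([pos[g] for g in sub["gene_id"]])
        m = len(idx)
        if m not in chols:
            corr = np.full((m, m), config.within_block_r)
            np.fill_diagonal(corr, 1.0)
            chols[m] = np.linalg.cholesky(corr)
        blocks.append((idx, chols[m]))
    return blocks


def _platform_dropout_masks(config: SimConfig) -> list[np.ndarray]:
    """Disjoint per-platform boolean masks of genes to drop."""
    rng = _rng(config.seed, _KEY_DROPOUT)
    perm = rng.permutation(config.n_genes)
    k = int(round(config.platform_dropout * config.n_genes))
    masks = []
    for p in range(config.n_platforms):
        drop = np.zeros(config.n_genes, dtype=bool)
        drop[perm[p * k:(p + 1) * k]] = True
        masks.append(drop)
    return masks


def simulate_expression_cohort(
    config: SimConfig,
    annotation: pd.DataFrame,
    truth_weights: Mapping[str, float],
    platform_index: int = 0,
) -> ExpressionCohort:
    """Draw one platform's case-control cohort under the liability model.

    The per-individual liability is ``c * S + e`` with ``S = sum_g w_g z_ig``
    (the true weighted-expression score), ``e`` standard normal, and ``c``
    solving ``c^2 Var(S) / (c^2 Var(S) + 1) = target_liability_r2``.  An
    individual is a case when the standardized liability exceeds
    ``Phi^-1(1 - K)``, so the pre-ascertainment case fraction is exactly K.
    Cases are oversampled from the population until ``n_cases`` accrue.

    Sampling uses exact Gaussian conditioning: the scalar pair ``(S, e)``
    is drawn for the whole rejection pool, and the full gene expression
    vector is drawn only for accepted individuals, conditional on their
    score.  This is distributionally identical to drawing expression first
    and is what makes small-prevalence ascertainment cheap.
    """
    if platform_index >= config.n_platforms:
        raise ValueError("platform_index out of range")
    rng = _rng(config.seed, _KEY_COHORT_BASE + platform_index)
    genes = annotation["gene_id"].to_numpy()
    n_genes = len(genes)
    pos = {g: i for i, g in enumerate(genes)}

    w = np.zeros(n_genes)
    for g, v in truth_weights.items():
        if g not in pos:
            raise ValueError(f"truth weight for unknown gene {g}")
        w[pos[g]] = v

    blocks = _gene_blocks(config, annotation)
    sigma_w = np.zeros(n_genes)
    for idx, chol in blocks:
        corr = chol @ chol.T
        sigma_w[idx] = corr @ w[idx]
    var_s = float(w @ sigma_w)

    r2 = config.target_liability_r2
    if r2 > 0.0 and var_s == 0.0:
        raise ValueError("target_liability_r2 > 0 requires non-empty "
                         "truth weights")
    c = math.sqrt(r2 / ((1.0 - r2) * var_s)) if (r2 > 0.0 and var_s > 0.0) \
        else 0.0
    sd_liab = math.sqrt(c * c * var_s + 1.0)
    threshold = stats.norm.ppf(1.0 - config.prevalence_K)

    # rejection pool on (S, e) scalars only
    s_cases, s_controls = [], []
    n_pool = 0
    n_pool_cases = 0
    got_cases = got_controls = 0
    chunk = 20_000
    sd_s = math.sqrt(var_s) if var_s > 0 else 0.0
    while got_cases < config.n_cases or got_controls < config.n_controls:
        s = rng.normal(0.0, sd_s, size=chunk) if sd_s > 0 else np.zeros(chunk)
        e = rng.standard_normal(chunk)
        case = (c * s + e) / sd_liab > threshold
        n_pool += chunk
        n_pool_cases += int(case.sum())
        if got_cases < config.n_cases:
            take = s[case][:config.n_cases - got_cases]
            s_cases.append(take)
            got_cases += len(take)
        if got_controls < config.n_controls:
            take = s[~case][:config.n_controls - got_controls]
            s_controls.append(take)
            got_controls += len(take)
    s_all = np.concatenate(s_cases + s_controls)
    status = np.r_[np.ones(config.n_cases, dtype=int),
                   np.zeros(config.n_controls, dtype=int)]
    n_total = len(s_all)

    # expression conditional on the accepted scores
    z0 = np.empty((n_total, n_genes))
    for idx, chol in blocks:
        z0[:, idx] = rng.standard_normal((n_total, len(idx))) @ chol.T
    if c > 0.0:
        adjust = (s_all - z0 @ w) / var_s
        z = z0 + adjust[:, None] * sigma_w[None, :]
    else:
        z = z0

    # phenotypes
    sex = rng.integers(0, 2, size=n_total)
    s_std = s_all / sd_s if sd_s > 0 else np.zeros(n_total)
    onset_site = np.full(n_total, np.nan)
    onset_age = np.full(n_total, np.nan)
    survival = np.full(n_total, np.nan)
    n_cases = config.n_cases
    latent = (config.onset_site_beta * s_std[:n_cases]
              + rng.standard_normal(n_cases))
    onset_site[:n_cases] = (latent > 0).astype(float)
    onset_age[:n_cases] = (config.onset_age_mean
                           + config.onset_age_beta * s_std[:n_cases]
                           + rng.normal(0.0, config.onset_age_sd, n_cases))
    survival[:n_cases] = np.clip(
        config.survival_mean + config.survival_beta * s_std[:n_cases]
        + rng.normal(0.0, config.survival_sd, n_cases), 0.5, None)

    # platform scale: per-gene baseline plus a small global shift
    platform = f"platform_{platform_index + 1}"
    baseline = rng.normal(8.0, 1.0, size=n_genes) \
        + config.platform_shift * platform_index
    observed = (z + baseline[None, :]).T  # genes x samples

    drop = _platform_dropout_masks(config)[platform_index]
    keep = ~drop
    sample_ids = [f"{platform}_S{i:05d}" for i in range(n_total)]
    expression = pd.DataFrame(observed[keep], index=genes[keep],
                              columns=sample_ids)
    phenotypes = pd.DataFrame({
        "case": status, "sex": sex, "onset_site": onset_site,
        "onset_age": onset_age, "survival": survival,
    }, index=pd.Index(sample_ids, name="sample_id"))
    meta = {"n_pool": n_pool, "n_pool_cases": n_pool_cases, "c": c,
            "var_score": var_s, "true_score": s_all,
            "survival_units": config.survival_units}
    return ExpressionCohort(platform, expression, phenotypes, meta)


def simulate_cohorts(config: SimConfig, annotation: pd.DataFrame,
                     truth_weights: Mapping[str, float]) -> list[ExpressionCohort]:
    """One :class:`ExpressionCohort` per platform."""
    return [simulate_expression_cohort(config, annotation, truth_weights, p)
            for p in range(config.n_platforms)]


# ---------------------------------------------------------------------------
# fine-mapping credible sets
# ---------------------------------------------------------------------------

def simulate_credible_sets(
    config: SimConfig, annotation: pd.DataFrame, truth: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate 95 % credible sets as variant position lists per locus.

    ``n_credible_sets`` loci place all variants inside the body of a signal
    gene (so the gene satisfies the containment criterion);
    ``n_decoy_credible_sets`` loci spread variants over two genes of one
    block and are contained in no gene.

    Returns a long-format frame ``locus_id, chrom, pos`` and the list of
    genes that truly contain a credible set.
    """
    rng = _rng(config.seed, _KEY_CREDSETS)
    ann = annotation.set_index("gene_id")
    signal = truth.loc[truth["is_signal"], "gene_id"].to_numpy()
    n_contained = min(config.n_credible_sets, len(signal))
    chosen = rng.choice(signal, size=n_contained, replace=False) \
        if n_contained else np.array([], dtype=object)

    rows = []
    contained_genes = []
    for i, g in enumerate(chosen):
        row = ann.loc[g]
        k = int(rng.integers(2, 5))
        pos = rng.integers(int(row["start"]), int(row["end"]) + 1, size=k)
        for p in pos:
            rows.append((f"locus_{i:03d}", str(row["chrom"]), int(p)))
        contained_genes.append(str(g))

    multi_blocks = annotation.groupby("block").filter(lambda s: len(s) >= 2)
    block_ids = multi_blocks["block"].unique()
    for j in range(config.n_decoy_credible_sets):
        if len(block_ids) == 0:
            break
        b = block_ids[int(rng.integers(0, len(block_ids)))]
        sub = annotation[annotation["block"] == b]
        pick = sub.sample(2, random_state=int(rng.integers(0, 2**31)))
        locus = f"decoy_{j:03d}"
        for _, row in pick.iterrows():
            p = int(rng.integers(int(row["start"]), int(row["end"]) + 1))
            rows.append((locus, str(row["chrom"]), p))
    credsets = pd.DataFrame(rows, columns=["locus_id", "chrom", "pos"])
    return credsets, contained_genes


# ---------------------------------------------------------------------------
# drug-gene interaction database
# ---------------------------------------------------------------------------

def simulate_drug_database(
    config: SimConfig, truth: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a directional drug-gene interaction table with ATC codes.

    Null drugs target random genes with random directions.  Planted
    "protective" drugs preferentially target signal genes with the
    direction opposing the gene's risk direction (drug decreases
    risk-increasing expression and vice versa) and share one ATC class;
    planted deleterious drugs (if configured) are anti-aligned and share a
    second class.

    Returns ``(interactions, drug_truth)``; ``interactions`` has columns
    ``drug_id, gene_id, label, atc3`` with labels from the closed
    five-label vocabulary plus UNDIRECTED.
    """
    rng = _rng(config.seed, _KEY_DRUGS)
    genes = truth["gene_id"].to_numpy()
    signal = truth.loc[truth["is_signal"]]
    signal_genes = signal["gene_id"].to_numpy()
    sign_of = dict(zip(signal["gene_id"], np.sign(signal["true_z"])))

    n_planted = config.n_enriched_drugs + config.n_deleterious_drugs
    if n_planted > config.n_drugs:
        raise ValueError("more planted drugs than n_drugs")

    def label_for(code: int) -> str:
        if code < 0:
            return NEGATIVE_LABELS[int(rng.integers(0, len(NEGATIVE_LABELS)))]
        if code > 0:
            return POSITIVE_LABELS[int(rng.integers(0, len(POSITIVE_LABELS)))]
        return UNDIRECTED_LABEL

    rows = []
    enriched, deleterious = [], []
    for d in range(config.n_drugs):
        drug = f"DRUG{d:04d}"
        k = max(2, int(rng.poisson(config.genes_per_drug_mean)))
        if d < config.n_enriched_drugs:
            kind = "protective"
            enriched.append(drug)
            atc = ATC3_CODES[0]
        elif d < n_planted:
            kind = "deleterious"
            deleterious.append(drug)
            atc = ATC3_CODES[1]
        else:
            kind = "null"
            atc = ATC3_CODES[int(rng.integers(0, len(ATC3_CODES)))]

        if kind == "null" or len(signal_genes) == 0:
            chosen = rng.choice(genes, size=min(k, len(genes)),
                                replace=False)
            codes = rng.choice([-1, 1, 0], size=len(chosen),
                               p=[0.4, 0.4, 0.2])
        else:
            n_sig = min(max(2, int(round(0.8 * k))), len(signal_genes))
            sig_pick = rng.choice(signal_genes, size=n_sig, replace=False)
            others = np.setdiff1d(genes, sig_pick, assume_unique=False)
            n_other = min(max(k - n_sig, 0), len(others))
            other_pick = rng.choice(others, size=n_other, replace=False)
            chosen = np.concatenate([sig_pick, other_pick])
            align = -1 if kind == "protective" else 1
            codes = np.concatenate([
                np.array([align * int(sign_of[g]) for g in sig_pick]),
                rng.choice([-1, 1, 0], size=n_other, p=[0.4, 0.4, 0.2]),
            ])
        for g, code in zip(chosen, codes):
            rows.append((drug, str(g), label_for(int(code)), atc))

    interactions = pd.DataFrame(rows, columns=["drug_id", "gene_id",
                                               "label", "atc3"])
    drug_truth = {
        "enriched_drugs": enriched,
        "deleterious_drugs": deleterious,
        "protective_atc": ATC3_CODES[0],
        "deleterious_atc": ATC3_CODES[1] if deleterious else None,
    }
    return interactions, drug_truth
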