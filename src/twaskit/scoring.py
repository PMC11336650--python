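"""Polytranscriptomic score (PTS) construction and scoring.

A PTS is the transcriptomic analogue of a polygenic score: for individual
*i*, ``PTS_i = sum_g w_g * z_ig`` where ``z_ig`` is the individual's
standardized observed expression of gene *g* and ``w_g`` is the TWAS
association Z-score of that gene (averaged across panels).  Because nearby
genes have correlated predicted expression, TWAS associations are first
pruned by greedy clumping on a predicted-expression correlation matrix
(within 500 kb windows, removing features with r^2 above a threshold
against a more significant lead), then filtered by a p-value threshold.
Weight sets can be stratified by tissue (blood/brain) and restricted to
colocalised associations (PP4 above a cut-off).
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureCorrelation",
    "WeightSet",
    "PtsVector",
    "correlation_from_predicted_expression",
    "clump",
    "build_weight_set",
    "standardize_expression",
    "compute_pts",
    "DEFAULT_THRESHOLD_GRID",
]

#: p-value threshold grid used when building weight sets across "a range of
#: p-value thresholds"; overridable everywhere it is consumed.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = (
    1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0,
)


class FeatureCorrelation:
    """Sparse symmetric Pearson correlation between gene-panel features.

    Only pairs whose genes lie within ``window_bp`` of each other are
    stored; absent pairs are treated as r = 0 (independent by construction).
    Self-correlation is implicitly 1.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float],
                 window_bp: int = 500_000):
        store: dict[tuple[str, str], float] = {}
        for (a, b), r in entries.items():
            if a == b:
                continue
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation out of [-1, 1] for ({a}, {b})")
            key = (a, b) if a < b else (b, a)
            prev = store.get(key)
            if prev is not None and prev != r:
                raise ValueError(f"conflicting entries for pair {key}")
            store[key] = r
        self._entries = store
        self.window_bp = int(window_bp)
        self._index: dict[str, list[tuple[str, float]]] | None = None

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, i: str, j: str) -> float:
        if i == j:
            return 1.0
        key = (i, j) if i < j else (j, i)
        return self._entries.get(key, 0.0)

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), r in self._entries.items():
            yield a, b, r

    def neighbors(self, feature: str) -> list[tuple[str, float]]:
        if self._index is None:
            index: dict[str, list[tuple[str, float]]] = {}
            for (a, b), r in self._entries.items():
                index.setdefault(a, []).append((b, r))
                index.setdefault(b, []).append((a, r))
            self._index = index
        return self._index.get(feature, [])

    # -- long-format round trip ------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r) for (a, b), r in sorted(self._entries.items())]
        return pd.DataFrame(rows, columns=["feature_i", "feature_j", "r"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   window_bp: int = 500_000) -> "FeatureCorrelation":
        entries = {(a, b): float(r) for a, b, r in
                   df[["feature_i", "feature_j", "r"]].itertuples(index=False)}
        return cls(entries, window_bp=window_bp)


@dataclasses.dataclass(frozen=True)
class WeightSet:
    """Post-clump, post-threshold gene -> averaged TWAS Z weight map."""

    weights: dict[str, float]
    threshold: float
    stratum: str = "all"
    coloc_only: bool = False
    n_features_pre_clump: int = 0

    def __post_init__(self) -> None:
        for g, w in self.weights.items():
            if not np.isfinite(w) or w == 0.0:
                raise ValueError(f"weight for {g} must be finite and non-zero")

    @property
    def n_genes(self) -> int:
        return len(self.weights)

    @property
    def label(self) -> str:
        tag = "coloc" if self.coloc_only else "any"
        return f"{self.stratum}|{tag}|p<={self.threshold:g}"


@dataclasses.dataclass(frozen=True)
class PtsVector:
    """Per-sample polytranscriptomic scores for one weight set."""

    scores: pd.Series
    weight_set: WeightSet
    n_genes_used: int

    def __post_init__(self) -> None:
        if self.n_genes_used > self.weight_set.n_genes:
            raise ValueError("n_genes_used cannot exceed weight set size")


def _interval_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Gap between the closest edges of two intervals (0 if overlapping)."""
    if e1 < s2:
        return s2 - e1
    if e2 < s1:
        return s1 - e2
    return 0


def correlation_from_predicted_expression(
    pred_expr: pd.DataFrame,
    annotation: pd.DataFrame,
    window_bp: int = 500_000,
    feature_genes: Mapping[str, str] | None = None,
) -> FeatureCorrelation:
    """Pearson correlation of predicted expression between nearby features.

    Parameters
    ----------
    pred_expr
        features x reference-individuals matrix (rows indexed by feature id).
    annotation
        gene annotation with columns ``gene_id, chrom, start, end``.
    window_bp
        maximum gap between gene interval edges for a pair to be stored.
    feature_genes
        optional feature -> gene map; by default feature ids of the form
        ``gene@panel`` are parsed.
    """
    if pred_expr.shape[1] < 3:
        raise ValueError("need at least 3 reference individuals")
    if feature_genes is None:
        feature_genes = {f: str(f).split("@", 1)[0] for f in pred_expr.index}

    values = pred_expr.to_numpy(dtype=float)
    sds = values.std(axis=1, ddof=1)
    keep = sds > 0
    if not keep.any():
        warnings.warn("all features constant; empty correlation")
        return FeatureCorrelation({}, window_bp=window_bp)
    if (~keep).any():
        dropped = list(pred_expr.index[~keep])
        warnings.warn(f"dropping {len(dropped)} zero-variance features")
    feats = list(pred_expr.index[keep])
    values = values[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / sds[keep][:, None]
    n_ref = values.shape[1]

    ann = annotation.set_index("gene_id")
    coords = []
    for f in feats:
        g = feature_genes[f]
        row = ann.loc[g]
        coords.append((str(row["chrom"]), int(row["start"]), int(row["end"])))

    entries: dict[tuple[str, str], float] = {}
    order = sorted(range(len(feats)), key=lambda i: (coords[i][0], coords[i][1]))
    for a_pos, ia in enumerate(order):
        ca, sa, ea = coords[ia]
        for ib in order[a_pos + 1:]:
            cb, sb, eb = coords[ib]
            if cb != ca:
                break
            if sb - ea > window_bp:
                # sorted by start: every later feature is at least this far
                break
            if _interval_gap(sa, ea, sb, eb) <= window_bp:
                r = float(z[ia] @ z[ib]) / (n_ref - 1)
                entries[(feats[ia], feats[ib])] = r
    return FeatureCorrelation(entries, window_bp=window_bp)


def clump(records: pd.DataFrame, corr: FeatureCorrelation,
          r2_threshold: float = 0.1) -> list[str]:
    """Greedy correlation clumping of TWAS features.

    Sort by p ascending (ties broken lexicographically on feature id); take
    the next unremoved feature as lead and remove all unremoved features
    with r^2 strictly above ``r2_threshold`` against it; repeat.  Missing
    correlation entries are treated as r = 0.

    Returns the retained (lead) feature ids in selection order.
    """
    if "feature" not in records.columns or "p" not in records.columns:
        raise ValueError("records must have 'feature' and 'p' columns")
    ordered = records.sort_values(["p", "feature"], kind="mergesort")
    present = set(ordered["feature"])
    if len(present) != len(ordered):
        raise ValueError("duplicate feature ids in clump input")
    removed: set[str] = set()
    retained: list[str] = []
    for f in ordered["feature"]:
        if f in removed:
            continue
        retained.append(f)
        for other, r in corr.neighbors(f):
            if other in present and other not in removed and r * r > r2_threshold:
                removed.add(other)
    return retained


def build_weight_set(
    records: pd.DataFrame,
    corr: FeatureCorrelation,
    threshold: float,
    stratum: str = "all",
    coloc_only: bool = False,
    pp4_cut: float = 0.8,
    r2_threshold: float = 0.1,
    methods: Iterable[str] | None = ("fusion",),
) -> WeightSet:
    """Build a PTS weight set: filter, threshold, clump, average Z per gene.

    ``methods`` restricts the record stream (default keeps fusion-style
    records so each gene@panel feature appears once); pass ``None`` to keep
    all records, in which case duplicate features keep their smallest-p row.
    """
    df = records.copy()
    if methods is not None and "method" in df.columns:
        df = df[df["method"].isin(set(methods))]
    if stratum != "all":
        df = df[df["stratum"] == stratum]
    if coloc_only:
        df = df[df["pp4"].notna() & (df["pp4"] > pp4_cut)]
    df = df[df["p"] <= threshold]
    # one row per feature (smallest p wins) so clumping sees unique features
    df = (df.sort_values(["p", "feature"], kind="mergesort")
            .drop_duplicates("feature", keep="first"))
    n_pre = len(df)
    if n_pre == 0:
        warnings.warn(f"empty weight set (stratum={stratum}, "
                      f"coloc_only={coloc_only}, threshold={threshold:g})")
        return WeightSet({}, threshold, stratum, coloc_only, 0)
    kept = clump(df, corr, r2_threshold=r2_threshold)
    sub = df.set_index("feature").loc[kept]
    weights = sub.groupby("gene_id")["z"].mean()
    weights = weights[weights != 0.0]
    return WeightSet(dict(weights), threshold, stratum, coloc_only, n_pre)


def standardize_expression(expression: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene row across all samples (sample SD, ddof = 1).

    Zero-variance genes are dropped with a warning; a single-sample matrix
    is rejected.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardize")
    values = expression.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes")
        logger.info("standardize_expression dropped genes: %s",
                    list(expression.index[~keep])[:10])
    z = (values[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=expression.index[keep],
                        columns=expression.columns)


def compute_pts(z_expr: pd.DataFrame, weight_set: WeightSet) -> PtsVector:
    """Score individuals: ``score_i = sum_g w_g * z_ig`` over measured genes.

    Genes in the weight set absent from the expression matrix are skipped
    (no imputation); the number of genes actually used is recorded.
    """
    common = [g for g in weight_set.weights if g in z_expr.index]
    if weight_set.n_genes and not common:
        warnings.warn("no weight-set genes measured; all scores are 0")
    if not common:
        scores = pd.Series(0.0, index=z_expr.columns)
        return PtsVector(scores, weight_set, 0)
    w = np.array([weight_set.weights[g] for g in common])
    scores = pd.Series(z_expr.loc[common].to_numpy(dtype=float).T @ w,
                       index=z_expr.columns)
    return PtsVector(scores, weight_set, len(common))
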