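"""Signature scoring and group comparison.

Implements single-sample rank-weighted enrichment (ssGSEA), marker-mean
abundance scores, rank-based stromal/immune/combined scores, ANOVA/Wilcoxon
group comparison of signature scores, and one-vs-rest differential
expression with the |log2fc| and raw-p threshold rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25
DEFAULT_LFC_CUT = float(np.log2(1.2))
DEFAULT_P_CUT = 0.05


@dataclass
class SignatureScoreMatrix:
    scores: pd.DataFrame  # signatures x samples
    method: str

    def __post_init__(self) -> None:
        if self.method not in {"ssgsea", "marker_mean", "estimate_like"}:
            raise ValueError(f"unknown method tag {self.method!r}")
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("signature scores must be finite")


def _ssgsea_sample(order_hit: np.ndarray, weights: np.ndarray) -> float:
    """Barbie-style score for one sample: sum over ranking positions of the
    difference between the weighted hit ECDF and the miss ECDF."""
    n = len(order_hit)
    m = int(order_hit.sum())
    hit_w = weights * order_hit
    p_hit = np.cumsum(hit_w) / hit_w.sum()
    p_miss = np.cumsum(~order_hit) / (n - m)
    return float(np.sum(p_hit - p_miss))


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> SignatureScoreMatrix:
    """Per-sample rank-weighted enrichment score for each signature.

    Genes are ranked per sample by descending expression (average ranks for
    ties) and hit increments are weighted by ``rank**alpha``.  With
    ``normalize=True`` scores are min-max scaled to [0, 1] across samples per
    signature; the unnormalized variant is rank-invariant per sample.
    """
    df = expr.values
    genes = np.array(df.index)
    # top-expressed gene gets the largest rank (= n) and hence the largest weight
    ranks = df.rank(axis=0, method="average").to_numpy()

    rows: dict[str, np.ndarray] = {}
    for name in sets.names():
        members = sets[name]
        hit_genes = np.isin(genes, list(members))
        if hit_genes.sum() < 2:
            logger.warning("signature %r shares < 2 genes with the matrix; skipped", name)
            continue
        scores = np.empty(df.shape[1])
        for j in range(df.shape[1]):
            order = np.argsort(-ranks[:, j], kind="stable")
            ordered_hit = hit_genes[order]
            weights = ranks[order, j] ** alpha
            scores[j] = _ssgsea_sample(ordered_hit, weights)
        rows[name] = scores
    if not rows:
        raise ValueError("no signature overlapped the expression matrix")
    mat = pd.DataFrame(rows, index=df.columns).T
    if normalize:
        rng_ = mat.max(axis=1) - mat.min(axis=1)
        rng_ = rng_.replace(0.0, 1.0)
        mat = mat.sub(mat.min(axis=1), axis=0).div(rng_, axis=0)
    return SignatureScoreMatrix(mat, "ssgsea")


def marker_mean_score(expr: ExpressionMatrix, sets: GeneSetCollection) -> SignatureScoreMatrix:
    """Mean log2 expression of each signature's genes per sample."""
    df = expr.values
    rows: dict[str, np.ndarray] = {}
    for name in sets.names():
        members = [g for g in sets[name] if g in df.index]
        if len(members) < 1:
            logger.warning("signature %r shares no genes with the matrix; skipped", name)
            continue
        rows[name] = df.loc[sorted(members)].mean(axis=0).to_numpy()
    if not rows:
        raise ValueError("no signature overlapped the expression matrix")
    return SignatureScoreMatrix(pd.DataFrame(rows, index=df.columns).T, "marker_mean")


def estimate_like_scores(
    expr: ExpressionMatrix, stromal_set: frozenset[str] | set[str], immune_set: frozenset[str] | set[str]
) -> pd.DataFrame:
    """Rank-based stromal/immune/combined scores (samples x 3).

    These are unnormalized single-sample enrichment analogues, not the
    published trained purity transform.
    """
    sets = GeneSetCollection({"stromal": frozenset(stromal_set), "immune": frozenset(immune_set)})
    overlap = {
        name: len(sets[name] & set(expr.gene_ids)) for name in ("stromal", "immune")
    }
    for name, k in overlap.items():
        if k < 2:
            raise ValueError(f"{name} set shares < 2 genes with the matrix")
    ss = ssgsea_score(expr, sets, normalize=False).scores
    out = pd.DataFrame(
        {
            "stromal": ss.loc["stromal"],
            "immune": ss.loc["immune"],
        }
    )
    out["combined"] = out["stromal"] + out["immune"]
    return out


def compare_groups(scores: SignatureScoreMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-signature group comparison: one-way ANOVA for >= 3 groups,
    two-sided Wilcoxon rank-sum for 2 groups."""
    labels = labels.loc[[s for s in scores.scores.columns if s in labels.index]]
    groups = sorted(labels.unique(), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    rows = []
    for name in scores.scores.index:
        vals = scores.scores.loc[name, labels.index]
        parts = [vals[labels == g].to_numpy(dtype=float) for g in groups]
        if len(groups) == 2:
            stat, p = stats.ranksums(parts[0], parts[1])
            test = "wilcoxon"
        else:
            stat, p = stats.f_oneway(*parts)
            test = "anova"
        row = {"signature": name, "test": test, "statistic": float(stat), "pvalue": float(p)}
        for g, part in zip(groups, parts):
            row[f"mean_{g}"] = float(part.mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("signature")


def one_vs_rest_deg(
    expr: ExpressionMatrix,
    labels: pd.Series,
    group,
    lfc_cut: float = DEFAULT_LFC_CUT,
    p_cut: float = DEFAULT_P_CUT,
) -> pd.DataFrame:
    """Welch-t one-vs-rest differential expression on log2 values.

    A gene is flagged DEG when ``|log2fc| > lfc_cut`` and raw ``p < p_cut``.
    Returns columns gene, log2fc, pvalue, fdr, direction, deg.
    """
    labels = labels.loc[[s for s in expr.sample_ids if s in labels.index]]
    in_group = labels.index[labels == group]
    rest = labels.index[labels != group]
    if len(in_group) < 3 or len(rest) < 3:
        raise ValueError("group and rest must each contain >= 3 samples")
    A = expr.values[list(in_group)].to_numpy()
    B = expr.values[list(rest)].to_numpy()
    keep = ~((A.std(axis=1) == 0) & (B.std(axis=1) == 0))
    if (~keep).any():
        logger.warning("excluded %d constant genes from DEG testing", int((~keep).sum()))
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    A, B = A[keep], B[keep]
    lfc = A.mean(axis=1) - B.mean(axis=1)
    _, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    fdr = stats.false_discovery_control(p, method="bh")
    table = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": lfc,
            "pvalue": p,
            "fdr": fdr,
            "direction": np.sign(lfc).astype(int),
            "deg": (np.abs(lfc) > lfc_cut) & (p < p_cut),
        }
    )
    return table.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
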