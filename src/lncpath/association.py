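"""Purity-adjusted lncRNA-mRNA association ranking.

For a given lncRNA, every mRNA is scored by the first-order partial
correlation with the lncRNA controlling for tumor purity, its two-sided
normal-approximation p-value, and a signed rank index
``ri = -ln(p) * sign(pcc)``; mRNAs are then ordered by descending ri.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import BIOTYPE_LNCRNA, ExpressionMatrix, PurityVector

logger = logging.getLogger(__name__)

_MIN_P = np.nextafter(0.0, 1.0)


class DegenerateCorrelationError(ValueError):
    """Correlation undefined (zero variance) or adjustment degenerate."""


@dataclass
class AssociationRanking:
    """Per-lncRNA association table, sorted by descending rank index.

    ``entries`` has columns mrna, pcc, pvalue, ri; ties in ri are broken by
    lexicographic mrna id for determinism.
    """

    lncrna_id: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mrna", "pcc", "pvalue", "ri"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"entries must have columns {sorted(required)}")
        ri = self.entries["ri"].to_numpy()
        if np.any(np.diff(ri) > 1e-12):
            raise ValueError("entries must be sorted by descending ri")
        self.entries = self.entries.reset_index(drop=True)

    @property
    def mrna_ids(self) -> list[str]:
        return list(self.entries["mrna"])

    @property
    def ri(self) -> np.ndarray:
        return self.entries["ri"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise DegenerateCorrelationError("zero variance vector in correlation")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def partial_correlation(lnc: np.ndarray, mrna: np.ndarray, purity: np.ndarray) -> float:
    """First-order partial correlation of ``lnc`` and ``mrna`` given purity.

    Computed as ``(Rlm - Rlp*Rmp) / sqrt((1 - Rlp^2)(1 - Rmp^2))`` from the
    three pairwise Pearson coefficients.
    """
    lnc = np.asarray(lnc, dtype=float)
    mrna = np.asarray(mrna, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if not len(lnc) == len(mrna) == len(purity):
        raise ValueError("vectors must be aligned on the same samples")
    if len(lnc) < 5:
        raise ValueError("need at least 5 samples")
    r_lm = _pearson(lnc, mrna)
    r_lp = _pearson(lnc, purity)
    r_mp = _pearson(mrna, purity)
    denom2 = (1.0 - r_lp**2) * (1.0 - r_mp**2)
    if denom2 <= 0:
        raise DegenerateCorrelationError(
            "a vector is perfectly correlated with purity; adjustment degenerate"
        )
    return float(np.clip((r_lm - r_lp * r_mp) / np.sqrt(denom2), -1.0, 1.0))


def association_pvalue(pcc: float | np.ndarray, n: int) -> float | np.ndarray:
    """Two-sided p-value for a first-order partial correlation.

    Fisher z with one adjusting covariate: ``z = atanh(pcc) * sqrt(n - 4)``,
    ``p = 2 * Phi(-|z|)``.  ``|pcc| = 1`` returns the smallest positive float
    with a warning.
    """
    if n < 5:
        raise ValueError("need n >= 5")
    pcc_arr = np.asarray(pcc, dtype=float)
    if np.any(np.abs(pcc_arr) > 1):
        raise ValueError("pcc must lie in [-1, 1]")
    saturated = np.abs(pcc_arr) == 1.0
    if np.any(saturated):
        logger.warning("|pcc| = 1: p-value floored at the smallest positive float")
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.where(saturated, 0.0, pcc_arr)) * np.sqrt(n - 4)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(saturated, _MIN_P, np.maximum(p, _MIN_P))
    p = np.minimum(p, 1.0)
    return float(p) if np.isscalar(pcc) or pcc_arr.ndim == 0 else p


def rank_index(pvalue: float | np.ndarray, pcc: float | np.ndarray) -> float | np.ndarray:
    """Signed rank index ``-ln(p) * sign(pcc)`` (0 when pcc is 0)."""
    p_arr = np.asarray(pvalue, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("pvalue must lie in (0, 1]")
    ri = -np.log(p_arr) * np.sign(np.asarray(pcc, dtype=float))
    return float(ri) if ri.ndim == 0 else ri


def rank_mrnas(
    lncrna_id: str, expr: ExpressionMatrix, purity: PurityVector
) -> AssociationRanking:
    """Rank every mRNA against one lncRNA by descending rank index.

    Zero-variance mRNAs are excluded with a logged count; ties are broken by
    lexicographic mrna id.
    """
    if expr.biotype.get(lncrna_id) != BIOTYPE_LNCRNA:
        raise ValueError(f"{lncrna_id!r} is not annotated as a lncRNA")
    mrna_ids = expr.mrna_ids
    if not mrna_ids:
        raise ValueError("no mRNAs in expression matrix")
    samples = expr.sample_ids
    p = purity.data.loc[samples].to_numpy(dtype=float)
    y = expr.values.loc[lncrna_id, samples].to_numpy(dtype=float)
    X = expr.values.loc[mrna_ids, samples].to_numpy(dtype=float)
    n = len(samples)
    if n < 5:
        raise ValueError("need at least 5 samples")

    if y.std() == 0:
        raise DegenerateCorrelationError(f"lncRNA {lncrna_id!r} has zero variance")
    if p.std() == 0:
        raise DegenerateCorrelationError("purity has zero variance")

    sd = X.std(axis=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluded %d zero-variance mRNAs from ranking", n_dropped)
    X = X[keep]
    mrna_ids = [m for m, k in zip(mrna_ids, keep) if k]
    if not mrna_ids:
        raise ValueError("all mRNAs have zero variance")

    pcc = _partial_correlation_vector(y, X, p)
    pvalue = association_pvalue(pcc, n)
    ri = rank_index(pvalue, pcc)
    table = pd.DataFrame({"mrna": mrna_ids, "pcc": pcc, "pvalue": pvalue, "ri": ri})
    table = table.sort_values(
        ["ri", "mrna"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return AssociationRanking(lncrna_id, table)


def _partial_correlation_vector(y: np.ndarray, X: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorized first-order partial correlation of y against each row of X."""
    yc = y - y.mean()
    pc = p - p.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    y_norm = np.sqrt(yc @ yc)
    p_norm = np.sqrt(pc @ pc)
    x_norm = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    r_lm = np.clip((Xc @ yc) / (x_norm * y_norm), -1.0, 1.0)
    r_lp = float(np.clip((yc @ pc) / (y_norm * p_norm), -1.0, 1.0))
    r_mp = np.clip((Xc @ pc) / (x_norm * p_norm), -1.0, 1.0)
    if abs(r_lp) == 1.0:
        raise DegenerateCorrelationError("lncRNA perfectly correlated with purity")
    denom2 = (1.0 - r_lp**2) * (1.0 - r_mp**2)
    sat = denom2 <= 0
    if np.any(sat):
        logger.warning(
            "%d mRNAs perfectly correlated with purity; partial correlation set to 0",
            int(sat.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        pcc = (r_lm - r_lp * r_mp) / np.sqrt(denom2)
    pcc = np.where(sat, 0.0, pcc)
    return np.clip(pcc, -1.0, 1.0)


def rank_all(
    expr: ExpressionMatrix, purity: PurityVector, lncrna_ids: list[str] | None = None
) -> dict[str, AssociationRanking]:
    """Compute a ranking for every (or each requested) lncRNA."""
    ids = lncrna_ids if lncrna_ids is not None else expr.lncrna_ids
    return {lnc: rank_mrnas(lnc, expr, purity) for lnc in ids}


def rankings_to_frame(rankings: dict[str, AssociationRanking]) -> pd.DataFrame:
    """Long-format table (lncrna, mrna, pcc, pvalue, ri) for the CLI output."""
    parts = []
    for lnc, ranking in rankings.items():
        part = ranking.entries.copy()
        part.insert(0, "lncrna", lnc)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def frame_to_rankings(frame: pd.DataFrame) -> dict[str, AssociationRanking]:
    """Inverse of :func:`rankings_to_frame`."""
    out: dict[str, AssociationRanking] = {}
    for lnc, part in frame.groupby("lncrna", sort=False):
        entries = part[["mrna", "pcc", "pvalue", "ri"]].reset_index(drop=True)
        out[str(lnc)] = AssociationRanking(str(lnc), entries)
    return out
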