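"""Synthetic cohort generator.

Produces an expression matrix with a tumor-purity confounder, a block of
lncRNAs whose purity-adjusted correlation is concentrated in a designated
pathway gene set, latent sample subtypes with shifted marker lncRNAs, and
survival times drawn from a Cox model on a handful of the planted lncRNAs.
Deterministic given the seed; ground truth is recorded for recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .io_core import (
    BIOTYPE_LNCRNA,
    BIOTYPE_MRNA,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    PurityVector,
    write_clinical,
    write_expression,
    write_gmt,
    write_purity,
)

logger = logging.getLogger(__name__)

PATHWAY_SET_NAME = "PATHWAY"
IMMUNE_SET_NAME = "IMMUNE"
MARKERS_PER_SUBTYPE = 5
BASELINE_SHIFT = 8.0  # shifts all genes to a nonnegative log2 scale


class CalibrationError(ValueError):
    """The requested association strength is unreachable at this noise level."""


@dataclass
class SimulationConfig:
    n_samples: int = 200
    n_mrna: int = 1000
    n_lncrna: int = 120
    pathway_size: int = 60
    n_true_lnc: int = 10
    assoc_strength: float = 0.6
    purity_load: float = 0.5
    n_subtypes: int = 3
    subtype_shift: float = 1.5
    n_risk_lnc: int = 6
    cox_betas: tuple[float, ...] = (1.2, -1.2, 1.0, -1.0, 0.8, 0.8)
    censor_rate: float = 0.3
    noise_sd: float = 0.8
    seed: int = 0
    immune_size: int = 50

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_mrna, self.n_lncrna, self.pathway_size) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_true_lnc > self.n_lncrna:
            raise ValueError("n_true_lnc exceeds n_lncrna")
        if self.pathway_size > self.n_mrna:
            raise ValueError("pathway_size exceeds n_mrna")
        if not 0 < self.assoc_strength < 1:
            raise ValueError("assoc_strength must be in (0, 1)")
        if not 0 <= self.purity_load < 1:
            raise ValueError("purity_load must be in [0, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_risk_lnc > self.n_true_lnc:
            raise ValueError("n_risk_lnc exceeds n_true_lnc (risk lncRNAs are planted ones)")
        if len(self.cox_betas) != self.n_risk_lnc:
            raise ValueError("cox_betas length must equal n_risk_lnc")
        needed = self.n_true_lnc + MARKERS_PER_SUBTYPE * self.n_subtypes
        if needed > self.n_lncrna:
            raise ValueError(
                f"n_lncrna={self.n_lncrna} too small for {self.n_true_lnc} associated "
                f"plus {MARKERS_PER_SUBTYPE * self.n_subtypes} marker lncRNAs"
            )


@dataclass
class GroundTruth:
    true_assoc_lnc: list[str]
    subtype_labels: dict[str, int]
    subtype_markers: dict[int, list[str]]
    risk_lnc: list[str]
    cox_betas: dict[str, float]
    purity: dict[str, float]
    pathway_genes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_assoc_lnc": self.true_assoc_lnc,
                "subtype_labels": self.subtype_labels,
                "subtype_markers": {str(k): v for k, v in self.subtype_markers.items()},
                "risk_lnc": self.risk_lnc,
                "cox_betas": self.cox_betas,
                "purity": self.purity,
                "pathway_genes": self.pathway_genes,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            true_assoc_lnc=obj["true_assoc_lnc"],
            subtype_labels={k: int(v) for k, v in obj["subtype_labels"].items()},
            subtype_markers={int(k): v for k, v in obj["subtype_markers"].items()},
            risk_lnc=obj["risk_lnc"],
            cox_betas=obj["cox_betas"],
            purity=obj["purity"],
            pathway_genes=obj.get("pathway_genes", []),
        )


def _calibrate_loading(assoc_strength: float, noise_sd: float) -> float:
    """Solve for the pathway-activity loading v of a planted lncRNA.

    After the purity term is partialled out, a planted lncRNA residual is
    v*a + eps and a pathway mRNA residual is w*a + eps with w ~ U(0.5, 1), so
    the expected adjusted correlation with the pathway is
    E_w[ v*w / sqrt((v^2 + s^2)(w^2 + s^2)) ].  The target must lie below the
    v -> inf limit E_w[w / sqrt(w^2 + s^2)].
    """
    s2 = noise_sd**2
    w = np.linspace(0.5, 1.0, 2001)

    def expected_corr(v: float) -> float:
        return float(np.trapezoid(v * w / np.sqrt((v**2 + s2) * (w**2 + s2)), w) / 0.5)

    limit = float(np.trapezoid(w / np.sqrt(w**2 + s2), w) / 0.5)
    if assoc_strength >= 0.995 * limit:
        raise CalibrationError(
            f"assoc_strength={assoc_strength} unreachable: the maximum expected "
            f"purity-adjusted correlation at noise_sd={noise_sd} is {limit:.3f}; "
            "lower assoc_strength or noise_sd"
        )
    return float(
        optimize.brentq(lambda v: expected_corr(v) - assoc_strength, 1e-9, 1e6)
    )


def _calibrate_censoring(rate: float, hazards: np.ndarray) -> float:
    """Censoring-exponential rate c with E[fraction censored] = rate.

    With independent Exponential event (rate h) and censoring (rate c) times,
    P(censored) = c / (c + h).
    """
    if rate <= 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards)))

    hi = float(hazards.max()) * 1e4 + 1.0
    return float(optimize.brentq(lambda c: frac(c) - rate, 1e-300, hi))


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, PurityVector, ClinicalTable, GeneSetCollection, GroundTruth]:
    """Generate one cohort; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sigma = cfg.noise_sd

    samples = [f"S{i + 1:04d}" for i in range(n)]
    mrnas = [f"M{i + 1:05d}" for i in range(cfg.n_mrna)]
    lncs = [f"L{i + 1:04d}" for i in range(cfg.n_lncrna)]

    purity = rng.beta(5.0, 2.0, size=n)
    z = (purity - purity.mean()) / purity.std(ddof=0)
    activity = rng.standard_normal(n)

    # mRNAs: pathway genes load the latent activity, the rest are pure noise
    # (plus the shared purity term).
    w = rng.uniform(0.5, 1.0, size=cfg.pathway_size)
    mrna_vals = cfg.purity_load * z[None, :] + rng.normal(0.0, sigma, size=(cfg.n_mrna, n))
    mrna_vals[: cfg.pathway_size] += w[:, None] * activity[None, :]

    # lncRNAs: the first n_true_lnc share the activity with calibrated loading.
    v = _calibrate_loading(cfg.assoc_strength, sigma)
    lnc_vals = cfg.purity_load * z[None, :] + rng.normal(0.0, sigma, size=(cfg.n_lncrna, n))
    lnc_vals[: cfg.n_true_lnc] += v * activity[None, :]

    # Subtypes: as-equal-as-possible sizes, assignment shuffled by the rng;
    # marker lncRNAs are disjoint from the planted associated block.
    base = np.repeat(np.arange(1, cfg.n_subtypes + 1), int(np.ceil(n / cfg.n_subtypes)))[:n]
    subtype = base[rng.permutation(n)]
    marker_start = cfg.n_true_lnc
    subtype_markers: dict[int, list[str]] = {}
    for c in range(1, cfg.n_subtypes + 1):
        rows = slice(
            marker_start + (c - 1) * MARKERS_PER_SUBTYPE,
            marker_start + c * MARKERS_PER_SUBTYPE,
        )
        subtype_markers[c] = lncs[rows]
        lnc_vals[rows, subtype == c] += cfg.subtype_shift

    # Survival from a Cox model on the first n_risk_lnc planted lncRNAs,
    # evaluated on the centered (pre-shift) expression values.
    risk_lnc = lncs[: cfg.n_risk_lnc]
    betas = np.asarray(cfg.cox_betas, dtype=float)
    lin_pred = betas @ lnc_vals[: cfg.n_risk_lnc]
    h0 = np.log(2.0) / 1500.0  # baseline median ~1500 days
    hazards = h0 * np.exp(lin_pred)
    event_t = rng.exponential(1.0 / hazards)
    c_rate = _calibrate_censoring(cfg.censor_rate, hazards)
    if c_rate > 0:
        censor_t = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_t = np.full(n, np.inf)
    os_time = np.minimum(event_t, censor_t)
    os_status = (event_t <= censor_t).astype(int)
    os_time = np.maximum(os_time, 1e-3)

    values = np.vstack([mrna_vals, lnc_vals]) + BASELINE_SHIFT
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=mrnas + lncs, columns=samples),
        pd.Series(
            [BIOTYPE_MRNA] * cfg.n_mrna + [BIOTYPE_LNCRNA] * cfg.n_lncrna,
            index=mrnas + lncs,
        ),
    )
    purity_vec = PurityVector(pd.Series(purity, index=samples))
    clin = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_status": os_status,
                "subtype": subtype,
            },
            index=pd.Index(samples, name="sample"),
        )
    )
    sets = {PATHWAY_SET_NAME: frozenset(mrnas[: cfg.pathway_size])}
    if cfg.immune_size > 0 and cfg.pathway_size + cfg.immune_size <= cfg.n_mrna:
        sets[IMMUNE_SET_NAME] = frozenset(
            mrnas[cfg.pathway_size : cfg.pathway_size + cfg.immune_size]
        )
    gene_sets = GeneSetCollection(sets)
    truth = GroundTruth(
        true_assoc_lnc=lncs[: cfg.n_true_lnc],
        subtype_labels={s: int(c) for s, c in zip(samples, subtype)},
        subtype_markers=subtype_markers,
        risk_lnc=risk_lnc,
        cox_betas={g: float(b) for g, b in zip(risk_lnc, betas)},
        purity={s: float(p) for s, p in zip(samples, purity)},
        pathway_genes=mrnas[: cfg.pathway_size],
    )
    return expr, purity_vec, clin, gene_sets, truth


COHORT_FILES = {
    "expression": "expression.tsv",
    "biotype": "biotype.tsv",
    "purity": "purity.tsv",
    "clinical": "clinical.tsv",
    "gene_sets": "gene_sets.gmt",
    "ground_truth": "ground_truth.json",
}


def write_cohort(
    expr: ExpressionMatrix,
    purity: PurityVector,
    clinical: ClinicalTable,
    gene_sets: GeneSetCollection,
    truth: GroundTruth,
    outdir: str | Path,
    force: bool = False,
) -> dict[str, Path]:
    """Emit the cohort artifacts into ``outdir``; refuses to overwrite unless
    ``force`` is set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {key: outdir / name for key, name in COHORT_FILES.items()}
    if not force:
        existing = [p.name for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {existing} in {outdir}; pass force=True / --force"
            )
    write_expression(expr, paths["expression"], paths["biotype"])
    write_purity(purity, paths["purity"])
    write_clinical(clinical, paths["clinical"])
    write_gmt(gene_sets, paths["gene_sets"])
    paths["ground_truth"].write_text(truth.to_json())
    logger.info("wrote cohort to %s", outdir)
    return paths
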