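"""Validated domain containers shared by every pipeline stage."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIOTYPE_LNCRNA = "lncRNA"
BIOTYPE_MRNA = "mRNA"
BIOTYPE_OTHER = "other"
_KNOWN_BIOTYPES = {BIOTYPE_LNCRNA, BIOTYPE_MRNA, BIOTYPE_OTHER}


class SchemaError(ValueError):
    """Input violates the expected table schema."""


class ParseError(ValueError):
    """Input file could not be parsed."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes x samples, with a biotype label per gene.

    ``values`` is a genes-by-samples DataFrame; ``biotype`` maps every gene id
    to one of ``lncRNA``, ``mRNA`` or ``other``.  Genes labeled ``other`` are
    carried but excluded from analysis.
    """

    values: pd.DataFrame
    biotype: pd.Series

    def __post_init__(self) -> None:
        if self.values.size == 0:
            raise SchemaError("expression matrix is empty")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups[:5]}")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise SchemaError("expression values must be numeric")
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise SchemaError(
                f"non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        # biotype must cover every gene; unknown labels collapse to "other"
        bio = self.biotype.reindex(self.values.index)
        n_missing = int(bio.isna().sum())
        if n_missing:
            logger.warning("%d genes missing from biotype map; labeled 'other'", n_missing)
        bio = bio.fillna(BIOTYPE_OTHER)
        unknown = ~bio.isin(_KNOWN_BIOTYPES)
        if unknown.any():
            logger.warning(
                "%d genes with unrecognized biotype labels; labeled 'other'",
                int(unknown.sum()),
            )
            bio[unknown] = BIOTYPE_OTHER
        bio.index.name = None
        bio.name = "biotype"
        self.biotype = bio
        self.values.index.name = None
        self.values.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def lncrna_ids(self) -> list[str]:
        return list(self.biotype.index[self.biotype == BIOTYPE_LNCRNA])

    @property
    def mrna_ids(self) -> list[str]:
        return list(self.biotype.index[self.biotype == BIOTYPE_MRNA])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[gene_ids].copy(), self.biotype.loc[gene_ids].copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[sample_ids].copy(), self.biotype.copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (each a frozenset of gene ids)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, genes in self.sets.items():
            genes = frozenset(genes)
            if not genes:
                raise SchemaError(f"gene set {name!r} is empty")
            clean[name] = genes
        self.sets = clean

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus optional covariates.

    ``data`` is indexed by sample id and contains at least ``os_time``
    (positive, days by default) and ``os_status`` (0 censored / 1 event).
    """

    data: pd.DataFrame

    REQUIRED = ("os_time", "os_status")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise SchemaError(f"clinical table missing required column {col!r}")
        if self.data.index.duplicated().any():
            raise SchemaError("duplicate sample ids in clinical table")
        times = self.data["os_time"].to_numpy(dtype=float)
        if np.any(~np.isfinite(times)) or np.any(times <= 0):
            raise SchemaError("os_time must be finite and > 0")
        status = self.data["os_status"].to_numpy()
        if not np.isin(status, [0, 1]).all():
            bad = sorted(set(status) - {0, 1})
            raise SchemaError(f"os_status must be 0 or 1; found {bad}")
        self.data = self.data.assign(
            os_time=times, os_status=status.astype(int)
        )
        self.data.index.name = "sample"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def os_time(self) -> pd.Series:
        return self.data["os_time"]

    @property
    def os_status(self) -> pd.Series:
        return self.data["os_status"]

    @property
    def n_events(self) -> int:
        return int(self.data["os_status"].sum())

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class PurityVector:
    """Tumor purity in [0, 1], one value per sample."""

    data: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise SchemaError("duplicate sample ids in purity vector")
        vals = self.data.to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals > 1):
            raise SchemaError("purity values must be finite and in [0, 1]")
        self.data = pd.Series(vals, index=self.data.index, name="purity")
        self.data.index.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids: Iterable[str]) -> "PurityVector":
        return PurityVector(self.data.loc[list(sample_ids)].copy())


def intersect_samples(
    expr: ExpressionMatrix,
    clinical: ClinicalTable | None = None,
    purity: PurityVector | None = None,
) -> list[str]:
    """Ordered intersection of sample ids across the supplied inputs.

    Order follows the expression matrix so that every downstream stage sees
    the same sample ordering.
    """
    keep = set(expr.sample_ids)
    if clinical is not None:
        keep &= set(clinical.sample_ids)
    if purity is not None:
        keep &= set(purity.sample_ids)
    common = [s for s in expr.sample_ids if s in keep]
    logger.info("sample intersection: %d of %d expression samples", len(common), expr.n_samples)
    if not common:
        raise SchemaError("no samples shared across inputs")
    return common
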