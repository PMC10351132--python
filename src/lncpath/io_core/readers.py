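"""Readers for the plain-text exchange formats (expression TSV, GMT, clinical
TSV, purity TSV)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BIOTYPE_OTHER,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    ParseError,
    PurityVector,
    SchemaError,
)

logger = logging.getLogger(__name__)


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("float_precision", "round_trip")
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc


def read_expression(path: str | Path, biotype_path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV plus a two-column gene->biotype TSV.

    Duplicate gene rows are resolved by keeping the row with the highest mean
    expression (logged).  Genes absent from the biotype map are labeled
    ``other``.
    """
    df = _read_tsv(path, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy().argmax()]
            raise ParseError(f"{path}: missing value at gene {row!r}, sample {col!r}")
        df[col] = converted.astype(float)

    if df.index.duplicated().any():
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        deduped = df.iloc[order]
        dropped = int(deduped.index.duplicated().sum())
        deduped = deduped[~deduped.index.duplicated(keep="first")]
        df = deduped.loc[[g for g in dict.fromkeys(df.index) ]]
        logger.warning("dropped %d duplicate gene rows (kept highest-mean row)", dropped)

    bio_df = _read_tsv(biotype_path, dtype=str)
    for col in ("gene_id", "biotype"):
        if col not in bio_df.columns:
            raise SchemaError(f"{biotype_path}: missing required column {col!r}")
    bio = pd.Series(
        bio_df["biotype"].to_numpy(), index=bio_df["gene_id"].to_numpy(), name="biotype"
    )
    bio = bio[~bio.index.duplicated(keep="first")]
    return ExpressionMatrix(df, bio.reindex(df.index).fillna(BIOTYPE_OTHER))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a standard GMT file: name, description, genes... per line."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            if len(set(genes)) < len(genes):
                logger.warning("%s:%d: duplicate genes within set %r deduplicated", path, lineno, name)
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(genes)
    return GeneSetCollection(sets)


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with required columns sample, os_time, os_status.

    Rows missing os_time or os_status are dropped with a logged count; any
    other value problems raise :class:`SchemaError`.
    """
    df = _read_tsv(path)
    for col in ("sample", "os_time", "os_status"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    n0 = len(df)
    df = df.dropna(subset=["os_time", "os_status"])
    if len(df) < n0:
        logger.warning("dropped %d clinical rows with missing os_time/os_status", n0 - len(df))
    df = df.set_index(df["sample"].astype(str)).drop(columns="sample")
    df.index.name = "sample"
    return ClinicalTable(df)


def read_purity(path: str | Path) -> PurityVector:
    """Read a two-column TSV (sample, purity)."""
    df = _read_tsv(path)
    for col in ("sample", "purity"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    ser = pd.Series(
        df["purity"].to_numpy(dtype=float), index=df["sample"].astype(str).to_numpy()
    )
    return PurityVector(ser)
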