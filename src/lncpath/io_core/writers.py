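"""Writers mirroring the readers; write->read round trips are identity."""

from __future__ import annotations

from pathlib import Path

from .types import ClinicalTable, ExpressionMatrix, GeneSetCollection, PurityVector


def write_expression(expr: ExpressionMatrix, path: str | Path, biotype_path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    bio = expr.biotype.rename("biotype").rename_axis("gene_id").reset_index()
    bio.to_csv(biotype_path, sep="\t", index=False)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets.names():
            genes = sorted(sets[name])
            fh.write("\t".join([name, "na", *genes]) + "\n")


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.data.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def write_purity(purity: PurityVector, path: str | Path) -> None:
    df = purity.data.rename("purity").rename_axis("sample").reset_index()
    df.to_csv(path, sep="\t", index=False)
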