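"""Readers and writers for the pipeline's external table formats.

All files are tab-separated UTF-8 with '.' as the decimal mark — there is no
dialect sniffing. Readers validate on load and raise :class:`FormatError` for
structural problems and :class:`ValidationError` for out-of-range values;
nothing is silently coerced. ``write_* / read_*`` pairs round-trip their
domain objects field-for-field.

Formats
-------
* expression matrix: genes x samples TSV, first column ``gene``
* mutation table: MAF-like TSV, one row per (patient, locus, variant);
  population-frequency columns are prefixed ``freq_``
* repertoire: AIRR-like TSV with ``sample_id``, ``junction_aa``,
  ``duplicate_count``
* gene sets: standard GMT (name, description, genes, tab-separated)
* affinity table: mutation/peptide/HLA rows with mutant and wild-type
  predicted affinities in nM
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .types import (
    Consequence,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    MutationRecord,
    RepertoireTable,
    ValidationError,
)

MUTATION_COLUMNS = (
    "patient_id",
    "locus_id",
    "gene",
    "protein_change",
    "consequence",
    "vaf",
    "coverage",
    "ploidy",
)

AFFINITY_COLUMNS = (
    "patient_id",
    "locus_id",
    "gene",
    "protein_change",
    "peptide",
    "hla_allele",
    "mutant_nM",
    "wildtype_nM",
)


def read_expression_matrix(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a genes x samples TPM matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.name is None or df.shape[1] == 0:
        raise FormatError(f"{path}: expected a header row of sample ids and a gene column")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    df.index.name = "gene"
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    out = matrix.df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT gene-set file; the description field is discarded."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene "
                    f"(found {len(fields)} fields)"
                )
            name, _desc, *genes = fields
            genes = [g for g in (g.strip() for g in genes) if g]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_mutation_table(path: str | os.PathLike) -> list[MutationRecord]:
    """Read a MAF-like somatic mutation TSV into validated records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    freq_cols = [c for c in df.columns if c.startswith("freq_")]
    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        pop_freqs = {}
        for col in freq_cols:
            raw = row[col]
            # a blank frequency means the variant is absent from that database
            if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw) == "":
                continue
            pop_freqs[col[len("freq_"):]] = float(raw)
        rec = MutationRecord(
            patient_id=str(row["patient_id"]),
            locus_id=str(row["locus_id"]),
            gene=str(row["gene"]),
            protein_change=str(row["protein_change"]),
            consequence=Consequence.parse(str(row["consequence"])),
            vaf=float(row["vaf"]),
            coverage=int(row["coverage"]),
            pop_freqs=pop_freqs,
            ploidy=float(row["ploidy"]),
        )
        ident = (rec.patient_id, rec.locus_id, rec.gene, rec.protein_change)
        if ident in seen:
            raise ValidationError(f"{path}: duplicate mutation row {ident}")
        seen.add(ident)
        records.append(rec)
    return records


def write_mutation_table(records: Sequence[MutationRecord], path: str | os.PathLike) -> None:
    freq_dbs = sorted({db for r in records for db in r.pop_freqs})
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "locus_id": r.locus_id,
            "gene": r.gene,
            "protein_change": r.protein_change,
            "consequence": r.consequence.value,
            "vaf": repr(float(r.vaf)),
            "coverage": r.coverage,
            "ploidy": repr(float(r.ploidy)),
        }
        for db in freq_dbs:
            row[f"freq_{db}"] = repr(float(r.pop_freqs[db])) if db in r.pop_freqs else ""
        rows.append(row)
    cols = list(MUTATION_COLUMNS) + [f"freq_{db}" for db in freq_dbs]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_repertoire(path: str | os.PathLike) -> RepertoireTable:
    """Read an AIRR-like clonotype count TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "junction_aa": str})
    return RepertoireTable(df)


def write_repertoire(table: RepertoireTable, path: str | os.PathLike) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_affinity_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read predicted mutant/wild-type peptide-HLA affinities (nM)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in AFFINITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    df["mutant_nM"] = df["mutant_nM"].astype(float)
    df["wildtype_nM"] = df["wildtype_nM"].astype(float)
    if (df["mutant_nM"] <= 0).any() or (df["wildtype_nM"] <= 0).any():
        raise ValidationError(f"{path}: affinities must be positive nM values")
    return df.loc[:, list(AFFINITY_COLUMNS)]


def write_affinity_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.loc[:, list(AFFINITY_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_gene_panel(path: str | os.PathLike) -> list[str]:
    """Read a YAML file holding a flat list of gene symbols."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list) or not all(isinstance(g, str) for g in data):
        raise FormatError(f"{path}: expected a YAML list of gene symbols")
    return [g.strip() for g in data]


def write_gene_panel(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(list(genes), fh, default_flow_style=False)
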