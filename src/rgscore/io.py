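"""Readers and writers for the plain-TSV interchange formats.

Counts: first column gene id, remaining columns sample ids.
Sample sheet: sample_id, patient_id, tissue (tumor|normal).
Clinical: patient_id plus the six characteristic columns, empty = missing.
Annotation: gene, aliases (';'-joined), n_isoforms, n_pseudogenes
[, mutation_count]; GO terms either as a simple gene -> ';'-joined term
names TSV or as GAF 2.x with an accompanying term-name table.
Corpus: id, title, abstract.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .annotations import GeneAnnotation

__all__ = [
    "read_counts", "read_samples", "read_clinical", "read_mutations",
    "read_annotations", "read_go_terms", "read_go_gaf", "read_corpus",
]

CLINICAL_COLUMNS = (
    "pathologic_t", "pathologic_n", "pathologic_m", "pathologic_stage",
    "neoplasm_cancer_status", "treatment_success",
)


class InputFormatError(ValueError):
    """A malformed input table, with the offending line where known."""


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                           na_values=[""], **kw)
    except pd.errors.ParserError as exc:
        raise InputFormatError(f"{path}: {exc}") from exc


def read_counts(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    df.index.name = "gene"
    try:
        out = df.astype(float)
    except ValueError as exc:
        raise InputFormatError(f"{path}: non-numeric count value ({exc})") from exc
    if (out < 0).any().any():
        raise InputFormatError(f"{path}: negative counts")
    return out


def read_samples(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"sample_id", "patient_id", "tissue"}
    if not required <= set(df.columns):
        raise InputFormatError(f"{path}: sample sheet needs columns {sorted(required)}")
    df = df.set_index("sample_id")
    for lineno, (sid, tissue) in enumerate(df["tissue"].items(), start=2):
        if tissue not in ("tumor", "normal"):
            raise InputFormatError(
                f"{path}:{lineno}: sample {sid!r} has tissue {tissue!r}"
            )
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "patient_id" not in df.columns:
        raise InputFormatError(f"{path}: clinical table needs a patient_id column")
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing clinical columns {sorted(missing)}")
    return df.set_index("patient_id")


def read_mutations(path: str | Path) -> pd.Series:
    df = _read_tsv(path)
    gene_col, count_col = df.columns[0], df.columns[1]
    s = pd.Series(df[count_col].astype(float).to_numpy(),
                  index=df[gene_col], name="mutation_count")
    s.index.name = "gene"
    return s


def read_go_terms(path: str | Path) -> dict[str, list[str]]:
    """Simple layout: columns gene, go_terms (';'-joined term names)."""
    df = _read_tsv(path)
    gene_col, term_col = df.columns[0], df.columns[1]
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        raw = row[term_col]
        terms = [] if pd.isna(raw) else [t.strip() for t in str(raw).split(";") if t.strip()]
        out[str(row[gene_col])] = terms
    return out


def read_go_gaf(gaf_path: str | Path, term_names_path: str | Path) -> dict[str, list[str]]:
    """GAF 2.x annotations resolved to term names via a GO id -> name TSV."""
    names = {}
    with open(term_names_path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) >= 2 and row[0].startswith("GO:"):
                names[row[0]] = row[1]
    out: dict[str, list[str]] = {}
    with open(gaf_path) as fh:
        for line in fh:
            if line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                continue
            symbol, go_id = cols[2], cols[4]
            name = names.get(go_id)
            if name:
                out.setdefault(symbol, [])
                if name not in out[symbol]:
                    out[symbol].append(name)
    return out


def read_annotations(
    path: str | Path,
    go_terms: dict[str, list[str]] | None = None,
) -> dict[str, GeneAnnotation]:
    df = _read_tsv(path)
    if "gene" not in df.columns:
        raise InputFormatError(f"{path}: annotation table needs a gene column")
    go_terms = go_terms or {}
    out: dict[str, GeneAnnotation] = {}
    for _, row in df.iterrows():
        gene = str(row["gene"])
        aliases = (
            [a.strip() for a in str(row["aliases"]).split(";") if a.strip()]
            if "aliases" in df.columns and not pd.isna(row.get("aliases"))
            else [gene]
        )
        out[gene] = GeneAnnotation(
            gene=gene,
            aliases=aliases,
            n_isoforms=int(float(row.get("n_isoforms", 1) or 1)),
            n_pseudogenes=int(float(row.get("n_pseudogenes", 0) or 0)),
            mutation_count=int(float(row.get("mutation_count", 0) or 0)),
            go_terms=go_terms.get(gene, []),
        )
    return out


def read_corpus(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("title", "abstract"):
        if col not in df.columns:
            raise InputFormatError(f"{path}: corpus needs a {col!r} column")
    return df
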