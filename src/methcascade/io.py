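"""Readers and writers for the plain-text formats the pipeline touches.

FASTA for promoters (via Biopython), tab-separated text for all tables,
BED6 for island intervals, YAML for configuration and JSON for the run
manifest.  Readers validate eagerly (duplicate keys, ragged rows,
non-numeric cells) and name the offending gene or line; writers preserve
column order so that write(read(x)) round-trips byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cgiscan import CpGIsland, PromoterRecord


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_promoters_fasta(promoters: Iterable[PromoterRecord], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.gene_id, description="") for p in promoters
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoters_fasta(path) -> list[PromoterRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate gene_id in FASTA: {rec.id}")
        seen.add(rec.id)
        records.append(PromoterRecord(gene_id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise DataError(f"no FASTA records found in {path}")
    return records


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_matrix_tsv(path, index_col: str = "gene_id") -> pd.DataFrame:
    """Numeric matrix keyed by gene_id (e.g. an expression table)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate {index_col} rows in {path}: {dups[:5]}")
    if df.empty:
        df.index.name = index_col
        return df.astype(float)
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ].tolist()
    if non_numeric:
        raise DataError(f"non-numeric cells in columns {non_numeric} of {path}")
    df.index.name = index_col
    return df


def read_design_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "arm", "stage", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"design table {path} missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"duplicate sample_id in design: {dup[:5]}")
    bad_arm = set(df["arm"]) - {"control", "disease"}
    if bad_arm:
        raise DataError(f"unknown arm labels in design: {sorted(bad_arm)}")
    return df.set_index("sample_id")


def read_long_tsv(path, value_columns: Sequence[str]) -> pd.DataFrame:
    """Long assay table (gene_id, sample_id, <values...>), validated."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "sample_id", *value_columns}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"table {path} missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["gene_id", "sample_id"])
    if dup.any():
        first = df.loc[dup, ["gene_id", "sample_id"]].iloc[0].tolist()
        raise DataError(f"duplicate (gene, sample) record in {path}: {first}")
    if df.empty:
        return df.astype({c: float for c in value_columns})
    for col in value_columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.loc[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise DataError(
                f"non-numeric values in column {col!r} of {path} "
                f"(first bad row: line {int(bad[0]) + 2})"
            )
    return df


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_islands_bed(islands_by_gene: dict[str, Sequence[CpGIsland]], path) -> None:
    """BED6: chrom = gene id (promoter-local coordinates), score = 1000*obs/exp."""
    with open(path, "w") as fh:
        for gene, islands in islands_by_gene.items():
            for isl in islands:
                score = min(1000, int(round(1000 * isl.obs_exp_ratio)))
                fh.write(f"{gene}\t{isl.start}\t{isl.end}\t{gene}\t{score}\t+\n")


def read_islands_bed(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer interval") from exc
            out.setdefault(fields[0], []).append((start, end))
    return out


# ---------------------------------------------------------------------------
# JSON manifest
# ---------------------------------------------------------------------------

def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
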