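"""Readers and writers for the plain-text formats the pipeline exchanges.

Intermediate files are the contract between stages, so real upstream
outputs (an assembler's FASTA, RSEM isoform tables, an external DE table)
can be dropped in without code changes.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scanner import GuideSpec, TargetSite, Transcriptome

logger = logging.getLogger(__name__)

WT_LABEL = "WT"
EDITED_LABEL = "edited"

SITE_COLUMNS = ["query", "contig_id", "start", "site_sequence", "strand", "mm_count"]


def read_fasta(path: str | Path) -> Transcriptome:
    contigs = tuple(
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    )
    return Transcriptome(contigs)


def write_fasta(contigs: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs]
    SeqIO.write(records, str(path), "fasta")


def sites_to_frame(sites: Iterable[TargetSite], guide: GuideSpec) -> pd.DataFrame:
    query = guide.protospacer + guide.pam_pattern
    rows = [
        (query, s.contig_id, s.start, s.site_sequence, s.strand, s.mm_count)
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_sites(
    sites: Iterable[TargetSite] | pd.DataFrame,
    guide: GuideSpec | None,
    path: str | Path,
    header: bool = False,
) -> None:
    """Write sites as a tab-delimited Cas-OFFinder-style table (no header
    by default)."""
    if not isinstance(sites, pd.DataFrame):
        if guide is None:
            raise ValueError("guide required when writing TargetSite objects")
        sites = sites_to_frame(sites, guide)
    sites.to_csv(path, sep="\t", index=False, header=header)


def read_sites(path: str | Path, header: bool = False) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=0 if header else None,
        names=None if header else SITE_COLUMNS,
    )
    df.columns = SITE_COLUMNS
    return df


def read_sample_manifest(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, group) with group in {WT, edited}."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("sample manifest needs two columns: sample_id, group")
    if set(df.iloc[0].astype(str)) >= {"sample_id", "group"}:
        df = df.iloc[1:]
    groups: dict[str, str] = {}
    for sample, group in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        if group not in (WT_LABEL, EDITED_LABEL):
            raise ValueError(
                f"sample {sample!r}: group must be {WT_LABEL!r} or {EDITED_LABEL!r}, got {group!r}"
            )
        groups[sample] = group
    return groups


def read_expression_csv(path: str | Path) -> pd.DataFrame:
    """Transcripts-by-samples matrix CSV; first column is transcript_id."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_rsem_isoforms(paths: Mapping[str, str | Path]) -> pd.DataFrame:
    """Assemble a TPM matrix from per-sample RSEM 'isoforms.results' tables.

    ``paths`` maps sample_id -> file; each file is a TSV whose header
    includes ``transcript_id`` and ``TPM``.
    """
    columns = {}
    for sample, path in paths.items():
        tab = pd.read_csv(path, sep="\t")
        if "transcript_id" not in tab.columns or "TPM" not in tab.columns:
            raise ValueError(f"{path}: expected 'transcript_id' and 'TPM' columns")
        columns[sample] = tab.set_index("transcript_id")["TPM"]
    df = pd.DataFrame(columns)
    df.index = df.index.astype(str)
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    """TSV with header transcript_id, m_value, p_value."""
    df = pd.read_csv(path, sep="\t")
    missing = {"transcript_id", "m_value", "p_value"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    df["transcript_id"] = df["transcript_id"].astype(str)
    return df


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """TSV (transcript_id, gene_id[, symbol])."""
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns or "gene_id" not in df.columns:
        raise ValueError("gene map needs 'transcript_id' and 'gene_id' columns")
    df["transcript_id"] = df["transcript_id"].astype(str)
    df["gene_id"] = df["gene_id"].astype(str)
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ValueError(f"transcript mapped to more than one gene: {dup!r}")
    return df


def read_go_annotations(path: str | Path) -> pd.DataFrame:
    """TSV (gene_id, go_id, go_term, category) with category in {BP, CC, MF}."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "go_id", "go_term", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GO annotation table missing columns: {sorted(missing)}")
    bad = ~df["go_id"].astype(str).str.fullmatch(r"GO:\d{7}")
    if bad.any():
        raise ValueError(
            f"malformed GO id: {df.loc[bad, 'go_id'].iloc[0]!r} (want GO:NNNNNNN)"
        )
    bad_cat = ~df["category"].isin(["BP", "CC", "MF"])
    if bad_cat.any():
        raise ValueError(
            f"unknown GO category: {df.loc[bad_cat, 'category'].iloc[0]!r}"
        )
    df["gene_id"] = df["gene_id"].astype(str)
    return df
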