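"""DANGER table construction: distinct deleterious off-target genes per
GO term per mismatch number.

N(m) for a GO term counts DISTINCT genes that (a) carry at least one
deleterious site with exactly m mismatches and (b) are annotated with
the term.  A gene with several sites at the same m counts once; a gene
with sites at several m values counts once per m.  Annotations are taken
as supplied — no GO-graph propagation.
"""

from __future__ import annotations

import logging

import pandas as pd

from .deleterious import UNIDENTIFIED

logger = logging.getLogger(__name__)

DANGER_COLUMNS = ["go_id", "go_term", "category", "m", "n_genes"]


def build_danger_table(
    deleterious_sites: pd.DataFrame,
    annotations: pd.DataFrame,
    m_max: int,
) -> pd.DataFrame:
    """The DANGER table: one row per (GO term, mismatch number) with n_genes >= 1.

    ``deleterious_sites`` must carry ``gene_id`` and ``mm_count``;
    unidentified-gene sites are skipped (logged).  Rows are sorted by
    go_id then m.
    """
    if m_max < 0:
        raise ValueError("m_max must be >= 0")
    empty = pd.DataFrame(columns=DANGER_COLUMNS).astype(
        {"m": int, "n_genes": int}, errors="ignore"
    )
    if deleterious_sites.empty:
        return empty
    sites = deleterious_sites[["gene_id", "mm_count"]].copy()
    unid = sites["gene_id"] == UNIDENTIFIED
    if unid.any():
        logger.info("skipping %d sites without gene annotation", int(unid.sum()))
        sites = sites.loc[~unid]
    over = sites["mm_count"] > m_max
    if over.any():
        sites = sites.loc[~over]
    if sites.empty:
        return empty
    no_go = set(sites["gene_id"]) - set(annotations["gene_id"])
    if no_go:
        logger.info("%d deleterious genes carry no GO annotation", len(no_go))
    gene_m = sites.drop_duplicates().rename(columns={"mm_count": "m"})
    merged = gene_m.merge(
        annotations[["gene_id", "go_id", "go_term", "category"]], on="gene_id"
    )
    if merged.empty:
        return empty
    table = (
        merged.groupby(["go_id", "go_term", "category", "m"], as_index=False)
        .agg(n_genes=("gene_id", "nunique"))
        .sort_values(["go_id", "m"], kind="mergesort")
        .reset_index(drop=True)
    )
    return table[DANGER_COLUMNS].astype({"m": int, "n_genes": int})
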