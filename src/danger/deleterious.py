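"""Intersection of candidate sites with downregulated transcripts.

A "deleterious" off-target site is a scanned site whose host transcript
carries a downregulation flag (dTPM or dDE).  The gene carrying the
intended on-target hit is removed entirely — every isoform, every site —
before risk scoring, since its expression change reflects the edit
itself, not off-targeting.  Perfect-match (0-MM) sites on *other* genes
(duplicated sequence) are legitimate off-targets and are retained.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNIDENTIFIED = "unidentified"

CRITERIA = ("dTPM", "dDE", "either")

_FLAG_COLS = {"dTPM": ["dtpm"], "dDE": ["dde"], "either": ["dtpm", "dde"]}


def attach_genes(sites: pd.DataFrame, gene_map: pd.DataFrame | None) -> pd.DataFrame:
    """Annotate each site with a gene_id (or 'unidentified').

    Site contig ids double as transcript ids.  Returns a copy with
    ``transcript_id`` and ``gene_id`` columns added.
    """
    out = sites.copy()
    out["transcript_id"] = out["contig_id"].astype(str)
    if gene_map is None or gene_map.empty:
        out["gene_id"] = UNIDENTIFIED
        return out
    mapping = gene_map.set_index("transcript_id")["gene_id"]
    out["gene_id"] = out["transcript_id"].map(mapping).fillna(UNIDENTIFIED)
    return out


def annotation_summary(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-mismatch-number counts of gene-annotated vs unidentified sites."""
    if sites.empty:
        return pd.DataFrame(columns=["mm_count", "annotated", "unidentified"]).astype(
            {"mm_count": int, "annotated": int, "unidentified": int}
        )
    is_ann = sites["gene_id"] != UNIDENTIFIED
    tab = (
        pd.DataFrame({"mm_count": sites["mm_count"], "annotated": is_ann})
        .groupby("mm_count")["annotated"]
        .agg(annotated="sum", unidentified=lambda s: (~s).sum())
        .reset_index()
    )
    return tab.astype({"mm_count": int, "annotated": int, "unidentified": int})


def exclude_on_target(
    sites: pd.DataFrame,
    on_target_sites: pd.DataFrame,
    gene_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Drop the on-target sites and every site on the on-target gene.

    When a gene map is available the exclusion is by gene (all isoforms);
    otherwise by transcript.  With no on-target found the input is
    returned unchanged with a warning.
    """
    if on_target_sites.empty:
        logger.warning("no on-target site found; nothing excluded")
        return sites.copy()
    on_tx = set(on_target_sites["contig_id"].astype(str))
    excluded_tx = set(on_tx)
    if gene_map is not None and not gene_map.empty:
        mapping = gene_map.set_index("transcript_id")["gene_id"]
        on_genes = {g for g in (mapping.get(t) for t in on_tx) if g is not None}
        if on_genes:
            excluded_tx |= set(mapping[mapping.isin(on_genes)].index.astype(str))
    keep = ~sites["contig_id"].astype(str).isin(excluded_tx)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("excluded %d sites on the on-target gene/transcript(s)", n_drop)
    return sites.loc[keep].reset_index(drop=True)


def find_deleterious(
    sites: pd.DataFrame, screen: pd.DataFrame, criterion: str = "dTPM"
) -> pd.DataFrame:
    """Sites whose host transcript carries the chosen downregulation flag.

    ``criterion`` is 'dTPM', 'dDE' or 'either'.  Adds an ``evidence``
    column ('dTPM', 'dDE' or 'both').  Sites on transcripts absent from
    the screen are dropped with a warning count.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    out = sites.copy()
    if "transcript_id" not in out.columns:
        out["transcript_id"] = out["contig_id"].astype(str)
    flags = screen.set_index("transcript_id")[["dtpm", "dde"]]
    known = out["transcript_id"].isin(flags.index)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning(
            "%d sites on transcripts absent from the expression screen; dropped",
            n_unknown,
        )
    out = out.loc[known]
    dtpm = out["transcript_id"].map(flags["dtpm"]).astype(bool)
    dde = out["transcript_id"].map(flags["dde"]).astype(bool)
    cols = _FLAG_COLS[criterion]
    keep = dtpm if cols == ["dtpm"] else dde if cols == ["dde"] else (dtpm | dde)
    out = out.loc[keep.values].reset_index(drop=True)
    ev_dtpm = dtpm[keep].values
    ev_dde = dde[keep].values
    if criterion == "dTPM":
        evidence = np.where(ev_dtpm, "dTPM", "")
    elif criterion == "dDE":
        evidence = np.where(ev_dde, "dDE", "")
    else:
        evidence = np.where(
            ev_dtpm & ev_dde, "both", np.where(ev_dtpm, "dTPM", "dDE")
        )
    out["evidence"] = evidence
    return out
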