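"""The D-index: a per-GO-term phenotypic risk score.

D-index = sum over m from 0 to m_max of N(m) * exp(4 - m), where N(m) is
the number of distinct deleterious off-target genes at mismatch number m
carrying the term.  The exponential weight mirrors the empirically
observed decay of off-target activity with mismatch count; the offset 4
pivots the weight at the 4-mismatch level beyond which off-target
cleavage is rarely reported, so low-mismatch genes dominate the score.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

D_INDEX_COLUMNS = ["go_id", "go_term", "category", "d_index"]


def mm_weight(m: int) -> float:
    """exp(4 - m), the contribution of one gene at mismatch number m."""
    if m < 0:
        raise ValueError("mismatch number must be >= 0")
    return math.exp(4 - m)


def compute_d_index(counts: Mapping[int, int], m_max: int) -> float:
    """Evaluate the D-index from a map m -> N(m); missing m contribute 0."""
    for m, n in counts.items():
        if m < 0 or m > m_max:
            raise ValueError(f"mismatch number {m} outside [0, {m_max}]")
        if n < 0:
            raise ValueError(f"negative gene count at m={m}")
    return float(sum(counts.get(m, 0) * mm_weight(m) for m in range(m_max + 1)))


def d_index_profile(
    danger_table: pd.DataFrame, m_max: int
) -> tuple[pd.DataFrame, float, int]:
    """Per-GO-term D-index records plus (total D-index, number of terms N).

    Returns a frame with columns go_id, go_term, category, d_index and
    N_0..N_{m_max} count columns, one row per distinct go_id, sorted by
    go_id.
    """
    count_cols = [f"N_{m}" for m in range(m_max + 1)]
    if danger_table.empty:
        rec = pd.DataFrame(columns=D_INDEX_COLUMNS + count_cols)
        return rec, 0.0, 0
    pivot = (
        danger_table.pivot_table(
            index=["go_id", "go_term", "category"],
            columns="m",
            values="n_genes",
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(columns=range(m_max + 1), fill_value=0)
        .astype(int)
    )
    weights = pd.Series({m: mm_weight(m) for m in range(m_max + 1)})
    d = (pivot * weights).sum(axis=1)
    rec = pivot.reset_index()
    rec.columns = ["go_id", "go_term", "category"] + count_cols
    rec.insert(3, "d_index", d.values)
    rec = rec.sort_values("go_id", kind="mergesort").reset_index(drop=True)
    return rec, float(rec["d_index"].sum()), int(len(rec))
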