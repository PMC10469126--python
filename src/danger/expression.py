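"""Per-transcript expression screening: the dTPM and dDE downregulation rules.

The dTPM rule flags a transcript when the ratio of mean edited TPM to
mean wild-type TPM falls strictly below a threshold ``t``.  The dDE rule
consumes an externally computed differential-expression table (M-value,
P-value per transcript — e.g. a TMM/edgeR run) and flags transcripts
with a negative M-value and P strictly below ``alpha``.  No pseudocount
is applied: a transcript unexpressed in wild type (mean 0) has an
undefined ratio and is never flagged dTPM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import EDITED_LABEL, WT_LABEL

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Downregulation thresholds: t for the TPM ratio, alpha for the DE P-value."""

    t: float = 0.4
    alpha: float = 0.001

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise ValueError("t must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Transcripts-by-samples expression values plus a sample->group map."""

    values: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples missing from manifest: {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.wt_samples or not self.edited_samples:
            raise ValueError(
                f"need at least one {WT_LABEL!r} and one {EDITED_LABEL!r} sample"
            )

    @property
    def wt_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == WT_LABEL]

    @property
    def edited_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == EDITED_LABEL]


def tpm_ratio(wt_values: Sequence[float], edited_values: Sequence[float]) -> float:
    """Mean edited TPM divided by mean WT TPM; NaN when the WT mean is 0."""
    wt = np.asarray(wt_values, dtype=float)
    ed = np.asarray(edited_values, dtype=float)
    if wt.size == 0 or ed.size == 0:
        raise ValueError("both groups must be non-empty")
    if (wt < 0).any() or (ed < 0).any():
        raise ValueError("expression values must be non-negative")
    wt_mean = wt.mean()
    if wt_mean == 0:
        return math.nan
    return float(ed.mean() / wt_mean)


def flag_dtpm(ratio: pd.Series, t: float) -> pd.Series:
    """dTPM is true iff the ratio is defined and strictly below t."""
    if not t > 0:
        raise ValueError("t must be > 0")
    return ratio.notna() & (ratio < t)


def flag_dde(de_table: pd.DataFrame, alpha: float) -> pd.Series:
    """dDE is true iff M < 0 and P strictly below alpha (indexed by transcript)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = de_table["p_value"]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p_value must lie in [0, 1]")
    flags = (de_table["m_value"] < 0) & (p < alpha)
    flags.index = de_table["transcript_id"]
    return flags


def screen_expression(
    matrix: ExpressionMatrix,
    config: ClassifierConfig = ClassifierConfig(),
    de_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-transcript screen: means, TPM ratio, dTPM and (optionally) dDE flags.

    Returns a frame with columns transcript_id, mean_wt, mean_edited,
    tpm_ratio, dtpm, m_value, p_value, dde.  DE-table transcripts absent
    from the matrix are kept (with NaN means) and counted in a warning.
    """
    vals = matrix.values
    mean_wt = vals[matrix.wt_samples].mean(axis=1)
    mean_ed = vals[matrix.edited_samples].mean(axis=1)
    ratio = mean_ed / mean_wt.replace(0.0, np.nan)
    out = pd.DataFrame(
        {
            "transcript_id": vals.index.astype(str),
            "mean_wt": mean_wt.values,
            "mean_edited": mean_ed.values,
            "tpm_ratio": ratio.values,
        }
    )
    out["dtpm"] = flag_dtpm(out["tpm_ratio"], config.t).values
    if de_table is not None:
        de = de_table[["transcript_id", "m_value", "p_value"]].copy()
        de["transcript_id"] = de["transcript_id"].astype(str)
        extra = set(de["transcript_id"]) - set(out["transcript_id"])
        if extra:
            logger.warning(
                "%d DE-table transcripts absent from the expression matrix; kept",
                len(extra),
            )
        out = out.merge(de, on="transcript_id", how="outer")
        out["dtpm"] = out["dtpm"].where(out["dtpm"].notna(), False).astype(bool)
        dde = flag_dde(out.fillna({"p_value": 1.0, "m_value": 0.0}), config.alpha)
        out["dde"] = dde.values
    else:
        out["m_value"] = np.nan
        out["p_value"] = np.nan
        out["dde"] = False
    return out.reset_index(drop=True)
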