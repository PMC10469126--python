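"""Permutation-null validation of D-indices.

The null distribution of each GO term's D-index ("pseudo-D-indices") is
built by repeatedly shuffling the two profiles that link sites to risk:
downregulation flags are permuted across transcripts and mismatch
labels are permuted across site rows, breaking the site-expression and
the mismatch-gene associations while preserving both marginals.  After
each shuffle the deleterious-site filter, the DANGER aggregation and the
D-index are recomputed.  Because an empirical quantile at L = 1E-15 is
unreachable with 100 permutations, the (1-L) confidence bound is
parametric: mean + z(1 - L/2) * sd with the population (ddof=0) standard
deviation; combined with the "above the mean" clause the call is
effectively one-sided upper.

Seeds: null permutations use base_seed+1 .. base_seed+n_null; the extra
shuffles of the false-detection check use the next n_extra integers, so
the two sets are disjoint by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .deleterious import UNIDENTIFIED
from .dindex import mm_weight

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationConfig:
    """Permutation-test settings: null size, extra shuffles, level L, base seed."""

    n_null: int = 100
    n_extra: int = 10
    L: float = 1e-15
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null < 2:
            raise ValueError("n_null must be >= 2 (sd undefined otherwise)")
        if self.n_extra < 1:
            raise ValueError("n_extra must be >= 1")
        if not 0 < self.L < 1:
            raise ValueError("L must be in (0, 1)")

    @property
    def null_seeds(self) -> list[int]:
        return [self.base_seed + 1 + i for i in range(self.n_null)]

    @property
    def extra_seeds(self) -> list[int]:
        return [self.base_seed + self.n_null + 1 + i for i in range(self.n_extra)]


def z_quantile(L: float) -> float:
    """Standard-normal upper quantile at 1 - L/2 (two-sided convention)."""
    return float(norm.isf(L / 2.0))


def shuffle_profiles(
    flags: pd.Series, sites: pd.DataFrame, seed: int
) -> tuple[pd.Series, pd.DataFrame]:
    """One seeded shuffle of the expression and off-target profiles.

    Returns (flags with values permuted across transcript ids, site table
    with mm_count values permuted across rows).  Both permutations derive
    from the single seed; the multisets of flags and of mismatch counts
    are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    perm_tx = rng.permutation(len(flags))
    perm_sites = rng.permutation(len(sites))
    new_flags = pd.Series(
        flags.to_numpy()[perm_tx], index=flags.index, name=flags.name
    )
    new_sites = sites.copy()
    new_sites["mm_count"] = sites["mm_count"].to_numpy()[perm_sites]
    return new_flags, new_sites


@dataclass(frozen=True)
class NullDistribution:
    """Per-GO-term pseudo-D-index null: raw values, mean, sd, threshold at L."""

    go_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_terms, n_null)
    L: float
    seeds: tuple[int, ...]
    mean: np.ndarray = field(init=False)
    sd: np.ndarray = field(init=False)
    threshold: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", self.values.mean(axis=1))
        object.__setattr__(self, "sd", self.values.std(axis=1, ddof=0))
        object.__setattr__(
            self, "threshold", self.mean + z_quantile(self.L) * self.sd
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "go_id": list(self.go_ids),
                "null_mean": self.mean,
                "null_sd": self.sd,
                "threshold": self.threshold,
            }
        )


@dataclass(frozen=True)
class FdrReport:
    """False-detection summary from the extra-shuffle check.

    ``expected_true`` carries both subtraction conventions, keyed by
    variant label: 'total_minus_false' (all D-indices minus expected
    false) and 'significant_minus_false' (significant D-indices minus
    expected false, clamped at 0).
    """

    false_positive_rate: float
    n_significant_pseudo: int
    n_new_pseudo: int
    n_original: int
    n_significant_original: int
    expected_false: float
    expected_true: dict[str, float]
    L: float

    def as_dict(self) -> dict:
        return {
            "false_positive_rate": self.false_positive_rate,
            "n_significant_pseudo": self.n_significant_pseudo,
            "n_new_pseudo": self.n_new_pseudo,
            "n_original": self.n_original,
            "n_significant_original": self.n_significant_original,
            "expected_false": self.expected_false,
            "expected_true": dict(self.expected_true),
            "L": self.L,
        }


class PermutationEngine:
    """Vectorised pseudo-D-index computation over many seeds.

    Built once from the observed profiles: downregulation flags over all
    screened transcripts, the gene-annotated non-on-target site table,
    and the GO annotation table restricted to the observed GO terms.
    ``pseudo(seed)`` reproduces exactly the composition
    shuffle -> deleterious filter -> DANGER table -> D-index.
    """

    def __init__(
        self,
        flags: pd.Series,
        sites: pd.DataFrame,
        annotations: pd.DataFrame,
        go_ids: list[str] | tuple[str, ...],
        m_max: int,
    ) -> None:
        self.flags = flags
        self.sites = sites
        self.m_max = int(m_max)
        self.go_ids = tuple(go_ids)

        usable = sites["gene_id"].astype(str) != UNIDENTIFIED
        site_tab = sites.loc[usable]
        tx_index = {t: i for i, t in enumerate(flags.index.astype(str))}
        tx_ids = site_tab["transcript_id"].astype(str)
        known = tx_ids.isin(tx_index)
        site_tab = site_tab.loc[known]
        # site rows outside the screen can never be deleterious; note them
        if int((~known).sum()):
            logger.info(
                "%d sites on unscreened transcripts ignored by the null engine",
                int((~known).sum()),
            )
        genes = pd.unique(site_tab["gene_id"].astype(str))
        gene_index = {g: i for i, g in enumerate(genes)}
        self._n_tx = len(flags)
        self._flag_values = flags.to_numpy(dtype=bool)
        self._site_tx = np.array(
            [tx_index[t] for t in site_tab["transcript_id"].astype(str)], dtype=np.intp
        )
        self._site_gene = np.array(
            [gene_index[g] for g in site_tab["gene_id"].astype(str)], dtype=np.intp
        )
        # mm labels of ALL site rows are shuffled (the off-target profile),
        # so keep the full-row mm vector and the usable-row positions
        self._all_mm = sites["mm_count"].to_numpy(dtype=np.intp)
        self._usable_pos = np.nonzero(usable.to_numpy())[0][known.to_numpy()]
        self._n_sites_all = len(sites)
        self._weights = np.array(
            [mm_weight(m) for m in range(self.m_max + 1)], dtype=float
        )
        n_go = len(self.go_ids)
        go_index = {g: i for i, g in enumerate(self.go_ids)}
        self._incidence = np.zeros((n_go, len(genes)), dtype=float)
        ann = annotations[["gene_id", "go_id"]].drop_duplicates()
        for gene, go in zip(ann["gene_id"].astype(str), ann["go_id"]):
            gi = gene_index.get(gene)
            ti = go_index.get(go)
            if gi is not None and ti is not None:
                self._incidence[ti, gi] = 1.0

    def pseudo(self, seed: int) -> np.ndarray:
        """Pseudo-D-index per observed GO term for one shuffle seed."""
        rng = np.random.default_rng(seed)
        perm_tx = rng.permutation(self._n_tx)
        perm_sites = rng.permutation(self._n_sites_all)
        new_flags = self._flag_values[perm_tx]
        mm_shuffled = self._all_mm[perm_sites][self._usable_pos]
        keep = new_flags[self._site_tx]
        if not keep.any():
            return np.zeros(len(self.go_ids))
        g = self._site_gene[keep]
        m = mm_shuffled[keep]
        ok = m <= self.m_max  # matches the DANGER table's m <= m_max filter
        g, m = g[ok], m[ok]
        key = g * (self.m_max + 1) + m
        uniq = np.unique(key)
        contrib = np.zeros(self._incidence.shape[1])
        np.add.at(contrib, uniq // (self.m_max + 1), self._weights[uniq % (self.m_max + 1)])
        return self._incidence @ contrib


def build_null(
    dindex_records: pd.DataFrame,
    flags: pd.Series,
    sites: pd.DataFrame,
    annotations: pd.DataFrame,
    m_max: int,
    config: ValidationConfig,
) -> NullDistribution:
    """Pseudo-D-index null over the observed GO terms (config.n_null shuffles).

    GO terms absent from a given permutation contribute pseudo value 0
    for that permutation.
    """
    go_ids = list(dindex_records["go_id"])
    engine = PermutationEngine(flags, sites, annotations, go_ids, m_max)
    seeds = config.null_seeds
    values = np.empty((len(go_ids), len(seeds)))
    for j, seed in enumerate(seeds):
        values[:, j] = engine.pseudo(seed)
    return NullDistribution(
        go_ids=tuple(go_ids), values=values, L=config.L, seeds=tuple(seeds)
    )


def call_significance(
    dindex_records: pd.DataFrame, null: NullDistribution, L: float | None = None
) -> pd.DataFrame:
    """Flag significant D-indices: above the (1-L) bound AND above the null mean.

    Terms without a null entry are treated as mean 0, sd 0 (so any
    positive D-index is significant).  Strict inequalities throughout.
    """
    if L is None:
        L = null.L
    stats = pd.DataFrame(
        {"go_id": list(null.go_ids), "null_mean": null.mean, "null_sd": null.sd}
    )
    out = dindex_records.merge(stats, on="go_id", how="left")
    out["null_mean"] = out["null_mean"].fillna(0.0)
    out["null_sd"] = out["null_sd"].fillna(0.0)
    out["threshold"] = out["null_mean"] + z_quantile(L) * out["null_sd"]
    out["significant"] = (out["d_index"] > out["threshold"]) & (
        out["d_index"] > out["null_mean"]
    )
    return out


def estimate_false_detection(
    dindex_records: pd.DataFrame,
    null: NullDistribution,
    flags: pd.Series,
    sites: pd.DataFrame,
    annotations: pd.DataFrame,
    m_max: int,
    config: ValidationConfig,
    L: float | None = None,
) -> FdrReport:
    """False-positive rate from fresh shuffles scored against the null.

    Generates ``config.n_extra`` shuffled datasets with seeds disjoint
    from the null seeds, computes their pseudo-D-indices, and counts
    those meeting the significance criterion against the existing null.
    rate = count / (n_extra * number of observed D-indices);
    expected_false = rate * number of observed D-indices.
    """
    if L is None:
        L = null.L
    extra = config.extra_seeds
    if set(extra) & set(null.seeds):
        raise ValueError("extra seeds overlap the null seeds")
    go_ids = list(null.go_ids)
    engine = PermutationEngine(flags, sites, annotations, go_ids, m_max)
    z = z_quantile(L)
    thr = null.mean + z * null.sd
    n_sig_pseudo = 0
    for seed in extra:
        pseudo = engine.pseudo(seed)
        n_sig_pseudo += int(((pseudo > thr) & (pseudo > null.mean)).sum())
    n_original = len(go_ids)
    n_new = config.n_extra * n_original
    rate = n_sig_pseudo / n_new if n_new else 0.0
    expected_false = rate * n_original
    called = call_significance(dindex_records, null, L)
    n_sig_orig = int(called["significant"].sum())
    return FdrReport(
        false_positive_rate=rate,
        n_significant_pseudo=n_sig_pseudo,
        n_new_pseudo=n_new,
        n_original=n_original,
        n_significant_original=n_sig_orig,
        expected_false=expected_false,
        expected_true={
            "total_minus_false": n_original - expected_false,
            "significant_minus_false": max(0.0, n_sig_orig - expected_false),
        },
        L=L,
    )
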