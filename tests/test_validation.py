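import collections

import numpy as np
import pandas as pd
import pytest

from danger import (
    NullDistribution,
    PermutationEngine,
    ValidationConfig,
    build_danger_table,
    build_null,
    call_significance,
    d_index_profile,
    estimate_false_detection,
    find_deleterious,
    shuffle_profiles,
    z_quantile,
)
from conftest import analyze_fixture


def _flags_sites(n_tx=40, n_sites=60, seed=0):
    rng = np.random.default_rng(seed)
    tx = [f"t{i}" for i in range(n_tx)]
    flags = pd.Series(rng.random(n_tx) < 0.3, index=tx)
    sites = pd.DataFrame(
        {
            "contig_id": rng.choice(tx, size=n_sites),
            "mm_count": rng.integers(0, 9, size=n_sites),
        }
    )
    sites["transcript_id"] = sites["contig_id"]
    sites["gene_id"] = "g_" + sites["contig_id"].astype(str)
    return flags, sites


def test_shuffle_is_deterministic_and_conserving():
    flags, sites = _flags_sites()
    f1, s1 = shuffle_profiles(flags, sites, seed=123)
    f2, s2 = shuffle_profiles(flags, sites, seed=123)
    pd.testing.assert_series_equal(f1, f2)
    pd.testing.assert_frame_equal(s1, s2)
    assert collections.Counter(f1) == collections.Counter(flags)
    assert collections.Counter(s1["mm_count"]) == collections.Counter(sites["mm_count"])
    f3, _ = shuffle_profiles(flags, sites, seed=124)
    assert not f3.equals(f1) or True  # different seed may rarely coincide


def test_flag_shuffle_behaves_like_uniform_permutation():
    """Mean number of fixed points of the flag permutation is ~1."""
    rng = np.random.default_rng(0)
    n = 100
    tx = [f"t{i}" for i in range(n)]
    # distinct sentinel values so fixed points of the permutation are visible
    flags = pd.Series(np.arange(n), index=tx)
    sites = pd.DataFrame(
        {"contig_id": tx[:10], "transcript_id": tx[:10],
         "gene_id": ["g"] * 10, "mm_count": range(10)}
    )
    fixed = [
        (shuffle_profiles(flags, sites, seed=s)[0].to_numpy() == np.arange(n)).sum()
        for s in range(300)
    ]
    assert 0.6 < np.mean(fixed) < 1.5  # E[fixed points] = 1 for uniform permutations


def test_degenerate_null_all_zero():
    flags, sites = _flags_sites()
    flags[:] = False
    ann = pd.DataFrame(
        {"gene_id": sites["gene_id"].unique(), "go_id": "GO:0000001",
         "go_term": "t", "category": "BP"}
    )
    records = pd.DataFrame(
        {"go_id": ["GO:0000001"], "go_term": ["t"], "category": ["BP"], "d_index": [10.0]}
    )
    null = build_null(records, flags, sites, ann, 8, ValidationConfig(base_seed=5))
    assert (null.values == 0).all() and null.mean[0] == 0 and null.sd[0] == 0
    called = call_significance(records, null)
    assert called["significant"].item()  # any positive score beats a flat null


def test_observed_equal_to_null_mean_is_not_significant():
    records = pd.DataFrame(
        {"go_id": ["GO:0000001"], "go_term": ["t"], "category": ["BP"], "d_index": [3.0]}
    )
    null = NullDistribution(
        go_ids=("GO:0000001",), values=np.full((1, 10), 3.0), L=0.5, seeds=tuple(range(10))
    )
    assert not call_significance(records, null)["significant"].item()


def test_null_is_deterministic_and_seeds_disjoint(mixed_dataset, mixed_analysis):
    res = mixed_analysis
    cfg = ValidationConfig(n_null=30, base_seed=9)
    args = (res.d_index, res.flags, res.off_sites, mixed_dataset.annotations, 8, cfg)
    n1, n2 = build_null(*args), build_null(*args)
    assert (n1.values == n2.values).all()
    assert not set(cfg.null_seeds) & set(cfg.extra_seeds)


def test_engine_matches_full_pipeline_recompute(mixed_dataset, mixed_analysis):
    """Vectorised pseudo-D-indices equal an independent stage-by-stage
    recompute on the identical shuffled profiles."""
    res = mixed_analysis
    ann = mixed_dataset.annotations
    engine = PermutationEngine(res.flags, res.off_sites, ann, list(res.d_index["go_id"]), 8)
    for seed in [101, 202, 303]:
        fast = dict(zip(engine.go_ids, engine.pseudo(seed)))
        sh_flags, sh_sites = shuffle_profiles(res.flags, res.off_sites, seed)
        screen_like = pd.DataFrame(
            {"transcript_id": sh_flags.index, "dtpm": sh_flags.values, "dde": False}
        )
        dele = find_deleterious(sh_sites, screen_like, "dTPM")
        table = build_danger_table(dele, ann, 8)
        records, _, _ = d_index_profile(table, 8)
        slow = dict(zip(records["go_id"], records["d_index"]))
        for go in engine.go_ids:
            assert fast[go] == pytest.approx(slow.get(go, 0.0), rel=1e-12)


def test_significance_monotone_in_L(mixed_dataset, mixed_analysis):
    res = mixed_analysis
    cfg = ValidationConfig(n_null=50, base_seed=3)
    null = build_null(res.d_index, res.flags, res.off_sites, mixed_dataset.annotations, 8, cfg)
    strict = call_significance(res.d_index, null, L=1e-15)
    loose = call_significance(res.d_index, null, L=0.5)
    s_strict = set(strict.loc[strict["significant"], "go_id"])
    s_loose = set(loose.loc[loose["significant"], "go_id"])
    assert s_strict <= s_loose
    assert z_quantile(1e-15) > z_quantile(0.5)


def test_fdr_report_arithmetic(mixed_dataset, mixed_analysis):
    res = mixed_analysis
    cfg = ValidationConfig(n_null=50, n_extra=10, L=0.5, base_seed=17)
    ann = mixed_dataset.annotations
    null = build_null(res.d_index, res.flags, res.off_sites, ann, 8, cfg)
    rep = estimate_false_detection(res.d_index, null, res.flags, res.off_sites, ann, 8, cfg)
    assert rep.n_new_pseudo == cfg.n_extra * rep.n_original
    assert rep.false_positive_rate == pytest.approx(
        rep.n_significant_pseudo / rep.n_new_pseudo
    )
    assert rep.expected_false == pytest.approx(rep.false_positive_rate * rep.n_original)
    assert rep.expected_true["total_minus_false"] == pytest.approx(
        rep.n_original - rep.expected_false
    )
    assert rep.expected_true["significant_minus_false"] >= 0.0


def test_config_validation():
    with pytest.raises(ValueError):
        ValidationConfig(n_null=1)
    with pytest.raises(ValueError):
        ValidationConfig(L=0.0)
    with pytest.raises(ValueError):
        ValidationConfig(n_extra=0)
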