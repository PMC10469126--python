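import io as stdio

import numpy as np
import pandas as pd
import pytest

from danger import (
    DEFAULT_GUIDE,
    ScanConfig,
    generate_annotations,
    generate_expression,
    generate_transcriptome,
    make_fixture,
    scan_transcriptome,
    tpm_ratio,
)
from danger import io as dio
from danger.simulate import FixtureError
from oracles import scan_oracle


def _truth_set(truth):
    return {(s["contig_id"], s["start"], s["strand"], s["mm_count"])
            for s in truth.planted_sites}


def test_planted_sites_round_trip_through_scanner():
    tr, truth = generate_transcriptome(
        n_contigs=12, length_range=(400, 600), guide=DEFAULT_GUIDE,
        plant_spec=[(0, 1, "+"), (3, 5, "both")], seed=5,
    )
    sites = scan_transcriptome(tr, DEFAULT_GUIDE, ScanConfig(max_mm=3))
    got = {(s.contig_id, s.start, s.strand, s.mm_count) for s in sites}
    assert got == _truth_set(truth)
    assert sum(1 for s in sites if s.mm_count == 3) == 5


def test_planted_truth_confirmed_by_bruteforce_oracle():
    tr, truth = generate_transcriptome(
        n_contigs=6, length_range=(300, 400), guide=DEFAULT_GUIDE,
        plant_spec=[(2, 3, "-")], seed=9,
    )
    want = {(c, s, st, m) for c, s, st, m in
            scan_oracle(list(tr), DEFAULT_GUIDE.protospacer, "NGG", 2)}
    assert want == _truth_set(truth)
    assert all(s["strand"] == "-" for s in truth.planted_sites)


def test_same_seed_identical_fasta_bytes(tmp_path):
    for name in ("a.fasta", "b.fasta"):
        tr, _ = generate_transcriptome(
            n_contigs=4, length_range=(300, 350), guide=DEFAULT_GUIDE,
            plant_spec=[(1, 2, "both")], seed=77,
        )
        dio.write_fasta(tr, tmp_path / name)
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_infeasible_plant_spec_errors():
    with pytest.raises(FixtureError):
        generate_transcriptome(
            n_contigs=2, length_range=(300, 400), guide=DEFAULT_GUIDE,
            plant_spec=[(1, 5, "+")], seed=0,
        )


def test_noiseless_expression_reproduces_fold_changes():
    tx = ["a", "b", "c"]
    mat = generate_expression(
        tx, n_wt=3, n_edited=3, base_tpm_range=(50, 100),
        fold_change_map={"a": 0.2}, noise_cv=0.0, seed=1,
    )
    screen_a = tpm_ratio(mat.values.loc["a", mat.wt_samples],
                         mat.values.loc["a", mat.edited_samples])
    screen_b = tpm_ratio(mat.values.loc["b", mat.wt_samples],
                         mat.values.loc["b", mat.edited_samples])
    assert screen_a == pytest.approx(0.2, rel=1e-12)
    assert screen_b == pytest.approx(1.0, rel=1e-12)


def test_noisy_expression_recovers_planted_labels():
    """With CV=0.1 and n=3, a 0.2-fold knockdown is flagged at t=0.4
    in virtually every seeded draw."""
    hits = 0
    for seed in range(50):
        mat = generate_expression(
            ["x"], 3, 3, (50, 100), {"x": 0.2}, noise_cv=0.1, seed=seed
        )
        r = tpm_ratio(mat.values.loc["x", mat.wt_samples],
                      mat.values.loc["x", mat.edited_samples])
        hits += r < 0.4
    assert hits >= 48


def test_annotations_plant_and_determinism():
    genes = [f"g{i}" for i in range(40)]
    a1 = generate_annotations(genes, 20, (1, 3), seed=4,
                              planted_term="GO:0000001", planted_genes=genes[:5])
    a2 = generate_annotations(genes, 20, (1, 3), seed=4,
                              planted_term="GO:0000001", planted_genes=genes[:5])
    pd.testing.assert_frame_equal(a1, a2)
    planted = a1[a1["go_id"] == "GO:0000001"]
    assert set(planted["gene_id"]) == set(genes[:5])
    # random pool stays clear of the planted id and is roughly uniform
    pool = a1[a1["go_id"] != "GO:0000001"]
    counts = pool["go_id"].value_counts()
    assert counts.idxmax() != "GO:0000001"
    # binomial sanity: each term drawn ~ n_genes * E[k]/n_terms times
    assert counts.max() <= 40


def test_fixture_presets_are_deterministic_and_complete(tmp_path):
    ds1 = make_fixture("strong", seed=3)
    ds2 = make_fixture("strong", seed=3)
    assert [s for s in ds1.transcriptome] == [s for s in ds2.transcriptome]
    pd.testing.assert_frame_equal(ds1.annotations, ds2.annotations)
    paths = ds1.write(tmp_path / "d")
    for p in paths.values():
        assert p.exists()
    # planted genes all carry the planted term
    planted = ds1.annotations[ds1.annotations["go_id"] == ds1.truth.planted_term]
    assert set(ds1.truth.planted_genes) == set(planted["gene_id"])
    # the on-target gene has two isoforms in the gene map
    on_gene = ds1.gene_map.iloc[0]["gene_id"]
    assert (ds1.gene_map["gene_id"] == on_gene).sum() == 2


def test_null_preset_has_no_planted_term():
    ds = make_fixture("null", seed=6)
    assert ds.truth.planted_term is None and ds.truth.planted_genes == []
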