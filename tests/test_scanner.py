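import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from danger import (
    GuideSpec,
    ScanConfig,
    ScanError,
    count_mismatches,
    match_pam,
    scan_transcriptome,
)
from conftest import random_contigs
from oracles import mm_oracle, revcomp, scan_oracle

GUIDE20 = "AGATTCTGGGTGGAAGCGCC"  # published SpCas9 protospacer


@pytest.mark.parametrize(
    "candidate,expected",
    [
        ("GCAGACTGGTTGGAAGCACC", 6),  # ALK-locus protospacer
        ("CCCTTCCGGCCGGAAGCGCC", 6),  # GBA2-locus protospacer
        (GUIDE20, 0),
        ("gcAgaCTGGtTGGAAGCaCC", 6),  # case-insensitive
    ],
)
def test_count_mismatches_reported_offtargets(candidate, expected):
    """The mismatch counter reproduces the published off-target mismatch numbers."""
    assert count_mismatches(candidate, GUIDE20) == expected


@given(st.text(alphabet="ACGTN", min_size=20, max_size=20))
@settings(max_examples=200, deadline=None)
def test_count_mismatches_equals_positional_oracle(candidate):
    assert count_mismatches(candidate, GUIDE20) == mm_oracle(candidate, GUIDE20)


def test_count_mismatches_rejects_length_mismatch():
    with pytest.raises(ScanError):
        count_mismatches("ACGT", GUIDE20)


@pytest.mark.parametrize(
    "window,pattern,expected",
    [
        ("AGG", "NGG", True),
        ("TGA", "NGG", False),
        ("TAG", "NRR", True),
        ("TCG", "NRR", False),
        ("NGG", "NGG", False),  # ambiguous bases never satisfy a PAM
    ],
)
def test_match_pam(window, pattern, expected):
    assert match_pam(window, pattern) is expected


def test_match_pam_rejects_bad_symbol():
    with pytest.raises(ScanError):
        match_pam("AGG", "NGX")


def test_guide_spec_validation():
    with pytest.raises(ScanError):
        GuideSpec(protospacer="ACGT")  # too short
    with pytest.raises(ScanError):
        GuideSpec(protospacer="N" + GUIDE20[1:])  # ambiguity code
    assert GuideSpec(protospacer=GUIDE20[:19]).window_length == 22


def test_planted_on_target_found(guide):
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    seq = seq[:100] + guide.protospacer + "AGG" + seq[123:]
    sites = scan_transcriptome([("c", seq)], guide, ScanConfig(max_mm=0))
    hits = [s for s in sites if s.start == 100 and s.strand == "+"]
    assert len(hits) == 1
    s = hits[0]
    assert s.mm_count == 0 and s.is_on_target
    assert s.site_sequence == guide.protospacer + "AGG"


def test_reverse_strand_coordinates(guide):
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    window = guide.protospacer + "TGG"
    planted = seq[:150] + revcomp(window) + seq[150 + 23 :]
    sites = scan_transcriptome([("c", planted)], guide, ScanConfig(max_mm=0))
    rev = [s for s in sites if s.strand == "-"]
    assert [(s.start, s.mm_count) for s in rev] == [(150, 0)]
    assert rev[0].site_sequence == window


def _site_set(sites):
    return {(s.contig_id, s.start, s.strand, s.mm_count) for s in sites}


@pytest.mark.parametrize("pam,max_mm", [("NGG", 3), ("NGG", 8), ("NRR", 5)])
def test_scan_equals_bruteforce(guide, pam, max_mm):
    """Vectorised scan set-equals an exhaustive sliding-window search."""
    rng = np.random.default_rng(42 + max_mm)
    for rep in range(8):
        contigs = random_contigs(rng, n=4, length=400)
        cfg = ScanConfig(max_mm=max_mm, pam_pattern=pam)
        got = _site_set(scan_transcriptome(contigs, guide, cfg))
        want = scan_oracle(contigs, guide.protospacer, pam, max_mm)
        assert got == want


def test_monotone_in_max_mm(guide):
    rng = np.random.default_rng(3)
    contigs = random_contigs(rng, n=5, length=600)
    previous = set()
    for k in (4, 6, 8, 10):
        sites = _site_set(
            scan_transcriptome(contigs, guide, ScanConfig(max_mm=k, pam_pattern="NRR"))
        )
        assert previous <= sites
        previous = sites


def test_strand_symmetry(guide):
    """Scanning the reverse-complemented transcriptome mirrors sites."""
    rng = np.random.default_rng(4)
    contigs = random_contigs(rng, n=3, length=500)
    cfg = ScanConfig(max_mm=6, pam_pattern="NGG")
    fwd = _site_set(scan_transcriptome(contigs, guide, cfg))
    flipped = [(cid, revcomp(seq)) for cid, seq in contigs]
    lengths = dict((cid, len(seq)) for cid, seq in contigs)
    back = {
        (cid, lengths[cid] - start - guide.window_length, "+-"[strand == "+"], mm)
        for cid, start, strand, mm in _site_set(
            scan_transcriptome(flipped, guide, cfg)
        )
    }
    assert fwd == back


def test_zero_mm_sites_are_exact_occurrences(guide):
    rng = np.random.default_rng(5)
    contigs = random_contigs(rng, n=2, length=300)
    window = guide.protospacer + "CGG"
    cid, seq = contigs[0]
    contigs[0] = (cid, seq[:50] + window + seq[50 + len(window) :])
    sites = scan_transcriptome(contigs, guide, ScanConfig(max_mm=2))
    perfect = [s for s in sites if s.mm_count == 0]
    assert [(s.contig_id, s.start, s.strand) for s in perfect] == [(cid, 50, "+")]


def test_short_and_empty_inputs(guide):
    assert scan_transcriptome([], guide, ScanConfig()) == []
    assert scan_transcriptome([("tiny", "ACGTACGT")], guide, ScanConfig()) == []


def test_ambiguous_bases_count_as_mismatch_and_block_pam(guide):
    seq = "T" * 30 + guide.protospacer[:-1] + "N" + "AGG" + "T" * 30
    sites = scan_transcriptome(
        [("c", seq)], guide, ScanConfig(max_mm=1, both_strands=False)
    )
    assert [(s.start, s.mm_count) for s in sites] == [(30, 1)]
    # N in the PAM's required-G position blocks the site entirely
    seq2 = "T" * 30 + guide.protospacer + "ANG" + "T" * 30
    assert (
        scan_transcriptome([("c", seq2)], guide, ScanConfig(max_mm=0, both_strands=False))
        == []
    )
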