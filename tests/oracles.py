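"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written with plain string operations and explicit loops —
none of the package's vectorised code paths are shared.
"""

from __future__ import annotations

import math

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def mm_oracle(candidate: str, protospacer: str) -> int:
    c, p = candidate.upper(), protospacer.upper()
    assert len(c) == len(p)
    return sum(1 for a, b in zip(c, p) if a != b or a not in "ACGT")


def pam_oracle(window: str, pattern: str) -> bool:
    return all(b in IUPAC[s] for b, s in zip(window.upper(), pattern.upper()))


def scan_oracle(contigs, protospacer, pam, max_mm, both_strands=True):
    """Exhaustive sliding-window search; returns {(contig, start, strand, mm)}."""
    hits = set()
    plen = len(protospacer)
    wlen = plen + len(pam)
    for cid, seq in contigs:
        s = seq.upper()
        for start in range(len(s) - wlen + 1):
            window = s[start : start + wlen]
            if pam_oracle(window[plen:], pam):
                mm = mm_oracle(window[:plen], protospacer)
                if mm <= max_mm:
                    hits.add((cid, start, "+", mm))
        if both_strands:
            r = revcomp(s)
            for start in range(len(r) - wlen + 1):
                window = r[start : start + wlen]
                if pam_oracle(window[plen:], pam):
                    mm = mm_oracle(window[:plen], protospacer)
                    if mm <= max_mm:
                        hits.add((cid, len(s) - start - wlen, "-", mm))
    return hits


def danger_table_oracle(site_rows, annotations_rows, m_max):
    """Triple loop over (gene, m, GO): {(go_id, m): n distinct genes}."""
    gene_go = {}
    for gene, go, *_ in annotations_rows:
        gene_go.setdefault(gene, set()).add(go)
    counts = {}
    seen = set()
    for gene, m in site_rows:
        if m > m_max or gene == "unidentified":
            continue
        for go in gene_go.get(gene, ()):
            if (go, m, gene) not in seen:
                seen.add((go, m, gene))
                counts[(go, m)] = counts.get((go, m), 0) + 1
    return counts


def d_index_oracle(counts: dict[int, int]) -> float:
    return sum(n * math.exp(4 - m) for m, n in counts.items())
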