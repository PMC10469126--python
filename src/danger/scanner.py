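"""Guide-RNA on/off-target site search on transcript sequences.

Scans every window of a (de novo assembled) transcriptome for
protospacer-like matches followed by a PAM, on both strands, counting
mismatches over the protospacer only.  The PAM is a hard IUPAC filter
(zero mismatch tolerance); a non-ACGT base in a contig counts as a
protospacer mismatch and never satisfies a PAM symbol.  Output rows use
the tab-delimited Cas-OFFinder convention: query sequence, contig id,
0-based forward-strand start of the protospacer+PAM window, the site
sequence read 5'->3' on the binding strand with mismatched protospacer
bases lowercased, strand and mismatch count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_ACGT = "ACGT"

# base -> code; 0..3 for ACGT (either case), 4 for anything else
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_ACGT):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# IUPAC symbol -> boolean over codes 0..4; code 4 (non-ACGT) never matches.
# "X" is a Biopython extension, not an IUPAC nucleotide code; excluded.
_IUPAC_OK: dict[str, np.ndarray] = {}
for _sym, _bases in ambiguous_dna_values.items():
    if _sym.upper() == "X":
        continue
    _row = np.zeros(5, dtype=bool)
    for _b in _bases:
        _row[_CODE[ord(_b)]] = True
    _IUPAC_OK[_sym.upper()] = _row


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class ScanError(ValueError):
    """Malformed guide, PAM pattern or candidate window."""


@dataclass(frozen=True)
class GuideSpec:
    """A guide: 19-20 nt protospacer (A/C/G/T only) plus an IUPAC PAM pattern."""

    protospacer: str
    pam_pattern: str = "NGG"
    guide_id: str = "guide"

    def __post_init__(self) -> None:
        proto = self.protospacer.upper()
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        if len(proto) not in (19, 20):
            raise ScanError(f"protospacer must be 19 or 20 nt, got {len(proto)}")
        if any(b not in _ACGT for b in proto):
            raise ScanError("protospacer may contain only A/C/G/T")
        if len(self.pam_pattern) < 2:
            raise ScanError("PAM pattern must be at least 2 symbols")
        for sym in self.pam_pattern:
            if sym not in _IUPAC_OK:
                raise ScanError(f"invalid IUPAC symbol in PAM pattern: {sym!r}")

    @property
    def window_length(self) -> int:
        return len(self.protospacer) + len(self.pam_pattern)


@dataclass(frozen=True)
class ScanConfig:
    """Search bounds: maximum protospacer mismatches, PAM pattern, strands."""

    max_mm: int = 8
    pam_pattern: str = "NGG"
    both_strands: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        if self.max_mm < 0:
            raise ScanError("max_mm must be >= 0")
        for sym in self.pam_pattern:
            if sym not in _IUPAC_OK:
                raise ScanError(f"invalid IUPAC symbol in PAM pattern: {sym!r}")


#: Named search presets: "optimized" = up-to-8-MM NGG, "approximate" = up-to-11-MM NRR.
SCAN_PRESETS: dict[str, ScanConfig] = {
    "optimized": ScanConfig(max_mm=8, pam_pattern="NGG"),
    "approximate": ScanConfig(max_mm=11, pam_pattern="NRR"),
}


@dataclass(frozen=True)
class Transcriptome:
    """Ordered collection of (contig_id, sequence) with unique ids."""

    contigs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise ScanError("contig ids must be unique")
        for cid, seq in self.contigs:
            if not seq:
                raise ScanError(f"empty sequence for contig {cid!r}")

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass(frozen=True)
class TargetSite:
    """One candidate guide-binding window on a contig.

    ``start`` is the 0-based forward-strand coordinate of the leftmost base
    of the protospacer+PAM window; the window occupies
    ``[start, start + len(site_sequence))``.  ``site_sequence`` is read
    5'->3' on the binding strand with mismatched protospacer bases
    lowercased.
    """

    contig_id: str
    start: int
    strand: str
    site_sequence: str
    mm_count: int
    is_on_target: bool = field(default=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "is_on_target", self.mm_count == 0)


def count_mismatches(candidate: str, protospacer: str) -> int:
    """Number of protospacer positions where the candidate differs.

    Case-insensitive; any non-ACGT candidate base counts as a mismatch.
    """
    if len(candidate) != len(protospacer):
        raise ScanError(
            f"window length {len(candidate)} != protospacer length {len(protospacer)}"
        )
    proto = protospacer.upper()
    if any(b not in _ACGT for b in proto):
        raise ScanError("protospacer may contain only A/C/G/T")
    cand = candidate.upper()
    return sum(1 for c, p in zip(cand, proto) if c != p or c not in _ACGT)


def match_pam(window: str, pam_pattern: str) -> bool:
    """True iff every window base is a concrete A/C/G/T inside the IUPAC
    set of the corresponding pattern symbol."""
    if len(window) != len(pam_pattern):
        raise ScanError("window and PAM pattern lengths differ")
    for base, sym in zip(window.upper(), pam_pattern.upper()):
        try:
            ok = _IUPAC_OK[sym]
        except KeyError:
            raise ScanError(f"invalid IUPAC symbol in PAM pattern: {sym!r}") from None
        if not ok[_CODE[ord(base)]]:
            return False
    return True


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _scan_forward(
    codes: np.ndarray, proto_codes: np.ndarray, pam_ok: np.ndarray, max_mm: int
) -> tuple[np.ndarray, np.ndarray]:
    """Starts and mismatch counts of qualifying windows on one strand.

    ``pam_ok`` is a (pam_len, 5) boolean lookup table.
    """
    plen = proto_codes.size
    wlen = plen + pam_ok.shape[0]
    n = codes.size - wlen + 1
    if n <= 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(codes, wlen)[:n]
    mm = (windows[:, :plen] != proto_codes).sum(axis=1)
    pam_hit = np.ones(n, dtype=bool)
    for j in range(pam_ok.shape[0]):
        pam_hit &= pam_ok[j][windows[:, plen + j]]
    keep = pam_hit & (mm <= max_mm)
    starts = np.nonzero(keep)[0]
    return starts, mm[starts]


def _format_site(window: str, protospacer: str) -> str:
    """Lowercase mismatched protospacer bases; PAM bases kept uppercase."""
    out = []
    for c, p in zip(window[: len(protospacer)].upper(), protospacer):
        out.append(c.lower() if (c != p or c not in _ACGT) else c)
    out.append(window[len(protospacer):].upper())
    return "".join(out)


def scan_transcriptome(
    transcriptome: Transcriptome | Sequence[tuple[str, str]],
    guide: GuideSpec,
    config: ScanConfig,
) -> list[TargetSite]:
    """All candidate sites for one guide on a transcriptome.

    Returns sites ordered by (contig order, start, strand), with '+' before
    '-'.  Contigs shorter than the protospacer+PAM window are skipped.
    """
    if not isinstance(transcriptome, Transcriptome):
        transcriptome = Transcriptome(tuple(transcriptome))
    proto = guide.protospacer
    proto_codes = _encode(proto)
    pam = config.pam_pattern
    pam_ok = np.stack([_IUPAC_OK[s] for s in pam])
    wlen = len(proto) + len(pam)

    sites: list[TargetSite] = []
    for contig_id, seq in transcriptome:
        if len(seq) < wlen:
            continue
        seq_u = seq.upper()
        codes = _encode(seq_u)
        hits: list[tuple[int, str, int]] = []  # (start, strand, mm)
        starts, mms = _scan_forward(codes, proto_codes, pam_ok, config.max_mm)
        hits.extend((int(s), "+", int(m)) for s, m in zip(starts, mms))
        if config.both_strands:
            rc = reverse_complement(seq_u)
            rc_codes = _encode(rc)
            starts, mms = _scan_forward(rc_codes, proto_codes, pam_ok, config.max_mm)
            L = len(seq_u)
            hits.extend(
                (L - int(s) - wlen, "-", int(m)) for s, m in zip(starts, mms)
            )
        hits.sort(key=lambda h: (h[0], h[1] != "+"))
        for start, strand, mm in hits:
            window = seq_u[start : start + wlen]
            binding = window if strand == "+" else reverse_complement(window)
            sites.append(
                TargetSite(
                    contig_id=contig_id,
                    start=start,
                    strand=strand,
                    site_sequence=_format_site(binding, proto),
                    mm_count=mm,
                )
            )
    return sites
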