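"""Seeded synthetic fixtures with exact planted ground truth.

Emulates the boundary at which the analysis starts: an assembled
transcriptome (contigs), per-sample TPM tables from wild-type and edited
replicates, a transcript-to-gene map and a gene-to-GO annotation table.
Guide-binding windows are planted with an exact number of protospacer
mismatches and a concrete PAM; every contig is rejection-checked with
the scanner so the emitted truth is exact, not probabilistic.  Replicate
noise is multiplicative log-normal parameterised by a coefficient of
variation, the simplest model consistent with TPM positivity.

What this generator does NOT emulate: read-level sampling, assembly
artefacts (chimeras, fragmented isoforms), library-size effects, or
correlated expression between transcripts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from . import io as dio
from .expression import ExpressionMatrix
from .scanner import (
    GuideSpec,
    ScanConfig,
    Transcriptome,
    reverse_complement,
    scan_transcriptome,
)

_BASES = "ACGT"

#: default guide used by the presets: a published SpCas9 guide sequence
DEFAULT_GUIDE = GuideSpec(
    protospacer="AGATTCTGGGTGGAAGCGCC", pam_pattern="NGG", guide_id="sim-guide"
)

PRESETS = ("strong", "null", "mixed")


class FixtureError(ValueError):
    """Infeasible planting specification."""


@dataclass
class FixtureTruth:
    """Ground truth of one synthetic dataset."""

    guide: GuideSpec
    planted_sites: list[dict]  # contig_id, start, strand, mm_count
    fold_changes: dict[str, float]  # transcript_id -> true fold change
    planted_term: str | None = None
    planted_genes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "guide": {
                "protospacer": self.guide.protospacer,
                "pam_pattern": self.guide.pam_pattern,
                "guide_id": self.guide.guide_id,
            },
            "planted_sites": self.planted_sites,
            "fold_changes": self.fold_changes,
            "planted_term": self.planted_term,
            "planted_genes": self.planted_genes,
        }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _concrete_pam(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(list(ambiguous_dna_values[s])) for s in pattern)


def _mutate_protospacer(rng: np.random.Generator, proto: str, mm: int) -> str:
    if mm > len(proto):
        raise FixtureError(f"cannot plant {mm} mismatches in a {len(proto)}-nt protospacer")
    positions = rng.choice(len(proto), size=mm, replace=False)
    seq = list(proto)
    for p in positions:
        seq[p] = rng.choice([b for b in _BASES if b != proto[p]])
    return "".join(seq)


def _build_contig(
    rng: np.random.Generator,
    length: int,
    guide: GuideSpec,
    plants: Sequence[tuple[int, str]],
    clean_mm: int,
) -> tuple[str, list[dict]]:
    """Random contig with the requested (mm_count, strand) windows planted.

    Rejection-sampled until the scanner finds exactly the planted sites at
    mismatch bound ``clean_mm``.
    """
    wlen = guide.window_length
    if length < (wlen + 10) * max(1, len(plants)):
        raise FixtureError("contig too short for the requested plantings")
    for _attempt in range(200):
        seq = _random_seq(rng, length)
        planted: list[dict] = []
        # non-overlapping slots, evenly spread
        slots = np.linspace(5, length - wlen - 5, num=max(1, len(plants)), dtype=int)
        for k, (mm, strand) in enumerate(plants):
            start = int(slots[k]) if len(plants) > 1 else int(rng.integers(5, length - wlen - 4))
            window = _mutate_protospacer(rng, guide.protospacer, mm) + _concrete_pam(
                rng, guide.pam_pattern
            )
            if strand == "-":
                window = reverse_complement(window)
            seq = seq[:start] + window + seq[start + wlen :]
            planted.append({"start": start, "strand": strand, "mm_count": mm})
        cfg = ScanConfig(max_mm=clean_mm, pam_pattern=guide.pam_pattern, both_strands=True)
        found = scan_transcriptome([("c", seq)], guide, cfg)
        found_set = {(s.start, s.strand, s.mm_count) for s in found}
        want_set = {(p["start"], p["strand"], p["mm_count"]) for p in planted if p["mm_count"] <= clean_mm}
        if found_set == want_set:
            return seq, planted
    raise FixtureError("could not build a clean contig in 200 attempts")


def generate_transcriptome(
    n_contigs: int,
    length_range: tuple[int, int],
    guide: GuideSpec,
    plant_spec: Sequence[tuple[int, int, str]],
    seed: int,
    clean_mm: int | None = None,
) -> tuple[Transcriptome, FixtureTruth]:
    """Random contigs with guide-binding windows planted per ``plant_spec``.

    ``plant_spec`` lists (mm_count, n_sites, strand) with strand '+', '-'
    or 'both' (random per site); each planted site goes on its own contig,
    assigned in order from contig 0.  ``clean_mm`` (default: the largest
    planted mm) is the mismatch bound below which contigs are guaranteed
    free of accidental extra sites.
    """
    rng = np.random.default_rng(seed)
    plants_flat: list[tuple[int, str]] = []
    for mm, n_sites, strand in plant_spec:
        for _ in range(n_sites):
            s = strand if strand in "+-" else ("+" if rng.random() < 0.5 else "-")
            plants_flat.append((mm, s))
    if len(plants_flat) > n_contigs:
        raise FixtureError("more planted sites than contigs")
    if clean_mm is None:
        clean_mm = max((mm for mm, _ in plants_flat), default=0)
    lo, hi = length_range
    contigs: list[tuple[str, str]] = []
    truth_sites: list[dict] = []
    for i in range(n_contigs):
        cid = f"tx_{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        plants = [plants_flat[i]] if i < len(plants_flat) else []
        seq, planted = _build_contig(rng, length, guide, plants, clean_mm)
        contigs.append((cid, seq))
        for p in planted:
            truth_sites.append({"contig_id": cid, **p})
    truth = FixtureTruth(guide=guide, planted_sites=truth_sites, fold_changes={})
    return Transcriptome(tuple(contigs)), truth


def generate_expression(
    transcript_ids: Sequence[str],
    n_wt: int,
    n_edited: int,
    base_tpm_range: tuple[float, float],
    fold_change_map: Mapping[str, float],
    noise_cv: float,
    seed: int,
) -> ExpressionMatrix:
    """Replicate TPM values with multiplicative log-normal noise.

    Wild-type replicates scatter around each transcript's base level;
    edited replicates around base x fold_change (1.0 where unmapped).
    ``noise_cv`` is the coefficient of variation of the noise (0 = exact).
    """
    if n_wt < 1 or n_edited < 1:
        raise ValueError("need at least one replicate per group")
    if noise_cv < 0 or base_tpm_range[0] < 0:
        raise ValueError("negative parameters are not allowed")
    rng = np.random.default_rng(seed)
    n_tx = len(transcript_ids)
    base = rng.uniform(base_tpm_range[0], base_tpm_range[1], size=n_tx)
    fc = np.array([fold_change_map.get(t, 1.0) for t in transcript_ids])
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0

    def noisy(mean_vec: np.ndarray, n_rep: int) -> np.ndarray:
        if sigma == 0.0:
            return np.tile(mean_vec[:, None], (1, n_rep))
        factors = np.exp(rng.normal(-sigma**2 / 2, sigma, size=(n_tx, n_rep)))
        return mean_vec[:, None] * factors

    wt = noisy(base, n_wt)
    ed = noisy(base * fc, n_edited)
    samples = [f"WT_{i+1}" for i in range(n_wt)] + [f"ED_{i+1}" for i in range(n_edited)]
    values = pd.DataFrame(
        np.hstack([wt, ed]), index=list(transcript_ids), columns=samples
    )
    groups = {s: (dio.WT_LABEL if s.startswith("WT_") else dio.EDITED_LABEL) for s in samples}
    return ExpressionMatrix(values=values, groups=groups)


def generate_annotations(
    gene_ids: Sequence[str],
    n_go_terms: int,
    terms_per_gene_range: tuple[int, int],
    seed: int,
    planted_term: str | None = None,
    planted_genes: Sequence[str] = (),
) -> pd.DataFrame:
    """Uniform random gene-to-GO assignment; the planted term (if any) is
    attached to exactly the planted genes and kept out of the random pool."""
    if n_go_terms < 1 or not gene_ids:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    cats = ["BP", "CC", "MF"]
    pool = [f"GO:{i + 2:07d}" for i in range(n_go_terms)]
    term_cat = {t: cats[i % 3] for i, t in enumerate(pool)}
    rows = []
    lo, hi = terms_per_gene_range
    for g in gene_ids:
        k = int(rng.integers(lo, hi + 1))
        for t in rng.choice(pool, size=min(k, len(pool)), replace=False):
            rows.append((g, t, f"synthetic term {t[-7:]}", term_cat[t]))
    if planted_term is not None:
        for g in planted_genes:
            rows.append((g, planted_term, "planted synthetic term", "BP"))
    df = pd.DataFrame(rows, columns=["gene_id", "go_id", "go_term", "category"])
    return df.drop_duplicates(subset=["gene_id", "go_id"]).reset_index(drop=True)


def generate_de_table(
    fold_change_map: Mapping[str, float],
    transcript_ids: Sequence[str],
    seed: int,
) -> pd.DataFrame:
    """Synthetic DE-result table consistent with the true fold changes.

    M-values are log2 fold changes with small noise; P-values are tiny for
    truly changed transcripts and near-uniform otherwise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in transcript_ids:
        fc = fold_change_map.get(t, 1.0)
        m = math.log2(fc) + rng.normal(0, 0.05)
        if fc < 0.5:
            p = 10.0 ** (-rng.uniform(4, 8))
        else:
            p = rng.uniform(0.02, 1.0)
        rows.append((t, m, p))
    return pd.DataFrame(rows, columns=["transcript_id", "m_value", "p_value"])


@dataclass
class SyntheticDataset:
    """A full synthetic input set plus its truth, writable to a directory."""

    transcriptome: Transcriptome
    expression: ExpressionMatrix
    de_table: pd.DataFrame
    gene_map: pd.DataFrame
    annotations: pd.DataFrame
    truth: FixtureTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "transcriptome.fasta",
            "expression": out / "expression.csv",
            "manifest": out / "samples.tsv",
            "de_table": out / "de_table.tsv",
            "gene_map": out / "gene_map.tsv",
            "annotations": out / "go_annotations.tsv",
            "truth": out / "truth.json",
        }
        dio.write_fasta(self.transcriptome, paths["fasta"])
        self.expression.values.rename_axis("transcript_id").to_csv(paths["expression"])
        pd.DataFrame(
            sorted(self.expression.groups.items()), columns=["sample_id", "group"]
        ).to_csv(paths["manifest"], sep="\t", index=False, header=False)
        self.de_table.to_csv(paths["de_table"], sep="\t", index=False)
        self.gene_map.to_csv(paths["gene_map"], sep="\t", index=False)
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        paths["truth"].write_text(json.dumps(self.truth.as_dict(), indent=1, sort_keys=True))
        return paths


def _preset_params(preset: str) -> dict:
    common = dict(
        n_contigs=120,
        length_range=(1800, 2200),
        n_wt=3,
        n_edited=3,
        base_tpm_range=(20.0, 200.0),
        noise_cv=0.1,
        n_go_terms=30,
        terms_per_gene_range=(1, 4),
    )
    if preset == "strong":
        return common | dict(
            planted_mm=[(1, 6), (2, 6), (3, 5), (4, 5)],
            n_background_sites=40,
            background_mm=(5, 8),
            background_down_fraction=0.10,
            planted_fc=0.15,
            background_fc=0.25,
            planted_term="GO:0000001",
        )
    if preset == "mixed":
        return common | dict(
            planted_mm=[(1, 6), (2, 6), (3, 5), (4, 5)],
            n_background_sites=60,
            background_mm=(5, 8),
            background_down_fraction=0.25,
            planted_fc=0.15,
            background_fc=0.25,
            planted_term="GO:0000001",
        )
    if preset == "null":
        # dense regime: each GO term must aggregate many flagged-site genes
        # for its score to sit in the regime the permutation bound
        # calibrates (genome-scale data reaches this with thousands of
        # genes per term); a sparse null fixture would make every observed
        # score a conditioned-on-nonzero rare event
        return common | dict(
            planted_mm=[],
            n_background_sites=100,
            background_mm=(3, 8),
            background_down_fraction=0.30,
            planted_fc=0.15,
            background_fc=0.25,
            planted_term=None,
            n_go_terms=12,
            terms_per_gene_range=(2, 5),
        )
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def make_fixture(preset: str, seed: int, guide: GuideSpec = DEFAULT_GUIDE) -> SyntheticDataset:
    """Build a complete synthetic dataset for one preset.

    'strong': low-mismatch deleterious sites concentrated on genes
    sharing one GO term, weak background.  'null': sites, flags and GO
    terms mutually independent.  'mixed': the strong signal over a
    heavier background.
    """
    p = _preset_params(preset)
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]

    # plant list: on-target + a 3-MM site on a second isoform of the
    # on-target gene (exercises gene-level exclusion), then signal sites,
    # then scattered background sites
    plant_spec: list[tuple[int, int, str]] = [(0, 1, "+"), (3, 1, "both")]
    for mm, n in p["planted_mm"]:
        plant_spec.append((mm, n, "both"))
    bg_lo, bg_hi = p["background_mm"]
    bg_mms = rng.integers(bg_lo, bg_hi + 1, size=p["n_background_sites"])
    for mm in bg_mms:
        plant_spec.append((int(mm), 1, "both"))

    transcriptome, truth = generate_transcriptome(
        n_contigs=p["n_contigs"],
        length_range=p["length_range"],
        guide=guide,
        plant_spec=plant_spec,
        seed=sub[0],
        clean_mm=8,
    )
    tx_ids = [cid for cid, _ in transcriptome]

    # gene map: contigs 0 and 1 are isoforms of the on-target gene
    gene_of = {tx_ids[0]: "gene_0000", tx_ids[1]: "gene_0000"}
    for i, t in enumerate(tx_ids[2:], start=1):
        gene_of[t] = f"gene_{i:04d}"
    gene_map = pd.DataFrame(
        {"transcript_id": tx_ids, "gene_id": [gene_of[t] for t in tx_ids]}
    )

    n_signal = sum(n for _, n in p["planted_mm"])
    signal_tx = tx_ids[2 : 2 + n_signal]
    planted_genes = sorted({gene_of[t] for t in signal_tx})
    background_tx = tx_ids[2 + n_signal :]

    # fold changes: on-target isoforms down (the edit itself), signal genes
    # strongly down, a random background fraction mildly down
    fc: dict[str, float] = {tx_ids[0]: 0.1, tx_ids[1]: 0.1}
    for t in signal_tx:
        fc[t] = p["planted_fc"]
    n_bg_down = int(round(p["background_down_fraction"] * len(background_tx)))
    for t in rng.choice(background_tx, size=n_bg_down, replace=False):
        fc[str(t)] = p["background_fc"]
    truth.fold_changes = fc
    truth.planted_term = p["planted_term"]
    truth.planted_genes = planted_genes if p["planted_term"] else []

    expression = generate_expression(
        tx_ids,
        n_wt=p["n_wt"],
        n_edited=p["n_edited"],
        base_tpm_range=p["base_tpm_range"],
        fold_change_map=fc,
        noise_cv=p["noise_cv"],
        seed=sub[1],
    )
    annotations = generate_annotations(
        gene_ids=sorted(set(gene_of.values())),
        n_go_terms=p["n_go_terms"],
        terms_per_gene_range=p["terms_per_gene_range"],
        seed=sub[2],
        planted_term=p["planted_term"],
        planted_genes=truth.planted_genes,
    )
    de_table = generate_de_table(fc, tx_ids, seed=sub[3])
    return SyntheticDataset(
        transcriptome=transcriptome,
        expression=expression,
        de_table=de_table,
        gene_map=gene_map,
        annotations=annotations,
        truth=truth,
    )
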