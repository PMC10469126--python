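"""End-to-end orchestration: scan -> screen -> deleterious -> DANGER table
-> D-index -> permutation validation -> false-detection report.

Intermediate files are the contract between stages; a run writes every
stage's table plus a manifest recording the configuration, the seeds and
SHA-256 checksums of the inputs.  Identical configuration and inputs
yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as dio
from .deleterious import (
    annotation_summary,
    attach_genes,
    exclude_on_target,
    find_deleterious,
)
from .dindex import d_index_profile
from .expression import ClassifierConfig, ExpressionMatrix, screen_expression
from .ontology import build_danger_table
from .scanner import GuideSpec, ScanConfig, scan_transcriptome
from .validation import (
    ValidationConfig,
    build_null,
    call_significance,
    estimate_false_detection,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


#: named parameter presets: (PAM, max mismatches, criterion, threshold, L)
PRESETS: dict[str, dict] = {
    "approximate_dtpm": dict(pam="NRR", max_mm=11, criterion="dTPM", t=0.4, L=5e-1),
    "optimized_dtpm": dict(pam="NGG", max_mm=8, criterion="dTPM", t=0.4, L=1e-15),
    "optimized_dde": dict(pam="NGG", max_mm=8, criterion="dDE", alpha=0.001, L=1e-15),
}


@dataclass
class RunConfig:
    """Everything one run needs: input paths, guide, stage parameters."""

    fasta: str
    expression: str  # matrix CSV
    manifest: str  # sample -> group TSV
    gene_map: str
    annotations: str
    protospacer: str
    out_dir: str = "danger_out"
    de_table: str | None = None
    guide_id: str = "guide"
    pam_pattern: str = "NGG"
    scan: ScanConfig = field(default_factory=ScanConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    criterion: str = "dTPM"
    target_gene: str | None = None  # default: genes of all 0-MM sites

    @classmethod
    def with_preset(cls, preset: str, **kwargs) -> "RunConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        p = PRESETS[preset]
        seed = kwargs.pop("base_seed", 0)
        cfg = cls(
            pam_pattern=p["pam"],
            scan=ScanConfig(max_mm=p["max_mm"], pam_pattern=p["pam"]),
            classifier=ClassifierConfig(t=p.get("t", 0.4), alpha=p.get("alpha", 0.001)),
            validation=ValidationConfig(L=p["L"], base_seed=seed),
            criterion=p["criterion"],
            **kwargs,
        )
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: str | None, stage: str, what: str) -> Path:
    if path is None:
        raise PipelineError(stage, f"{what} not configured")
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"{what} not found: {p}")
    return p


@dataclass
class RunResult:
    """In-memory stage outputs of one pipeline run."""

    sites: pd.DataFrame
    screen: pd.DataFrame
    deleterious: pd.DataFrame
    danger_table: pd.DataFrame
    d_index: pd.DataFrame
    total_d_index: float
    n_d_indices: int
    significance: pd.DataFrame
    fdr: dict
    out_dir: Path


@dataclass
class AnalysisResult:
    """In-memory results of ``analyze_dataset`` (no files written)."""

    sites: pd.DataFrame
    off_sites: pd.DataFrame  # gene-annotated, on-target-excluded
    screen: pd.DataFrame
    flags: pd.Series
    deleterious: pd.DataFrame
    danger_table: pd.DataFrame
    d_index: pd.DataFrame
    total_d_index: float
    n_d_indices: int


def analyze_dataset(
    transcriptome,
    guide: GuideSpec,
    matrix: ExpressionMatrix,
    gene_map: pd.DataFrame,
    annotations: pd.DataFrame,
    scan_config: ScanConfig,
    classifier: ClassifierConfig = ClassifierConfig(),
    criterion: str = "dTPM",
    de_table: pd.DataFrame | None = None,
    target_gene: str | None = None,
) -> AnalysisResult:
    """Run scan -> screen -> deleterious -> DANGER table -> D-index in memory.

    The returned ``off_sites`` and ``flags`` are exactly the profiles the
    permutation validation shuffles.
    """
    sites_list = scan_transcriptome(transcriptome, guide, scan_config)
    sites = dio.sites_to_frame(sites_list, guide)
    screen = screen_expression(matrix, classifier, de_table)
    annotated = attach_genes(sites, gene_map)
    on_target = annotated[annotated["mm_count"] == 0]
    if target_gene is not None:
        on_target = on_target[on_target["gene_id"] == target_gene]
    off_sites = exclude_on_target(annotated, on_target, gene_map)
    deleterious = find_deleterious(off_sites, screen, criterion)
    danger_table = build_danger_table(deleterious, annotations, scan_config.max_mm)
    d_index, total_d, n_terms = d_index_profile(danger_table, scan_config.max_mm)
    if criterion == "dTPM":
        flag_values = screen["dtpm"]
    elif criterion == "dDE":
        flag_values = screen["dde"]
    else:
        flag_values = screen["dtpm"] | screen["dde"]
    flags = pd.Series(flag_values.values, index=screen["transcript_id"].values)
    return AnalysisResult(
        sites=sites,
        off_sites=off_sites,
        screen=screen,
        flags=flags,
        deleterious=deleterious,
        danger_table=danger_table,
        d_index=d_index,
        total_d_index=total_d,
        n_d_indices=n_terms,
    )


def run_pipeline(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    # --- scan ---------------------------------------------------------
    stage = "scan"
    fasta = _require(config.fasta, stage, "transcriptome FASTA")
    inputs["fasta"] = _sha256(fasta)
    try:
        transcriptome = dio.read_fasta(fasta)
        guide = GuideSpec(
            protospacer=config.protospacer,
            pam_pattern=config.pam_pattern,
            guide_id=config.guide_id,
        )
        sites_list = scan_transcriptome(transcriptome, guide, config.scan)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    sites = dio.sites_to_frame(sites_list, guide)
    dio.write_sites(sites, guide, out / "sites.tsv")
    logger.info("[scan] %d candidate sites", len(sites))

    # --- screen -------------------------------------------------------
    stage = "screen"
    expr_path = _require(config.expression, stage, "expression matrix")
    manifest_path = _require(config.manifest, stage, "sample manifest")
    inputs["expression"] = _sha256(expr_path)
    inputs["manifest"] = _sha256(manifest_path)
    try:
        values = dio.read_expression_csv(expr_path)
        groups = dio.read_sample_manifest(manifest_path)
        matrix = ExpressionMatrix(values=values, groups=groups)
        de_table = None
        if config.de_table is not None:
            de_path = _require(config.de_table, stage, "DE table")
            inputs["de_table"] = _sha256(de_path)
            de_table = dio.read_de_table(de_path)
        elif config.criterion == "dDE":
            raise PipelineError(stage, "criterion dDE requires a DE table")
        screen = screen_expression(matrix, config.classifier, de_table)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    screen.to_csv(out / "screen.csv", index=False)

    # --- deleterious --------------------------------------------------
    stage = "deleterious"
    gene_map_path = _require(config.gene_map, stage, "gene map")
    inputs["gene_map"] = _sha256(gene_map_path)
    try:
        gene_map = dio.read_gene_map(gene_map_path)
        annotated = attach_genes(sites, gene_map)
        if config.target_gene is not None:
            on_target = annotated[
                (annotated["mm_count"] == 0)
                & (annotated["gene_id"] == config.target_gene)
            ]
        else:
            on_target = annotated[annotated["mm_count"] == 0]
        off_sites = exclude_on_target(annotated, on_target, gene_map)
        deleterious = find_deleterious(off_sites, screen, config.criterion)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    deleterious.to_csv(out / "deleterious.csv", index=False)
    annotation_summary(deleterious).to_csv(out / "deleterious_summary.csv", index=False)
    if deleterious.empty:
        logger.warning("[deleterious] no deleterious sites; downstream tables empty")

    # --- danger-table / d-index --------------------------------------
    stage = "danger-table"
    ann_path = _require(config.annotations, stage, "GO annotation table")
    inputs["annotations"] = _sha256(ann_path)
    try:
        annotations = dio.read_go_annotations(ann_path)
        danger_table = build_danger_table(deleterious, annotations, config.scan.max_mm)
        d_index, total_d, n_terms = d_index_profile(danger_table, config.scan.max_mm)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    danger_table.to_csv(out / "danger_table.csv", index=False)
    d_index.to_csv(out / "d_index.csv", index=False)
    pd.DataFrame(
        {"total_d_index": [total_d], "n_d_indices": [n_terms]}
    ).to_csv(out / "d_index_summary.csv", index=False)

    # --- validate / fdr ----------------------------------------------
    stage = "validate"
    try:
        flag_col = "dtpm" if config.criterion == "dTPM" else "dde"
        if config.criterion == "either":
            flags = pd.Series(
                (screen["dtpm"] | screen["dde"]).values,
                index=screen["transcript_id"].values,
            )
        else:
            flags = pd.Series(
                screen[flag_col].values, index=screen["transcript_id"].values
            )
        null = build_null(
            d_index, flags, off_sites, annotations, config.scan.max_mm,
            config.validation,
        )
        significance = call_significance(d_index, null, config.validation.L)
        fdr = estimate_false_detection(
            d_index, null, flags, off_sites, annotations, config.scan.max_mm,
            config.validation,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    sig_cols = ["go_id", "go_term", "category", "d_index", "null_mean", "null_sd",
                "threshold", "significant"]
    significance[sig_cols].to_csv(out / "significance.csv", index=False)
    (out / "fdr.json").write_text(json.dumps(fdr.as_dict(), indent=1, sort_keys=True))

    manifest = {
        "config": {
            **{k: v for k, v in asdict(config).items()
               if k not in ("scan", "classifier", "validation", "out_dir")},
            "scan": asdict(config.scan),
            "classifier": asdict(config.classifier),
            "validation": asdict(config.validation),
        },
        "seeds": {
            "null": list(config.validation.null_seeds),
            "extra": list(config.validation.extra_seeds),
        },
        "input_sha256": inputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return RunResult(
        sites=sites,
        screen=screen,
        deleterious=deleterious,
        danger_table=danger_table,
        d_index=d_index,
        total_d_index=total_d,
        n_d_indices=n_terms,
        significance=significance,
        fdr=fdr.as_dict(),
        out_dir=out,
    )
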