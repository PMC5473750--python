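"""End-to-end orchestration with config snapshots and logging.

``run_pipeline`` chains the stages — (optional) simulation, LOCO kinship,
per-trait genome scan with BH adjustment, QTL calling and cross-trait
merging, the BSR-seq allele-frequency arm, and candidate cross-referencing
— writing every stage output plus a machine-readable config snapshot and a
log of versions, seeds and filter counts into a run directory.  Any stage
error aborts the run with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bsr import af_test, candidates_to_frame, cross_reference, estimate_qvalues, filter_pool_snps
from .io import (
    read_gene_intervals,
    read_genotypes,
    read_phenotypes,
    read_pool_counts,
    write_regions,
    write_scan,
)
from .kinship import compute_loco_kinship
from .scan import call_qtl, merge_regions, scan_all_traits


@dataclass
class RunConfig:
    """Paths, thresholds and mode flags for a full pipeline run.

    Threshold defaults follow the analysis the pipeline implements: scan
    q <= 0.5 for QTL retention, per-pool SNP depth >= 10, allele-frequency
    FDR < 0.001, expression ratio > 5, -log10 p > 6 for QTL/BSR
    cross-referencing with a 15 kb gene flank.
    """

    genotypes: str
    phenotypes: str
    out_dir: str
    pool_vcf: str | None = None
    annotations: str | None = None
    de_genes: str | None = None
    traits: list[str] | None = None
    q_threshold: float = 0.5
    min_reads: int = 10
    af_fdr: float = 0.001
    ratio_threshold: float = 5.0
    neglog10p_min: float = 6.0
    flank: int = 15_000
    max_gap: int = 0
    scan_mode: str = "exact"
    qvalue_method: str = "storey"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold <= 1):
            raise ValueError("q_threshold must lie in (0, 1]")
        if self.min_reads < 0 or self.flank < 0 or self.max_gap < 0:
            raise ValueError("min_reads, flank and max_gap must be non-negative")
        if not (0 < self.af_fdr <= 1):
            raise ValueError("af_fdr must lie in (0, 1]")
        if self.ratio_threshold <= 1:
            raise ValueError("ratio_threshold must exceed 1")
        if self.scan_mode not in ("exact", "fast"):
            raise ValueError("scan_mode must be 'exact' or 'fast'")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


def run_pipeline(config: RunConfig) -> Path:
    """Run every configured stage; returns the populated run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"mpqtl {__version__} on python {platform.python_version()}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed {config.seed}",
    ]
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2) + "\n"
    )

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except FileNotFoundError as exc:
                raise StageError(name, exc) from exc
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrap

    geno = stage("load-genotypes")(read_genotypes, config.genotypes)
    log_lines.append(
        f"genotypes: {geno.n_segregants} segregants x {geno.n_markers} markers, "
        f"founders {','.join(geno.founder_labels)}"
    )
    pheno = stage("load-phenotypes")(read_phenotypes, config.phenotypes)
    log_lines.append(f"phenotypes: {len(pheno.trait_names)} traits")

    kin = stage("kinship")(compute_loco_kinship, geno)
    log_lines.append(f"kinship: {len(kin.chromosomes)} LOCO matrices")

    traits = config.traits or pheno.trait_names
    scan_df = stage("scan")(
        scan_all_traits, pheno, geno, kin, traits=traits, mode=config.scan_mode
    )
    write_scan(scan_df, out / "scan.tsv")
    n_tested = int((scan_df["status"] == "ok").sum())
    log_lines.append(
        f"scan: {len(traits)} traits, {len(scan_df)} marker tests "
        f"({n_tested} testable), mode={config.scan_mode}"
    )

    regions = stage("call-qtl")(
        call_qtl, scan_df, q_threshold=config.q_threshold, max_gap=config.max_gap
    )
    merged = stage("merge-regions")(merge_regions, regions)
    write_regions(merged, out / "regions.bed")
    log_lines.append(
        f"qtl: {len(regions)} per-trait regions -> {len(merged)} merged regions "
        f"at q <= {config.q_threshold}"
    )

    af_df = None
    if config.pool_vcf is not None:
        counts = stage("bsr-load")(read_pool_counts, config.pool_vcf)
        filtered, report = stage("bsr-filter")(
            filter_pool_snps, counts, min_reads=config.min_reads
        )
        log_lines.append(
            f"bsr filter: {report.n_input} SNPs in, {report.n_retained} retained "
            f"({report.n_absent_from_pool} absent from a pool, "
            f"{report.n_low_depth} low depth, "
            f"{counts.n_multiallelic_skipped} multi-allelic skipped)"
        )
        af_df = stage("bsr-test")(af_test, filtered)
        af_df["q_value"] = stage("bsr-qvalues")(
            estimate_qvalues, af_df["p_value"].to_numpy(), config.qvalue_method
        )
        af_df.to_csv(out / "af.tsv", sep="\t", index=False, float_format="%.17g")
        n_sig = int((af_df["q_value"] <= config.af_fdr).sum())
        log_lines.append(f"bsr: {n_sig} SNPs significant at FDR <= {config.af_fdr}")

    if config.annotations is not None:
        ann = stage("crossref-load")(read_gene_intervals, config.annotations)
        de = None
        if config.de_genes is not None:
            de = [
                line.strip()
                for line in Path(config.de_genes).read_text().splitlines()
                if line.strip() and not line.startswith("#")
            ]
        candidates = stage("crossref")(
            cross_reference,
            scan_df,
            ann,
            af_results=af_df,
            de_genes=de,
            neglog10p_min=config.neglog10p_min,
            flank=config.flank,
            af_q_max=config.af_fdr,
        )
        candidates_to_frame(candidates).to_csv(
            out / "candidates.tsv", sep="\t", index=False
        )
        log_lines.append(f"crossref: {len(candidates)} candidate genes")

    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
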