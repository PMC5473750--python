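"""Bulk-segregant RNA-seq (BSR-seq) allele-frequency arm.

Pooled SNP read counts from two high- and two low-ammonium-consumption
replicate pools are filtered for coverage, tested for allele-frequency
differences between conditions with Fisher's exact test (replicates summed
within condition), FDR-adjusted with Storey q-values, and cross-referenced
with the genome scan: candidate genes are those whose (flanked) interval
contains a strongly associated marker and that also carry allele-frequency
or expression evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .io import HLA_POOLS, LLA_POOLS, POOLS, PoolAlleleCounts


@dataclass
class FilterReport:
    """Tally of SNPs removed by each coverage rule."""

    n_input: int
    n_retained: int
    n_absent_from_pool: int
    n_low_depth: int


def filter_pool_snps(
    counts: PoolAlleleCounts, min_reads: int = 10, strict: bool = False
) -> tuple[PoolAlleleCounts, FilterReport]:
    """Retain high-quality SNPs covered in all four pools.

    Default rule: total (ref + alt) depth >= ``min_reads`` in every pool,
    and the SNP observed (depth > 0) in all four pools.  ``strict=True``
    instead requires >= ``min_reads`` for the reference *and* alternative
    allele separately in every pool; the default reading keeps pool-fixed
    SNPs, which are the most informative for bulk-segregant contrasts.
    """
    depths = np.column_stack([counts.depth(p) for p in POOLS])
    present = (depths > 0).all(axis=1)
    if strict:
        refs = np.column_stack([counts.ref(p) for p in POOLS])
        alts = np.column_stack([counts.alt(p) for p in POOLS])
        deep = ((refs >= min_reads) & (alts >= min_reads)).all(axis=1)
    else:
        deep = (depths >= min_reads).all(axis=1)
    keep = present & deep
    report = FilterReport(
        n_input=len(counts),
        n_retained=int(keep.sum()),
        n_absent_from_pool=int((~present).sum()),
        n_low_depth=int((present & ~deep).sum()),
    )
    filtered = PoolAlleleCounts(
        counts.table.loc[keep].reset_index(drop=True),
        n_multiallelic_skipped=counts.n_multiallelic_skipped,
    )
    return filtered, report


def fisher_p(table: np.ndarray) -> tuple[float, bool]:
    """Two-sided Fisher exact p for a 2x2 count table.

    Returns ``(p, degenerate)``; a zero margin makes the table
    uninformative and yields p = 1 with the degenerate flag set.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    degenerate = bool((t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any())
    if degenerate:
        return 1.0, True
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(min(max(p, 5e-324), 1.0)), False


def af_test(
    counts: PoolAlleleCounts, mode: str = "summed"
) -> pd.DataFrame:
    """Fisher allele-frequency tests for every (filtered) SNP.

    ``mode="summed"`` (default) sums replicate pools within each condition
    and tests one (ref, alt) x (HLA, LLA) table per SNP.
    ``mode="per-replicate"`` tests replicate pairs (HLA-i vs LLA-i)
    separately and reports the larger (more conservative) p.

    Output columns: the SNP key, condition counts, ``p_value``,
    ``direction`` (condition enriched for the reference allele, or ``.``)
    and ``degenerate``.
    """
    if mode not in ("summed", "per-replicate"):
        raise ValueError(f"unknown AF test mode {mode!r}")
    hla_ref, hla_alt = counts.condition_counts("HLA")
    lla_ref, lla_alt = counts.condition_counts("LLA")
    n = len(counts)
    p_values = np.empty(n)
    degenerate = np.zeros(n, dtype=bool)
    for i in range(n):
        if mode == "summed":
            p, dg = fisher_p(
                [[hla_ref[i], hla_alt[i]], [lla_ref[i], lla_alt[i]]]
            )
        else:
            ps, dgs = [], []
            for h, l in zip(HLA_POOLS, LLA_POOLS):
                p_i, dg_i = fisher_p(
                    [
                        [counts.ref(h)[i], counts.alt(h)[i]],
                        [counts.ref(l)[i], counts.alt(l)[i]],
                    ]
                )
                ps.append(p_i)
                dgs.append(dg_i)
            p, dg = max(ps), all(dgs)
        p_values[i] = p
        degenerate[i] = dg

    with np.errstate(divide="ignore", invalid="ignore"):
        hla_f = hla_ref / (hla_ref + hla_alt)
        lla_f = lla_ref / (lla_ref + lla_alt)
    direction = np.where(hla_f > lla_f, "HLA", np.where(lla_f > hla_f, "LLA", "."))
    out = counts.table[["chrom", "pos", "ref", "alt"]].copy()
    out["HLA.ref"] = hla_ref
    out["HLA.alt"] = hla_alt
    out["LLA.ref"] = lla_ref
    out["LLA.alt"] = lla_alt
    out["p_value"] = p_values
    out["direction"] = direction
    out["degenerate"] = degenerate
    return out


_DEFAULT_LAMBDAS = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(p_values: np.ndarray, lambdas: np.ndarray = _DEFAULT_LAMBDAS) -> float:
    """Estimate the null proportion pi0 by the smoother method.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is smoothed with a
    cubic spline over the lambda grid and evaluated at the largest lambda;
    the estimate is clipped into (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return 1.0
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if len(lambdas) >= 4:
        spline = interpolate.UnivariateSpline(lambdas, pi0_l, k=3)
        pi0 = float(spline(lambdas[-1]))
    else:
        pi0 = float(pi0_l[-1])
    return float(np.clip(pi0, 1.0 / m, 1.0))


def estimate_qvalues(
    p_values: np.ndarray,
    method: str = "storey",
    lambdas: np.ndarray = _DEFAULT_LAMBDAS,
) -> np.ndarray:
    """Storey q-values (default) or BH step-up adjusted p-values.

    The Storey estimate is the BH step-up scaled by the estimated null
    proportion pi0, so it is never larger than the BH value.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    if p.min() <= 0 or p.max() > 1:
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        from .scan import bh_qvalues

        return bh_qvalues(p)
    if method != "storey":
        raise ValueError(f"unknown q-value method {method!r}")
    m = len(p)
    pi0 = estimate_pi0(p, lambdas)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def expression_ratio(
    genes, pseudocount: float = 1.0, ratio_threshold: float = 5.0
) -> pd.DataFrame:
    """Bulk expression frequency ratios between conditions (HLA/LLA).

    Counts are library-size normalized (scaled to equal per-pool totals),
    summed within condition, and the pseudocounted ratio computed; genes
    with ratio beyond the threshold in either direction are flagged with
    the enriched condition.
    """
    table = genes.table if hasattr(genes, "table") else genes
    counts = table[list(POOLS)].to_numpy(float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a pool has zero total gene counts")
    norm = counts * (totals.mean() / totals)[None, :]
    hla = norm[:, [POOLS.index(p) for p in HLA_POOLS]].sum(axis=1)
    lla = norm[:, [POOLS.index(p) for p in LLA_POOLS]].sum(axis=1)
    ratio = (hla + pseudocount) / (lla + pseudocount)
    extreme = (ratio > ratio_threshold) | (ratio < 1.0 / ratio_threshold)
    out = pd.DataFrame(
        {
            "gene_id": table["gene_id"],
            "HLA": hla,
            "LLA": lla,
            "ratio": ratio,
            "extreme": extreme,
            "direction": np.where(ratio > 1, "HLA", np.where(ratio < 1, "LLA", ".")),
        }
    )
    out.loc[~extreme, "direction"] = "."
    return out


@dataclass
class CandidateGene:
    """A gene with combined scan + BSR-seq evidence."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    in_qtl: bool
    af_significant: bool
    ratio_extreme: bool
    de_listed: bool
    qtl_traits: list[str]

    @property
    def flags(self) -> dict[str, bool]:
        return {
            "in_QTL": self.in_qtl,
            "AF_significant": self.af_significant,
            "ratio_extreme": self.ratio_extreme,
            "DE_listed": self.de_listed,
        }


def cross_reference(
    scan_df: pd.DataFrame,
    annotations: pd.DataFrame,
    af_results: pd.DataFrame | None = None,
    de_genes: Iterable[str] | None = None,
    ratio_genes: Iterable[str] | None = None,
    neglog10p_min: float = 6.0,
    flank: int = 15_000,
    af_q_max: float = 0.001,
) -> list[CandidateGene]:
    """Intersect strong scan signals with BSR-seq evidence per gene.

    A gene is ``in_QTL`` when its interval, extended by ``flank`` bp up-
    and downstream, contains a marker with ``-log10 p > neglog10p_min`` for
    any trait.  ``AF_significant`` requires a SNP with ``q_value <=
    af_q_max`` inside the (unflanked) gene interval.  Returned candidates
    carry at least one evidence flag.
    """
    ann_chroms = set(annotations["chromosome"].astype(str))
    marker_chroms = set(scan_df["chromosome"].astype(str))
    unmatched = sorted(ann_chroms - marker_chroms)
    if unmatched:
        raise ValueError(
            f"annotation chromosomes {unmatched} not present among scan "
            f"markers (chromosome naming mismatch?)"
        )

    ok = scan_df[scan_df["status"] == "ok"].copy()
    ok = ok[np.isfinite(ok["p_value"])]
    passing = ok[-np.log10(ok["p_value"]) > neglog10p_min]

    de_set = set(de_genes) if de_genes is not None else set()
    ratio_set = set(ratio_genes) if ratio_genes is not None else set()

    candidates: list[CandidateGene] = []
    for _, gene in annotations.iterrows():
        chrom = str(gene["chromosome"])
        gstart, gend = int(gene["start"]), int(gene["end"])
        hits = passing[
            (passing["chromosome"].astype(str) == chrom)
            & (passing["position"] >= gstart - flank)
            & (passing["position"] <= gend + flank)
        ]
        in_qtl = len(hits) > 0
        qtl_traits = sorted(hits["trait"].unique()) if in_qtl else []

        af_sig = False
        if af_results is not None and "q_value" in af_results.columns:
            snps = af_results[
                (af_results["chrom"].astype(str) == chrom)
                & (af_results["pos"] >= gstart)
                & (af_results["pos"] <= gend)
            ]
            af_sig = bool((snps["q_value"] <= af_q_max).any())

        gid = str(gene["gene_id"])
        cand = CandidateGene(
            gene_id=gid,
            chromosome=chrom,
            start=gstart,
            end=gend,
            in_qtl=in_qtl,
            af_significant=af_sig,
            ratio_extreme=gid in ratio_set,
            de_listed=gid in de_set,
            qtl_traits=qtl_traits,
        )
        if in_qtl and (af_sig or cand.de_listed or cand.ratio_extreme):
            candidates.append(cand)
    return candidates


def candidates_to_frame(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "chromosome": c.chromosome,
            "start": c.start,
            "end": c.end,
            "in_QTL": c.in_qtl,
            "AF_significant": c.af_significant,
            "ratio_extreme": c.ratio_extreme,
            "DE_listed": c.de_listed,
            "qtl_traits": ",".join(c.qtl_traits),
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chromosome", "start", "end", "in_QTL",
            "AF_significant", "ratio_extreme", "DE_listed", "qtl_traits",
        ],
    )
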