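"""Per-marker genome scan, FDR adjustment and QTL region calling.

For every testable segregating site the scan drops segregants with a
missing call or phenotype, rebuilds the covariate and allele designs,
estimates the variance components by REML against the kinship of the
remaining chromosomes, and applies the Wald test to the parental-allele
block.  p-value vectors are adjusted per trait with the Benjamini-Hochberg
step-up; runs of markers at or below the q threshold become QTL regions
whose peak is the minimum-p marker, and regions from different traits are
merged on bp overlap into major QTL regions.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import (
    FounderGenotypeTable,
    MISSING_CODE,
    PhenotypeTable,
    QTLRegion,
    SCAN_COLUMNS,
)
from .kinship import LocoKinshipSet
from .lmm import SingularDesignError, fit_reml, psd_eigh, wald_test

MIN_NONMISSING = 30


def build_covariate_design(
    covariates: pd.DataFrame,
    combo_columns: Sequence[str] = ("lys2", "ura3"),
    extra_columns: Sequence[str] = ("mating_type",),
    max_combinations: int = 4,
) -> tuple[np.ndarray, list[str]]:
    """Covariate fixed-effect design matrix.

    The auxotrophy markers form a full membership indicator over their
    observed combinations (rows sum to 1, so the block spans the intercept;
    empty combinations are dropped).  Mating type, which the model lists
    alongside them, contributes additional indicator columns only where
    they increase the design rank — with four LYS2/URA3 combinations and a
    2:2 mating-type segregation the extra column is usually collinear.
    """
    combo_cols = [c for c in combo_columns if c in covariates.columns]
    if combo_cols:
        combo = covariates[combo_cols].astype(str).agg("|".join, axis=1)
        levels = sorted(combo.unique())
        if len(levels) > max_combinations:
            raise ValueError(
                f"{len(levels)} covariate combinations exceed the declared "
                f"maximum of {max_combinations}"
            )
        M = np.column_stack([(combo == lv).to_numpy(float) for lv in levels])
        names = [f"combo[{lv}]" for lv in levels]
    else:
        M = np.ones((len(covariates), 1))
        names = ["intercept"]
    rank = np.linalg.matrix_rank(M)
    for col in extra_columns:
        if col not in covariates.columns:
            continue
        for lv in sorted(covariates[col].astype(str).unique()):
            cand = (covariates[col].astype(str) == lv).to_numpy(float)[:, None]
            trial = np.hstack([M, cand])
            r = np.linalg.matrix_rank(trial)
            if r > rank:
                M, rank = trial, r
                names.append(f"{col}[{lv}]")
    return M, names


def _allele_design(codes_at_marker: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indicator design over the distinct founder alleles observed.

    Returns (n_eff x q matrix, array of the q founder codes in column order).
    """
    alleles = np.unique(codes_at_marker)
    Xq = (codes_at_marker[:, None] == alleles[None, :]).astype(float)
    return Xq, alleles


def scan_trait(
    pheno: PhenotypeTable,
    trait: str,
    geno: FounderGenotypeTable,
    kin: LocoKinshipSet,
    mode: str = "exact",
) -> pd.DataFrame:
    """Wald genome scan of one trait over every marker of the genotype table.

    ``mode="exact"`` re-optimizes the REML variance ratio at each marker
    under the joint covariate + allele design (per-position model fit);
    ``mode="fast"`` estimates the variance components once per chromosome
    under the covariates-only null model and reuses them for every marker
    on that chromosome (EMMAX-style approximation).

    Returns one row per marker with columns :data:`mpqtl.io.SCAN_COLUMNS`
    plus ``effect_<founder>`` deviations; markers that cannot be tested get
    ``status`` of ``"monomorphic"`` or ``"singular"`` and NaN statistics.
    """
    if mode not in ("exact", "fast"):
        raise ValueError(f"unknown scan mode {mode!r}")
    if list(pheno.segregant_ids) != list(geno.segregant_ids):
        raise ValueError("phenotype and genotype segregant ids differ (order matters)")
    missing_chr = set(geno.markers.chromosomes) - set(kin.chromosomes)
    if missing_chr:
        raise ValueError(f"kinship lacks chromosomes {sorted(missing_chr)}")

    y_all = pheno.trait_values(trait)
    pheno_mask = np.isfinite(y_all)
    if pheno_mask.sum() == 0:
        raise ValueError(f"trait {trait!r} has no non-missing values")
    if pheno_mask.sum() < MIN_NONMISSING:
        raise ValueError(
            f"trait {trait!r} has {int(pheno_mask.sum())} non-missing values; "
            f"at least {MIN_NONMISSING} required"
        )

    founders = geno.founder_labels
    eig_cache: dict[tuple[str, bytes], tuple[np.ndarray, np.ndarray]] = {}
    vc_cache: dict[tuple[str, bytes], object] = {}

    rows = []
    chrom_arr = geno.markers.chromosome
    for k in range(geno.n_markers):
        chrom = chrom_arr[k]
        calls = geno.codes[:, k]
        keep = pheno_mask & (calls != MISSING_CODE)
        n_eff = int(keep.sum())
        row = {
            "trait": trait,
            "marker": geno.markers.marker_id[k],
            "chromosome": chrom,
            "position": int(geno.markers.position[k]),
            "status": "ok",
            "n_eff": n_eff,
            "df": np.nan,
            "wald": np.nan,
            "p_value": np.nan,
            "q_value": np.nan,
        }
        for lab in founders:
            row[f"effect_{lab}"] = np.nan

        Xq, alleles = _allele_design(calls[keep])
        if len(alleles) < 2:
            row["status"] = "monomorphic"
            rows.append(row)
            continue

        key = (chrom, keep.tobytes())
        if key not in eig_cache:
            ix = np.flatnonzero(keep)
            eig_cache[key] = psd_eigh(kin[chrom][np.ix_(ix, ix)])
        eig = eig_cache[key]
        y = y_all[keep]
        X, _ = build_covariate_design(pheno.covariates.iloc[keep])

        try:
            if mode == "exact":
                from .lmm import sum_to_zero_contrasts

                D = np.hstack([X, Xq @ sum_to_zero_contrasts(len(alleles))])
                vc = fit_reml(y, D, eig=eig)
            else:
                if key not in vc_cache:
                    vc_cache[key] = fit_reml(y, X, eig=eig)
                vc = vc_cache[key]
            result = wald_test(y, X, Xq, None, vc, eig=eig)
        except SingularDesignError:
            row["status"] = "singular"
            rows.append(row)
            continue

        row["df"] = result.df
        row["wald"] = result.statistic
        row["p_value"] = result.p_value
        for code, dev in zip(alleles, result.allele_effects):
            row[f"effect_{founders[code]}"] = dev
        rows.append(row)

    cols = SCAN_COLUMNS + [f"effect_{lab}" for lab in founders]
    return pd.DataFrame(rows, columns=cols)


def scan_all_traits(
    pheno: PhenotypeTable,
    geno: FounderGenotypeTable,
    kin: LocoKinshipSet,
    traits: Sequence[str] | None = None,
    mode: str = "exact",
) -> pd.DataFrame:
    """Scan every trait (or the given subset) and BH-adjust per trait."""
    frames = []
    for trait in traits if traits is not None else pheno.trait_names:
        df = scan_trait(pheno, trait, geno, kin, mode=mode)
        frames.append(add_qvalues(df))
    return pd.concat(frames, ignore_index=True)


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.nanmin(p) <= 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_qvalues(scan_df: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust within each trait's full marker vector (tested markers)."""
    out = scan_df.copy()
    for trait, idx in out.groupby("trait").groups.items():
        sub = out.loc[idx]
        ok = sub["status"] == "ok"
        if ok.any():
            out.loc[sub.index[ok], "q_value"] = bh_qvalues(
                sub.loc[ok, "p_value"].to_numpy()
            )
    return out


def call_qtl(
    scan_df: pd.DataFrame, q_threshold: float = 0.5, max_gap: int = 0
) -> list[QTLRegion]:
    """Call per-trait QTL regions from a q-thresholded scan.

    Per trait and chromosome, contiguous runs of tested markers with
    ``q <= q_threshold`` (allowing up to ``max_gap`` interspersed
    non-significant tested markers) form one region spanning the first to
    last significant marker; the peak is the minimum-p marker of the run.
    """
    regions: list[QTLRegion] = []
    for (trait, chrom), sub in scan_df.groupby(["trait", "chromosome"], sort=False):
        sub = sub[sub["status"] == "ok"].sort_values("position")
        if sub.empty:
            continue
        sig = (sub["q_value"] <= q_threshold).to_numpy()
        pos = sub["position"].to_numpy()
        pvals = sub["p_value"].to_numpy()
        qvals = sub["q_value"].to_numpy()
        names = sub["marker"].to_numpy()

        runs: list[list[int]] = []
        current: list[int] = []
        gap = 0
        for i, is_sig in enumerate(sig):
            if is_sig:
                current.append(i)
                gap = 0
            elif current:
                gap += 1
                if gap > max_gap:
                    runs.append(current)
                    current = []
                    gap = 0
        if current:
            runs.append(current)

        for j, run in enumerate(runs, start=1):
            peak = run[int(np.argmin(pvals[run]))]
            regions.append(
                QTLRegion(
                    region_id=f"{trait}:{chrom}:{j}",
                    chromosome=chrom,
                    start=int(pos[run[0]]),
                    end=int(pos[run[-1]]),
                    traits=[trait],
                    peak_marker=str(names[peak]),
                    peak_neglog10p=float(-np.log10(pvals[peak])),
                    peak_q=float(qvals[peak]),
                )
            )
    return regions


def merge_regions(regions: Iterable[QTLRegion]) -> list[QTLRegion]:
    """Merge regions across traits whose bp intervals overlap by >= 1 bp.

    Merged (major) regions report the union interval, the union of
    contributing traits, and the strongest contributing peak; ids are
    reassigned ``QTL1..QTLn`` in (chromosome, start) order.  The operation
    is idempotent.
    """
    by_key = sorted(regions, key=lambda r: (str(r.chromosome), r.start, r.end))
    merged: list[QTLRegion] = []
    for r in by_key:
        if (
            merged
            and merged[-1].chromosome == r.chromosome
            and r.start <= merged[-1].end
        ):
            last = merged[-1]
            traits = sorted(set(last.traits) | set(r.traits))
            if r.peak_neglog10p > last.peak_neglog10p:
                peak_marker, peak_nlp, peak_q = r.peak_marker, r.peak_neglog10p, r.peak_q
            else:
                peak_marker, peak_nlp, peak_q = (
                    last.peak_marker,
                    last.peak_neglog10p,
                    last.peak_q,
                )
            merged[-1] = QTLRegion(
                last.region_id,
                last.chromosome,
                last.start,
                max(last.end, r.end),
                traits,
                peak_marker,
                peak_nlp,
                peak_q,
            )
        else:
            merged.append(
                QTLRegion(
                    r.region_id,
                    r.chromosome,
                    r.start,
                    r.end,
                    sorted(set(r.traits)),
                    r.peak_marker,
                    r.peak_neglog10p,
                    r.peak_q,
                )
            )
    return [
        QTLRegion(
            f"QTL{i}", r.chromosome, r.start, r.end, r.traits,
            r.peak_marker, r.peak_neglog10p, r.peak_q,
        )
        for i, r in enumerate(merged, start=1)
    ]
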