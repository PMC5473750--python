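"""Synthetic four-founder advanced-intercross data.

Generates (i) an F12-style advanced intercross line (AIL): founder pairs
are crossed into F1 hybrids, the hybrids' spores are pooled, and the
population is propagated by rounds of random mating with Poisson crossover
counts (no interference) and uniform breakpoint placement; haploid
segregants are sampled at the end and their founder-of-origin recorded at
each marker.  (ii) quantitative traits under the scan's own generative
model (covariate effects + founder-allele QTL effects + polygenic draw
with allele-sharing covariance + residuals).  (iii) pooled RNA-seq-style
allele counts for two high- and two low-phenotype replicate pools of the
same extreme segregants, with Dirichlet RNA-mixture weights, negative-
binomial depths and binomial allele sampling, plus per-gene expression
counts.

Every generator is fully deterministic given its config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_FOUNDERS,
    FounderGenotypeTable,
    GeneExpressionCounts,
    HLA_POOLS,
    LLA_POOLS,
    MarkerMap,
    PhenotypeTable,
    POOLS,
    PoolAlleleCounts,
)
from .kinship import genomewide_kinship
from .lmm import psd_eigh

#: S288c chromosome lengths (bp).
YEAST_CHROMOSOMES: dict[str, int] = {
    "I": 230_218, "II": 813_184, "III": 316_620, "IV": 1_531_933,
    "V": 576_874, "VI": 270_161, "VII": 1_090_940, "VIII": 562_643,
    "IX": 439_888, "X": 745_751, "XI": 666_816, "XII": 1_078_177,
    "XIII": 924_431, "XIV": 784_333, "XV": 1_091_291, "XVI": 948_066,
}


# ---------------------------------------------------------------------------
# AIL population
# ---------------------------------------------------------------------------


@dataclass
class AILSimConfig:
    """Parameters of the advanced-intercross population generator.

    Defaults mirror the mapped population: four founders, 12 generations
    (F1 plus 11 rounds of random mating), a yeast-typical uniform
    recombination rate of 0.35 cM/kb, 165 sampled haploid segregants and
    markers every 120 bp across the 16 yeast chromosomes (~100k sites).
    The per-generation population size is a knob (default 1,000).
    """

    seed: int
    founders: tuple[str, ...] = DEFAULT_FOUNDERS
    chromosomes: dict[str, int] = field(default_factory=lambda: dict(YEAST_CHROMOSOMES))
    recomb_rate_cm_per_kb: float = 0.35
    generations: int = 12
    pop_size: int = 1_000
    n_segregants: int = 165
    marker_spacing: int = 120

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.generations < 2:
            raise ValueError("need generations >= 2")
        if any(L <= 0 for L in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")
        if len(self.founders) not in (2, 4):
            raise ValueError("founders are paired into F1s; need 2 or 4 labels")

    def map_length_morgans(self, chromosome: str) -> float:
        """Map length of one chromosome in Morgans."""
        bp = self.chromosomes[chromosome]
        return bp / 1000.0 * self.recomb_rate_cm_per_kb / 100.0


Haplotype = tuple[np.ndarray, np.ndarray]  # (segment end bp, founder code)


def _founder_haplotype(code: int, length: int) -> Haplotype:
    return np.array([length], dtype=np.int64), np.array([code], dtype=np.int8)


def _gamete(
    hapA: Haplotype, hapB: Haplotype, length: int, morgans: float, rng: np.random.Generator
) -> Haplotype:
    """One meiotic product: Poisson crossovers, uniform breakpoints."""
    k = int(rng.poisson(morgans))
    use = int(rng.integers(2))
    if k == 0:
        return (hapA, hapB)[use]
    cuts = np.unique(rng.integers(1, length, size=k))
    haps = (hapA, hapB)
    out_ends: list[int] = []
    out_labs: list[int] = []
    start = 0
    for bound in [*cuts.tolist(), length]:
        if bound > start:
            ends, labs = haps[use]
            i = int(np.searchsorted(ends, start, side="right"))
            s = start
            while s < bound:
                e = min(int(ends[i]), bound)
                lab = int(labs[i])
                if out_labs and out_labs[-1] == lab:
                    out_ends[-1] = e
                else:
                    out_ends.append(e)
                    out_labs.append(lab)
                s = e
                i += 1
        use ^= 1
        start = bound
    return np.asarray(out_ends, dtype=np.int64), np.asarray(out_labs, dtype=np.int8)


def _marker_positions(config: AILSimConfig) -> MarkerMap:
    ids, chroms, pos = [], [], []
    for name, length in config.chromosomes.items():
        p = np.arange(config.marker_spacing, length + 1, config.marker_spacing, dtype=np.int64)
        pos.append(p)
        chroms += [name] * len(p)
        ids += [f"{name}.{x}" for x in p]
    return MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object), np.concatenate(pos))


def simulate_ail(
    config: AILSimConfig, return_haplotypes: bool = False
) -> FounderGenotypeTable | tuple[FounderGenotypeTable, list[dict[str, Haplotype]]]:
    """Simulate the AIL and genotype sampled haploid segregants.

    Founders are paired into F1 hybrids ((0,1) and (2,3)); spores of both
    crosses are pooled, and ``generations - 1`` rounds of random mating
    follow.  Haploid segregants are single gametes of the final diploid
    generation.  With ``return_haplotypes=True`` the per-segregant mosaic
    haplotypes (segment ends + founder codes per chromosome) are returned
    alongside the genotype table.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = list(config.chromosomes)
    lengths = {c: config.chromosomes[c] for c in chrom_names}
    morgans = {c: config.map_length_morgans(c) for c in chrom_names}

    nf = len(config.founders)
    f1_types = []
    for a in range(0, nf, 2):
        f1_types.append(
            {
                c: (
                    _founder_haplotype(a, lengths[c]),
                    _founder_haplotype(a + 1, lengths[c]),
                )
                for c in chrom_names
            }
        )

    def offspring(parent_a, parent_b):
        return {
            c: (
                _gamete(*parent_a[c], lengths[c], morgans[c], rng),
                _gamete(*parent_b[c], lengths[c], morgans[c], rng),
            )
            for c in chrom_names
        }

    pop = f1_types
    for _ in range(config.generations - 1):
        if len(pop) <= 2:
            # F1 stage: both hybrid types are clonal; sample the type
            parents = [pop[int(rng.integers(len(pop)))] for _ in range(2 * config.pop_size)]
            pairs = [(parents[2 * i], parents[2 * i + 1]) for i in range(config.pop_size)]
        else:
            idx = [rng.choice(len(pop), size=2, replace=False) for _ in range(config.pop_size)]
            pairs = [(pop[i], pop[j]) for i, j in idx]
        pop = [offspring(a, b) for a, b in pairs]

    segregants = []
    for _ in range(config.n_segregants):
        parent = pop[int(rng.integers(len(pop)))]
        segregants.append(
            {c: _gamete(*parent[c], lengths[c], morgans[c], rng) for c in chrom_names}
        )

    markers = _marker_positions(config)
    codes = np.empty((config.n_segregants, markers.n_markers), dtype=np.int8)
    col = 0
    for c in chrom_names:
        pos = markers.position[markers.chromosome == c]
        for i, hap in enumerate(segregants):
            ends, labs = hap[c]
            codes[i, col : col + len(pos)] = labs[np.searchsorted(ends, pos, side="left")]
        col += len(pos)
    seg_ids = [f"seg{i + 1:04d}" for i in range(config.n_segregants)]
    table = FounderGenotypeTable(seg_ids, markers, codes, tuple(config.founders))
    if return_haplotypes:
        return table, segregants
    return table


def simulate_unlinked_panel(
    seed: int,
    n_segregants: int,
    markers_per_chromosome: int,
    n_chromosomes: int = 16,
    founders: Sequence[str] = DEFAULT_FOUNDERS,
    spacing: int = 1_000,
) -> FounderGenotypeTable:
    """Panel with independent uniform founder draws at every marker.

    No linkage and no relatedness structure: useful for calibration
    experiments whose statistics assume independent markers, and as the
    'unrelated' reference for kinship checks (expected sharing = 1/q).
    """
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1:02d}" for i in range(n_chromosomes)]
    ids, chroms, pos = [], [], []
    for c in chrom_names:
        p = np.arange(spacing, spacing * (markers_per_chromosome + 1), spacing, dtype=np.int64)
        pos.append(p)
        chroms += [c] * len(p)
        ids += [f"{c}.{x}" for x in p]
    markers = MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object), np.concatenate(pos))
    codes = rng.integers(0, len(founders), size=(n_segregants, markers.n_markers), dtype=np.int8)
    seg_ids = [f"seg{i + 1:04d}" for i in range(n_segregants)]
    return FounderGenotypeTable(seg_ids, markers, codes, tuple(founders))


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass
class QTLEffect:
    """One planted QTL: per-founder effect deviations at a marker.

    ``effects`` maps founder labels to deviations summing to zero.  When
    ``variance_frac`` is set the deviations are rescaled so the QTL term's
    realized variance is that fraction of the realized total of QTL +
    background (covariates + polygenic + residual).
    """

    marker_id: str
    effects: dict[str, float]
    variance_frac: float | None = None

    def __post_init__(self) -> None:
        total = sum(self.effects.values())
        if abs(total) > 1e-8 * max(1.0, max(abs(v) for v in self.effects.values())):
            raise ValueError("QTL effect deviations must sum to 0")
        if self.variance_frac is not None and not (0 < self.variance_frac < 1):
            raise ValueError("variance_frac must lie in (0, 1)")


@dataclass
class TraitSimConfig:
    """Generative parameters for one quantitative trait."""

    seed: int
    name: str = "trait"
    qtls: list[QTLEffect] = field(default_factory=list)
    h2: float = 0.0
    covariate_effects: Mapping[str, float] | None = None
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ValueError("polygenic h2 must lie in [0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


def simulate_covariates(geno: FounderGenotypeTable, seed: int) -> pd.DataFrame:
    """Random mating-type and LYS2/URA3 auxotrophy states (2:2 segregation)."""
    rng = np.random.default_rng(seed)
    n = geno.n_segregants
    return pd.DataFrame(
        {
            "mating_type": rng.choice(["a", "alpha"], size=n),
            "lys2": rng.choice(["LYS2", "lys2"], size=n),
            "ura3": rng.choice(["URA3", "ura3"], size=n),
        },
        index=pd.Index(geno.segregant_ids),
    )


def simulate_phenotypes(
    geno: FounderGenotypeTable,
    configs: TraitSimConfig | Sequence[TraitSimConfig],
    covariates: pd.DataFrame | None = None,
    covariate_seed: int | None = None,
    kinship: np.ndarray | None = None,
) -> PhenotypeTable:
    """Generate trait values under the scan's mixed model.

    ``y = covariate effects + sum of QTL allele-effect lookups + polygenic
    draw with covariance sigma_a^2 * A (genome-wide allele sharing) +
    N(0, sigma_e^2) residuals``, with ``sigma_a^2 = h2/(1-h2) * sigma_e^2``.
    Covariates are shared across traits; pass them in or let them be drawn
    from ``covariate_seed`` (default: derived from the first trait seed).
    """
    if isinstance(configs, TraitSimConfig):
        configs = [configs]
    if not configs:
        raise ValueError("need at least one trait config")
    if covariates is None:
        if covariate_seed is None:
            covariate_seed = int(configs[0].seed) + 10_007
        covariates = simulate_covariates(geno, covariate_seed)

    n = geno.n_segregants
    eig = None
    if any(cfg.h2 > 0 for cfg in configs):
        A = kinship if kinship is not None else genomewide_kinship(geno)
        eig = psd_eigh(A)

    combo = covariates["lys2"].astype(str) + "|" + covariates["ura3"].astype(str)
    traits = {}
    for cfg in configs:
        rng = np.random.default_rng(cfg.seed)
        y = np.zeros(n)
        if cfg.covariate_effects:
            y += combo.map(lambda c: cfg.covariate_effects.get(c, 0.0)).to_numpy(float)
        sigma_e = cfg.residual_sd
        if cfg.h2 > 0:
            sigma_a2 = cfg.h2 / (1.0 - cfg.h2) * sigma_e**2
            d, U = eig
            y += U @ (np.sqrt(sigma_a2 * d) * rng.standard_normal(n))
        y += sigma_e * rng.standard_normal(n)

        for qtl in cfg.qtls:
            k = geno.markers.index_of(qtl.marker_id)
            calls = geno.codes[:, k]
            observed = calls[calls >= 0]
            if len(np.unique(observed)) < 2:
                raise ValueError(
                    f"QTL marker {qtl.marker_id!r} is monomorphic in the sample; "
                    "its effect is unidentifiable"
                )
            effect_by_code = np.zeros(len(geno.founder_labels))
            for lab, dev in qtl.effects.items():
                effect_by_code[geno.founder_labels.index(lab)] = dev
            g = np.where(calls >= 0, effect_by_code[np.clip(calls, 0, None)], 0.0)
            if qtl.variance_frac is not None:
                v_rest = float(np.var(y))
                v_g = float(np.var(g))
                if v_g == 0:
                    raise ValueError(f"QTL term at {qtl.marker_id!r} has zero variance")
                g = g * np.sqrt(qtl.variance_frac / (1.0 - qtl.variance_frac) * v_rest / v_g)
            y = y + g
        traits[cfg.name] = y

    return PhenotypeTable(
        list(geno.segregant_ids), pd.DataFrame(traits), covariates.copy()
    )


# ---------------------------------------------------------------------------
# Pooled counts
# ---------------------------------------------------------------------------


@dataclass
class PoolSimConfig:
    """Parameters of the pooled allele-count / expression generator."""

    seed: int
    n_per_pool: int = 8
    mean_depth: float = 100.0
    depth_dispersion: float = 10.0  # negative-binomial size; larger = tighter
    dirichlet_alpha: float = 50.0   # RNA-mixture concentration around equal
    snp_marker_ids: Sequence[str] | None = None
    alt_founders: Mapping[str, Sequence[str]] | None = None
    n_genes: int = 200
    gene_fold_changes: Mapping[str, float] | None = None
    gene_mean_expression: float = 200.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if self.n_per_pool < 1:
            raise ValueError("need at least one segregant per pool")


@dataclass
class PoolSimResult:
    """Pooled counts plus the generative truth needed by validation tests."""

    counts: PoolAlleleCounts
    genes: GeneExpressionCounts
    gene_intervals: pd.DataFrame
    high_segregants: list[str]
    low_segregants: list[str]
    alt_founders: dict[str, tuple[str, ...]]
    pool_weights: dict[str, np.ndarray]
    true_ref_freq: pd.DataFrame


def simulate_pool_counts(
    geno: FounderGenotypeTable,
    trait_values: np.ndarray,
    config: PoolSimConfig,
) -> PoolSimResult:
    """Pooled allele counts for phenotypic-extreme segregant pools.

    The top and bottom ``n_per_pool`` segregants by trait value form the
    high and low pools; each condition's two replicate pools contain the
    same individuals with Dirichlet-drawn RNA-mixture weights.  Per SNP a
    subset of founders carries the alternative allele (random 1..q-1
    founders unless overridden); each pool's true reference-allele
    frequency is the weighted founder-indicator mean, read depths are
    negative-binomial around the mean depth and reference reads binomial.
    """
    trait_values = np.asarray(trait_values, dtype=float)
    if len(trait_values) != geno.n_segregants:
        raise ValueError("trait value count != number of segregants")
    need = 2 * config.n_per_pool
    ok = np.isfinite(trait_values)
    if ok.sum() < need:
        raise ValueError(
            f"fewer than {need} phenotyped segregants; cannot form extreme pools"
        )
    rng = np.random.default_rng(config.seed)
    order = np.argsort(trait_values[ok], kind="mergesort")
    ok_idx = np.flatnonzero(ok)
    low_idx = ok_idx[order[: config.n_per_pool]]
    high_idx = ok_idx[order[-config.n_per_pool :]]

    members = {p: high_idx for p in HLA_POOLS} | {p: low_idx for p in LLA_POOLS}
    weights = {
        p: rng.dirichlet(np.full(config.n_per_pool, config.dirichlet_alpha))
        for p in POOLS
    }

    if config.snp_marker_ids is None:
        snp_idx = np.arange(geno.n_markers)
    else:
        snp_idx = np.array([geno.markers.index_of(m) for m in config.snp_marker_ids])

    founder_list = list(geno.founder_labels)
    nf = len(founder_list)
    overrides = dict(config.alt_founders or {})
    bases = ("A", "C", "G", "T")

    rows = []
    truth_rows = []
    alt_map: dict[str, tuple[str, ...]] = {}
    r = config.depth_dispersion
    p_nb = r / (r + config.mean_depth)
    for k in snp_idx:
        marker = str(geno.markers.marker_id[k])
        if marker in overrides:
            alt_set = tuple(overrides[marker])
        else:
            n_alt = int(rng.integers(1, nf))
            alt_set = tuple(
                founder_list[i] for i in rng.choice(nf, size=n_alt, replace=False)
            )
        alt_map[marker] = alt_set
        alt_codes = {founder_list.index(f) for f in alt_set}
        ref_base, alt_base = rng.choice(len(bases), size=2, replace=False)
        row = {
            "chrom": geno.markers.chromosome[k],
            "pos": int(geno.markers.position[k]),
            "ref": bases[ref_base],
            "alt": bases[alt_base],
        }
        truth = {"marker": marker}
        for pool in POOLS:
            idx = members[pool]
            w = weights[pool]
            calls = geno.codes[idx, k]
            observed = calls >= 0
            if observed.sum() == 0:
                freq_ref = 0.5
            else:
                w_obs = w[observed] / w[observed].sum()
                is_ref = np.array([c not in alt_codes for c in calls[observed]])
                # renormalized weights can overshoot [0, 1] by an ulp
                freq_ref = float(np.clip(np.sum(w_obs * is_ref), 0.0, 1.0))
            depth = int(rng.negative_binomial(r, p_nb))
            ref_reads = int(rng.binomial(depth, freq_ref)) if depth > 0 else 0
            row[f"{pool}.ref"] = ref_reads
            row[f"{pool}.alt"] = depth - ref_reads
            truth[f"{pool}.freq_ref"] = freq_ref
        rows.append(row)
        truth_rows.append(truth)

    cols = ["chrom", "pos", "ref", "alt"] + [
        f"{p}.{part}" for p in POOLS for part in ("ref", "alt")
    ]
    counts = PoolAlleleCounts(pd.DataFrame(rows, columns=cols))

    genes, gene_intervals = _simulate_expression(geno, config, rng)
    seg = np.asarray(geno.segregant_ids, dtype=object)
    return PoolSimResult(
        counts=counts,
        genes=genes,
        gene_intervals=gene_intervals,
        high_segregants=list(seg[high_idx]),
        low_segregants=list(seg[low_idx]),
        alt_founders=alt_map,
        pool_weights=weights,
        true_ref_freq=pd.DataFrame(truth_rows),
    )


def _simulate_expression(
    geno: FounderGenotypeTable, config: PoolSimConfig, rng: np.random.Generator
) -> tuple[GeneExpressionCounts, pd.DataFrame]:
    """Log-normal per-gene expression with optional HLA/LLA fold changes."""
    chroms = geno.markers.chromosomes
    lengths = {
        c: int(geno.markers.position[geno.markers.chromosome == c].max()) for c in chroms
    }
    total = sum(lengths.values())
    per_chrom = {
        c: max(1, int(round(config.n_genes * lengths[c] / total))) for c in chroms
    }
    folds = dict(config.gene_fold_changes or {})
    rows, interval_rows = [], []
    g = 0
    for c in chroms:
        n_c = per_chrom[c]
        span = lengths[c] // (n_c + 1)
        for j in range(n_c):
            g += 1
            gene_id = f"GENE{g:04d}"
            start = (j + 1) * span
            end = min(start + 1_499, lengths[c])
            expr = config.gene_mean_expression * float(rng.lognormal(0.0, 1.0))
            fold = folds.get(gene_id, 1.0)
            row = {"gene_id": gene_id}
            for pool in POOLS:
                scale = np.sqrt(fold) if pool in HLA_POOLS else 1.0 / np.sqrt(fold)
                row[pool] = int(rng.poisson(expr * scale))
            rows.append(row)
            interval_rows.append(
                {"gene_id": gene_id, "chromosome": c, "start": start, "end": end}
            )
    genes = GeneExpressionCounts(pd.DataFrame(rows, columns=["gene_id", *POOLS]))
    intervals = pd.DataFrame(interval_rows, columns=["gene_id", "chromosome", "start", "end"])
    return genes, intervals
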