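"""Data model and file I/O for the mapping pipeline.

Containers for founder-of-origin genotype tables, phenotype tables, pooled
SNP allele counts, gene-expression counts and gene annotation intervals,
plus TSV/VCF/BED/GFF3 readers and writers.

Conventions
-----------
* Internal coordinates are 1-based inclusive (markers are named like
  ``XII.232561`` for chromosome XII, position 232561 bp).  BED export
  converts to 0-based half-open.
* A missing founder-of-origin call is encoded by the reserved token ``"."``.
  ``"NA"`` cannot be used for missingness because it is a founder label
  (North American); genotype TSVs are therefore parsed with pandas NA
  handling disabled.
* Pooled samples play four fixed roles: two high-ammonium-consumption
  replicate pools and two low ones (``HLA-1``, ``HLA-2``, ``LLA-1``,
  ``LLA-2``).  Arbitrary VCF sample names are mapped onto the roles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = "."
MISSING_CODE = -1

#: The four pool roles of the bulk-segregant design.
POOLS = ("HLA-1", "HLA-2", "LLA-1", "LLA-2")
HLA_POOLS = ("HLA-1", "HLA-2")
LLA_POOLS = ("LLA-1", "LLA-2")

#: Default founder labels of the four-parent population.
DEFAULT_FOUNDERS = ("NA", "WA", "WE", "SA")


class FormatError(ValueError):
    """Raised when an input file violates the documented layout."""


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Genome positions of the segregating sites used by the scan.

    Positions are 1-based bp and must be strictly increasing within each
    chromosome; marker ids must be unique.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        if not (len(self.marker_id) == len(self.chromosome) == len(self.position)):
            raise FormatError("marker_id/chromosome/position length mismatch")
        ids, counts = np.unique(self.marker_id, return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][:5]
            raise FormatError(f"duplicate marker ids: {list(dup)}")
        for chrom in self.chromosomes:
            pos = self.position[self.chromosome == chrom]
            if not (np.diff(pos) > 0).all():
                raise FormatError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chromosome:
            seen.setdefault(c)
        return list(seen)

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.marker_id == marker_id)
        if len(hits) == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(hits[0])

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.marker_id[mask], self.chromosome[mask], self.position[mask])


# ---------------------------------------------------------------------------
# Founder genotype table
# ---------------------------------------------------------------------------


@dataclass
class FounderGenotypeTable:
    """Segregants x markers matrix of founder-of-origin labels.

    ``codes`` is an ``int8`` matrix; entry ``(i, k)`` is the index into
    ``founder_labels`` of the founder whose allele segregant ``i`` carries at
    marker ``k``, or :data:`MISSING_CODE` for a missing call.
    """

    segregant_ids: list[str]
    markers: MarkerMap
    codes: np.ndarray
    founder_labels: tuple[str, ...] = DEFAULT_FOUNDERS

    def __post_init__(self) -> None:
        self.segregant_ids = list(self.segregant_ids)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.founder_labels = tuple(self.founder_labels)
        n, p = self.codes.shape
        if n != len(self.segregant_ids):
            raise FormatError("codes row count != number of segregants")
        if p != self.markers.n_markers:
            raise FormatError("codes column count != number of markers")
        if n < 2:
            raise FormatError("need at least 2 segregants")
        if len(self.markers.chromosomes) < 2:
            raise FormatError("need markers on at least 2 chromosomes")
        if len(self.founder_labels) > 4:
            raise FormatError("at most 4 founder labels supported")
        if self.codes.max(initial=-1) >= len(self.founder_labels) or self.codes.min(
            initial=0
        ) < MISSING_CODE:
            raise FormatError("genotype codes out of range")

    @classmethod
    def from_labels(
        cls,
        segregant_ids: Sequence[str],
        markers: MarkerMap,
        calls: np.ndarray,
        founder_labels: Sequence[str] = DEFAULT_FOUNDERS,
    ) -> "FounderGenotypeTable":
        """Build from a matrix of founder-label strings (``"."`` = missing)."""
        calls = np.asarray(calls, dtype=object)
        lookup = {lab: i for i, lab in enumerate(founder_labels)}
        lookup[MISSING] = MISSING_CODE
        codes = np.empty(calls.shape, dtype=np.int8)
        for (i, k), val in np.ndenumerate(calls):
            try:
                codes[i, k] = lookup[val]
            except KeyError:
                raise FormatError(
                    f"unknown founder label {val!r} at segregant "
                    f"{segregant_ids[i]!r}, marker {markers.marker_id[k]!r}"
                ) from None
        return cls(list(segregant_ids), markers, codes, tuple(founder_labels))

    @property
    def n_segregants(self) -> int:
        return len(self.segregant_ids)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def label_matrix(self) -> np.ndarray:
        """Decode codes back to a matrix of label strings (small tables)."""
        labels = np.array(list(self.founder_labels) + [MISSING], dtype=object)
        return labels[self.codes]

    def subset_markers(self, mask: np.ndarray) -> "FounderGenotypeTable":
        return FounderGenotypeTable(
            self.segregant_ids, self.markers.subset(mask), self.codes[:, mask],
            self.founder_labels,
        )


def read_genotypes(path: str | Path, founder_labels: Sequence[str] | None = None) -> FounderGenotypeTable:
    """Read a founder-of-origin genotype TSV.

    Canonical layout: one row per marker with columns ``marker``, ``chrom``,
    ``pos`` followed by one column per segregant; cells hold founder labels
    or ``"."``.  An optional ``#founders=A,B,...`` comment line declares the
    founder label set (defaults to NA, WA, WE, SA).
    """
    path = Path(path)
    declared: tuple[str, ...] | None = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line[1:].strip()
            if stripped.startswith("founders="):
                declared = tuple(s.strip() for s in stripped[len("founders="):].split(","))
    if founder_labels is None:
        founder_labels = declared if declared is not None else DEFAULT_FOUNDERS

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("marker", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"genotype table missing required column {col!r}")
    seg_cols = [c for c in df.columns if c not in ("marker", "chrom", "pos")]
    markers = MarkerMap(
        df["marker"].to_numpy(object),
        df["chrom"].to_numpy(object),
        df["pos"].astype(np.int64).to_numpy(),
    )
    calls = df[seg_cols].to_numpy(object).T  # segregants x markers
    return FounderGenotypeTable.from_labels(seg_cols, markers, calls, founder_labels)


def write_genotypes(table: FounderGenotypeTable, path: str | Path) -> None:
    path = Path(path)
    labels = table.label_matrix()
    df = pd.concat(
        [
            pd.DataFrame(
                {
                    "marker": table.markers.marker_id,
                    "chrom": table.markers.chromosome,
                    "pos": table.markers.position,
                }
            ),
            pd.DataFrame(labels.T, columns=table.segregant_ids),
        ],
        axis=1,
    )
    with open(path, "w") as fh:
        fh.write(f"#founders={','.join(table.founder_labels)}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Per-segregant nitrogen-consumption traits plus covariate markers.

    ``traits`` holds numeric consumption values (mg/L or mgN/L, NaN =
    missing); ``covariates`` holds categorical per-segregant states for the
    mating-type locus and the LYS2/URA3 auxotrophy markers.
    """

    segregant_ids: list[str]
    traits: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.segregant_ids = list(self.segregant_ids)
        n = len(self.segregant_ids)
        if len(self.traits) != n or len(self.covariates) != n:
            raise FormatError("trait/covariate row count != number of segregants")
        self.traits = self.traits.astype(float)
        self.traits.index = pd.Index(self.segregant_ids)
        self.covariates.index = pd.Index(self.segregant_ids)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def trait_values(self, trait: str) -> np.ndarray:
        if trait not in self.traits.columns:
            raise KeyError(f"unknown trait {trait!r}")
        return self.traits[trait].to_numpy(float)


DEFAULT_COVARIATE_COLUMNS = ("mating_type", "lys2", "ura3")


def read_phenotypes(
    path: str | Path,
    covariate_columns: Sequence[str] = DEFAULT_COVARIATE_COLUMNS,
) -> PhenotypeTable:
    """Read a phenotype TSV: ``segregant`` column, covariate columns, then
    one numeric column per trait (empty cells = missing)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if "segregant" not in df.columns:
        raise FormatError("phenotype table missing 'segregant' column")
    missing_cov = [c for c in covariate_columns if c not in df.columns]
    if missing_cov:
        raise FormatError(f"phenotype table missing covariate columns {missing_cov}")
    seg = df["segregant"].tolist()
    cov = df[list(covariate_columns)].copy()
    trait_cols = [c for c in df.columns if c != "segregant" and c not in covariate_columns]
    traits = df[trait_cols].replace("", np.nan).apply(
        lambda col: pd.to_numeric(col, errors="raise")
    )
    return PhenotypeTable(seg, traits, cov)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pd.concat(
        [
            pd.DataFrame({"segregant": pheno.segregant_ids}),
            pheno.covariates.reset_index(drop=True),
            pheno.traits.reset_index(drop=True),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Scan results
# ---------------------------------------------------------------------------

#: Fixed column order of scan result TSVs; one ``effect_<founder>`` column
#: per founder label is appended after these.
SCAN_COLUMNS = [
    "trait",
    "marker",
    "chromosome",
    "position",
    "status",
    "n_eff",
    "df",
    "wald",
    "p_value",
    "q_value",
]


def write_scan(results: pd.DataFrame, path: str | Path) -> None:
    """Write a per-marker scan result table (TSV, full float precision)."""
    cols = [c for c in SCAN_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scan(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# ---------------------------------------------------------------------------
# QTL regions
# ---------------------------------------------------------------------------


@dataclass
class QTLRegion:
    """A contiguous genomic interval of significant association.

    ``start``/``end`` are 1-based inclusive bp; the peak marker (minimum
    p-value) lies within the interval.
    """

    region_id: str
    chromosome: str
    start: int
    end: int
    traits: list[str]
    peak_marker: str
    peak_neglog10p: float
    peak_q: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.region_id}: start > end")


def write_regions(regions: Sequence[QTLRegion], path: str | Path) -> None:
    """Write regions as BED6 (0-based half-open; score = capped -log10 p)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for r in regions:
            score = int(min(1000, round(10 * max(r.peak_neglog10p, 0.0))))
            name = f"{r.region_id}|{','.join(r.traits)}|{r.peak_marker}"
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{name}\t{score}\t.\n")


def region_to_bed_interval(region: QTLRegion) -> tuple[int, int]:
    """Internal 1-based inclusive -> BED 0-based half-open."""
    return region.start - 1, region.end


# ---------------------------------------------------------------------------
# Pooled allele counts
# ---------------------------------------------------------------------------


@dataclass
class PoolAlleleCounts:
    """Per-SNP ref/alt read counts in the four bulk-segregant pools.

    ``table`` columns: ``chrom``, ``pos``, ``ref``, ``alt`` plus
    ``{pool}.ref`` / ``{pool}.alt`` integer columns for each role in
    :data:`POOLS`.  A pool with zero total reads at a SNP is treated as not
    covering ("absent from") that SNP.
    """

    table: pd.DataFrame
    n_multiallelic_skipped: int = 0

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "ref", "alt"]
        for pool in POOLS:
            required += [f"{pool}.ref", f"{pool}.alt"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"pool count table missing columns {missing}")
        for pool in POOLS:
            for part in ("ref", "alt"):
                col = f"{pool}.{part}"
                vals = self.table[col]
                if (vals < 0).any():
                    raise FormatError(f"negative counts in column {col}")
                self.table[col] = vals.astype(np.int64)
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def ref(self, pool: str) -> np.ndarray:
        return self.table[f"{pool}.ref"].to_numpy()

    def alt(self, pool: str) -> np.ndarray:
        return self.table[f"{pool}.alt"].to_numpy()

    def depth(self, pool: str) -> np.ndarray:
        return self.ref(pool) + self.alt(pool)

    def condition_counts(self, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-summed (ref, alt) counts for ``"HLA"`` or ``"LLA"``."""
        pools = HLA_POOLS if condition == "HLA" else LLA_POOLS
        ref = sum(self.ref(p) for p in pools)
        alt = sum(self.alt(p) for p in pools)
        return ref, alt


def read_pool_counts(
    path: str | Path, sample_map: Mapping[str, str] | None = None
) -> PoolAlleleCounts:
    """Read per-pool allelic depths (AD) from a VCF.

    ``sample_map`` maps pool roles (:data:`POOLS`) to VCF sample names;
    defaults to the roles themselves.  Multi-allelic records are skipped and
    counted; a VCF lacking one of the four mapped samples is rejected.
    """
    import pysam

    sample_map = dict(sample_map or {p: p for p in POOLS})
    missing_roles = [p for p in POOLS if p not in sample_map]
    if missing_roles:
        raise FormatError(f"sample_map lacks pool roles {missing_roles}")
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    absent = [sample_map[p] for p in POOLS if sample_map[p] not in vcf_samples]
    if absent:
        raise FormatError(f"VCF is missing pool sample column(s) {absent}")

    rows = []
    n_multi = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_multi += 1
            continue
        row = {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alts[0]}
        for pool in POOLS:
            ad = rec.samples[sample_map[pool]].get("AD")
            if ad is None or ad[0] is None:
                ref_n = alt_n = 0
            else:
                ref_n, alt_n = int(ad[0]), int(ad[1])
            row[f"{pool}.ref"] = ref_n
            row[f"{pool}.alt"] = alt_n
        rows.append(row)
    vf.close()
    cols = ["chrom", "pos", "ref", "alt"] + [
        f"{p}.{part}" for p in POOLS for part in ("ref", "alt")
    ]
    table = pd.DataFrame(rows, columns=cols)
    if len(table) == 0:
        table = table.astype({"pos": np.int64})
    return PoolAlleleCounts(table, n_multiallelic_skipped=n_multi)


def write_pool_counts_vcf(counts: PoolAlleleCounts, path: str | Path) -> None:
    """Write pool counts as a minimal VCF 4.2 with per-sample AD fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for chrom in pd.unique(counts.table["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(POOLS) + "\n"
        )
        for _, row in counts.table.iterrows():
            fields = [
                str(row["chrom"]), str(int(row["pos"])), ".",
                str(row["ref"]), str(row["alt"]), ".", ".", ".", "AD",
            ]
            for pool in POOLS:
                fields.append(f"{int(row[f'{pool}.ref'])},{int(row[f'{pool}.alt'])}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Gene expression counts
# ---------------------------------------------------------------------------


@dataclass
class GeneExpressionCounts:
    """Per-gene read counts in the four pools (columns = pool roles)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("gene_id", *POOLS) if c not in self.table.columns]
        if missing:
            raise FormatError(f"expression table missing columns {missing}")
        for pool in POOLS:
            vals = self.table[pool]
            if (vals < 0).any():
                raise FormatError(f"negative counts in pool {pool}")
            self.table[pool] = vals.astype(np.int64)
        self.table = self.table.reset_index(drop=True)


def read_expression_counts(path: str | Path) -> GeneExpressionCounts:
    return GeneExpressionCounts(pd.read_csv(path, sep="\t", comment="#"))


def write_expression_counts(genes: GeneExpressionCounts, path: str | Path) -> None:
    genes.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation intervals
# ---------------------------------------------------------------------------


def read_gene_intervals(path: str | Path, feature_types: Sequence[str] = ("gene",)) -> pd.DataFrame:
    """Read gene intervals from GFF3 or BED into a 1-based inclusive table.

    Returns a DataFrame with columns ``gene_id``, ``chromosome``, ``start``,
    ``end``.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=[0, 1, 2, 3],
            names=["chromosome", "bed_start", "bed_end", "gene_id"],
        )
        out = pd.DataFrame(
            {
                "gene_id": df["gene_id"],
                "chromosome": df["chromosome"],
                "start": df["bed_start"].astype(np.int64) + 1,
                "end": df["bed_end"].astype(np.int64),
            }
        )
        return out
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            rows.append(
                {
                    "gene_id": gene_id,
                    "chromosome": feat.seqid,
                    "start": feat.start,
                    "end": feat.end,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
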