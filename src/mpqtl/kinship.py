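"""Leave-one-chromosome-out (LOCO) allele-sharing kinship.

The polygenic random effect of the scan model has covariance
``sigma_a^2 * A(c)``, where ``A(c)[i, j]`` is the proportion of segregating
sites, on chromosomes other than ``c``, at which segregants ``i`` and ``j``
inherited their allele from the same founder.  Excluding the tested
chromosome prevents the tested signal from being absorbed by the polygenic
term.

Missing calls are handled pairwise-complete: the denominator for a pair is
the number of off-chromosome markers where both calls are present.  The
diagonal is 1 by definition.  ``A(c)`` is not forced to be positive
semi-definite here; the mixed-model fitter truncates negative eigenvalues
at zero before rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FounderGenotypeTable, MISSING_CODE


class DegenerateKinshipError(ValueError):
    """A pair of segregants has no jointly observed off-chromosome marker."""


@dataclass
class LocoKinshipSet:
    """Per-chromosome n x n allele-sharing matrices.

    ``matrices[c]`` uses only markers *not* on chromosome ``c``;
    ``n_markers_used[c]`` is the count of those markers.
    """

    segregant_ids: list[str]
    matrices: dict[str, np.ndarray]
    n_markers_used: dict[str, int]

    def __getitem__(self, chromosome: str) -> np.ndarray:
        return self.matrices[chromosome]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.matrices)


def _sharing_counts(codes: np.ndarray, n_founders: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise (#equal non-missing calls, #jointly non-missing calls)."""
    observed = (codes != MISSING_CODE).astype(np.float64)
    joint = observed @ observed.T
    match = np.zeros_like(joint)
    for f in range(n_founders):
        ind = (codes == f).astype(np.float64)
        match += ind @ ind.T
    return match, joint


def allele_sharing(codes: np.ndarray, n_founders: int) -> np.ndarray:
    """Proportion of shared founder alleles for every segregant pair.

    Raises :class:`DegenerateKinshipError` if some pair has no jointly
    observed marker.
    """
    match, joint = _sharing_counts(codes, n_founders)
    n = codes.shape[0]
    off = ~np.eye(n, dtype=bool)
    if (joint[off] == 0).any():
        i, j = np.argwhere((joint == 0) & off)[0]
        raise DegenerateKinshipError(
            f"segregant pair ({i}, {j}) has no jointly observed marker"
        )
    A = match / joint
    np.fill_diagonal(A, 1.0)
    return A


def compute_loco_kinship(geno: FounderGenotypeTable) -> LocoKinshipSet:
    """Compute A(c) for every chromosome c of the marker map.

    Match and joint-observation counts are accumulated per chromosome once
    and subtracted from the genome-wide totals, so the cost is a single pass
    over the markers.
    """
    chroms = geno.markers.chromosomes
    if len(chroms) < 2:
        raise ValueError("LOCO kinship requires markers on >= 2 chromosomes")
    nf = len(geno.founder_labels)
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for c in chroms:
        mask = geno.markers.chromosome == c
        m, j = _sharing_counts(geno.codes[:, mask], nf)
        per_chrom[c] = (m, j, int(mask.sum()))
    total_match = sum(v[0] for v in per_chrom.values())
    total_joint = sum(v[1] for v in per_chrom.values())

    n = geno.n_segregants
    off = ~np.eye(n, dtype=bool)
    matrices: dict[str, np.ndarray] = {}
    n_used: dict[str, int] = {}
    for c in chroms:
        m, j, k = per_chrom[c]
        match = total_match - m
        joint = total_joint - j
        if (joint[off] == 0).any():
            i, jdx = np.argwhere((joint == 0) & off)[0]
            raise DegenerateKinshipError(
                f"segregants {geno.segregant_ids[i]!r} and "
                f"{geno.segregant_ids[jdx]!r} share no observed marker off "
                f"chromosome {c}"
            )
        with np.errstate(invalid="ignore"):
            A = match / joint
        np.fill_diagonal(A, 1.0)
        matrices[c] = A
        n_used[c] = geno.n_markers - k
        if n_used[c] == 0:
            raise ValueError(f"no markers available off chromosome {c}")
    return LocoKinshipSet(list(geno.segregant_ids), matrices, n_used)


def genomewide_kinship(geno: FounderGenotypeTable) -> np.ndarray:
    """Allele-sharing matrix over all markers (used by the phenotype
    simulator's polygenic term)."""
    return allele_sharing(geno.codes, len(geno.founder_labels))


def write_kinship(kin: LocoKinshipSet, directory: str | Path) -> None:
    """Optional writer: one square TSV per chromosome, ids as header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for c, A in kin.matrices.items():
        df = pd.DataFrame(A, index=kin.segregant_ids, columns=kin.segregant_ids)
        df.to_csv(directory / f"kinship_{c}.tsv", sep="\t", float_format="%.10g")
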