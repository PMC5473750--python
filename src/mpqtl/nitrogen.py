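"""Nitrogen-consumption phenotypes and transgression summaries.

Consumption of each nitrogen source is the difference between its initial
concentration in the synthetic must and its residual concentration after
fermentation.  Conversion to yeast-assimilable-nitrogen (YAN) units
multiplies by the source's nitrogen mass fraction, computed from the
N-atom count and the molecular weight of the compound *as supplied* (salt
and hydrate forms included, since the recipe's concentrations are salt
masses).

The shipped composition mirrors a 300 mgN/L synthetic wine must: 120 mgN/L
ammonium plus 180 mgN/L from a 19-amino-acid mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

_N_MASS = 14.007

#: molecular weight (g/mol, as-supplied form) and nitrogen atoms per molecule
AMINO_ACID_DATA: dict[str, tuple[float, int]] = {
    "proline": (115.13, 1),
    "glutamine": (146.15, 2),
    "arginine": (210.66, 4),      # L-arginine monohydrochloride
    "tryptophan": (204.23, 2),
    "alanine": (89.09, 1),
    "glutamic_acid": (147.13, 1),
    "serine": (105.09, 1),
    "threonine": (119.12, 1),
    "leucine": (131.17, 1),
    "aspartic_acid": (133.10, 1),
    "valine": (117.15, 1),
    "phenylalanine": (165.19, 1),
    "isoleucine": (131.17, 1),
    "histidine": (209.63, 3),     # L-histidine monohydrochloride monohydrate
    "methionine": (149.21, 1),
    "tyrosine": (181.19, 1),
    "glycine": (75.07, 1),
    "lysine": (182.65, 2),        # L-lysine monohydrochloride
    "cysteine": (121.16, 1),
}

#: SM300-style must: amino acid mg/L; ammonium carried directly in mgN/L.
SM300_AMINO_MG_PER_L: dict[str, float] = {
    "proline": 612.6,
    "glutamine": 503.5,
    "arginine": 503.5,
    "tryptophan": 179.3,
    "alanine": 145.3,
    "glutamic_acid": 120.4,
    "serine": 78.5,
    "threonine": 75.92,
    "leucine": 48.4,
    "aspartic_acid": 44.5,
    "valine": 44.5,
    "phenylalanine": 37.9,
    "isoleucine": 32.7,
    "histidine": 50.0,
    "methionine": 31.4,
    "tyrosine": 18.3,
    "glycine": 18.3,
    "lysine": 17.0,
    "cysteine": 13.1,
}

AMMONIUM = "ammonium"
SM300_AMMONIUM_MGN_PER_L = 120.0


def nitrogen_fraction(source: str, mode: str = "total") -> float:
    """mg N per mg of compound as supplied.

    ``mode="total"`` counts every nitrogen atom (N atoms x 14.007 / MW);
    ``mode="alpha_amino"`` counts one nitrogen per amino acid (14.007 /
    MW), the accounting under which the must recipe's 120 + 180 = 300
    mgN/L YAN budget adds up (formol-titration-style assimilable N).
    """
    if mode not in ("total", "alpha_amino"):
        raise ValueError(f"unknown nitrogen accounting mode {mode!r}")
    if source == AMMONIUM:
        return 1.0  # ammonium concentrations are carried in mgN/L directly
    try:
        mw, n_atoms = AMINO_ACID_DATA[source]
    except KeyError:
        raise KeyError(f"unknown nitrogen source {source!r}") from None
    atoms = n_atoms if mode == "total" else 1
    return atoms * _N_MASS / mw


@dataclass
class MustComposition:
    """Initial concentrations (mg/L; ammonium in mgN/L) and N fractions."""

    concentrations: dict[str, float]
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for src, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(f"negative initial concentration for {src!r}")
            if src not in self.fractions:
                raise ValueError(f"no nitrogen fraction for source {src!r}")
        for src, frac in self.fractions.items():
            if not (0 < frac <= 1):
                raise ValueError(f"nitrogen fraction for {src!r} outside (0, 1]")

    @classmethod
    def sm300(cls, mode: str = "total") -> "MustComposition":
        conc = dict(SM300_AMINO_MG_PER_L)
        conc[AMMONIUM] = SM300_AMMONIUM_MGN_PER_L
        frac = {src: nitrogen_fraction(src, mode) for src in conc}
        return cls(conc, frac)

    @property
    def sources(self) -> list[str]:
        return list(self.concentrations)

    def total_yan(self, include_proline: bool = True) -> float:
        """Total initial assimilable nitrogen (mgN/L) under this table's
        fractions.

        Proline is excludable: the recipe contains it but it is not
        assimilated under anaerobic fermentation.  Under alpha-amino
        fractions and with proline excluded the shipped recipe totals
        ~300 mgN/L (120 ammonium + ~180 amino acids).
        """
        total = 0.0
        for src, conc in self.concentrations.items():
            if src == "proline" and not include_proline:
                continue
            total += conc * self.fractions[src]
        return total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": self.sources,
                "initial_mg_per_l": [self.concentrations[s] for s in self.sources],
                "n_fraction": [self.fractions[s] for s in self.sources],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path) -> "MustComposition":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            dict(zip(df["source"], df["initial_mg_per_l"].astype(float))),
            dict(zip(df["source"], df["n_fraction"].astype(float))),
        )


@dataclass
class ConsumptionProfile:
    """Segregant x source consumption in mg/L and mgN/L.

    ``negative`` flags cells where the final concentration exceeded the
    initial one (measurement noise); the values are retained as-is.
    """

    consumed: pd.DataFrame
    consumed_n: pd.DataFrame
    negative: pd.DataFrame


def compute_consumption(
    composition: MustComposition, final: pd.DataFrame
) -> ConsumptionProfile:
    """Consumption = initial - final for every source column of ``final``.

    ``final`` is a segregant-indexed DataFrame of residual concentrations
    (same units as the composition).  Sources absent from the composition
    are rejected.
    """
    unknown = [c for c in final.columns if c not in composition.concentrations]
    if unknown:
        raise KeyError(f"final concentrations given for unknown source(s) {unknown}")
    if (final.to_numpy(float) < 0).any():
        raise ValueError("final concentrations must be >= 0")
    initial = pd.Series({c: composition.concentrations[c] for c in final.columns})
    consumed = initial - final
    fractions = pd.Series({c: composition.fractions[c] for c in final.columns})
    consumed_n = consumed * fractions
    return ConsumptionProfile(consumed, consumed_n, consumed < 0)


def to_yan(consumed_mg_per_l, source: str, composition: MustComposition | None = None) -> float:
    """Convert consumed mg/L of one source to mgN/L (linear in the amount)."""
    fractions = composition.fractions if composition is not None else None
    if fractions is not None:
        if source not in fractions:
            raise KeyError(f"unknown nitrogen source {source!r}")
        frac = fractions[source]
    else:
        frac = nitrogen_fraction(source)
    return consumed_mg_per_l * frac


@dataclass
class TransgressionSummary:
    """Fractions of segregants beyond the founder phenotype range."""

    positive_pct: float
    negative_pct: float
    n_positive: int
    n_negative: int
    n_total: int
    margin: float

    @property
    def total_pct(self) -> float:
        return self.positive_pct + self.negative_pct


def transgression_fraction(
    segregant_values: np.ndarray,
    founder_values: Mapping[str, np.ndarray],
    margin_sd: float = 1.0,
    margin: float | None = None,
) -> TransgressionSummary:
    """Percentage of segregants transgressing the founder mean range.

    A segregant is a positive transgressor if its value exceeds the maximum
    founder mean by more than the margin, negative if it falls below the
    minimum founder mean by more.  The default margin is ``margin_sd``
    pooled founder standard deviations; pass ``margin`` for an absolute
    margin (``margin=0`` reduces to simple range exceedance).  The
    criterion is a reported parameter, not a field standard.
    """
    seg = np.asarray(segregant_values, dtype=float)
    seg = seg[np.isfinite(seg)]
    means = []
    ss = 0.0
    dof = 0
    for founder, vals in founder_values.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValueError(f"founder {founder!r} needs >= 2 replicate values")
        means.append(vals.mean())
        ss += float(np.sum((vals - vals.mean()) ** 2))
        dof += len(vals) - 1
    if margin is None:
        pooled_sd = np.sqrt(ss / dof)
        if pooled_sd == 0:
            raise ValueError(
                "founder replicates have zero variance; use margin=0 for a "
                "pure range-exceedance rule"
            )
        margin = margin_sd * pooled_sd
    hi = max(means) + margin
    lo = min(means) - margin
    n_pos = int(np.sum(seg > hi))
    n_neg = int(np.sum(seg < lo))
    n = len(seg)
    return TransgressionSummary(
        positive_pct=100.0 * n_pos / n,
        negative_pct=100.0 * n_neg / n,
        n_positive=n_pos,
        n_negative=n_neg,
        n_total=n,
        margin=float(margin),
    )
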