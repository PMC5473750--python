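"""Shared fixtures: small simulated populations reused across test modules."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "scripts"))  # acceptance experiments live there

from mpqtl import (  # noqa: E402
    AILSimConfig,
    FounderGenotypeTable,
    MarkerMap,
    QTLEffect,
    TraitSimConfig,
    compute_loco_kinship,
    simulate_ail,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_ail():
    """165 segregants, 3 x 1 Mb chromosomes, markers every 20 kb."""
    config = AILSimConfig(
        seed=1101,
        chromosomes={"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000},
        pop_size=300,
        n_segregants=165,
        marker_spacing=20_000,
    )
    return simulate_ail(config)


@pytest.fixture(scope="session")
def small_kinship(small_ail):
    return compute_loco_kinship(small_ail)


@pytest.fixture(scope="session")
def qtl_phenotypes(small_ail):
    """One trait with a 25%-variance QTL mid-chromosome 2, one pure-noise trait."""
    causal = "chr2.500000"
    configs = [
        TraitSimConfig(
            seed=2202,
            name="arginine",
            h2=0.3,
            qtls=[
                QTLEffect(
                    causal,
                    {"NA": 1.5, "WA": -0.5, "WE": -0.5, "SA": -0.5},
                    variance_frac=0.25,
                )
            ],
        ),
        TraitSimConfig(seed=2203, name="noise", h2=0.0),
    ]
    return simulate_phenotypes(small_ail, configs)


@pytest.fixture()
def tiny_genotypes():
    """Hand-built 4-segregant, 2-chromosome table with one missing call."""
    markers = MarkerMap(
        np.array(["I.100", "I.200", "II.100", "II.200", "II.300"], dtype=object),
        np.array(["I", "I", "II", "II", "II"], dtype=object),
        np.array([100, 200, 100, 200, 300]),
    )
    calls = np.array(
        [
            ["NA", "NA", "WE", "WE", "SA"],
            ["WA", "NA", "WE", "SA", "SA"],
            ["NA", "WA", ".", "WE", "WA"],
            ["SA", "SA", "WA", "NA", "NA"],
        ],
        dtype=object,
    )
    return FounderGenotypeTable.from_labels(
        ["s1", "s2", "s3", "s4"], markers, calls
    )
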