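"""Genome scan orchestration, FDR step-up, region calling and merging."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mpqtl import (
    FounderGenotypeTable,
    PhenotypeTable,
    QTLRegion,
    add_qvalues,
    bh_qvalues,
    call_qtl,
    merge_regions,
    scan_trait,
)
from mpqtl.scan import build_covariate_design


# ---------------------------------------------------------------------------
# scan_trait
# ---------------------------------------------------------------------------


def test_planted_qtl_is_the_global_peak(small_ail, small_kinship, qtl_phenotypes):
    df = add_qvalues(scan_trait(qtl_phenotypes, "arginine", small_ail, small_kinship))
    ok = df[df["status"] == "ok"]
    peak = ok.loc[ok["p_value"].idxmin()]
    assert peak["chromosome"] == "chr2"
    assert abs(peak["position"] - 500_000) <= 50_000
    assert peak["q_value"] <= 0.5


def test_scan_relabeling_invariance(small_ail, small_kinship, qtl_phenotypes):
    """Permuting segregants jointly in genotypes and phenotypes changes nothing."""
    rng = np.random.default_rng(8)
    perm = rng.permutation(small_ail.n_segregants)
    geno_p = FounderGenotypeTable(
        [small_ail.segregant_ids[i] for i in perm],
        small_ail.markers,
        small_ail.codes[perm],
        small_ail.founder_labels,
    )
    pheno_p = PhenotypeTable(
        [qtl_phenotypes.segregant_ids[i] for i in perm],
        qtl_phenotypes.traits.iloc[perm].reset_index(drop=True),
        qtl_phenotypes.covariates.iloc[perm].reset_index(drop=True),
    )
    from mpqtl import compute_loco_kinship

    # scan two chromosomes for speed (tables must keep >= 2 chromosomes)
    sub = np.isin(small_ail.markers.chromosome, ["chr1", "chr2"])
    base = scan_trait(
        qtl_phenotypes, "arginine", small_ail.subset_markers(sub), small_kinship
    )
    perm_df = scan_trait(
        pheno_p, "arginine", geno_p.subset_markers(sub), compute_loco_kinship(geno_p)
    )
    # permutation reorders the eigendecomposition, so agreement is to
    # optimizer precision rather than bitwise
    np.testing.assert_allclose(
        base["p_value"].to_numpy(), perm_df["p_value"].to_numpy(), rtol=1e-5
    )


def test_scan_scale_invariance(small_ail, small_kinship, qtl_phenotypes):
    sub = np.isin(small_ail.markers.chromosome, ["chr1", "chr2"])
    geno = small_ail.subset_markers(sub)
    base = scan_trait(qtl_phenotypes, "arginine", geno, small_kinship)
    scaled = PhenotypeTable(
        qtl_phenotypes.segregant_ids,
        qtl_phenotypes.traits * 37.5,
        qtl_phenotypes.covariates.copy(),
    )
    other = scan_trait(scaled, "arginine", geno, small_kinship)
    np.testing.assert_allclose(
        base["wald"].to_numpy(), other["wald"].to_numpy(), rtol=1e-6
    )


def test_monomorphic_marker_skipped(small_ail, small_kinship, qtl_phenotypes):
    geno = small_ail
    mono = FounderGenotypeTable(
        geno.segregant_ids,
        geno.markers,
        np.where(
            (geno.markers.chromosome == "chr1")[None, :], 0, geno.codes
        ).astype(np.int8),
        geno.founder_labels,
    )
    df = scan_trait(qtl_phenotypes, "noise", mono, small_kinship)
    chr1 = df[df["chromosome"] == "chr1"]
    assert (chr1["status"] == "monomorphic").all()
    assert chr1["p_value"].isna().all()


def test_all_missing_trait_rejected(small_ail, small_kinship, qtl_phenotypes):
    empty = PhenotypeTable(
        qtl_phenotypes.segregant_ids,
        pd.DataFrame({"empty": np.full(small_ail.n_segregants, np.nan)}),
        qtl_phenotypes.covariates.copy(),
    )
    with pytest.raises(ValueError, match="no non-missing"):
        scan_trait(empty, "empty", small_ail, small_kinship)


def test_underpowered_trait_rejected(small_ail, small_kinship, qtl_phenotypes):
    y = np.full(small_ail.n_segregants, np.nan)
    y[:20] = np.random.default_rng(0).normal(size=20)
    sparse = PhenotypeTable(
        qtl_phenotypes.segregant_ids,
        pd.DataFrame({"sparse": y}),
        qtl_phenotypes.covariates.copy(),
    )
    with pytest.raises(ValueError, match="at least 30"):
        scan_trait(sparse, "sparse", small_ail, small_kinship)


def test_missing_calls_reduce_n_eff(small_ail, small_kinship, qtl_phenotypes):
    codes = small_ail.codes.copy()
    k = 3
    codes[:10, k] = -1
    geno = FounderGenotypeTable(
        small_ail.segregant_ids, small_ail.markers, codes, small_ail.founder_labels
    )
    sub = np.isin(geno.markers.chromosome, ["chr1", "chr2"])
    df = scan_trait(qtl_phenotypes, "noise", geno.subset_markers(sub), small_kinship)
    assert df.iloc[k]["n_eff"] == small_ail.n_segregants - 10


def test_covariate_design_rows_sum_to_one():
    cov = pd.DataFrame(
        {
            "mating_type": ["a", "alpha", "a", "alpha"],
            "lys2": ["LYS2", "lys2", "LYS2", "lys2"],
            "ura3": ["URA3", "URA3", "ura3", "ura3"],
        }
    )
    M, names = build_covariate_design(cov)
    combo_block = M[:, : sum(n.startswith("combo") for n in names)]
    np.testing.assert_array_equal(combo_block.sum(axis=1), np.ones(4))
    assert np.linalg.matrix_rank(M) == M.shape[1]


def test_covariate_design_rejects_excess_combinations():
    cov = pd.DataFrame(
        {"lys2": ["a", "b", "c", "d", "e"], "ura3": ["1", "2", "3", "4", "5"]}
    )
    with pytest.raises(ValueError, match="combinations exceed"):
        build_covariate_design(cov)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def test_bh_step_up_hand_case():
    np.testing.assert_allclose(
        bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_equal_and_single():
    np.testing.assert_allclose(bh_qvalues(np.array([0.2, 0.2, 0.2])), [0.2, 0.2, 0.2])
    np.testing.assert_allclose(bh_qvalues(np.array([0.123])), [0.123])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60)
)
def test_bh_monotone_and_nested(p_list):
    p = np.array(p_list)
    q = bh_qvalues(p)
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()  # q monotone in p rank
    for alpha, alpha2 in [(0.05, 0.2), (0.1, 0.5)]:
        assert set(np.flatnonzero(q <= alpha)) <= set(np.flatnonzero(q <= alpha2))


def test_qvalues_adjusted_within_trait(small_ail, small_kinship, qtl_phenotypes):
    sub = np.isin(small_ail.markers.chromosome, ["chr1", "chr2"])
    geno = small_ail.subset_markers(sub)
    a = scan_trait(qtl_phenotypes, "arginine", geno, small_kinship)
    b = scan_trait(qtl_phenotypes, "noise", geno, small_kinship)
    both = add_qvalues(pd.concat([a, b], ignore_index=True))
    solo = add_qvalues(a)
    merged = both[both["trait"] == "arginine"]
    np.testing.assert_allclose(
        merged["q_value"].to_numpy(), solo["q_value"].to_numpy(), rtol=1e-12
    )


# ---------------------------------------------------------------------------
# Region calling and merging
# ---------------------------------------------------------------------------


def _scan_frame(qvals, positions=None, chrom="I", trait="t"):
    n = len(qvals)
    positions = positions or [1000 * (i + 1) for i in range(n)]
    return pd.DataFrame(
        {
            "trait": [trait] * n,
            "marker": [f"{chrom}.{p}" for p in positions],
            "chromosome": [chrom] * n,
            "position": positions,
            "status": ["ok"] * n,
            "n_eff": [100] * n,
            "df": [3] * n,
            "wald": [1.0] * n,
            "p_value": [q / 2 for q in qvals],
            "q_value": qvals,
        }
    )


def test_call_qtl_empty_when_nothing_passes():
    assert call_qtl(_scan_frame([0.9, 0.8, 0.7])) == []


def test_call_qtl_isolated_marker_width_one():
    regions = call_qtl(_scan_frame([0.9, 0.1, 0.9]))
    assert len(regions) == 1
    assert regions[0].start == regions[0].end == 2000
    assert regions[0].peak_marker == "I.2000"


def test_call_qtl_run_splitting_rule():
    # two significant runs separated by two non-significant markers
    qv = [0.1, 0.1, 0.9, 0.9, 0.1, 0.1]
    assert len(call_qtl(_scan_frame(qv), max_gap=0)) == 2
    assert len(call_qtl(_scan_frame(qv), max_gap=1)) == 2
    assert len(call_qtl(_scan_frame(qv), max_gap=2)) == 1


def test_call_qtl_peak_is_min_p():
    df = _scan_frame([0.2, 0.05, 0.2])
    region = call_qtl(df)[0]
    assert region.peak_marker == "I.2000"
    assert region.start == 1000 and region.end == 3000


def _r(chrom, start, end, trait="t", nlp=5.0):
    return QTLRegion(f"{trait}:{chrom}", chrom, start, end, [trait], "m", nlp, 0.1)


def test_merge_overlapping_intervals():
    merged = merge_regions([_r("I", 1, 10, "a"), _r("I", 5, 15, "b")])
    assert len(merged) == 1
    assert (merged[0].start, merged[0].end) == (1, 15)
    assert merged[0].traits == ["a", "b"]


def test_merge_keeps_chromosomes_apart():
    merged = merge_regions([_r("I", 1, 10), _r("II", 1, 10)])
    assert len(merged) == 2


def test_merge_transitive_chain():
    merged = merge_regions([_r("I", 1, 10), _r("I", 8, 20), _r("I", 19, 30)])
    assert len(merged) == 1
    assert (merged[0].start, merged[0].end) == (1, 30)


def test_merge_adjacent_but_disjoint_not_merged():
    merged = merge_regions([_r("I", 1, 10), _r("I", 11, 20)])
    assert len(merged) == 2


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["I", "II"]),
            st.integers(min_value=1, max_value=500),
            st.integers(min_value=0, max_value=100),
        ),
        min_size=0,
        max_size=12,
    )
)
def test_merge_idempotent(raw):
    regions = [_r(c, s, s + w) for c, s, w in raw]
    once = merge_regions(regions)
    twice = merge_regions(once)
    assert [(r.chromosome, r.start, r.end, tuple(r.traits)) for r in once] == [
        (r.chromosome, r.start, r.end, tuple(r.traits)) for r in twice
    ]
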