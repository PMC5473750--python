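"""Pooled SNP filtering, Fisher testing, q-values and cross-referencing."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from mpqtl import PoolAlleleCounts, POOLS
from mpqtl.bsr import (
    af_test,
    candidates_to_frame,
    cross_reference,
    estimate_pi0,
    estimate_qvalues,
    expression_ratio,
    filter_pool_snps,
    fisher_p,
)
from mpqtl.io import GeneExpressionCounts
from mpqtl.scan import bh_qvalues


def _counts(rows):
    cols = ["chrom", "pos", "ref", "alt"] + [
        f"{p}.{part}" for p in POOLS for part in ("ref", "alt")
    ]
    return PoolAlleleCounts(pd.DataFrame(rows, columns=cols))


def _row(chrom, pos, pools):
    row = {"chrom": chrom, "pos": pos, "ref": "A", "alt": "T"}
    for pool, (r, a) in zip(POOLS, pools):
        row[f"{pool}.ref"] = r
        row[f"{pool}.alt"] = a
    return row


def enumeration_fisher(table):
    """Oracle: two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    n1, n2 = a + b, c + d
    N = n1 + n2
    c1 = a + c
    lo, hi = max(0, c1 - n2), min(n1, c1)
    xs = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(xs, N, c1, n1)
    p_obs = hypergeom.pmf(a, N, c1, n1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def test_filter_low_depth_pool_removed():
    counts = _counts([_row("I", 100, [(12, 3), (10, 5), (20, 4), (5, 4)])])
    filtered, report = filter_pool_snps(counts, min_reads=10)
    assert len(filtered) == 0
    assert report.n_low_depth == 1


def test_filter_absent_pool_removed():
    counts = _counts([_row("I", 100, [(0, 0), (10, 5), (20, 4), (15, 4)])])
    filtered, report = filter_pool_snps(counts, min_reads=10)
    assert len(filtered) == 0
    assert report.n_absent_from_pool == 1


def test_filter_retains_covered_snp():
    counts = _counts([_row("I", 100, [(12, 0), (15, 0), (30, 0), (10, 0)])])
    filtered, report = filter_pool_snps(counts, min_reads=10)
    assert len(filtered) == 1
    assert report.n_retained == 1


def test_filter_strict_mode_requires_both_alleles():
    counts = _counts([_row("I", 100, [(12, 10), (15, 11), (30, 12), (10, 10)]),
                      _row("I", 200, [(22, 0), (25, 1), (30, 2), (20, 3)])])
    default, _ = filter_pool_snps(counts, min_reads=10)
    strict, _ = filter_pool_snps(counts, min_reads=10, strict=True)
    assert len(default) == 2
    assert len(strict) == 1  # pool-fixed SNP dropped only under strict reading


def test_filter_then_test_commutes():
    rows = [
        _row("I", 100 * (i + 1), [(10 + i, 5), (12, 4 + i), (3 * i, 8), (9, 9)])
        for i in range(6)
    ]
    counts = _counts(rows)
    filtered, _ = filter_pool_snps(counts)
    direct = af_test(filtered)
    full = af_test(counts)
    keys = filtered.table[["chrom", "pos"]].apply(tuple, axis=1)
    subset = full[full[["chrom", "pos"]].apply(tuple, axis=1).isin(set(keys))]
    np.testing.assert_allclose(
        direct["p_value"].to_numpy(), subset["p_value"].to_numpy(), rtol=1e-12
    )


# ---------------------------------------------------------------------------
# Fisher tests
# ---------------------------------------------------------------------------


def test_fisher_identical_proportions():
    p, degenerate = fisher_p([[10, 10], [10, 10]])
    assert p == 1.0 and not degenerate


def test_fisher_extreme_table_closed_form():
    p, _ = fisher_p([[50, 0], [0, 50]])
    assert p == pytest.approx(2 / comb(100, 50), rel=1e-9)


def test_fisher_matches_enumeration_moderate_margins():
    for table in ([[15, 5], [5, 15]], [[12, 8], [7, 13]], [[20, 0], [18, 2]]):
        p, _ = fisher_p(table)
        assert p == pytest.approx(enumeration_fisher(table), rel=1e-9)


def test_fisher_zero_margin_degenerate():
    p, degenerate = fisher_p([[10, 0], [20, 0]])
    assert p == 1.0 and degenerate


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(min_value=0, max_value=40)] * 4))
def test_fisher_symmetric_under_condition_swap(cells):
    a, b, c, d = cells
    p1, _ = fisher_p([[a, b], [c, d]])
    p2, _ = fisher_p([[c, d], [a, b]])
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_af_test_summed_and_direction():
    counts = _counts([_row("I", 100, [(30, 0), (28, 2), (1, 29), (3, 27)])])
    out = af_test(counts)
    assert out.loc[0, "HLA.ref"] == 58 and out.loc[0, "LLA.alt"] == 56
    assert out.loc[0, "direction"] == "HLA"
    assert out.loc[0, "p_value"] == pytest.approx(
        enumeration_fisher([[58, 2], [4, 56]]), rel=1e-9
    )


def test_af_test_per_replicate_mode_is_conservative():
    counts = _counts([_row("I", 100, [(30, 0), (28, 2), (1, 29), (3, 27)])])
    summed = af_test(counts, mode="summed").loc[0, "p_value"]
    per_rep = af_test(counts, mode="per-replicate").loc[0, "p_value"]
    assert per_rep >= summed


def test_null_pools_calibrated_rejection_rate():
    """Equal allele frequencies in both conditions: ~5% of SNPs at p<0.05."""
    rng = np.random.default_rng(42)
    n = 10_000
    freq = rng.uniform(0.2, 0.8, size=n)
    rows = []
    for i in range(n):
        pools = []
        for _ in POOLS:
            depth = rng.poisson(60)
            ref = rng.binomial(depth, freq[i])
            pools.append((ref, depth - ref))
        rows.append(_row("I", i + 1, pools))
    out = af_test(_counts(rows))
    rate = float((out["p_value"] < 0.05).mean())
    assert abs(rate - 0.05) < 0.02  # Fisher is discrete, slightly conservative


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------


def test_qvalues_all_ones():
    np.testing.assert_allclose(estimate_qvalues(np.ones(50)), np.ones(50))


def test_storey_never_exceeds_bh():
    rng = np.random.default_rng(9)
    for _ in range(10):
        p = rng.uniform(1e-6, 1.0, size=200)
        storey = estimate_qvalues(p, method="storey")
        bh = bh_qvalues(p)
        assert (storey <= bh + 1e-12).all()


def test_pi0_near_one_for_uniform_pvalues():
    rng = np.random.default_rng(31)
    p = rng.uniform(size=10_000)
    assert 0.9 <= estimate_pi0(p) <= 1.0


def test_qvalues_bh_mode_matches_step_up():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(estimate_qvalues(p, method="bh"), bh_qvalues(p))


# ---------------------------------------------------------------------------
# expression ratios
# ---------------------------------------------------------------------------


def _genes(rows):
    return GeneExpressionCounts(pd.DataFrame(rows, columns=["gene_id", *POOLS]))


def test_expression_ratio_equal_counts_not_flagged():
    genes = _genes([{"gene_id": "g1", **{p: 100 for p in POOLS}}])
    out = expression_ratio(genes)
    assert out.loc[0, "ratio"] == pytest.approx(1.0)
    assert not out.loc[0, "extreme"]


def test_expression_ratio_direct_arithmetic():
    # equal library sizes; combined HLA 600 vs LLA 10 -> (600+1)/(10+1)
    genes = _genes(
        [
            {"gene_id": "g1", "HLA-1": 300, "HLA-2": 300, "LLA-1": 5, "LLA-2": 5},
            {"gene_id": "g2", "HLA-1": 5, "HLA-2": 5, "LLA-1": 300, "LLA-2": 300},
        ]
    )
    out = expression_ratio(genes, pseudocount=1, ratio_threshold=5)
    assert out.loc[0, "ratio"] == pytest.approx(601 / 11, rel=1e-9)
    assert out.loc[0, "extreme"] and out.loc[0, "direction"] == "HLA"
    assert out.loc[1, "extreme"] and out.loc[1, "direction"] == "LLA"


def test_expression_ratio_zero_lla_finite():
    genes = _genes(
        [
            {"gene_id": "g1", "HLA-1": 50, "HLA-2": 50, "LLA-1": 0, "LLA-2": 0},
            {"gene_id": "g2", "HLA-1": 50, "HLA-2": 50, "LLA-1": 100, "LLA-2": 100},
        ]
    )
    out = expression_ratio(genes)
    assert np.isfinite(out["ratio"]).all()


# ---------------------------------------------------------------------------
# cross-referencing
# ---------------------------------------------------------------------------


def _scan(rows):
    return pd.DataFrame(
        rows,
        columns=["trait", "marker", "chromosome", "position", "status", "p_value"],
    )


ANN = pd.DataFrame(
    {
        "gene_id": ["g_near", "g_far", "g_other"],
        "chromosome": ["I", "I", "II"],
        "start": [100_000, 300_000, 50_000],
        "end": [102_000, 302_000, 52_000],
    }
)


def _passing_scan():
    return _scan(
        [
            ("t", "I.110000", "I", 110_000, "ok", 1e-7),   # 8 kb from g_near
            ("t", "I.280000", "I", 280_000, "ok", 1e-8),   # 20 kb from g_far
            ("t", "II.51000", "II", 51_000, "ok", 1e-3),   # not passing
        ]
    )


def test_cross_reference_flank_rule():
    cands = cross_reference(
        _passing_scan(), ANN, de_genes=["g_near", "g_far", "g_other"], flank=15_000
    )
    ids = {c.gene_id for c in cands}
    assert ids == {"g_near"}  # g_far is 20 kb away, g_other has no passing marker
    assert cands[0].in_qtl and cands[0].de_listed
    assert not cands[0].af_significant


def test_cross_reference_requires_second_evidence():
    assert cross_reference(_passing_scan(), ANN) == []


def test_cross_reference_af_evidence():
    af = pd.DataFrame(
        {"chrom": ["I"], "pos": [101_000], "p_value": [1e-9], "q_value": [1e-6]}
    )
    cands = cross_reference(_passing_scan(), ANN, af_results=af, af_q_max=0.001)
    assert [c.gene_id for c in cands] == ["g_near"]
    assert cands[0].af_significant


def test_cross_reference_exact_overlap_set():
    wide = cross_reference(
        _passing_scan(), ANN, de_genes=list(ANN["gene_id"]), flank=25_000
    )
    assert {c.gene_id for c in wide} == {"g_near", "g_far"}


def test_cross_reference_chromosome_mismatch():
    ann = ANN.assign(chromosome=["chrI", "chrI", "chrII"])
    with pytest.raises(ValueError, match="chrI"):
        cross_reference(_passing_scan(), ann)


def test_candidates_frame_columns():
    cands = cross_reference(
        _passing_scan(), ANN, de_genes=["g_near"], flank=15_000
    )
    df = candidates_to_frame(cands)
    assert list(df["gene_id"]) == ["g_near"]
    assert bool(df.loc[0, "DE_listed"])
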