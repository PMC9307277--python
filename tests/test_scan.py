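"""Association scan: SNP coding, calibration, genomic control, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridmap.scan import (
    annotate_significance,
    effective_tests,
    encode_genotypes,
    genomic_control,
    scan_trait,
    thresholds,
)

from conftest import make_genotypes


class TestEncoding:
    def test_paper_coding(self):
        # counted allele 'A' at frequency 4/6 -> A is the major allele
        g = make_genotypes(np.array([[2], [1], [0]]))
        enc = encode_genotypes(g, 0)
        assert enc.xa.tolist() == [1.0, 0.0, -1.0]
        assert enc.xd.tolist() == [0.0, 1.0, 0.0]
        assert enc.major_allele == "A"

    def test_all_heterozygotes(self):
        g = make_genotypes(np.ones((4, 1), dtype=np.int8))
        enc = encode_genotypes(g, 0)
        assert np.all(enc.xa == 0.0)
        assert np.all(enc.xd == 1.0)

    def test_allele_relabelling_flips_xa_only(self):
        calls = np.array([[2], [2], [1], [0], [2]])
        g1 = make_genotypes(calls)
        g2 = make_genotypes(2 - calls, counted=["G"], other=["A"])
        e1, e2 = encode_genotypes(g1, 0), encode_genotypes(g2, 0)
        assert np.array_equal(e1.xa, e2.xa)  # same major allele either way
        assert np.array_equal(e1.xd, e2.xd)
        assert e1.major_allele == e2.major_allele == "A"

    def test_monomorphic_rejected(self):
        g = make_genotypes(np.full((4, 1), 2, dtype=np.int8))
        with pytest.raises(ValueError, match="monomorphic"):
            encode_genotypes(g, 0)

    def test_missing_individuals_dropped(self):
        g = make_genotypes(np.array([[2], [-1], [0], [1]]))
        enc = encode_genotypes(g, 0)
        assert enc.mask.sum() == 3
        assert len(enc.xa) == 3


class TestGenomicControl:
    def test_reference_median_gives_lambda_one(self):
        lam, adj = genomic_control(np.full(101, 0.5))
        assert lam == pytest.approx(1.0)
        assert np.allclose(adj, 0.5)

    def test_uniform_p_lambda_near_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=10_000)
        lam, _ = genomic_control(p)
        assert 0.95 < lam < 1.05

    def test_doubled_chi2_deflated_back_to_uniform(self):
        rng = np.random.default_rng(2)
        p0 = rng.uniform(0.001, 1.0, size=5001)
        chi2 = stats.chi2.isf(p0, 1)
        p_infl = stats.chi2.sf(2.0 * chi2, 1)
        lam, adj = genomic_control(p_infl)
        assert lam == pytest.approx(2.0, rel=0.05)
        # deflation divides by the estimated lambda, recovering the originals
        assert np.allclose(adj, stats.chi2.sf(2.0 * chi2 / lam, 1))
        assert stats.kstest(adj, "uniform").pvalue > 0.01

    def test_no_adjustment_below_trigger(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=999)
        lam, adj = genomic_control(p)
        if lam <= 1.05:
            assert np.array_equal(adj, p)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_control([])


class TestEffectiveTests:
    def test_perfectly_correlated_traits_give_one(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(200)
        y = np.column_stack([base] * 6)
        assert effective_tests(y) == pytest.approx(1.0)

    def test_independent_traits_approach_m(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((5000, 10))
        meff = effective_tests(y)
        assert abs(meff - 10) / 10 < 0.05

    def test_block_structure_matches_closed_form(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal((2, 4000))
        y = np.column_stack([a] * 5 + [b] * 5)
        # eigenvalues of the 10x10 correlation matrix: (5, 5, 0 x 8)
        lam = np.array([5.0] * 2 + [0.0] * 8)
        expected = 1 + 9 * (1 - np.var(lam, ddof=1) / 10)
        assert effective_tests(y) == pytest.approx(expected, abs=0.05)

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(7)
        y = np.column_stack([rng.standard_normal(100),
                             np.ones(100),
                             rng.standard_normal(100)])
        with pytest.warns(UserWarning, match="constant"):
            meff = effective_tests(y)
        assert 1.0 <= meff <= 2.0


class TestThresholds:
    def test_study_bonferroni_value(self):
        gw, _ = thresholds(32_625, meff=1.0)
        assert gw == pytest.approx(1.53e-6, rel=5e-3)

    def test_meff_one_collapses_thresholds(self):
        gw, sw = thresholds(1000, meff=1.0)
        assert gw == sw

    def test_arithmetic(self):
        assert thresholds(10, 2.0) == (0.005, 0.0025)


@pytest.fixture(scope="module")
def small_scan_inputs(cohort_small):
    from hybridmap.relatedness import loco_grms

    geno, ped = cohort_small
    return geno, ped, loco_grms(geno)


class TestScan:
    def test_null_scan_roughly_uniform(self, small_scan_inputs):
        geno, ped, loco = small_scan_inputs
        rng = np.random.default_rng(8)
        y = rng.standard_normal(geno.n_samples)
        res = scan_trait(y, geno, ped, loco)
        assert stats.kstest(res["p_total"], "uniform").pvalue > 0.001
        assert res["p_total"].between(0, 1).all()

    def test_additive_qtl_detected_with_additive_signature(self, small_scan_inputs):
        geno, ped, loco = small_scan_inputs
        rng = np.random.default_rng(9)
        j = int(np.argmax(geno.maf()))
        g = geno.calls[:, j].astype(float)
        y = 1.5 * (g - 1.0) + rng.standard_normal(geno.n_samples)
        res = scan_trait(y, geno, ped, loco).set_index("marker_id")
        rec = res.loc[geno.marker_map["marker_id"].iloc[j]]
        assert rec["p_total"] < 1e-6
        assert rec["p_additive"] < rec["p_dominance"]
        assert rec["a"] == pytest.approx(1.5, abs=0.5)

    def test_overdominant_qtl_has_dominance_signature(self, small_scan_inputs):
        geno, ped, loco = small_scan_inputs
        rng = np.random.default_rng(10)
        j = int(np.argmax(geno.maf()))
        het = (geno.calls[:, j] == 1).astype(float)
        y = 1.5 * het + rng.standard_normal(geno.n_samples)
        res = scan_trait(y, geno, ped, loco).set_index("marker_id")
        rec = res.loc[geno.marker_map["marker_id"].iloc[j]]
        assert rec["p_dominance"] < rec["p_additive"]

    def test_exact_mode_agrees_with_approximate(self, small_scan_inputs):
        geno, ped, loco = small_scan_inputs
        rng = np.random.default_rng(11)
        j = int(np.argmax(geno.maf()))
        chrom = geno.marker_map["chromosome"].iloc[j]
        idx = np.flatnonzero((geno.marker_map["chromosome"] == chrom).to_numpy())
        sub = geno.subset(marker_idx=idx)
        g = geno.calls[:, j].astype(float)
        y = 1.0 * (g - 1.0) + rng.standard_normal(geno.n_samples)
        approx = scan_trait(y, sub, ped, loco, mode="approximate")
        exact = scan_trait(y, sub, ped, loco, mode="exact")
        m = geno.marker_map["marker_id"].iloc[j]
        pa = approx.set_index("marker_id").loc[m, "p_total"]
        pe = exact.set_index("marker_id").loc[m, "p_total"]
        assert pa < 1e-4 and pe < 1e-4
        assert abs(np.log10(pa) - np.log10(pe)) < 1.0

    def test_missing_loco_grm_rejected(self, small_scan_inputs):
        geno, ped, loco = small_scan_inputs
        partial = {k: v for k, v in loco.items()
                   if k != geno.marker_map["chromosome"].iloc[0]}
        with pytest.raises(ValueError, match="LOCO"):
            scan_trait(np.zeros(geno.n_samples), geno, ped, partial)

    def test_significance_flags_nested(self, small_scan_inputs):
        geno, ped, loco = small_scan_inputs
        rng = np.random.default_rng(12)
        y = rng.standard_normal(geno.n_samples)
        res = scan_trait(y, geno, ped, loco)
        res = annotate_significance(res, genome_wide=0.05, study_wide=0.005)
        assert (res.loc[res["study_wide"], "genome_wide"]).all()
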