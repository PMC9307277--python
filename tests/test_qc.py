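"""Genotype QC: HWE exact test, filters, LD pruning, AIMs, hybrid index."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from hybridmap.genotypes import MISSING
from hybridmap.qc import (
    find_aims,
    hwe_exact_test,
    hybrid_index,
    ld_prune,
    ld_r2,
    qc_filter,
)

from conftest import make_genotypes


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact-arithmetic enumeration of the conditional HWE distribution."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    rare = min(na, 2 * n - na)
    if rare == 0 or n == 0:
        return 1.0
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        homr = (rare - h) // 2
        homc = (2 * n - rare - h) // 2
        probs[h] = Fraction(
            2**h * math.factorial(n),
            math.factorial(h) * math.factorial(homr) * math.factorial(homc),
        )
    total = sum(probs.values())
    obs = probs[n_ab]
    return float(sum(v for v in probs.values() if v <= obs) / total)


class TestHWE:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(42, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(0, 50, 0), (25, 50, 25), (10, 5, 40), (3, 20, 3), (1, 1, 1),
         (0, 3, 97), (12, 0, 12)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-9)

    def test_balanced_sample_not_rejected(self):
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 0)


class TestQCFilter:
    def test_low_maf_marker_removed(self):
        # 50 individuals; marker 1 has MAF 0.04, marker 2 MAF 0.5 in HWE
        m1 = np.array([1] * 4 + [0] * 46)
        m2 = np.array([0] * 13 + [1] * 25 + [2] * 12)
        g = make_genotypes(np.column_stack([m1, m2]))
        out, report = qc_filter(g)
        assert out.n_markers == 1
        assert report.removed_markers["maf"] == 1
        assert out.marker_map["marker_id"].tolist() == ["snp2"]

    def test_low_call_rate_individual_removed(self):
        calls = np.array(
            [[(i + j) % 3 for j in range(20)] for i in range(12)], dtype=np.int8
        )
        calls[0, :3] = MISSING  # 85% call rate on 20 markers
        g = make_genotypes(calls)
        out, report = qc_filter(g, maf=0.0, hwe_p=0.0)
        assert report.removed_individuals["call_rate"] == 1
        assert out.n_samples == g.n_samples - 1

    def test_removed_plus_retained_consistent(self, cohort_small):
        geno, _ = cohort_small
        out, report = qc_filter(geno)
        removed = sum(report.removed_markers.values())
        assert removed + report.n_markers_out == report.n_markers_in

    def test_idempotent(self, cohort_small):
        geno, _ = cohort_small
        once, _ = qc_filter(geno)
        twice, rep2 = qc_filter(once)
        assert np.array_equal(once.calls, twice.calls)
        assert sum(rep2.removed_markers.values()) == 0


class TestLDr2:
    def test_self_is_one(self, cohort_small):
        geno, _ = cohort_small
        j = int(np.argmax(geno.maf()))
        assert ld_r2(geno, j, j) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        g = make_genotypes(np.array([[0, 2], [1, 1], [2, 0], [0, 2]]))
        assert ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_zero_variance_is_nan(self):
        g = make_genotypes(np.array([[1, 0], [1, 1], [1, 2]]))
        assert np.isnan(ld_r2(g, 0, 1))

    def test_null_mean_near_one_over_n(self):
        rng = np.random.default_rng(5)
        n, m = 1000, 400
        calls = rng.binomial(2, 0.4, size=(n, m)).astype(np.int8)
        g = make_genotypes(calls)
        vals = np.array([ld_r2(g, 2 * k, 2 * k + 1) for k in range(m // 2)])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 1 / (n - 1)) < 3 * se


def brute_force_prune(g, r2_max=0.9):
    """All-pairs greedy pruning oracle with the same tie rules."""
    mafs = g.maf()
    alive = list(range(g.n_markers))
    while True:
        worst = None
        for ai, a in enumerate(alive):
            for b in alive[ai + 1 :]:
                r2 = ld_r2(g, a, b)
                if not np.isnan(r2) and r2 > r2_max:
                    worst = (a, b)
                    break
            if worst:
                break
        if worst is None:
            return [g.marker_map["marker_id"].iloc[k] for k in alive]
        a, b = worst
        drop = a if mafs[a] < mafs[b] else b  # tie -> later position (b)
        alive.remove(drop)


class TestLDPrune:
    def test_duplicate_marker_keeps_one(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        g = make_genotypes(np.column_stack([col, col]))
        kept = ld_prune(g)
        assert len(kept) == 1

    def test_low_ld_keeps_all(self):
        rng = np.random.default_rng(6)
        calls = rng.binomial(2, 0.5, size=(200, 10)).astype(np.int8)
        g = make_genotypes(calls)
        assert len(ld_prune(g)) == 10

    def test_matches_brute_force_oracle_on_ld_block(self):
        rng = np.random.default_rng(7)
        base = rng.binomial(2, 0.5, size=(150, 3)).astype(np.int8)
        cols = [base[:, 0]]
        for k in range(9):
            src = cols[-1] if k % 2 else base[:, k % 3]
            noisy = src.copy()
            flip = rng.random(150) < 0.02
            noisy[flip] = rng.binomial(2, 0.5, size=flip.sum())
            cols.append(noisy.astype(np.int8))
        g = make_genotypes(np.column_stack(cols))
        assert ld_prune(g, window=10) == brute_force_prune(g)

    def test_insensitive_to_individual_order(self, cohort_small):
        geno, _ = cohort_small
        kept = ld_prune(geno)
        perm = np.random.default_rng(8).permutation(geno.n_samples)
        kept_perm = ld_prune(geno.subset(sample_idx=perm))
        assert kept == kept_perm


class TestAIMs:
    def _panels(self, mus_col, dom_col):
        gm = make_genotypes(np.array(mus_col)[:, None])
        gd = make_genotypes(np.array(dom_col)[:, None])
        return gm, gd

    def test_fixed_difference_is_aim(self):
        gm, gd = self._panels([2] * 10, [0] * 10)
        aims = find_aims(gm, gd)
        assert len(aims) == 1
        assert aims["musculus_allele"].iloc[0] == "A"

    def test_small_freq_difference_rejected(self):
        # freqs 0.6 vs 0.4: major allele differs but diff <= 0.3
        gm, gd = self._panels([2] * 6 + [0] * 4, [2] * 4 + [0] * 6)
        assert len(find_aims(gm, gd)) == 0

    def test_too_few_calls_rejected(self):
        gm, gd = self._panels([2] * 9, [0] * 10)
        assert len(find_aims(gm, gd)) == 0

    def test_marker_map_mismatch_rejected(self):
        gm = make_genotypes(np.zeros((10, 2), dtype=np.int8))
        gd = make_genotypes(np.zeros((10, 1), dtype=np.int8))
        with pytest.raises(ValueError):
            find_aims(gm, gd)


class TestHybridIndex:
    def _aims(self, g, allele="A"):
        return pd.DataFrame(
            {"marker_id": g.marker_map["marker_id"], "musculus_allele": allele}
        )

    def test_pure_musculus_is_one(self):
        g = make_genotypes(np.full((3, 5), 2, dtype=np.int8))
        hi = hybrid_index(g, self._aims(g))
        assert np.allclose(hi, 1.0)

    def test_all_het_is_half(self):
        g = make_genotypes(np.ones((3, 5), dtype=np.int8))
        assert np.allclose(hybrid_index(g, self._aims(g)), 0.5)

    def test_pure_domesticus_reference_is_zero(self):
        g = make_genotypes(np.zeros((3, 5), dtype=np.int8))
        assert np.allclose(hybrid_index(g, self._aims(g)), 0.0)

    def test_g2_cohort_matches_pedigree_expectation(self, cohort320, founders320):
        # every G2 has two domesticus-like (w=0.1) and two musculus-like
        # (w=0.9) grandparental lines -> expected musculus ancestry is the
        # mean of the grandparental weights, 0.5
        geno, _ = cohort320
        diag_ids = geno.marker_map["marker_id"][founders320.diagnostic]
        aims = pd.DataFrame({"marker_id": diag_ids, "musculus_allele": "M"})
        hi = hybrid_index(geno, aims)
        assert abs(hi.mean() - 0.5) < 0.05
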