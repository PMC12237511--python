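"""maxT and adaptive drivers against exact brute-force oracles.

The exhaustive oracles use Fraction arithmetic on integer-valued toy data:
with an integer phenotype and integer allele counts the dot-product
numerator is an exact integer, so ranking statistics by
``num^2 / ss_x`` (F is strictly monotone in rho^2 at fixed n) gives an
arithmetic-error-free reference for exceedance counts.
"""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from permforge import (AdaptiveConfig, GenotypeMatrix, adjust_phenotype,
                       dropping_schedule, run_adaptive, run_maxt)
from permforge.model import PhenotypeSet
from permforge.engine import PermutationPlan, kth_permutation
from permforge.plink_io import MISSING
from permforge.synthdata import SimSpec, beta_for_r2, simulate_genotypes, \
    simulate_phenotype


def exact_stats(codes, y, perm):
    """Exact per-SNP rho^2 proxies num^2 / ss_x for one permutation."""
    m, n = codes.shape
    yp = [int(y[i]) for i in perm]
    out = []
    for j in range(m):
        row = [int(v) for v in codes[j]]
        s = sum(row)
        num = sum(a * yv for a, yv in zip(row, yp))  # integer: sum(y) == 0
        ss_x = Fraction(sum(a * a for a in row)) - Fraction(s * s, n)
        out.append(Fraction(num * num) / ss_x)
    return out


class TestMaxT:
    def test_identical_snps_get_identical_pvalues(self, tiny_dataset):
        G, pheno = tiny_dataset
        codes = np.vstack([G.codes, G.codes[0:1]])
        G2 = GenotypeMatrix(codes.astype(np.int8))
        res = run_maxt(G2, pheno, n_perm=200, seed=5)
        assert res.emp1[0] == res.emp1[-1]
        assert res.emp2[0] == res.emp2[-1]

    def test_emp2_dominates_emp1(self, small_cohort, null_pheno):
        G, _, _ = small_cohort
        res = run_maxt(G, null_pheno, n_perm=100, seed=8)
        assert np.all(res.emp2 >= res.emp1)
        assert np.all(res.emp2 >= 1 / 101)
        assert len(res.null_maxima) == 100

    def test_exhaustive_enumeration_matches_exact_oracle(self, tiny_dataset):
        """All 5040 permutations at n=7: emp1/emp2 equal the Fraction oracle."""
        G, pheno = tiny_dataset
        perms = [np.array(p) for p in itertools.permutations(range(7))]
        res = run_maxt(G, pheno, n_perm=0, permutations=iter(perms))
        assert res.n_perm == 5040

        obs = exact_stats(G.codes, pheno.y, range(7))
        exceed1 = [0] * G.n_snps
        maxima = []
        for p in perms:
            stats = exact_stats(G.codes, pheno.y, p)
            for j in range(G.n_snps):
                exceed1[j] += stats[j] >= obs[j]
            maxima.append(max(stats))
        emp1 = [(c + 1) / 5041 for c in exceed1]
        emp2 = [(sum(mx >= obs[j] for mx in maxima) + 1) / 5041
                for j in range(G.n_snps)]
        np.testing.assert_array_equal(res.emp1, emp1)
        np.testing.assert_array_equal(res.emp2, emp2)

    def test_degenerate_snps_do_not_dilute_maxima(self, tiny_dataset):
        G, pheno = tiny_dataset
        codes = np.vstack([G.codes,
                           np.full((1, 7), MISSING, dtype=np.int8),   # all missing
                           np.full((1, 7), 1, dtype=np.int8)])        # monomorphic
        G2 = GenotypeMatrix(codes)
        res2 = run_maxt(G2, pheno, n_perm=150, seed=13)
        res1 = run_maxt(G, pheno, n_perm=150, seed=13)
        assert np.all(res2.degenerate[-2:])
        assert np.all(res2.emp2[-2:] == 1.0)
        np.testing.assert_array_equal(res2.emp2[:4], res1.emp2)
        np.testing.assert_array_equal(res2.null_maxima, res1.null_maxima)

    def test_planted_effect_reaches_pvalue_floor(self):
        """A SNP explaining ~20% of variance pins maxT emp2 at 1/(n_perm+1)."""
        hits = 0
        for seed in range(10):
            spec = SimSpec(m=1000, n=500, maf_range=(0.2, 0.4),
                           causal_idx=(37,), betas=(beta_for_r2(0.2, 0.3),),
                           seed=seed)
            G, _ = simulate_genotypes(spec)
            b, _ = simulate_phenotype(G, spec)
            res = run_maxt(G, adjust_phenotype(b), n_perm=999, seed=1000 + seed)
            if res.emp2[37] == 1 / 1000:
                hits += 1
        assert hits >= 9


class TestDroppingSchedule:
    def test_published_recurrence(self):
        cps = dropping_schedule(AdaptiveConfig(b_max=10 ** 6, mps=121))
        assert cps[:5] == [121, 242, 363, 484, 605]
        assert cps[5] == 751  # ceil(605 + 121 * 1.2)

    def test_mps_36_setting(self):
        cps = dropping_schedule(AdaptiveConfig(b_max=10 ** 5, mps=36))
        assert cps[:5] == [36, 72, 108, 144, 180]
        assert cps[5] == 224  # ceil(180 + 43.2)

    def test_mps_at_least_b_max_single_checkpoint(self):
        assert dropping_schedule(AdaptiveConfig(b_max=50, mps=50)) == [50]

    def test_schedule_properties_random_configs(self):
        rng = np.random.Generator(np.random.PCG64(77))
        for _ in range(100):
            b_max = int(rng.integers(10, 5000))
            cfg = AdaptiveConfig(b_max=b_max,
                                 mps=int(rng.integers(1, b_max + 1)),
                                 growth=float(rng.uniform(1.05, 2.0)),
                                 drops_per_growth=int(rng.integers(1, 10)))
            cps = dropping_schedule(cfg)
            assert cps[-1] == cfg.b_max
            assert all(b > a for a, b in zip(cps, cps[1:]))
            assert cps[0] >= cfg.mps

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AdaptiveConfig(b_max=10, mps=11)
        with pytest.raises(ValueError):
            AdaptiveConfig(b_max=10, growth=1.0)


class TestAdaptive:
    def test_unreachable_limit_equals_pointwise_oracle(self, tiny_dataset):
        """With R unreachable, p equals the exact full-permutation estimate."""
        G, pheno = tiny_dataset
        b_max = 300
        cfg = AdaptiveConfig(b_max=b_max, R=b_max + 1, mps=50)
        res = run_adaptive(G, pheno, cfg, seed=19)

        plan = PermutationPlan(seed=19, n_perm=b_max, n=7)
        obs = exact_stats(G.codes, pheno.y, range(7))
        x = [0] * G.n_snps
        for k in range(b_max):
            stats = exact_stats(G.codes, pheno.y, kth_permutation(plan, k))
            for j in range(G.n_snps):
                x[j] += stats[j] >= obs[j]
        expected = [(c + 1) / (b_max + 1) for c in x]
        np.testing.assert_array_equal(res.pvalue, expected)
        assert not res.dropped.any()
        assert np.all(res.B == b_max)

    def test_unreachable_limit_matches_maxt_pointwise(self, small_cohort,
                                                      null_pheno):
        G, _, _ = small_cohort
        b_max = 150
        res_a = run_adaptive(G, null_pheno,
                             AdaptiveConfig(b_max=b_max, R=b_max + 1, mps=40),
                             seed=23)
        res_m = run_maxt(G, null_pheno, n_perm=b_max, seed=23)
        np.testing.assert_array_equal(res_a.pvalue[~res_a.degenerate],
                                      res_m.emp1[~res_m.degenerate])

    def test_dropped_snps_obey_second_branch(self, small_cohort, null_pheno):
        G, _, _ = small_cohort
        cfg = AdaptiveConfig(b_max=400, R=10, mps=50)
        res = run_adaptive(G, null_pheno, cfg, seed=29)
        assert res.dropped.any()
        for j in np.flatnonzero(res.dropped):
            assert res.x[j] == cfg.R
            assert int(res.B[j]) in res.checkpoints
            assert res.pvalue[j] == (cfg.R + 1) / (res.B[j] + 1)
            assert res.pvalue[j] >= (cfg.R + 1) / (cfg.b_max + 1)
        for j in np.flatnonzero(~res.dropped & ~res.degenerate):
            assert res.B[j] == cfg.b_max
            assert res.x[j] < cfg.R

    def test_active_set_shrinks_monotonically(self, small_cohort, null_pheno):
        G, _, _ = small_cohort
        cfg = AdaptiveConfig(b_max=400, R=10, mps=50)
        res = run_adaptive(G, null_pheno, cfg, seed=29)
        drops_by_cp = [int((res.dropped_at == c).sum())
                       for c in range(len(res.checkpoints))]
        # cumulative active count never increases
        active = G.n_snps
        for d in drops_by_cp:
            assert d >= 0
            active -= d
            assert active >= 0

    def test_zero_f_snp_dropped_at_first_checkpoint(self):
        """An exactly orthogonal genotype (F_obs = 0) is dropped immediately:
        every permuted F ties or exceeds zero."""
        y = np.array([-3.0, -1.0, 1.0, 3.0, -2.0, 2.0])
        # row 0 orthogonal to y by construction; row 1 generic
        codes = np.array([[0, 2, 2, 0, 1, 1],
                          [0, 1, 2, 2, 0, 1]], dtype=np.int8)
        assert float((codes[0] - codes[0].mean()) @ y) == 0.0
        pheno = PhenotypeSet(b_raw=y, C=None, y=y, ss_y=float(y @ y))
        cfg = AdaptiveConfig(b_max=200, R=10, mps=20)
        for seed in range(50):
            res = run_adaptive(GenotypeMatrix(codes), pheno, cfg, seed=seed)
            assert res.dropped[0]
            assert res.B[0] == res.checkpoints[0]

    def test_strict_mode_stops_at_exact_permutation(self, tiny_dataset):
        G, pheno = tiny_dataset
        cfg = AdaptiveConfig(b_max=300, R=5, mps=50)
        res = run_adaptive(G, pheno, cfg, seed=31, strict=True)

        plan = PermutationPlan(seed=31, n_perm=300, n=7)
        obs = exact_stats(G.codes, pheno.y, range(7))
        for j in range(G.n_snps):
            count = 0
            stop = None
            for k in range(300):
                stats = exact_stats(G.codes, pheno.y, kth_permutation(plan, k))
                if stats[j] >= obs[j]:
                    count += 1
                    if count == cfg.R:
                        stop = k + 1
                        break
            if stop is not None:
                assert res.dropped[j]
                assert res.B[j] == stop
                assert res.pvalue[j] == (cfg.R + 1) / (stop + 1)
            else:
                assert not res.dropped[j]

    def test_results_do_not_depend_on_checkpoint_density_when_unreachable(
            self, small_cohort, null_pheno):
        G, _, _ = small_cohort
        p = [run_adaptive(G, null_pheno,
                          AdaptiveConfig(b_max=120, R=121, mps=mps),
                          seed=37).pvalue
             for mps in (10, 60, 120)]
        np.testing.assert_array_equal(p[0], p[1])
        np.testing.assert_array_equal(p[0], p[2])
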