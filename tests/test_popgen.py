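"""Diversity and neutrality statistics, simulated nulls, differentiation."""

import math

import mpmath
import numpy as np
import pytest

from barcodegap.coalescent import (
    ConstantSize,
    simulate_sample_stats,
)
from barcodegap.popgen import (
    NeutralNull,
    amova,
    basic_diversity,
    ewens_log_pmf,
    exact_differentiation,
    fu_li_constants,
    fu_li_tests,
    fus_fs,
    harmonic,
    neutral_null,
    pool_populations,
    r2_from_parts,
    r2_statistic,
    statistics_from_seqs,
    tajima_constants,
    tajimas_d,
)
from barcodegap.simulate import simulate_coalescent_sample

mpmath.mp.dps = 50


class TestBasicDiversity:
    def test_all_distinct_haplotypes_hd_one(self):
        # ten sequences, each with a private substitution
        base = "A" * 20
        seqs = [base[:i] + "G" + base[i + 1 :] for i in range(10)]
        d = basic_diversity(seqs)
        assert d.hd == pytest.approx(1.0)
        assert d.K == 10

    def test_two_sequences_one_difference(self):
        a = "A" * 100
        b = "G" + "A" * 99
        d = basic_diversity([a, b])
        assert d.k == 1.0
        assert d.pi == pytest.approx(0.01)
        assert d.S == 1 and d.eta_s == 1

    def test_identical_pair_all_zero(self):
        d = basic_diversity(["ACGT", "ACGT"])
        assert d.S == 0 and d.hd == 0.0 and d.pi == 0.0

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            basic_diversity(["ACGT"])

    def test_watterson_normalization(self):
        base = "A" * 50
        seqs = [base, base[:1] + "G" + base[2:], base[:2] + "T" + base[3:]]
        d = basic_diversity(seqs)
        assert d.theta_w == pytest.approx(d.S / (1 + 0.5))

    def test_missing_data_pairwise_deletion(self):
        a, b = "AANGT", "GANGT"
        d = basic_diversity([a, b])
        assert d.k == 1.0  # N column drops out

    def test_duplicating_sample_order_invariance(self):
        seqs = ["AAAA", "AAGA", "AAGA", "TAGA"]
        s1 = statistics_from_seqs(seqs)
        s2 = statistics_from_seqs(list(reversed(seqs)))
        for key in s1:
            assert s1[key] == pytest.approx(s2[key], nan_ok=True)


class TestCoefficients:
    """Tajima and Fu & Li variance coefficients vs 50-digit evaluation."""

    @pytest.mark.parametrize("n", [4, 10, 25, 100, 200])
    def test_tajima_constants_high_precision(self, n):
        a1 = mpmath.fsum(mpmath.mpf(1) / i for i in range(1, n))
        a2 = mpmath.fsum(mpmath.mpf(1) / i**2 for i in range(1, n))
        b1 = mpmath.mpf(n + 1) / (3 * (n - 1))
        b2 = mpmath.mpf(2 * (n * n + n + 3)) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        got = tajima_constants(n)
        for name, ref in [("a1", a1), ("a2", a2), ("e1", e1), ("e2", e2)]:
            assert got[name] == pytest.approx(float(ref), abs=1e-12)

    @pytest.mark.parametrize("n", [4, 25, 100, 200])
    def test_fu_li_constants_high_precision(self, n):
        an = mpmath.fsum(mpmath.mpf(1) / i for i in range(1, n))
        bn = mpmath.fsum(mpmath.mpf(1) / i**2 for i in range(1, n))
        an1 = an + mpmath.mpf(1) / n
        cn = mpmath.mpf(2) * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
        dn = cn + mpmath.mpf(n - 2) / (n - 1) ** 2 + mpmath.mpf(2) / (n - 1) * (
            mpmath.mpf(3) / 2 - (2 * an1 - 3) / (n - 2) - mpmath.mpf(1) / n
        )
        nn = mpmath.mpf(n)
        v_d = (
            (nn / (nn - 1)) ** 2 * bn
            + an**2 * dn
            - 2 * (nn * an * (an + 1)) / (nn - 1) ** 2
        ) / (an**2 + bn)
        u_d = (nn / (nn - 1)) * (an - nn / (nn - 1)) - v_d
        got = fu_li_constants(n)
        assert got["an"] == pytest.approx(float(an), abs=1e-12)
        assert got["v_d"] == pytest.approx(float(v_d), abs=1e-12)
        assert got["u_d"] == pytest.approx(float(u_d), abs=1e-12)


class TestTajimasD:
    def test_hand_evaluated_small_case(self):
        # n=4: a1 = 1 + 1/2 + 1/3, evaluated by hand gives D ~ -0.75
        assert tajimas_d(4, 3, 1.5) == pytest.approx(-0.754, abs=1e-3)

    def test_zero_when_estimators_agree(self):
        a1 = harmonic(9)
        assert tajimas_d(10, 5, 5 / a1) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_without_segregating_sites(self):
        assert math.isnan(tajimas_d(10, 0, 0.0))

    def test_mean_near_zero_under_neutral_coalescent(self, rng):
        values = []
        for _ in range(2000):
            st = simulate_sample_stats(25, ConstantSize(5.0), rng)
            d = tajimas_d(st.n, st.S, st.k)
            if not math.isnan(d):
                values.append(d)
        assert abs(np.mean(values)) < 0.15


class TestFuLi:
    def test_all_singletons_negative_d_star(self):
        # every mutation private: strong deficit of old mutations
        assert fu_li_tests(20, 30, 30, 3.0)[0] < 0

    def test_no_singletons_positive_d_star(self):
        assert fu_li_tests(20, 30, 0, 3.0)[0] > 0

    def test_undefined_without_segregating_sites(self):
        d_star, f_star = fu_li_tests(10, 0, 0, 0.0)
        assert math.isnan(d_star) and math.isnan(f_star)

    def test_mean_near_zero_under_neutral_coalescent(self, rng):
        d_vals, f_vals = [], []
        for _ in range(2000):
            st = simulate_sample_stats(20, ConstantSize(5.0), rng)
            d_star, f_star = fu_li_tests(st.n, st.S, st.eta_s, st.k)
            if not math.isnan(d_star):
                d_vals.append(d_star)
                f_vals.append(f_star)
        assert abs(np.mean(d_vals)) < 0.2
        assert abs(np.mean(f_vals)) < 0.2


class TestFusFs:
    def test_two_sequence_case_by_hand(self):
        # n=2: P(K=2 | theta) = theta/(theta+1) = 1/2 at theta=k=1 -> Fs=0
        assert fus_fs(2, 1.0, 2) == pytest.approx(0.0, abs=1e-12)

    def test_single_haplotype_reported_missing(self):
        assert math.isnan(fus_fs(10, 2.0, 1))

    def test_undefined_at_zero_diversity(self):
        assert math.isnan(fus_fs(10, 0.0, 3))

    def test_ewens_pmf_normalizes(self):
        for n, theta in [(5, 0.5), (20, 3.0), (60, 10.0)]:
            log_pmf = ewens_log_pmf(n, theta)
            assert np.exp(log_pmf).sum() == pytest.approx(1.0, abs=1e-10)

    def test_many_haplotypes_drive_fs_negative(self):
        assert fus_fs(30, 3.0, 25) < -5


class TestR2:
    def test_two_sequence_example(self):
        assert r2_from_parts(2, 1, 1.0, np.array([1.0, 0.0])) == 0.5

    def test_from_alignment(self):
        a = "A" * 100
        b = "G" + "A" * 99
        assert r2_statistic([a, b]) == 0.5

    def test_undefined_without_segregating_sites(self):
        assert math.isnan(r2_statistic(["AAAA", "AAAA"]))


class TestNeutralNull:
    def test_fixed_s_conditioning_exact(self, rng):
        for _ in range(50):
            st = simulate_sample_stats(10, ConstantSize(1.0), rng, fixed_S=7)
            assert st.S == 7

    def test_null_median_p_near_half(self):
        null = neutral_null(15, ("S", 10), reps=2000, seed=4)
        for stat in ("D", "Fs", "R2"):
            median = float(np.nanmedian(null.null[stat]))
            p = null.p_value(stat, median)
            if stat in ("Fs", "R2"):
                assert 0.45 <= p <= 0.55
            else:  # two-tailed: median maps to p ~ 1
                assert p > 0.9

    def test_same_seed_reproducible(self):
        n1 = neutral_null(12, ("S", 8), reps=300, seed=9)
        n2 = neutral_null(12, ("S", 8), reps=300, seed=9)
        for stat in n1.null:
            assert np.array_equal(
                n1.null[stat], n2.null[stat], equal_nan=True
            )

    def test_theta_conditioning_matches_watterson_scale(self, rng):
        null = neutral_null(20, ("theta", 5.0), reps=1000, seed=5)
        assert null.theta == 5.0

    def test_bad_conditioning_rejected(self):
        with pytest.raises(ValueError):
            neutral_null(10, ("bogus", 1), reps=200, seed=0)
        with pytest.raises(ValueError):
            NeutralNull(10, reps=200, seed=0)  # neither S nor theta


class TestExactDifferentiation:
    def test_identical_composition_not_differentiated(self):
        res = exact_differentiation([[3, 3], [4, 4]])
        assert res.p_value >= 0.99
        assert res.method == "exact"

    def test_fixed_alternative_haplotypes_enumerated(self):
        res = exact_differentiation([[7, 0], [0, 7]])
        assert res.p_value == pytest.approx(2 / 3432, rel=1e-9)

    def test_monte_carlo_fallback_on_large_tables(self, rng):
        table = rng.integers(3, 15, size=(8, 4))
        res = exact_differentiation(
            table, reps=2000, seed=1, enumeration_cap=1000
        )
        assert res.method == "monte-carlo"
        assert 0.0 < res.p_value <= 1.0

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            exact_differentiation([[2, 0], [3, 0]])

    def test_p_valid_and_nondegenerate_under_panmixia(self, rng):
        """Random splits of one panmictic sample give valid p-values.

        Exact-test p-values are discrete (the fixed-margin table universe
        has few atoms), so they cannot be continuously uniform; the
        defining null property is conservative validity,
        P(p <= alpha) <= alpha, with a non-degenerate spread.
        """
        seqs, _ = simulate_coalescent_sample(16, 4.0, seed=77)
        uniq = {s: i for i, s in enumerate(dict.fromkeys(seqs))}
        haps = np.array([uniq[s] for s in seqs])
        pvals = []
        for _ in range(1000):
            perm = rng.permutation(len(haps))
            table = np.zeros((len(uniq), 2), dtype=np.int64)
            np.add.at(table[:, 0], haps[perm[:8]], 1)
            np.add.at(table[:, 1], haps[perm[8:]], 1)
            res = exact_differentiation(table, reps=2000, seed=3)
            pvals.append(res.p_value)
        pvals = np.asarray(pvals)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            # 3-sd binomial slack (the p distribution has large atoms)
            slack = 3.0 * math.sqrt(alpha * (1 - alpha) / len(pvals)) + 0.005
            assert np.mean(pvals <= alpha) <= alpha + slack
        assert np.mean(pvals <= 0.5) >= 0.1  # not degenerate at 1


class TestAmova:
    def test_panmictic_pool_no_structure(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            seqs, _ = simulate_coalescent_sample(20, 5.0, seed=1000 + seed)
            res = amova(
                {"p1": seqs[:10], "p2": seqs[10:]},
                permutations=200, seed=seed,
            )
            if res.p_values["Phi_ST"] > 0.05:
                hits += 1
        assert hits >= int(0.9 * reps) - 2

    def test_fixed_divergent_populations_phi_one(self, rng, random_pair):
        a, b = random_pair(rng, length=640, n_sub=64)
        res = amova({"p1": [a] * 5, "p2": [b] * 5}, permutations=100, seed=0)
        assert res.phi["Phi_ST"] == pytest.approx(1.0)
        assert res.p_values["Phi_ST"] < 0.05

    def test_identical_sequences_components_zero(self):
        res = amova(
            {"p1": ["ACGT" * 10] * 4, "p2": ["ACGT" * 10] * 4},
            permutations=50, seed=0,
        )
        assert all(v == 0 for v in res.components.values())
        assert res.p_values["Phi_ST"] == 1.0

    def test_singleton_population_excluded_with_warning(self):
        seqs, _ = simulate_coalescent_sample(9, 3.0, seed=2)
        res = amova(
            {"p1": seqs[:4], "p2": seqs[4:8], "lone": seqs[8:]},
            permutations=50, seed=0,
        )
        assert res.excluded == ["lone"]

    def test_two_level_components_sum_to_total(self):
        seqs, _ = simulate_coalescent_sample(24, 5.0, seed=3)
        res = amova(
            {"p1": seqs[:6], "p2": seqs[6:12], "p3": seqs[12:18],
             "p4": seqs[18:]},
            groups={"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"},
            permutations=100, seed=0,
        )
        total = sum(res.components.values())
        assert res.phi["Phi_ST"] == pytest.approx(
            (res.components["among_groups"]
             + res.components["among_populations_within_groups"]) / total
        )


class TestPooling:
    def test_indistinguishable_populations_pool(self):
        seqs, _ = simulate_coalescent_sample(20, 4.0, seed=11)
        pooled, log = pool_populations(
            {"a": seqs[:10], "b": seqs[10:]}, reps=2000, seed=0
        )
        assert pooled["a"] == pooled["b"] == "a"
        assert any("pooled" in line for line in log)

    def test_different_species_never_pool(self):
        seqs, _ = simulate_coalescent_sample(20, 4.0, seed=11)
        pooled, _log = pool_populations(
            {"a": seqs[:10], "b": seqs[10:]},
            species_of_pop={"a": "sp1", "b": "sp2"},
            reps=500, seed=0,
        )
        assert pooled["a"] != pooled["b"]
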