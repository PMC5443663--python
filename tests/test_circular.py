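"""Circular statistics, each validated against an independent oracle."""

import numpy as np
import pytest

from ormia.circular import (circ_mean_deg, circ_r, circ_sem_deg,
                            circular_anova_hk, hotelling_paired,
                            watson_u2, watson_williams, wrap_angles_deg)


# ---------------------------------------------------------------------------
# independent oracles (deliberately written from the definitions, not the
# package's code paths)
# ---------------------------------------------------------------------------

def oracle_watson_u2(a_deg, b_deg):
    """U2 via empirical CDFs evaluated with searchsorted at pooled points."""
    a = np.sort(np.asarray(a_deg) % 360.0)
    b = np.sort(np.asarray(b_deg) % 360.0)
    pooled = np.sort(np.concatenate((a, b)))
    n1, n2 = len(a), len(b)
    N = n1 + n2
    d = (np.searchsorted(a, pooled, side="right") / n1
         - np.searchsorted(b, pooled, side="right") / n2)
    return n1 * n2 / N ** 2 * (np.sum(d ** 2) - np.sum(d) ** 2 / N)


def oracle_permutation_p(a, b, stat_fn, n_perm, seed):
    rng = np.random.default_rng(seed)
    pooled = np.concatenate((a, b))
    obs = stat_fn(a, b)
    n1 = len(a)
    hits = sum(stat_fn(p[:n1], p[n1:]) >= obs
               for p in (rng.permutation(pooled) for _ in range(n_perm)))
    return (hits + 1) / (n_perm + 1)


class TestDescriptive:
    def test_wrap_to_half_open_interval(self):
        assert list(wrap_angles_deg([-180.0, 180.0, 190.0, 540.0])) == \
            [180.0, 180.0, -170.0, 180.0]

    def test_mean_and_resultant_match_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        a = np.degrees(rng.vonmises(0.5, 2.0, 40))
        assert circ_mean_deg(a) == pytest.approx(
            np.degrees(pingouin.circ_mean(np.radians(a))), abs=1e-9)
        assert circ_r(a) == pytest.approx(
            float(pingouin.circ_r(np.radians(a))), abs=1e-12)

    def test_sem_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        a = np.degrees(rng.vonmises(0, 4.0, 400))
        assert circ_sem_deg(a[:25]) > circ_sem_deg(a)


class TestWatsonU2:
    def test_hand_computed_separated_samples(self):
        # a fully below b on the circle's (0, 360) line: d walks
        # .25,.5,.75,1,.75,.5,.25,0 -> U2 = (16/64)(2.75 - 2) = 0.1875
        u2 = watson_u2([10, 20, 30, 40], [50, 60, 70, 80]).statistic
        assert u2 == pytest.approx(0.1875, abs=1e-12)

    def test_statistic_matches_independent_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.uniform(0, 360, rng.integers(5, 15))
            b = rng.uniform(0, 360, rng.integers(5, 15))
            assert watson_u2(a, b).statistic == pytest.approx(
                oracle_watson_u2(a, b), abs=1e-10)

    def test_identical_samples_minimal(self):
        a = [10.0, 40.0, 90.0, 200.0, 300.0]
        res = watson_u2(a, a)
        assert res.p_value > 0.5

    def test_asymptotic_p_reproduces_reported_scale(self):
        # U2 = 0.256 lies just beyond the 1% critical value (0.2684 at inf n);
        # the asymptotic tail gives p ~ 0.013
        from ormia.circular import _watson_u2_pvalue_asymptotic

        assert _watson_u2_pvalue_asymptotic(0.256) == pytest.approx(0.013,
                                                                    abs=0.002)
        # the classical 5% critical value 0.1869 maps to p = 0.05
        assert _watson_u2_pvalue_asymptotic(0.1869) == pytest.approx(0.05,
                                                                     abs=0.001)

    def test_asymptotic_tracks_permutation_for_small_n(self):
        """n = 6+6: the asymptotic tail agrees with the permutation oracle
        in the decision-relevant range (p < 0.25); in the flat mid-range the
        N = 12 permutation distribution is too coarse for closer agreement,
        which is why the exact-permutation option exists for small samples.
        """
        rng = np.random.default_rng(5)
        pairs = []
        for k in range(10):
            a = rng.uniform(0, 360, 6)
            b = rng.uniform(0, 360, 6) + (20.0 if k % 2 else 140.0)
            asym = watson_u2(a, b).p_value
            perm = watson_u2(a, b, p_method="permutation",
                             n_permutations=1999, seed=k).p_value
            pairs.append((asym, perm))
        for asym, perm in pairs:
            if perm < 0.25 or asym < 0.25:
                assert abs(asym - perm) < 0.05
            assert abs(asym - perm) < 0.25
        # and the two p-values are strongly correlated overall
        arr = np.array(pairs)
        assert np.corrcoef(arr[:, 0], arr[:, 1])[0, 1] > 0.95

    def test_rotation_and_unit_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 360, 10)
        b = rng.uniform(0, 360, 12)
        base = watson_u2(a, b).statistic
        assert watson_u2(a + 73.0, b + 73.0).statistic == pytest.approx(
            base, abs=1e-9)
        assert watson_u2(np.radians(a), np.radians(b),
                         degrees=False).statistic == pytest.approx(base,
                                                                   abs=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            watson_u2([1, 2, 3], [4, 5, 6, 7])


class TestWatsonWilliams:
    def test_equal_samples_give_zero_f(self):
        a = [350.0, 10.0, 5.0, 355.0, 0.0]
        res = watson_williams(a, list(a))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_small_dispersion_limit_matches_linear_anova(self):
        # angles spread << 1 rad: the circular F converges to one-way ANOVA
        from scipy.stats import f_oneway

        rng = np.random.default_rng(7)
        a = 1.5 * rng.standard_normal(25)  # degrees
        b = 1.5 * rng.standard_normal(25) + 1.0
        res = watson_williams(a, b)
        lin = f_oneway(a, b)
        assert res.statistic == pytest.approx(lin.statistic, rel=0.01)

    def test_separated_means_detected(self):
        rng = np.random.default_rng(8)
        a = np.degrees(rng.vonmises(0.0, 8.0, 13))
        b = np.degrees(rng.vonmises(np.pi / 4, 8.0, 13))
        res = watson_williams(a, b)
        assert res.p_value < 0.01

    def test_low_concentration_warns_but_returns(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 360, 12)
        b = rng.uniform(0, 360, 12)
        with pytest.warns(RuntimeWarning):
            res = watson_williams(a, b)
        assert res.warning is not None
        assert np.isfinite(res.statistic)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(10)
        a = np.degrees(rng.vonmises(0.3, 5.0, 15))
        b = np.degrees(rng.vonmises(0.5, 5.0, 15))
        r1 = watson_williams(a, b)
        r2 = watson_williams(a + 111.0, b + 111.0)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)


class TestHotellingPaired:
    def test_identical_pairs_give_zero(self):
        a = [10.0, 30.0, 50.0, 70.0, 110.0]
        res = hotelling_paired(a, list(a))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_rotation_zero_spread_is_degenerate_significant(self):
        # every subject at the same angle, all rotated by exactly +10 deg:
        # difference vectors identical and nonzero -> p -> 0
        a = [20.0] * 6
        b = [30.0] * 6
        res = hotelling_paired(a, b)
        assert res.p_value == 0.0

    def test_consistent_rotation_with_spread_detected(self):
        rng = np.random.default_rng(11)
        a = np.degrees(rng.vonmises(0, 6.0, 13))
        res = hotelling_paired(a, a + 25.0)
        assert res.p_value < 0.01

    def test_matches_permutation_oracle_under_pair_exchange(self):
        # under H0 the pair labels are exchangeable: flipping (a_i, b_i)
        # at random gives an exact reference distribution for F
        rng = np.random.default_rng(12)
        a = np.degrees(rng.vonmises(0, 2.0, 12))
        b = np.degrees(rng.vonmises(0.4, 2.0, 12))
        obs = hotelling_paired(a, b).statistic
        hits = 0
        n_perm = 999
        for _ in range(n_perm):
            flip = rng.random(12) < 0.5
            aa = np.where(flip, b, a)
            bb = np.where(flip, a, b)
            if hotelling_paired(aa, bb).statistic >= obs:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        assert abs(hotelling_paired(a, b).p_value - p_perm) < 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            hotelling_paired([1.0, 2.0], [3.0, 4.0])


class TestHarrisonKanji:
    @staticmethod
    def _design(n_per_cell=10):
        fa = np.repeat(["s6", "s90"], 3 * n_per_cell)
        fb = np.tile(np.repeat([-6, 0, 6], n_per_cell), 2)
        return fa, fb

    def test_pure_factor_a_rotation_detected_only_in_a(self):
        rng = np.random.default_rng(13)
        fa, fb = self._design()
        angles = np.degrees(rng.vonmises(0, 8.0, len(fa)))
        angles[fa == "s90"] += 30.0
        res = circular_anova_hk(angles, fa, fb)
        assert res["factor_a"].p_value < 0.001
        assert res["factor_b"].p_value > 0.05

    def test_identical_cells_give_zero_f(self):
        fa, fb = self._design(4)
        angles = np.full(len(fa), 15.0)
        res = circular_anova_hk(angles, fa, fb)
        for key in ("factor_a", "factor_b", "interaction"):
            assert res[key].statistic == pytest.approx(0.0, abs=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(14)
        fa, fb = self._design()
        angles = np.degrees(rng.vonmises(0.2, 5.0, len(fa)))
        r1 = circular_anova_hk(angles, fa, fb)
        r2 = circular_anova_hk(angles + 97.0, fa, fb)
        for key in r1:
            assert r1[key].statistic == pytest.approx(r2[key].statistic,
                                                      rel=1e-6)

    def test_empty_cell_rejected(self):
        fa = ["x", "x", "y", "y"]
        fb = [0, 0, 0, 1]  # cell (x, 1) empty
        with pytest.raises(ValueError):
            circular_anova_hk([1.0, 2.0, 3.0, 4.0], fa, fb)

    def test_interaction_detected_when_constructed(self):
        rng = np.random.default_rng(15)
        fa, fb = self._design()
        angles = np.degrees(rng.vonmises(0, 8.0, len(fa)))
        mask = (fa == "s90") & (fb == 6)
        angles[mask] += 40.0
        res = circular_anova_hk(angles, fa, fb)
        assert res["interaction"].p_value < 0.05
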