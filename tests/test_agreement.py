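"""Agreement battery: Spearman/Holm, Lin's concordance, Bland-Altman."""

import math

import numpy as np
import pytest
from scipy import stats

from paconcord import (
    PairedSample,
    bias_correction_factor,
    bland_altman_log,
    holm_adjust,
    lin_ccc,
    spearman,
)

from oracles import ccc_oracle, holm_oracle, spearman_oracle


def sample(x, y):
    return PairedSample(np.asarray(x, float), np.asarray(y, float))


class TestPairedSample:
    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValueError):
            sample([1, 2], [1, 2, 3])

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError):
            sample([1, np.nan, 3], [1, 2, 3])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman(sample([1, 2, 3], [10, 20, 30]))
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_reversed(self):
        rho, _ = spearman(sample([1, 2, 3], [30, 20, 10]))
        assert rho == pytest.approx(-1.0)

    def test_midranks_match_definition_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        rho, _ = spearman(sample(x, y))
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_random_samples_match_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            x = rng.integers(0, 10, n).astype(float)  # heavy ties
            y = x + rng.normal(0, 3, n)
            rho, _ = spearman(sample(x, y))
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_p_from_t_approximation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(sample(x, y))
        t = rho * math.sqrt((30 - 2) / (1 - rho * rho))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 30 - 2), rel=1e-10)

    def test_constant_vector_returns_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman(sample([1, 1, 1], [1, 2, 3]))
        assert math.isnan(rho) and math.isnan(p)

    def test_invariant_under_monotone_transform(self, rng):
        x, y = rng.gamma(2, 50, 30), rng.gamma(2, 50, 30)
        r1, _ = spearman(sample(x, y))
        r2, _ = spearman(sample(np.log1p(x), y ** 3))
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestHolm:
    def test_sequential_stop(self):
        # 0.001 <= .05/3 rejects; then 0.04 > .05/2 stops the sequence
        flags = holm_adjust([0.001, 0.04, 0.04])
        assert flags.tolist() == [True, False, False]

    def test_all_ones(self):
        assert not holm_adjust([1.0, 1.0, 1.0]).any()

    def test_single_p_reduces_to_plain_test(self):
        assert holm_adjust([0.049]).tolist() == [True]
        assert holm_adjust([0.051]).tolist() == [False]

    def test_matches_hand_rule_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 12)))
            np.testing.assert_array_equal(holm_adjust(p), holm_oracle(p))

    def test_between_bonferroni_and_unadjusted(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 10))
            p = rng.random(m) * 0.2
            holm = holm_adjust(p)
            bonf = p <= 0.05 / m
            raw = p <= 0.05
            assert (holm | raw).tolist() == raw.tolist()  # Holm subset of raw
            assert (holm & bonf).tolist() == bonf.tolist()  # Holm superset of Bonferroni

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestLinCcc:
    def test_perfect_concordance(self, rng):
        x = rng.normal(100, 20, 25)
        res = lin_ccc(sample(x, x))
        assert res.lcc == pytest.approx(1.0)
        assert res.bcf == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_location_shift_penalty(self, rng):
        x = rng.normal(50, 10, 20)
        res = lin_ccc(sample(x, x + 10))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.lcc < 1.0
        assert res.bcf == pytest.approx(res.lcc, abs=1e-12)  # bcf = lcc when r = 1

    def test_identity_with_squared_difference_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x = rng.normal(100, 30, n)
            y = 0.7 * x + rng.normal(10, 20, n)
            res = lin_ccc(sample(x, y))
            assert res.lcc == pytest.approx(ccc_oracle(x, y), abs=1e-12)

    def test_decomposition_forms_agree(self, rng):
        # lcc = r * C_b with C_b from its closed form, to 1e-10
        for _ in range(100):
            n = int(rng.integers(5, 80))
            x = rng.gamma(2, 60, n)
            y = 0.5 * x + rng.gamma(2, 40, n)
            s = sample(x, y)
            res = lin_ccc(s)
            cb = bias_correction_factor(s)
            assert res.lcc == pytest.approx(res.pearson_r * cb, abs=1e-10)
            assert abs(res.lcc) <= abs(res.pearson_r) + 1e-12
            assert 0 <= cb <= 1 + 1e-12
            assert res.lcc_ci_low <= res.lcc <= res.lcc_ci_high

    def test_symmetry(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(1, 2, 30)
        assert lin_ccc(sample(x, y)).lcc == pytest.approx(
            lin_ccc(sample(y, x)).lcc, abs=1e-12)

    def test_equals_pearson_iff_no_shift(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 1, 40)
        # standardize so both vectors share mean and sd exactly
        xs = (x - x.mean()) / x.std()
        ys = (y - y.mean()) / y.std()
        res = lin_ccc(sample(xs, ys))
        assert res.lcc == pytest.approx(res.pearson_r, abs=1e-10)
        assert res.bcf == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_returns_none(self):
        with pytest.warns(UserWarning, match="constant"):
            assert lin_ccc(sample([1, 1, 1], [1, 2, 3])) is None

    def test_log_transform_variant(self, rng):
        x = rng.gamma(2, 100, 50)
        y = rng.gamma(2, 100, 50)
        raw = lin_ccc(sample(x, y))
        logged = lin_ccc(sample(x, y), log_transform=True)
        expect = ccc_oracle(np.log(x + 1), np.log(y + 1))
        assert logged.lcc == pytest.approx(expect, abs=1e-12)
        assert logged.lcc != pytest.approx(raw.lcc)

    def test_ci_coverage_bivariate_normal(self):
        # Lin's atanh-scale CI should cover the true coefficient ~95% of the
        # time; a modest replicate count here, the full check is in acceptance
        rng = np.random.default_rng(99)
        mu = np.array([100.0, 90.0])
        cov = np.array([[400.0, 240.0], [240.0, 360.0]])
        true_ccc = 2 * cov[0, 1] / (cov[0, 0] + cov[1, 1] + (mu[0] - mu[1]) ** 2)
        hits = 0
        reps = 200
        for _ in range(reps):
            xy = rng.multivariate_normal(mu, cov, size=150)
            res = lin_ccc(sample(xy[:, 0], xy[:, 1]))
            hits += res.lcc_ci_low <= true_ccc <= res.lcc_ci_high
        assert 0.90 <= hits / reps <= 0.99


class TestBlandAltman:
    def test_identical_vectors_collapse(self, rng):
        x = rng.gamma(2, 100, 20)
        res = bland_altman_log(sample(x, x))
        assert res.mean_diff == pytest.approx(0.0)
        assert res.loa_low == pytest.approx(0.0)
        assert res.loa_high == pytest.approx(0.0)

    def test_constant_ratio_with_zero_offset(self, rng):
        x = rng.gamma(2, 100, 20) + 1
        res = bland_altman_log(sample(x, 2 * x), offset=0.0)
        assert res.mean_diff == pytest.approx(-math.log(2))
        assert res.loa_low == pytest.approx(-math.log(2))
        assert res.loa_high == pytest.approx(-math.log(2))

    def test_zero_offset_with_zeros_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            bland_altman_log(sample([0, 1, 2], [1, 2, 3]), offset=0.0)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            bland_altman_log(sample([-1, 1, 2], [1, 2, 3]))

    def test_limits_cover_95pct_of_lognormal_differences(self):
        rng = np.random.default_rng(4)
        n = 500
        y = rng.lognormal(4, 0.8, n)
        x = y * rng.lognormal(0.2, 0.5, n)  # lognormal ratio -> normal log-diffs
        res = bland_altman_log(sample(x, y), offset=0.0)
        frac = np.mean((res.diffs >= res.loa_low) & (res.diffs <= res.loa_high))
        assert frac == pytest.approx(0.95, abs=0.02)

    def test_ordering_invariant(self, rng):
        x, y = rng.gamma(2, 100, 40), rng.gamma(2, 80, 40)
        res = bland_altman_log(sample(x, y))
        assert res.loa_low < res.mean_diff < res.loa_high
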