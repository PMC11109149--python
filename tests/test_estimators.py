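import math

import numpy as np
import pytest
import statsmodels.api as sm

from metabomr.errors import DegenerateInputError, InsufficientInstrumentsError
from metabomr.estimators import ivw, mr_egger, mr_presso, wald_ratio, weighted_median
from metabomr.harmonize import HarmonizedVariant, from_arrays
from metabomr.synthetic_data import ScenarioConfig, harmonized_truth_set, simulate_pair

from conftest import SEED, random_harmonized_set


def hv(gamma, se_gamma, big_gamma, se_big_gamma, vid="v1"):
    return HarmonizedVariant(vid, gamma, se_gamma, big_gamma, se_big_gamma)


class TestWaldRatio:
    def test_zero_outcome_effect(self):
        assert wald_ratio(hv(0.1, 0.01, 0.0, 0.02)).beta == 0.0

    def test_hand_example(self):
        r = wald_ratio(hv(0.1, 0.01, 0.05, 0.02))
        assert r.beta == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)

    def test_scale_invariance(self):
        a = wald_ratio(hv(0.1, 0.01, 0.05, 0.02)).beta
        b = wald_ratio(hv(0.2, 0.02, 0.10, 0.04)).beta
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_gamma_degenerate(self):
        with pytest.raises(DegenerateInputError):
            wald_ratio(hv(0.0, 0.01, 0.05, 0.02))


class TestIvw:
    def test_single_snp_fixed_equals_wald(self):
        v = hv(0.1, 0.01, 0.05, 0.02)
        h = from_arrays([0.1], [0.01], [0.05], [0.02])
        w = wald_ratio(v)
        f = ivw(h, model="fixed")
        assert (f.beta, f.se) == (pytest.approx(w.beta), pytest.approx(w.se))

    def test_two_identical_ratios_closed_form(self):
        # both SNPs: ratio 0.5 with ratio-SE 0.2 (gamma=1 exactly)
        h = from_arrays([1.0, 1.0], [0.0001, 0.0001], [0.5, 0.5], [0.2, 0.2])
        f = ivw(h, model="fixed")
        assert f.beta == pytest.approx(0.5)
        assert f.se == pytest.approx(0.2 / math.sqrt(2), rel=1e-12)
        r = ivw(h, model="random")
        assert (r.beta, r.se) == (f.beta, f.se)  # Q = 0: floor keeps fixed SE

    def test_equals_weighted_lstsq_oracle(self, rng):
        for _ in range(100):
            h = random_harmonized_set(rng, j=int(rng.integers(3, 25)))
            g, _, G, sG = h.arrays()
            sw = 1.0 / sG
            slope = np.linalg.lstsq((g * sw)[:, None], G * sw, rcond=None)[0][0]
            assert ivw(h).beta == pytest.approx(slope, abs=1e-10)

    def test_matches_statsmodels_wls(self, rng):
        h = random_harmonized_set(rng, j=15)
        g, _, G, sG = h.arrays()
        fit = sm.WLS(G, g[:, None], weights=1.0 / sG**2).fit()
        assert ivw(h).beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(20):
            h = random_harmonized_set(rng, j=10)
            assert ivw(h, "random").se >= ivw(h, "fixed").se - 1e-15

    def test_insufficient_instruments(self):
        h = from_arrays([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h, model="random")


class TestEgger:
    def test_exact_linear_data(self):
        g = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        G = 0.1 + 0.4 * g
        h = from_arrays(g, [0.01] * 5, G, [0.02] * 5)
        fit = mr_egger(h)
        assert fit.result.beta == pytest.approx(0.4, abs=1e-10)
        assert fit.intercept == pytest.approx(0.1, abs=1e-10)
        assert fit.result.se == pytest.approx(0.0, abs=1e-8)

    def test_equals_normal_equations_oracle(self, rng):
        for _ in range(50):
            h = random_harmonized_set(rng, j=int(rng.integers(4, 20)))
            g, _, G, sG = h.arrays()
            s = np.sign(np.where(g == 0, 1, g))
            g, G = g * s, G * s
            X = sm.add_constant(g)
            fit = sm.WLS(G, X, weights=1.0 / sG**2).fit()
            got = mr_egger(h)
            assert got.intercept == pytest.approx(fit.params[0], rel=1e-9, abs=1e-12)
            assert got.result.beta == pytest.approx(fit.params[1], rel=1e-9)
            assert got.result.se == pytest.approx(fit.bse[1], rel=1e-9)
            assert got.intercept_se == pytest.approx(fit.bse[0], rel=1e-9)
            assert got.intercept_p == pytest.approx(fit.pvalues[0], rel=1e-6, abs=1e-12)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2))


class TestWeightedMedian:
    def test_plain_median_equal_weights(self):
        h = from_arrays([1.0, 1.0, 1.0], [1e-4] * 3, [0.1, 0.2, 0.3], [0.1] * 3)
        assert weighted_median(h, n_boot=100, seed=SEED).beta == pytest.approx(0.2)

    def test_interpolation_hand_example(self):
        # ratios {0, 1} with normalized weights {0.75, 0.25} -> 0.25; pad with
        # a zero-weight-ish third ratio to satisfy the J >= 3 contract
        h = from_arrays(
            [1.0, 1.0, 1.0], [1e-6] * 3, [0.0, 1.0, 50.0],
            [math.sqrt(1 / 0.75), math.sqrt(1 / 0.25), 1e6],
        )
        assert weighted_median(h, n_boot=100, seed=SEED).beta == pytest.approx(0.25, abs=1e-6)

    def test_order_invariance(self, rng):
        h = random_harmonized_set(rng, j=9)
        est = weighted_median(h, n_boot=100, seed=SEED).beta
        perm = rng.permutation(len(h.variants))
        h2 = from_arrays(*(arr[perm] for arr in h.arrays()))
        assert weighted_median(h2, n_boot=100, seed=SEED).beta == pytest.approx(est, rel=1e-12)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(from_arrays([1.0], [0.01], [0.5], [0.2]), seed=SEED)


class TestConsistencyAcrossMethods:
    def test_all_methods_agree_on_proportional_data(self):
        g = np.array([0.1, 0.15, 0.2, 0.3, 0.45])
        h = from_arrays(g, [0.01] * 5, 0.7 * g, [0.02] * 5)
        assert ivw(h).beta == pytest.approx(0.7, abs=1e-12)
        assert mr_egger(h).result.beta == pytest.approx(0.7, abs=1e-10)
        assert weighted_median(h, n_boot=100, seed=SEED).beta == pytest.approx(0.7, abs=1e-12)

    def test_result_invariants(self, rng):
        h = random_harmonized_set(rng, j=10)
        rep, raw, _ = mr_presso(h, n_sim=200, seed=SEED)
        results = [ivw(h), mr_egger(h).result, weighted_median(h, n_boot=100, seed=SEED), raw]
        for r in results:
            assert r.ci_low < r.ci_high
            assert r.odds_ratio == pytest.approx(math.exp(r.beta))
            assert r.or_ci_low == pytest.approx(math.exp(r.ci_low))
            assert r.or_ci_high == pytest.approx(math.exp(r.ci_high))
            assert 0 < r.pval <= 1


class TestPresso:
    def make_clean(self):
        e, o, t = simulate_pair(ScenarioConfig(seed=SEED, n_snps=20, beta_causal=0.3))
        return harmonized_truth_set(e, o, t)

    def test_clean_data_no_correction(self):
        h = self.make_clean()
        rep, raw, corrected = mr_presso(h, n_sim=500, seed=SEED)
        assert corrected is None and rep.outlier_ids == ()
        assert raw.beta == pytest.approx(ivw(h).beta)

    def test_planted_outlier_flagged_and_corrected(self):
        cfg = ScenarioConfig(seed=SEED, n_snps=20, beta_causal=0.3,
                             outlier_frac=1 / 20, outlier_scale=10.0)
        e, o, t = simulate_pair(cfg)
        h = harmonized_truth_set(e, o, t)
        rep, raw, corrected = mr_presso(h, n_sim=1000, seed=SEED)
        (true_outlier,) = [r.variant_id for r in t.records if r.is_outlier]
        assert true_outlier in rep.outlier_ids
        assert rep.global_p < 0.05
        assert corrected is not None and corrected.n_snp < raw.n_snp
        # removing the planted outlier moves the estimate toward the truth
        assert abs(corrected.beta - 0.3) < abs(raw.beta - 0.3)
        assert rep.distortion_p is None or 0 < rep.distortion_p <= 1

    def test_seeded_reproducibility(self):
        h = self.make_clean()
        a = mr_presso(h, n_sim=300, seed=7)[0]
        b = mr_presso(h, n_sim=300, seed=7)[0]
        assert a.global_p == b.global_p and a.outlier_p == b.outlier_p

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(from_arrays([0.1] * 3, [0.01] * 3, [0.05] * 3, [0.02] * 3), seed=SEED)
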