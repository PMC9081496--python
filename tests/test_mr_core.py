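"""Estimators: Wald ratio, IVW, Egger, medians, RAPS, PRESSO, per-SNP batteries."""

import numpy as np
import pytest

from mrmediation import (
    DegenerateInstrumentError,
    HarmonizedPair,
    InsufficientInstrumentsError,
    beta_to_or,
    ivw_fixed,
    leave_one_out,
    mr_egger,
    mr_presso,
    mr_raps,
    simple_median,
    single_snp,
    wald_ratio,
    weighted_median,
)
from mrmediation.mr_core import _weighted_median_point

from conftest import random_pair


def make_pair(bx, by, se_y, se_x=None):
    bx, by, se_y = map(np.asarray, (bx, by, se_y))
    se_x = np.full_like(bx, 1e-6, dtype=float) if se_x is None else np.asarray(se_x)
    return HarmonizedPair([f"rs{i}" for i in range(len(bx))], bx, se_x, by, se_y)


class TestWaldRatio:
    @pytest.mark.parametrize("bx,by,se_y,ratio,ratio_se", [
        (0.5, 0.25, 0.10, 0.5, 0.2),
        (1.0, 0.0, 0.05, 0.0, 0.05),
        (-0.2, 0.1, 0.02, -0.5, 0.1),  # SE uses |bx|, stays positive
    ])
    def test_ratio_and_delta_se(self, bx, by, se_y, ratio, ratio_se):
        r, s = wald_ratio(bx, by, se_y)
        assert r == pytest.approx(ratio)
        assert s == pytest.approx(ratio_se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.1, 0.05)


class TestIVW:
    def test_single_snp_reduces_to_wald_ratio(self):
        e = ivw_fixed(make_pair([0.1], [-0.02], [0.01]))
        assert e.beta == pytest.approx(-0.2)
        assert e.se == pytest.approx(0.1)

    def test_duplicate_snp_halves_variance(self):
        e = ivw_fixed(make_pair([0.1, 0.1], [-0.02, -0.02], [0.01, 0.01]))
        assert e.beta == pytest.approx(-0.2)
        assert e.se == pytest.approx(0.1 / np.sqrt(2))

    def test_equals_wls_through_origin_oracle(self, rng):
        for _ in range(20):
            h = random_pair(rng, k=10)
            e = ivw_fixed(h)
            # independent oracle: weighted normal equations, origin regression
            w = h.se_y ** -2
            beta = (w * h.bx * h.by).sum() / (w * h.bx ** 2).sum()
            se = (w * h.bx ** 2).sum() ** -0.5
            assert e.beta == pytest.approx(beta, abs=1e-12)
            assert e.se == pytest.approx(se, abs=1e-12)

    def test_scale_equivariance(self, rng):
        h = random_pair(rng, k=8)
        e = ivw_fixed(h)
        c = 3.7
        scaled_y = HarmonizedPair(h.variant_ids, h.bx, h.se_x, c * h.by, c * h.se_y)
        ey = ivw_fixed(scaled_y)
        assert ey.beta == pytest.approx(c * e.beta)
        assert ey.se == pytest.approx(c * e.se)
        scaled_x = HarmonizedPair(h.variant_ids, c * h.bx, h.se_x, h.by, h.se_y)
        ex = ivw_fixed(scaled_x)
        assert ex.beta == pytest.approx(e.beta / c)

    def test_orientation_invariance(self, rng):
        h = random_pair(rng, k=9)
        flip = np.where(np.arange(9) % 2 == 0, -1.0, 1.0)
        h2 = HarmonizedPair(h.variant_ids, flip * h.bx, h.se_x, flip * h.by, h.se_y)
        assert ivw_fixed(h2).beta == pytest.approx(ivw_fixed(h).beta, abs=1e-14)


class TestEgger:
    def test_exact_linear_recovery(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        by = 0.05 + 0.3 * bx
        slope, intercept = mr_egger(make_pair(bx, by, [0.01] * 5))
        assert slope.beta == pytest.approx(0.3, abs=1e-10)
        assert intercept.beta == pytest.approx(0.05, abs=1e-12)

    def test_reduces_to_ivw_without_pleiotropy_or_noise(self):
        bx = np.array([0.05, 0.1, 0.15, 0.25])
        by = 0.3 * bx
        h = make_pair(bx, by, [0.01] * 4)
        slope, intercept = mr_egger(h)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)
        assert slope.beta == pytest.approx(ivw_fixed(h).beta, abs=1e-10)

    def test_matches_weighted_regression_oracle(self, rng):
        for _ in range(10):
            h = random_pair(rng, k=20)
            slope, intercept = mr_egger(h)
            sign = np.where(h.bx < 0, -1.0, 1.0)
            bx, by, w = h.bx * sign, h.by * sign, h.se_y ** -2
            X = np.column_stack([np.ones_like(bx), bx])
            XtWX = X.T @ (w[:, None] * X)
            coef = np.linalg.solve(XtWX, X.T @ (w * by))
            resid = by - X @ coef
            rse2 = (w * resid ** 2).sum() / (len(bx) - 2)
            cov = np.linalg.inv(XtWX) * max(1.0, rse2)
            assert slope.beta == pytest.approx(coef[1], abs=1e-10)
            assert intercept.beta == pytest.approx(coef[0], abs=1e-10)
            assert slope.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)
            assert intercept.se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)

    def test_directional_pleiotropy_recovered_noise_free(self):
        bx = np.linspace(0.05, 0.4, 12)
        by = 0.07 + (-0.25) * bx
        slope, intercept = mr_egger(make_pair(bx, by, [0.02] * 12))
        assert intercept.beta == pytest.approx(0.07, abs=1e-12)
        assert slope.beta == pytest.approx(-0.25, abs=1e-10)

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_pair([0.1, 0.2], [0.02, 0.04], [0.01, 0.01]))


class TestMedians:
    def test_three_equal_weight_ratios(self):
        h = make_pair([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], [0.05, 0.05, 0.05])
        e = simple_median(h, n_boot=200, seed=1)
        assert e.beta == pytest.approx(0.2)

    def test_dominant_weight_pins_estimate(self):
        # first SNP carries ~99% of inverse-variance weight
        h = make_pair([1.0, 1.0, 1.0], [0.30, 0.1, 0.9], [0.01, 0.1, 0.1])
        e = weighted_median(h, n_boot=200, seed=1)
        assert e.beta == pytest.approx(0.30, abs=0.02)

    def test_matches_brute_force_cdf_scan(self, rng):
        h = random_pair(rng, k=15)
        for est, weights in [
            (weighted_median(h, n_boot=100, seed=3), (h.bx / h.se_y) ** 2),
            (simple_median(h, n_boot=100, seed=3), np.ones(15)),
        ]:
            ratios = h.by / h.bx
            order = np.argsort(ratios)
            r, w = ratios[order], weights[order] / weights.sum()
            cdf = np.cumsum(w) - 0.5 * w
            expected = float(np.interp(0.5, cdf, r))
            assert est.beta == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_se_stable_across_seeds(self, rng):
        h = random_pair(rng, k=15)
        se1 = weighted_median(h, n_boot=2000, seed=1).se
        se2 = weighted_median(h, n_boot=2000, seed=2).se
        assert abs(se1 - se2) / se1 < 0.10

    def test_tolerates_forty_percent_invalid_weight(self):
        # 8 of 20 equal-weight SNPs (40%) ratio-shifted by +0.3; in the
        # small-noise limit the median stays at the valid instruments' ratio
        for seed in range(5):
            g = np.random.default_rng(seed)
            k = 20
            bx = g.uniform(0.1, 0.3, k)
            se_y = np.full(k, 1e-5)
            by = 0.2 * bx + g.normal(0, se_y)
            by[:8] += 0.3 * bx[:8]
            h = HarmonizedPair([f"rs{i}" for i in range(k)],
                               bx, np.full(k, 1e-6), by, se_y)
            e = simple_median(h, n_boot=100, seed=seed)
            assert e.beta == pytest.approx(0.2, abs=1e-3)


class TestRAPS:
    def test_no_measurement_error_limit_equals_ivw(self, rng):
        h = random_pair(rng, k=12)
        h0 = HarmonizedPair(h.variant_ids, h.bx, np.full(12, 1e-10), h.by, h.se_y)
        assert mr_raps(h0).beta == pytest.approx(ivw_fixed(h0).beta, abs=1e-6)

    def test_score_vanishes_at_estimate(self, rng):
        h = random_pair(rng, k=20)
        e = mr_raps(h)
        v = h.se_y ** 2 + e.beta ** 2 * h.se_x ** 2
        score = np.sum((h.by - e.beta * h.bx) * h.bx / v)
        assert abs(score) < 1e-8

    def test_parameter_recovery_simulation(self):
        ests = []
        for seed in range(200):
            g = np.random.default_rng(seed)
            k = 100
            gamma = g.uniform(0.05, 0.2, k)
            se_x = np.full(k, 0.01)
            se_y = np.full(k, 0.02)
            bx = gamma + g.normal(0, se_x)
            by = 0.2 * gamma + g.normal(0, se_y)
            h = HarmonizedPair([f"rs{i}" for i in range(k)], bx, se_x, by, se_y)
            ests.append(mr_raps(h).beta)
        mc_se = np.std(ests) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(0.2, abs=3 * mc_se + 1e-4)

    def test_overdispersion_variant_runs(self, rng):
        h = random_pair(rng, k=30)
        by = h.by + rng.normal(0, 0.02, 30)  # extra heterogeneity
        h2 = HarmonizedPair(h.variant_ids, h.bx, h.se_x, by, h.se_y)
        e = mr_raps(h2, overdispersion=True)
        assert np.isfinite(e.beta) and e.se > 0


class TestPresso:
    def test_planted_outlier_flagged_and_corrected(self, rng):
        h = random_pair(rng, k=30, beta=0.2)
        by = h.by.copy()
        by[5] += 10 * h.se_y[5]
        h2 = HarmonizedPair(h.variant_ids, h.bx, h.se_x, by, h.se_y)
        res = mr_presso(h2, n_sim=1000, seed=4)
        assert res.outlier_flags[5]
        assert res.corrected is not None
        # corrected estimate is exactly the IVW of the unflagged subset
        keep = ~res.outlier_flags
        h_clean = HarmonizedPair(
            [v for v, k_ in zip(h2.variant_ids, keep) if k_],
            h2.bx[keep], h2.se_x[keep], h2.by[keep], h2.se_y[keep],
        )
        assert res.corrected.beta == pytest.approx(ivw_fixed(h_clean).beta, abs=1e-14)

    def test_global_pval_large_for_homogeneous_data(self, rng):
        h = random_pair(rng, k=20, beta=0.1)
        res = mr_presso(h, n_sim=1000, seed=5)
        assert res.global_pval > 0.05
        assert res.n_outliers == 0 and res.corrected is None

    def test_correction_beats_contaminated_ivw_usually(self):
        wins = tried = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            h = random_pair(g, k=30, beta=0.2)
            by = h.by.copy()
            idx = int(np.argmax(np.abs(h.bx) / h.se_y))
            by[idx] += 8 * h.se_y[idx]
            h2 = HarmonizedPair(h.variant_ids, h.bx, h.se_x, by, h.se_y)
            res = mr_presso(h2, n_sim=1000, seed=seed)
            if res.corrected is None:
                continue
            tried += 1
            wins += abs(res.corrected.beta - 0.2) < abs(ivw_fixed(h2).beta - 0.2)
        assert tried > 80
        assert wins / tried >= 0.9

    def test_requires_four_snps(self, rng):
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(random_pair(rng, k=3), seed=0)


class TestPerSnpBatteries:
    def test_loo_with_two_snps_equals_remaining_wald(self):
        h = make_pair([0.1, 0.2], [0.02, 0.08], [0.01, 0.01])
        res = leave_one_out(h)
        assert res[0].label == "rs0"
        assert res[0].beta == pytest.approx(0.08 / 0.2)  # rs0 omitted
        assert res[1].beta == pytest.approx(0.02 / 0.1)

    def test_loo_stability_on_homogeneous_data(self, rng):
        h = random_pair(rng, k=25, beta=0.15)
        full = ivw_fixed(h)
        for e in leave_one_out(h):
            assert abs(e.beta - full.beta) < 2 * full.se

    def test_omitting_planted_outlier_moves_estimate_most(self, rng):
        h = random_pair(rng, k=20, beta=0.15)
        # plant at the highest-leverage instrument so the displacement
        # dominates every clean SNP's influence
        idx = int(np.argmax(np.abs(h.bx) / h.se_y))
        by = h.by.copy()
        by[idx] += 8 * h.se_y[idx]
        h2 = HarmonizedPair(h.variant_ids, h.bx, h.se_x, by, h.se_y)
        full = ivw_fixed(h2).beta
        shifts = {e.label: abs(e.beta - full) for e in leave_one_out(h2)}
        assert max(shifts, key=shifts.get) == h.variant_ids[idx]

    def test_single_snp_weighted_mean_recovers_ivw(self, rng):
        h = random_pair(rng, k=12)
        singles = single_snp(h)
        w = np.array([e.se ** -2 for e in singles])
        b = np.array([e.beta for e in singles])
        assert (w * b).sum() / w.sum() == pytest.approx(ivw_fixed(h).beta, abs=1e-12)

    def test_single_snp_equal_ratios(self):
        h = make_pair([0.1, 0.2, 0.4], [0.02, 0.04, 0.08], [0.01, 0.01, 0.01])
        betas = [e.beta for e in single_snp(h)]
        assert betas == pytest.approx([0.2, 0.2, 0.2])


class TestBetaToOr:
    def test_null_effect_is_unit_or(self):
        or_, lo, hi = beta_to_or(0.0, 0.1)
        assert or_ == 1.0
        assert lo == pytest.approx(np.exp(-1.959963984540054 * 0.1))
        assert hi == pytest.approx(np.exp(1.959963984540054 * 0.1))

    def test_bounds_match_quantile_arithmetic(self):
        from scipy import stats
        or_, lo, hi = beta_to_or(0.2, 0.1)
        z = stats.norm.ppf(0.975)
        assert or_ == pytest.approx(np.exp(0.2))
        assert lo == pytest.approx(np.exp(0.2 - z * 0.1))
        assert hi == pytest.approx(np.exp(0.2 + z * 0.1))


def test_weighted_median_point_edge_cases():
    # all weight on one end pins the estimate to that ratio
    r = np.array([0.1, 0.5, 0.9])
    assert _weighted_median_point(r, np.array([100.0, 1e-9, 1e-9])) == pytest.approx(0.1, abs=1e-6)
    assert _weighted_median_point(r, np.array([1e-9, 1e-9, 100.0])) == pytest.approx(0.9, abs=1e-6)
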