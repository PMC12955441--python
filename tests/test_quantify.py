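"""Classification, Poisson estimation, reaction QC, and limit of detection."""

import math

import numpy as np
import pytest
from scipy import stats

from ddpcrkit import (
    ChannelThresholds,
    ConcentrationEstimate,
    SimulationParams,
    TrueConcentrations,
    classify_droplets,
    compute_lod,
    estimate_concentration,
    fit_thresholds,
    qc_reaction,
    quantify_reaction,
    simulate_ntc,
    simulate_reaction,
)
from ddpcrkit.droplets import DropletReaction
from ddpcrkit.quantify import round_up_lod

from conftest import true_labels


def _make_reaction(fam, hex_, **kwargs):
    return DropletReaction("W1", "test", np.asarray(fam, float), np.asarray(hex_, float), **kwargs)


class TestFitThresholds:
    def test_cutoff_near_midpoint_of_generating_means(self):
        """Clusters generated at 700 and 9,600 put the cutoff at ~5,150."""
        rng = np.random.default_rng(0)
        fam = np.concatenate([rng.normal(700, 21, 8000), rng.normal(9600, 290, 2000)])
        hex_ = rng.normal(1030, 31, 10_000)
        th = fit_thresholds(_make_reaction(fam, hex_))
        assert abs(th.fam_cutoff - 5150) < 100

    def test_all_negative_well_yields_zero_positives(self, default_params):
        rx = simulate_reaction(default_params, TrueConcentrations(0.0, 0.0), seed=3)
        th = fit_thresholds(rx)
        assert (rx.fam_amplitudes > th.fam_cutoff).sum() == 0

    def test_instrument_scale_separation(self, default_params):
        """Default amplitudes (negatives ~700, positives ~9,600) leave every
        droplet far from the cutoff."""
        rx = simulate_reaction(default_params, TrueConcentrations(300.0, 0.0), seed=1)
        th = fit_thresholds(rx)
        assert np.all(np.abs(rx.fam_amplitudes - th.fam_cutoff) > 2000)

    def test_crosstalk_coefficient_recovered(self, default_params):
        rx = simulate_reaction(default_params, TrueConcentrations(400.0, 200.0), seed=6)
        th = fit_thresholds(rx)
        assert abs(th.crosstalk_alpha_hat - default_params.crosstalk_alpha) < 0.02

    def test_rejects_tiny_wells(self):
        with pytest.raises(ValueError):
            fit_thresholds(_make_reaction(np.ones(50) * 700, np.ones(50) * 1000))


class TestClassifyDroplets:
    def test_quadrant_assignment(self):
        th = ChannelThresholds(fam_cutoff=5150, hex_cutoff=2600, crosstalk_alpha_hat=0.0)
        rx = _make_reaction([9600, 700, 700, 9600], [1050, 4300, 1050, 4300])
        cl = classify_droplets(rx, th)
        assert list(cl.label_names()) == ["fam_only", "hex_only", "negative", "double"]
        assert cl.n_total == 4 and cl.n_fam_only == 1 and cl.n_double == 1

    def test_crosstalk_compensation_prevents_double_misassignment(self):
        """FAM-only droplets whose HEX signal is inflated by spectral bleed
        must not be classified double once compensated."""
        params = SimulationParams(crosstalk_alpha=0.05, competition_kappa=1.0)
        rx, of, oh = simulate_reaction(
            params, TrueConcentrations(400.0, 200.0), seed=8, return_occupancy=True
        )
        cl = classify_droplets(rx, fit_thresholds(rx))
        truth = true_labels(of, oh)
        fam_only = truth == 1
        misassigned = (cl.labels[fam_only] == 3).mean()
        assert misassigned < 0.01

    def test_counts_match_occupancy_truth(self, duplex_well):
        rx, of, oh, _ = duplex_well
        cl = classify_droplets(rx, fit_thresholds(rx))
        truth = true_labels(of, oh)
        for code, count in [(0, cl.n_negative), (1, cl.n_fam_only), (2, cl.n_hex_only), (3, cl.n_double)]:
            n_true = int((truth == code).sum())
            assert abs(count - n_true) <= max(5, 0.005 * n_true)

    def test_rejects_cutoff_below_range(self):
        rx = _make_reaction([700, 9600], [1000, 1000])
        with pytest.raises(ValueError):
            classify_droplets(rx, ChannelThresholds(fam_cutoff=10.0, hex_cutoff=2600))


class TestEstimateConcentration:
    def _classified(self, n_pos, n_total):
        labels = np.zeros(n_total, dtype=np.int8)
        labels[:n_pos] = 1
        from ddpcrkit.quantify import ClassifiedDroplets

        return ClassifiedDroplets(
            labels=labels,
            n_total=n_total,
            n_negative=n_total - n_pos,
            n_fam_only=n_pos,
            n_hex_only=0,
            n_double=0,
            thresholds=ChannelThresholds(5000, 2600),
        )

    def test_zero_positive_gives_zero_with_zero_lower_bound(self):
        est = estimate_concentration(self._classified(0, 15_000), "FAM")
        assert est.copies_per_reaction == 0.0
        assert est.ci95_low == 0.0
        assert est.ci95_high > 0.0

    def test_closed_form_poisson_correction(self):
        """2,000 of 20,000 positive: λ̂ = −ln 0.9, copies/µL ≈ 123.95,
        copies/reaction ≈ 2,479 at V_d = 0.85 nL, V_r = 20 µL."""
        est = estimate_concentration(self._classified(2000, 20_000), "FAM", 20.0, 0.85)
        lam = -math.log(0.9)
        assert est.lambda_hat == pytest.approx(lam, abs=1e-12)
        assert est.copies_per_ul == pytest.approx(lam / 0.00085, rel=1e-12)
        assert est.copies_per_reaction == pytest.approx(lam / 0.00085 * 20, rel=1e-12)
        assert est.ci95_low < est.copies_per_reaction < est.ci95_high

    def test_lambda_monotone_in_positive_count(self):
        lams = [
            estimate_concentration(self._classified(k, 1000), "FAM").lambda_hat
            for k in range(0, 1000, 50)
        ]
        assert all(b > a for a, b in zip(lams, lams[1:]))

    def test_small_lambda_limit_matches_uncorrected_count(self):
        """At p̂ < 0.01 the Poisson correction is negligible: copies/reaction
        agrees with the raw count scaled by volume within 1%."""
        est = estimate_concentration(self._classified(100, 15_000), "FAM", 20.0, 0.85)
        uncorrected = 100 / 15_000 / 0.00085 * 20
        assert est.copies_per_reaction == pytest.approx(uncorrected, rel=0.01)

    def test_saturated_well_flagged(self):
        est = estimate_concentration(self._classified(1000, 1000), "FAM")
        assert est.saturated
        assert math.isinf(est.copies_per_reaction)
        assert est.ci95_low > 0 and math.isinf(est.ci95_high)

    def test_exact_bounds_at_extreme_counts(self):
        """≤5 positives switch to Clopper–Pearson: bounds match the beta
        quantiles transformed through −ln(1−p)."""
        n, k = 15_000, 3
        est = estimate_concentration(self._classified(k, n), "FAM", 20.0, 0.85)
        p_lo = stats.beta.ppf(0.025, k, n - k + 1)
        p_hi = stats.beta.ppf(0.975, k + 1, n - k)
        scale = 20.0 / 0.00085
        assert est.ci95_low == pytest.approx(-math.log1p(-p_lo) * scale, rel=1e-9)
        assert est.ci95_high == pytest.approx(-math.log1p(-p_hi) * scale, rel=1e-9)

    def test_estimator_recovers_simulated_truth(self, default_params):
        """Mean relative error of copies/reaction < 2% across λ ∈ {0.05, 0.5, 2}."""
        for lam in (0.05, 0.5, 2.0):
            conc = lam / default_params.droplet_volume_ul
            truth_copies = conc * 20.0
            ests = []
            for seed in range(30):
                rx = simulate_reaction(default_params, TrueConcentrations(conc, 0.0), seed=seed)
                cl = classify_droplets(rx, fit_thresholds(rx))
                ests.append(estimate_concentration(cl, "FAM", 20.0, 0.85).copies_per_reaction)
            assert abs(np.mean(ests) / truth_copies - 1) < 0.02

    def test_rejects_empty(self):
        from ddpcrkit.quantify import ClassifiedDroplets

        with pytest.raises(ValueError):
            ClassifiedDroplets(np.array([], dtype=np.int8), 0, 0, 0, 0, 1, ChannelThresholds(1, 1))


class TestReactionQC:
    @pytest.mark.parametrize(
        "n,expected", [(9_999, False), (10_000, True), (15_000, True)]
    )
    def test_droplet_yield_rule(self, n, expected):
        rng = np.random.default_rng(0)
        rx = _make_reaction(rng.normal(700, 21, n), rng.normal(1030, 31, n))
        assert qc_reaction(rx) is expected

    def test_qc_failure_propagates_to_estimates(self, default_params):
        params = SimulationParams(n_droplets=5000)
        rx = simulate_reaction(params, TrueConcentrations(100.0, 100.0), seed=1)
        ests = quantify_reaction(rx)
        assert all(not e.qc_pass for e in ests)


class TestLOD:
    def _ntc_estimate(self, n_pos, n_total, qc=True):
        cl_kwargs = dict(
            target_name="cifA",
            n_droplets=n_total,
            n_positive=n_pos,
            qc_pass=qc,
            is_ntc=True,
        )
        from ddpcrkit.quantify import ClassifiedDroplets, ChannelThresholds as CT

        labels = np.zeros(n_total, dtype=np.int8)
        labels[:n_pos] = 1
        cl = ClassifiedDroplets(labels, n_total, n_total - n_pos, n_pos, 0, 0, CT(5000, 2600))
        est = estimate_concentration(cl, "FAM", 20.0, 0.85, target_name="cifA", is_ntc=True)
        est.qc_pass = qc
        return est

    def test_single_clean_ntc_uses_exact_upper_bound(self):
        """0 positives of 15,000: LOD = −ln(1−CP_upper)/V_d·V_r ≈ 5.786
        copies/reaction (CP upper bound ≈ 3.689/15,000 on p), ceiling 6."""
        result = compute_lod([self._ntc_estimate(0, 15_000)])
        p_hi = stats.beta.ppf(0.975, 1, 15_000)
        expected = -math.log1p(-p_hi) / 0.00085 * 20
        assert result.lod_copies_per_reaction == pytest.approx(expected, rel=1e-9)
        assert result.lod_copies_per_reaction == pytest.approx(5.7865, abs=1e-3)
        assert result.lod_rounded_up == 6

    def test_replicate_t_interval(self):
        ests = [self._ntc_estimate(k, 15_000) for k in (1, 2, 3)]
        result = compute_lod(ests)
        values = np.array([e.copies_per_reaction for e in ests])
        expected = values.mean() + stats.t.ppf(0.975, 2) * values.std(ddof=1) / math.sqrt(3)
        assert result.lod_copies_per_reaction == pytest.approx(expected, rel=1e-9)

    def test_all_zero_replicates_fall_back_to_pooled_bound(self):
        ests = [self._ntc_estimate(0, 15_000) for _ in range(4)]
        result = compute_lod(ests)
        assert result.lod_copies_per_reaction > 0
        p_hi = stats.beta.ppf(0.975, 1, 60_000)
        expected = -math.log1p(-p_hi) / 0.00085 * 20
        assert result.lod_copies_per_reaction == pytest.approx(expected, rel=1e-9)

    def test_round_up_rule(self):
        assert round_up_lod(2.59) == 3
        assert round_up_lod(0.54) == 1
        assert round_up_lod(0.87) == 1

    def test_rejections(self):
        with pytest.raises(ValueError):
            compute_lod([])
        bad = self._ntc_estimate(0, 15_000, qc=False)
        with pytest.raises(ValueError):
            compute_lod([bad])
        a = self._ntc_estimate(0, 15_000)
        b = self._ntc_estimate(0, 15_000)
        b.target_name = "cifB"
        with pytest.raises(ValueError):
            compute_lod([a, b])

    def test_simulated_ntcs_give_single_copy_lod(self, default_params):
        """Eight default-rate NTC wells typically produce an LOD of ~1 copy
        per reaction, matching the single-copy sensitivity regime."""
        ests = []
        for i in range(8):
            ntc = simulate_ntc(default_params, seed=100 + i)
            ests.append(quantify_reaction(ntc, fam_target="cifA")[0])
        result = compute_lod(ests)
        assert 0 < result.lod_copies_per_reaction < 6
        assert 1 <= result.lod_rounded_up <= 6


class TestSingleMoleculeSensitivity:
    def test_detection_probability_matches_occupancy_model(self, default_params):
        """One template copy per 20 µL reaction: the chance that at least one
        droplet lights up equals 1−exp(−c·n·V_d) for the partitioned volume."""
        conc = 1.0 / 20.0
        n, vd = default_params.n_droplets, default_params.droplet_volume_ul
        p_detect = 1 - math.exp(-conc * n * vd)
        detected = 0
        n_runs = 150
        for seed in range(n_runs):
            rx = simulate_reaction(default_params, TrueConcentrations(conc, 0.0), seed=seed)
            cl = classify_droplets(rx, fit_thresholds(rx))
            detected += cl.n_fam_positive >= 1
        se = math.sqrt(p_detect * (1 - p_detect) / n_runs)
        assert abs(detected / n_runs - p_detect) < 4 * se
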