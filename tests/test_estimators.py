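import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsrspike import (
    ISIModel,
    SpikeTrainSet,
    UniformTrialRateSpec,
    choose_bin_size,
    count_stats,
    dsr_phi_from_moments,
    estimate_phi_dsr,
    estimate_phi_dtr,
    estimate_phi_mr,
    modulation_index,
    mr_error_prediction,
    partition_variance,
    renewal_count_moments,
    sample_constant_rate,
    sample_uniform_trial_rates,
    select_units,
    simulate_dsr,
    simulate_inhomogeneous_poisson,
)


def _translate(spikes: SpikeTrainSet, shift: float) -> SpikeTrainSet:
    return SpikeTrainSet(
        tuple(tr + shift for tr in spikes.trials),
        spikes.t_start + shift,
        spikes.t_end + shift,
    )


class TestCountStats:
    def test_identical_counts_zero_variance(self):
        trials = tuple(np.array([0.1, 0.4, 0.8]) for _ in range(5))
        s = SpikeTrainSet(trials, 0.0, 1.0)
        cs = count_stats(s, 1.0, stride=1.0)
        assert cs.mean[0] == 3.0 and cs.variance[0] == 0.0

    def test_hand_arithmetic(self, three_count_trials):
        cs = count_stats(three_count_trials, 1.0, stride=1.0)
        assert cs.mean[0] == pytest.approx(2.0)
        assert cs.variance[0] == pytest.approx(1.0)

    def test_homogeneous_poisson_mean_equals_variance(self):
        rp = sample_constant_rate(20.0, 0.5, 1e-3, 5000)
        s = simulate_inhomogeneous_poisson(rp, seed=0)
        cs = count_stats(s, 0.1, stride=0.1)
        se_mean = np.sqrt(2.0 / 5000)
        se_var = 2.0 * np.sqrt(2.0 / 4999)
        assert np.all(np.abs(cs.mean - 2.0) < 3 * se_mean)
        assert np.all(np.abs(cs.variance - 2.0) < 3 * se_var)

    def test_window_shorter_than_bin_flagged_empty(self, three_count_trials):
        cs = count_stats(three_count_trials, 5.0)
        assert cs.positions.size == 0


class TestChooseBinSize:
    def test_twenty_hz_gives_100_ms(self):
        trials = tuple(np.linspace(0.025, 0.975, 20) for _ in range(4))
        s = SpikeTrainSet(trials, 0.0, 1.0)
        assert choose_bin_size(s) == pytest.approx(0.1)

    def test_forty_hz_gives_50_ms(self):
        trials = tuple(np.linspace(0.0125, 0.9875, 40) for _ in range(4))
        s = SpikeTrainSet(trials, 0.0, 1.0)
        assert choose_bin_size(s) == pytest.approx(0.05)

    def test_no_spikes_raises(self):
        s = SpikeTrainSet((np.empty(0), np.empty(0)), 0.0, 1.0)
        with pytest.raises(ValueError):
            choose_bin_size(s)


class TestQuadraticRoot:
    @pytest.mark.parametrize("m", [2.0, 5.0, 0.8])
    def test_exact_poisson_moments_give_unity(self, m):
        # roots are {1, 4m-1}; the stable (smaller) branch is exactly 1
        root = dsr_phi_from_moments(m, m, 2 * m, 2 * m)
        assert root == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.1, 0.3, 0.5, 1.0, 1.3, 1.7])
    @pytest.mark.parametrize("rate_var", [0.0, 0.5, 2.0])
    @pytest.mark.parametrize("lam", [1.0, 3.0])
    def test_exact_gamma_moments_recover_phi(self, phi, rate_var, lam):
        # renewal count moments at rate lam plus any consistent Var(lambda*T)
        # leave the stable root exactly at phi
        T = 2.0 / lam
        m = ISIModel(phi)
        mean_T, var_T = lam * T, phi * lam * T + 1 / 6 - phi**2 / 6
        mean_2T, var_2T = lam * 2 * T, phi * lam * 2 * T + 1 / 6 - phi**2 / 6
        root = dsr_phi_from_moments(
            mean_T, var_T + rate_var, mean_2T, var_2T + 4 * rate_var
        )
        assert root == pytest.approx(phi, abs=1e-10)

    def test_general_alpha_consistency(self):
        phi, lam, T, alpha = 0.6, 2.0, 1.0, 3.0
        mean, var = lam * T, phi * lam * T + 1 / 6 - phi**2 / 6
        mean_a, var_a = lam * alpha * T, phi * lam * alpha * T + 1 / 6 - phi**2 / 6
        assert dsr_phi_from_moments(mean, var, mean_a, var_a, alpha) == pytest.approx(phi, abs=1e-10)

    def test_rejects_alpha_at_most_one(self):
        with pytest.raises(ValueError):
            dsr_phi_from_moments(1, 1, 1, 1, alpha=1.0)


class TestEstimatePhiDSR:
    @pytest.mark.parametrize("phi", [0.3, 1.0])
    def test_recovers_phi_with_trial_rate_variance(self, phi):
        rp = sample_uniform_trial_rates(UniformTrialRateSpec(30, 20), 2.0, 1e-3, 200, seed=21)
        s = simulate_dsr(ISIModel(phi), rp, seed=22)
        est = estimate_phi_dsr(s)
        assert est.method == "DSR" and est.valid
        assert est.phi == pytest.approx(phi, abs=0.12)

    def test_translation_invariance(self):
        rp = sample_uniform_trial_rates(UniformTrialRateSpec(30, 20), 2.0, 1e-3, 60, seed=3)
        s = simulate_dsr(ISIModel(0.5), rp, seed=4)
        a = estimate_phi_dsr(s, T=0.1)
        b = estimate_phi_dsr(_translate(s, 5.0), T=0.1)
        assert a.phi == pytest.approx(b.phi, rel=1e-9)

    def test_window_too_short_flagged(self, three_count_trials):
        est = estimate_phi_dsr(three_count_trials, T=2.0)
        assert not est.valid and est.n_valid_windows == 0


class TestPartition:
    def test_poisson_constant_rate_near_zero_rate_variance(self):
        rp = sample_constant_rate(20.0, 2.0, 1e-3, 500)
        s = simulate_inhomogeneous_poisson(rp, seed=1)
        part = partition_variance(s, 1.0, 0.1)
        # raw (unclipped) component should hover around zero
        raw = part.diagnostics["raw_rate_variance"]
        assert abs(raw.mean()) < 0.1
        assert np.all(part.rate_variance >= 0)

    def test_uniform_trial_rates_recover_w_squared_over_12(self):
        w, T = 20.0, 0.1
        rp = sample_uniform_trial_rates(UniformTrialRateSpec(30, w), 2.0, 1e-3, 800, seed=2)
        s = simulate_dsr(ISIModel(0.5), rp, seed=3)
        part = partition_variance(s, 0.5, T)
        implied = part.rate_variance.mean() / T**2
        assert implied == pytest.approx(w**2 / 12, rel=0.25)

    def test_components_sum_to_total(self):
        rp = sample_uniform_trial_rates(UniformTrialRateSpec(30, 20), 2.0, 1e-3, 100, seed=5)
        s = simulate_dsr(ISIModel(0.8), rp, seed=6)
        part = partition_variance(s, 0.8, 0.1)
        raw = part.diagnostics["raw_rate_variance"]
        np.testing.assert_allclose(
            raw + part.point_process_variance, part.total_variance, rtol=1e-9
        )


class TestDTR:
    def test_deterministic_rate_converges_to_phi(self):
        phi = 0.4
        rp = sample_constant_rate(30.0, 2.0, 1e-3, 300)
        s = simulate_dsr(ISIModel(phi), rp, seed=7)
        est = estimate_phi_dtr(s)
        assert est.phi == pytest.approx(phi, abs=0.06)

    def test_homogeneous_poisson_near_one(self):
        rp = sample_constant_rate(30.0, 2.0, 1e-3, 300)
        s = simulate_inhomogeneous_poisson(rp, seed=8)
        assert estimate_phi_dtr(s).phi == pytest.approx(1.0, abs=0.1)

    def test_overestimates_with_trial_rate_variance(self):
        phi = 0.4
        gaps = []
        for w in (10.0, 30.0):
            rp = sample_uniform_trial_rates(UniformTrialRateSpec(30, w), 2.0, 1e-3, 300, seed=9)
            s = simulate_dsr(ISIModel(phi), rp, seed=10)
            gaps.append(estimate_phi_dtr(s).phi - phi)
        assert gaps[0] > 0 and gaps[1] > gaps[0]


class TestMR:
    def test_zero_variance_bin_gives_zero(self):
        trials = tuple(np.array([0.05, 0.45, 0.85]) for _ in range(6))
        s = SpikeTrainSet(trials, 0.0, 1.0)
        assert estimate_phi_mr(s, T=0.06).phi == 0.0

    def test_homogeneous_poisson_biased_at_or_below_one(self):
        rp = sample_constant_rate(30.0, 2.0, 1e-3, 200)
        s = simulate_inhomogeneous_poisson(rp, seed=12)
        est = estimate_phi_mr(s)
        assert 0.5 < est.phi <= 1.05  # min of noisy Fano factors sits below 1

    def test_prediction_arithmetic_example(self):
        # Var(lambda)=0, phi=0.5, T=0.1, mean rate 30 Hz
        rp = sample_constant_rate(30.0, 1.0, 1e-3, 2)
        pred = mr_error_prediction(ISIModel(0.5), rp, 0.1)
        assert pred == pytest.approx((1 / 0.1) * (1 / 6 + 0.125 - 1 / 6) / 30.0, rel=1e-9)

    def test_prediction_vanishes_for_constant_rate_poisson(self):
        rp = sample_constant_rate(30.0, 1.0, 1e-3, 2)
        assert mr_error_prediction(ISIModel(1.0), rp, 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_prediction_tracks_empirical_error(self):
        # the prediction is for the expected Fano factor, so the empirical MR
        # is taken over few window positions with many trials (the min over
        # many noisy overlapping windows adds an order-statistic bias the
        # closed form does not model)
        phi, w = 0.5, 20.0
        rp = sample_uniform_trial_rates(UniformTrialRateSpec(30, w), 2.0, 1e-3, 1500, seed=13)
        s = simulate_dsr(ISIModel(phi), rp, seed=14)
        est = estimate_phi_mr(s, T=0.06, stride=0.6)
        pred = mr_error_prediction(ISIModel(phi), rp, 0.06)
        assert pred > 0
        assert est.phi - phi == pytest.approx(pred, abs=0.08)


class TestRenewalMoments:
    def test_poisson_corrections_cancel(self):
        mean, var = renewal_count_moments(ISIModel(1.0), 3.0)
        assert var == pytest.approx(mean) == pytest.approx(3.0)

    def test_plugin_value(self):
        mean, var = renewal_count_moments(ISIModel(0.5), 10.0)
        assert mean == pytest.approx(10.0)
        assert var == pytest.approx(5.0 + 1 / 6 - 1 / 24)


class TestSelectUnits:
    def test_boundary_and_brute_force(self):
        rows = []
        # unit 0: passes everywhere (boundary values); unit 1: 19 trials in one
        # condition; unit 2: 499 spikes in one condition; unit 3: passes;
        # unit 4: fails both in one condition
        data = {
            0: [(20, 500), (25, 900)],
            1: [(19, 800), (30, 900)],
            2: [(22, 499), (30, 900)],
            3: [(40, 2000), (21, 777)],
            4: [(10, 100), (30, 900)],
        }
        for unit, conds in data.items():
            for ci, (nt, ns) in enumerate(conds):
                rows.append({"unit": unit, "condition": ci, "n_trials": nt, "n_spikes": ns})
        df = pd.DataFrame(rows)
        kept = select_units(df)
        brute = [
            u for u, conds in data.items() if all(nt >= 20 and ns >= 500 for nt, ns in conds)
        ]
        assert kept == sorted(brute) == [0, 3]


class TestModulationIndex:
    def test_symmetry_and_conventions(self):
        assert modulation_index(0.7, 0.7) == 0.0
        assert modulation_index(0.7, 0.7, "full") == 0.0
        assert modulation_index(1.0, 0.8, "full") == pytest.approx(0.2222, abs=1e-4)

    def test_undefined_for_zero_sum(self):
        with pytest.raises(ValueError):
            modulation_index(0.5, -0.5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        a=st.floats(0.01, 10.0),
        b=st.floats(0.01, 10.0),
        conv=st.sampled_from(["half", "full"]),
    )
    def test_antisymmetry(self, a, b, conv):
        assert modulation_index(a, b, conv) == pytest.approx(-modulation_index(b, a, conv))
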