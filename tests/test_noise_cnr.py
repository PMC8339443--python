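"""Correlator noise model, noisy-g2 ensembles, and detectability calculators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcsim.noise_cnr import (
    NoiseParams,
    cnr,
    earliest_detectable_delay,
    estimate_std_tau_c,
    generate_noisy_g2,
    required_channels,
    sigma_g2,
)

PAPER_PARAMS = NoiseParams()  # Tb=1us, T=10ms, beta=1, <n>=0.1, tau_c=46us


class TestSigma:
    def test_bin_grid_validation(self):
        with pytest.raises(ValueError):
            sigma_g2(np.array([0.0]), PAPER_PARAMS)  # m = 0 invalid
        with pytest.raises(ValueError):
            sigma_g2(np.array([1.5e-6]), PAPER_PARAMS)  # off-grid

    def test_prefactor_scaling(self):
        """sigma scales exactly as sqrt(Tb/T) with everything else fixed."""
        tau = PAPER_PARAMS.bin_grid()
        a = sigma_g2(tau, NoiseParams(T=1e-2))
        b = sigma_g2(tau, NoiseParams(T=4e-2))
        np.testing.assert_allclose(a / b, 2.0, rtol=1e-12)

    def test_bright_limit_is_speckle_only(self):
        """<n> -> inf leaves only the beta^2 (speckle) term."""
        tau = PAPER_PARAMS.bin_grid()
        p_bright = NoiseParams(n_mean=1e12)
        got = sigma_g2(tau, p_bright)
        G = p_bright.Gamma
        e_tb = np.exp(-2 * G * p_bright.Tb)
        e_tau = np.exp(-2 * G * tau)
        m = np.round(tau / p_bright.Tb)
        speckle = ((1 + e_tb) * (1 + e_tau) + 2 * m * (1 - e_tb) * e_tau) / (1 - e_tb)
        want = np.sqrt(p_bright.Tb / p_bright.T) * np.sqrt(speckle)
        np.testing.assert_allclose(got, want, rtol=1e-6)

    def test_decreasing_over_fit_window_at_reference_parameters(self):
        tau = PAPER_PARAMS.bin_grid()
        sig = sigma_g2(tau, PAPER_PARAMS)
        assert np.all(np.diff(sig) < 0)
        assert sig[0] < 1.0  # sanity on magnitude: sub-unity for these parameters


class TestNoisyG2:
    def test_zero_noise_returns_model(self):
        c = generate_noisy_g2(PAPER_PARAMS, seed=1, noise_scale=0.0)
        model = 1.0 + PAPER_PARAMS.model_g2_minus_1(c.tau)
        np.testing.assert_array_equal(c.values, model)

    def test_seed_determinism(self):
        a = generate_noisy_g2(PAPER_PARAMS, seed=5)
        b = generate_noisy_g2(PAPER_PARAMS, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        c = generate_noisy_g2(PAPER_PARAMS, seed=6)
        assert not np.array_equal(a.values, c.values)

    def test_no_clipping_below_one(self):
        c = generate_noisy_g2(PAPER_PARAMS, seed=2)
        assert np.any(c.values < 1.0)  # at this noise level, tails do dip below 1

    def test_ensemble_mean_is_unbiased(self):
        """CLT: the sample mean at fixed tau approaches the model value."""
        rng = np.random.default_rng(11)
        n = 10_000
        tau = PAPER_PARAMS.bin_grid()
        sig = sigma_g2(tau, PAPER_PARAMS)
        model = 1.0 + PAPER_PARAMS.model_g2_minus_1(tau)
        acc = np.zeros_like(tau)
        for _ in range(n):
            acc += model + rng.standard_normal(tau.size) * sig
        mean = acc / n
        for j in (0, 30, 69):
            assert abs(mean[j] - model[j]) < 3.5 * sig[j] / np.sqrt(n)


class TestStdTauC:
    def test_zero_noise_recovers_tau_c_exactly(self):
        d = estimate_std_tau_c(PAPER_PARAMS, n_instances=100, noise_scale=0.0, seed=1)
        assert d.std == 0.0
        assert d.mean == pytest.approx(PAPER_PARAMS.tau_c, rel=1e-12)

    def test_mean_unbiased_within_error(self):
        d = estimate_std_tau_c(PAPER_PARAMS, n_instances=4000, seed=3)
        se = d.std / np.sqrt(d.samples.size)
        assert abs(d.mean - PAPER_PARAMS.tau_c) < 3 * se
        assert d.discard_rate < 0.01

    def test_quadrupling_channels_halves_spread(self):
        d1 = estimate_std_tau_c(PAPER_PARAMS, n_instances=4000, nc=1, seed=9)
        d4 = estimate_std_tau_c(PAPER_PARAMS, n_instances=4000, nc=4, seed=10)
        assert d1.std / d4.std == pytest.approx(2.0, rel=0.1)

    def test_sigma_scaling_equals_explicit_channel_averaging(self):
        """Scaling sigma by 1/sqrt(Nc) is distributionally identical to
        averaging Nc synthetic channels; check std agreement at Nc=4."""
        rng = np.random.default_rng(21)
        tau = PAPER_PARAMS.bin_grid()
        sig = sigma_g2(tau, PAPER_PARAMS)
        model = 1.0 + PAPER_PARAMS.model_g2_minus_1(tau)
        n = 1500
        from dcsim.noise_cnr import fit_noisy_g2_rates

        averaged = model[None, :] + (
            rng.standard_normal((n, 4, tau.size)) * sig[None, None, :]
        ).mean(axis=1)
        th_avg, ok_a = fit_noisy_g2_rates(tau, averaged, PAPER_PARAMS.beta)
        d_scaled = estimate_std_tau_c(PAPER_PARAMS, n_instances=n, nc=4, seed=22)
        std_avg = np.std(1.0 / th_avg[ok_a], ddof=1)
        assert std_avg == pytest.approx(d_scaled.std, rel=0.15)

    def test_inverse_spread_linear_in_sqrt_channels(self):
        """1/std(tau_c) vs sqrt(Nc) is linear (R^2 > 0.99) over Nc = 1..64."""
        ncs = np.array([1, 4, 16, 64])
        inv_std = []
        for i, nc in enumerate(ncs):
            d = estimate_std_tau_c(PAPER_PARAMS, n_instances=2000, nc=int(nc), seed=30 + i)
            inv_std.append(1.0 / d.std)
        x = np.sqrt(ncs)
        y = np.array(inv_std)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r2 > 0.99


class TestDetectability:
    def test_required_channels_examples(self):
        assert required_channels(0.25, 0.28) == 2
        assert required_channels(0.3, 0.3) == 1
        nc = required_channels(1.01e-5, 0.28)
        assert 1e8 < nc < 1e10  # ~1e9 channels for the cell-motion signal
        with pytest.raises(ValueError):
            required_channels(0.0, 0.28)

    @given(
        c1=st.floats(1e-6, 0.5),
        c2=st.floats(1e-6, 0.5),
        s=st.floats(1e-3, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_required_channels_monotone_in_contrast(self, c1, c2, s):
        lo, hi = sorted((c1, c2))
        assert required_channels(lo, s) >= required_channels(hi, s)

    def test_cnr_scaling(self):
        assert cnr(0.25, 0.28, nc=1) == pytest.approx(0.25 / 0.28)
        assert cnr(0.25, 0.28, nc=4) == pytest.approx(2 * 0.25 / 0.28)

    def test_earliest_delay_threshold_logic(self):
        td = np.arange(1, 41) * 0.05
        C = 1e-3 * (td / 0.05)  # contrast rising linearly along the grid
        res = earliest_detectable_delay(td, C, snr=300.0)
        assert res.td == pytest.approx(0.2)  # first C >= 1/300
        assert res.t_after_activation == pytest.approx(0.2 + 0.45)
        inf = earliest_detectable_delay(td, C, snr=1e12)
        assert inf.td == pytest.approx(td[0])  # snr -> inf: first grid point
        with pytest.raises(ValueError):
            earliest_detectable_delay(td, C, snr=1.0)  # never detectable

    def test_earliest_delay_monotone_in_snr(self):
        td = np.arange(1, 41) * 0.05
        C = 1e-4 * (td / 0.05) ** 2
        tds = [earliest_detectable_delay(td, C, snr).td for snr in (100, 300, 1000)]
        assert tds[0] >= tds[1] >= tds[2]
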