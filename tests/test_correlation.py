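"""Autocorrelation synthesis, the Siegert relation, and decay-time fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcsim.correlation import (
    BallisticComponent,
    DiffusiveComponent,
    DynamicsSpec,
    FitError,
    G1Curve,
    decay_time_1e,
    default_tau_grid,
    fit_tau_c,
    g1_analytic_semiinf,
    g1_from_records,
    siegert,
    tau_s_ratio,
)
from dcsim.mc_transport import OpticalMedium


BASELINE = DynamicsSpec.baseline(1e-6)


def brute_force_g1(records, alpha_D_out, alpha_D_region, ballistic, tau):
    """Independent re-implementation: explicit per-photon, per-tau loops."""
    k02 = records.medium.k0**2
    out = []
    for t in tau:
        num = 0.0
        den = 0.0
        for n in range(records.n_detected):
            w = math.exp(-records.medium.mu_a * records.L[n])
            y2 = records.Y2[n]
            y1 = records.Y[n] - y2
            ex = 2.0 * k02 * t * (alpha_D_out * y1 + alpha_D_region * y2)
            for v_nm, alpha, scope in ballistic:
                ys = records.Y[n] if scope == "global" else y2
                ex += alpha * k02 * (v_nm * 1e-3) ** 2 * t * t * ys / 3.0
            num += w * math.exp(-ex)
            den += w
        out.append(num / den)
    return np.array(out)


def test_g1_normalization_and_static_limits(records):
    grid = default_tau_grid()
    g = g1_from_records(records, BASELINE, grid)
    assert g.values[0] == pytest.approx(1.0, abs=1e-14)
    assert np.all(np.diff(g.values) <= 1e-14)  # non-increasing
    static = g1_from_records(records, DynamicsSpec.baseline(0.0), grid)
    np.testing.assert_allclose(static.values, 1.0, atol=1e-15)


def test_g1_rejects_bad_inputs(records, medium, geometry, region):
    from dcsim.mc_transport import run_mc

    empty = run_mc(medium, geometry, region, 0, seed=1)
    with pytest.raises(ValueError):
        g1_from_records(empty, BASELINE)
    with pytest.raises(ValueError):
        g1_from_records(records, BASELINE, np.array([-1e-6, 0.0]))


def test_g1_matches_brute_force_oracle(records):
    """Vectorized synthesis == explicit Eq.-by-Eq. loops (global + local + ballistic)."""
    tau = np.array([0.0, 1e-5, 4e-5, 7e-5])
    spec = DynamicsSpec(
        diffusive=(
            DiffusiveComponent(1e-6, "outside"),
            DiffusiveComponent(1.4e-6, "local"),
        ),
        ballistic=(BallisticComponent(1.0, 1.0, "global"),),
    )
    got = g1_from_records(records, spec, tau).values
    want = brute_force_g1(records, 1e-6, 1.4e-6, [(1.0, 1.0, "global")], tau)
    np.testing.assert_allclose(got, want, rtol=1e-12)


def test_two_tissue_decomposition_identity(whole_medium_records):
    """With the region covering the whole medium, the split local/outside form
    reduces bit-for-bit to the single global blood term (Y1 = 0 exactly)."""
    grid = default_tau_grid()
    g_global = g1_from_records(whole_medium_records, BASELINE, grid)
    g_split = g1_from_records(
        whole_medium_records, DynamicsSpec.two_tissue(1e-6, 1e-6), grid
    )
    np.testing.assert_array_equal(g_global.values, g_split.values)


def test_analytic_semiinf_shape(medium):
    grid = default_tau_grid()
    g = g1_analytic_semiinf(medium, 30.0, 1e-6, grid)
    assert g.values[0] == pytest.approx(1.0, abs=1e-14)
    assert np.all(np.diff(g.values) < 0)  # strictly decreasing for alpha_D > 0
    assert np.all((g.values >= 0) & (g.values <= 1))


def test_mc_and_analytic_routes_agree(records, medium):
    """Monte Carlo synthesis vs the correlation-diffusion closed form."""
    grid = default_tau_grid()
    g_mc = g1_from_records(records, BASELINE, grid)
    g_an = g1_analytic_semiinf(medium, 30.0, 1e-6, grid)
    tc_mc = fit_tau_c(g_mc).tau_c
    tc_an = fit_tau_c(g_an).tau_c
    assert tc_mc == pytest.approx(tc_an, rel=0.15)
    window = grid <= 3 * tc_mc
    assert np.max(np.abs(g_mc.values - g_an.values)[window]) <= 0.02


class TestSiegert:
    def test_values(self):
        g = G1Curve(np.array([0.0, 1e-5]), np.array([1.0, 0.6]))
        g2 = siegert(g, beta=0.5)
        assert g2.values[0] == pytest.approx(1.5)
        assert g2.values[1] == pytest.approx(1.18)
        full = siegert(G1Curve(np.array([0.0]), np.array([1.0])), beta=1.0)
        assert full.values[0] == pytest.approx(2.0)
        zero = siegert(G1Curve(np.array([0.0]), np.array([0.0])), beta=0.7)
        assert zero.values[0] == pytest.approx(1.0)

    def test_beta_validated(self):
        g = G1Curve(np.array([0.0]), np.array([1.0]))
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                siegert(g, beta=bad)

    @given(beta=st.floats(0.01, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_bounds(self, beta):
        vals = np.linspace(0.0, 1.0, 50)
        g2 = siegert(G1Curve(np.linspace(0, 1e-4, 50), vals), beta=beta)
        assert np.all(g2.values >= 1.0 - 1e-12)
        assert np.all(g2.values <= 1.0 + beta + 1e-12)


class TestDecayFit:
    @given(tau_c=st.floats(5e-6, 2e-4))
    @settings(max_examples=30, deadline=None)
    def test_recovers_exact_exponential(self, tau_c):
        grid = default_tau_grid()
        curve = G1Curve(grid, np.exp(-grid / tau_c))
        fit = fit_tau_c(curve)
        assert fit.tau_c == pytest.approx(tau_c, rel=1e-3)
        if 2e-5 < tau_c < 1e-4:  # well-conditioned on this window
            assert fit.tau_c == pytest.approx(tau_c, rel=1e-9)

    def test_g2_form_with_beta_fixed(self):
        grid = default_tau_grid()
        tau_c = 46e-6
        from dcsim.correlation import G2Curve

        curve = G2Curve(grid, 1.0 + 0.8 * np.exp(-2 * grid / tau_c), beta=0.8)
        assert fit_tau_c(curve).tau_c == pytest.approx(tau_c, rel=1e-9)

    def test_flat_curve_raises(self):
        grid = default_tau_grid()
        with pytest.raises(FitError):
            fit_tau_c(G1Curve(grid, np.ones_like(grid)))

    def test_1e_crossing(self):
        grid = np.linspace(0, 5e-4, 2000)
        curve = G1Curve(grid, np.exp(-grid / 1e-4))
        assert decay_time_1e(curve) == pytest.approx(1e-4, rel=1e-3)
        with pytest.raises(FitError):
            decay_time_1e(G1Curve(grid[:3], np.exp(-grid[:3] / 1e-4)))


class TestTauSRatio:
    def test_reference_parameters(self, medium):
        # sqrt(0.75 * 0.01 * 1 * (900 + (1 + 5/3)^2)) = 2.608 -> printed as 2.6
        assert tau_s_ratio(medium, 30.0) == pytest.approx(2.6, abs=0.05)

    def test_zero_absorption_limit(self):
        assert tau_s_ratio(OpticalMedium(mu_a=0.0), 30.0) == 0.0

    def test_monotone_in_separation(self, medium):
        rhos = np.array([10.0, 20.0, 30.0, 40.0])
        vals = [tau_s_ratio(medium, r) for r in rhos]
        assert np.all(np.diff(vals) > 0)


def test_curve_tsv_round_trip(records, tmp_path):
    g = g1_from_records(records, BASELINE, default_tau_grid())
    p = tmp_path / "g1.tsv"
    g.to_tsv(str(p), metadata={"alpha_D": 1e-6})
    back = G1Curve.from_tsv(str(p))
    np.testing.assert_allclose(back.values, g.values, rtol=1e-15)
    np.testing.assert_allclose(back.tau, g.tau, rtol=1e-10)
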