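"""Closed-form model functions: limits, oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import polysesans as ps
from conftest import abel_quadrature


class TestDebyeFormFactor:
    def test_zero_q_is_one(self, rg15):
        assert ps.debye_form_factor(0.0, rg15) == pytest.approx(1.0)

    def test_qrg_one_is_two_over_e(self, rg15):
        # direct evaluation of 2(e^-x - 1 + x)/x^2 at x = 1
        assert ps.debye_form_factor(1.0 / 15.0, rg15) == pytest.approx(2.0 / math.e, rel=1e-12)

    def test_large_q_decays_as_q_minus_2(self, rg15):
        Q = 300.0 / rg15.Rg
        assert ps.debye_form_factor(Q, rg15) * (Q * rg15.Rg) ** 2 == pytest.approx(2.0, rel=1e-2)

    def test_depends_on_x_only(self):
        # same x = Q^2 Rg^2 from different (Q, Rg) pairs gives the same value
        a = ps.debye_form_factor(0.3, ps.GaussianChainModel(Rg=10.0))
        b = ps.debye_form_factor(3.0, ps.GaussianChainModel(Rg=1.0))
        assert a == pytest.approx(b, rel=1e-14)

    def test_negative_q_rejected(self, rg15):
        with pytest.raises(ValueError):
            ps.debye_form_factor(-0.1, rg15)

    def test_series_stitch_continuous(self, rg15):
        # just above the switch the closed form must equal the series
        x = 1.01e-4
        closed = ps.debye_form_factor(math.sqrt(x) / rg15.Rg, rg15)
        assert closed == pytest.approx(1.0 - x / 3.0 + x * x / 12.0 - x**3 / 60.0, abs=1e-11)


class TestDivergentCorrelation:
    def test_raises_at_origin(self, rg15):
        with pytest.raises(ps.DivergenceError):
            ps.gamma_auto_divergent(0.0, rg15)

    def test_unbounded_near_origin(self, rg15):
        small = ps.gamma_auto_divergent(1e-9 * rg15.Rg, rg15)
        assert small > 1e6

    def test_vanishes_at_infinity(self, rg15):
        assert ps.gamma_auto_divergent(40.0 * rg15.Rg, rg15) < 1e-12

    def test_strictly_decreasing(self, rg15):
        r = np.linspace(0.01, 10, 500) * rg15.Rg
        assert np.all(np.diff(ps.gamma_auto_divergent(r, rg15)) < 0)

    def test_matches_inverse_fourier_of_debye(self, rg15):
        """The divergent correlation IS the spherical inverse FT of the
        Debye function (physical normalization), checked at r = Rg."""
        r = np.array([1.0, 2.0]) * rg15.Rg
        curve = ps.radial_fourier_invert(
            lambda Q: ps.debye_form_factor(Q, rg15), r, Q_cut=2000 / rg15.Rg
        )
        expected = ps.gamma_auto_divergent(r, rg15, normalized=False)
        np.testing.assert_allclose(curve.values, expected, rtol=1e-4)


class TestNonDivergentCorrelation:
    def test_finite_and_one_at_origin(self, rg15):
        assert ps.gamma_auto(0.0, rg15) == pytest.approx(1.0)

    def test_vanishes_at_infinity(self, rg15):
        assert ps.gamma_auto(40.0 * rg15.Rg, rg15) < 1e-12

    def test_nonnegative(self, rg15):
        r = np.linspace(0, 30, 2000) * rg15.Rg
        assert np.all(ps.gamma_auto(r, rg15) >= 0)

    def test_negative_r_rejected(self, rg15):
        with pytest.raises(ValueError):
            ps.gamma_auto(-1.0, rg15)

    def test_series_stitch(self, rg15):
        """Series and closed form agree to 1e-10 at the switch point."""
        from polysesans.models import chain_overlap_g

        for eta in (0.999e-3, 0.5e-3):  # series branch of the package
            v = float(ps.gamma_auto(eta * rg15.Rg, rg15))
            closed = float((chain_overlap_g(eta / 2) - 4 * chain_overlap_g(2 * eta)) / 12)
            assert v == pytest.approx(closed, abs=1e-10)

    def test_agrees_with_divergent_beyond_rg(self, rg15):
        """Both describe the same chain at large separation: <=1% relative
        agreement for eta >= 1, while they differ wildly near the origin."""
        r = np.linspace(1.0, 8.0, 50) * rg15.Rg
        auto = ps.gamma_auto(r, rg15)
        div = ps.gamma_auto_divergent(r, rg15)
        assert np.all(np.abs(div / auto - 1.0) <= 0.01)
        assert ps.gamma_auto_divergent(1e-6 * rg15.Rg, rg15) > 1e3 * ps.gamma_auto(0.0, rg15)

    def test_matches_monte_carlo_pair_density(self, ideal_ensemble_large):
        """At eta = 1 the model agrees with the normalized intra-chain
        pair-distance density p(r)/(4 pi r^2) of 1e4 ideal chains within
        3 Monte-Carlo standard errors (amplitude calibrated over the
        surrounding window, where model and sampled chain share their
        functional form)."""
        ens = ideal_ensemble_large
        rg = ps.ensemble_rg(ens, "rms").value
        model = ps.GaussianChainModel(Rg=rg, N=ens.beads_per_chain - 1)
        edges = np.linspace(0.8 * rg, 4.0 * rg, 65)
        curve = ps.gamma_from_trajectory(ens, edges)
        m = ps.gamma_auto(curve.grid, model)
        w = 1.0 / curve.errors**2
        amp = np.sum(w * curve.values * m) / np.sum(w * m * m)
        i = int(np.argmin(np.abs(curve.grid - rg)))
        assert abs(curve.values[i] - amp * m[i]) <= 3.0 * curve.errors[i]


class TestFullCorrelation:
    def _contrast(self, phi=0.3, bh=1.0, bd=6.0):
        return ps.ContrastSpec(N_c=50, phi=phi, beta_H=bh, beta_D=bd, n_c=1e-5)

    def test_zero_without_labeling(self, rg15):
        r = np.linspace(0, 5, 20) * rg15.Rg
        assert np.all(ps.gamma_full(r, rg15, self._contrast(phi=0.0)) == 0)
        assert np.all(ps.gamma_full(r, rg15, self._contrast(bh=2.0, bd=2.0)) == 0)

    def test_half_deuteration_maximal(self, rg15):
        r = 2.0 * rg15.Rg
        vals = [ps.gamma_full(r, rg15, self._contrast(phi=p)) for p in np.linspace(0, 1, 11)]
        assert np.argmax(vals) == 5

    def test_ratio_to_auto_independent_of_r(self, rg15):
        c = self._contrast()
        r = np.linspace(0.1, 10, 40) * rg15.Rg
        ratio = ps.gamma_full(r, rg15, c) / ps.gamma_auto(r, rg15)
        assert np.ptp(ratio) / ratio[0] < 1e-12


class TestProjectedCorrelation:
    def test_one_at_origin(self, rg15):
        assert ps.g0_projected(0.0, rg15) == pytest.approx(1.0)

    def test_vanishes_at_infinity(self, rg15):
        assert ps.g0_projected(60.0 * rg15.Rg, rg15) < 1e-12

    def test_monotone_nonincreasing(self, rg15):
        z = np.linspace(0, 20, 2000) * rg15.Rg
        assert np.all(np.diff(ps.g0_projected(z, rg15)) <= 1e-15)

    def test_bounded_in_unit_interval(self, rg15):
        z = np.linspace(0, 50, 500) * rg15.Rg
        g0 = ps.g0_projected(z, rg15)
        assert np.all((g0 >= 0) & (g0 <= 1.0 + 1e-12))

    def test_negative_z_rejected(self, rg15):
        with pytest.raises(ValueError):
            ps.g0_projected(-0.5, rg15)

    @pytest.mark.parametrize("zeta", [0.5, 1.0, 2.0, 5.0])
    def test_equals_abel_of_gamma_auto(self, rg15, zeta):
        """Closed form vs singularity-free quadrature of the Abel integral."""
        norm = abel_quadrature(lambda r: ps.gamma_auto(r, rg15), 1e-9 * rg15.Rg)
        num = abel_quadrature(lambda r: ps.gamma_auto(r, rg15), zeta * rg15.Rg)
        assert ps.g0_projected(zeta * rg15.Rg, rg15) == pytest.approx(num / norm, rel=1e-4)

    def test_series_stitch(self, rg15):
        from polysesans.models import _LN2, projection_f

        for zeta in (0.999e-3, 0.5e-3):  # series branch of the package
            v = float(ps.g0_projected(zeta * rg15.Rg, rg15))
            c = zeta * zeta / 4.0
            closed = float((projection_f(c) - projection_f(16 * c)) / (4 * _LN2))
            assert v == pytest.approx(closed, abs=1e-10)


class TestGAtZero:
    def _contrast(self, phi=0.3):
        return ps.ContrastSpec(N_c=50, phi=phi, beta_H=1.0, beta_D=6.0, n_c=1e-5)

    def test_zero_at_pure_phases(self, rg15):
        for phi in (0.0, 1.0):
            assert ps.g_at_zero(rg15, self._contrast(phi)) == 0.0

    def test_inverse_square_rg_scaling(self):
        c = self._contrast()
        a = ps.g_at_zero(ps.GaussianChainModel(Rg=10.0), c)
        b = ps.g_at_zero(ps.GaussianChainModel(Rg=20.0), c)
        assert a == pytest.approx(4.0 * b, rel=1e-14)

    def test_equals_abel_of_gamma_full_at_origin(self, rg15):
        c = self._contrast()
        num = abel_quadrature(lambda r: ps.gamma_full(r, rg15, c), 1e-9 * rg15.Rg)
        assert ps.g_at_zero(rg15, c) == pytest.approx(num, rel=1e-4)


class TestPolarization:
    def test_one_at_origin(self, rg15):
        assert ps.polarization(0.0, rg15, opacity=0.7) == pytest.approx(1.0)

    def test_no_scattering_no_depolarization(self, rg15):
        z = np.linspace(0, 10, 30) * rg15.Rg
        assert np.allclose(ps.polarization(z, rg15, opacity=0.0), 1.0)

    def test_saturates_at_exp_minus_opacity(self, rg15):
        assert ps.polarization(100 * rg15.Rg, rg15, opacity=0.8) == pytest.approx(
            math.exp(-0.8), rel=1e-10
        )

    def test_monotone_nonincreasing(self, rg15):
        z = np.linspace(0, 30, 1000) * rg15.Rg
        assert np.all(np.diff(ps.polarization(z, rg15, opacity=0.5)) <= 1e-15)

    def test_single_scattering_is_first_order(self, rg15):
        """|P - (1 + opacity (G0 - 1))| = O(opacity^2) on a z grid."""
        z = np.linspace(0, 10, 50) * rg15.Rg
        g0 = ps.g0_projected(z, rg15)
        for op in (0.01, 0.005):
            gap = np.max(np.abs(ps.polarization(z, rg15, opacity=op) - (1 + op * (g0 - 1))))
            assert gap <= op**2  # |e^x - 1 - x| <= x^2/2 for |x| <= 1
        # and the bound actually scales quadratically
        g1 = np.max(np.abs(ps.polarization(z, rg15, opacity=0.02) - (1 + 0.02 * (g0 - 1))))
        g2 = np.max(np.abs(ps.polarization(z, rg15, opacity=0.01) - (1 + 0.01 * (g0 - 1))))
        assert g1 / g2 == pytest.approx(4.0, rel=0.1)

    def test_opacity_constructor_dimensionless_pipeline(self, rg15):
        c = ps.ContrastSpec(N_c=100, phi=0.5, beta_H=-0.37, beta_D=0.67, n_c=2e-6)
        inst = ps.InstrumentSpec(wavelength=2.0, thickness=10.0)
        op = ps.opacity_from_contrast(rg15, c, inst)
        assert op > 0
        p = ps.polarization(np.array([5.0]), rg15, contrast=c, instrument=inst)
        assert p[0] == pytest.approx(
            math.exp(op * (ps.g0_projected(5.0, rg15) - 1.0)), rel=1e-12
        )

    def test_negative_opacity_rejected(self, rg15):
        with pytest.raises(ValueError):
            ps.polarization(1.0, rg15, opacity=-0.1)


class TestScalingInvariance:
    """All outputs are invariant under r -> c r, z -> c z, Rg -> c Rg, Q -> Q/c."""

    @given(st.floats(min_value=0.05, max_value=50.0), st.floats(min_value=0.01, max_value=8.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_dimensionless_functions_scale(self, c, eta):
        m1 = ps.GaussianChainModel(Rg=7.0)
        m2 = ps.GaussianChainModel(Rg=7.0 * c)
        assert ps.gamma_auto(eta * m1.Rg, m1) == pytest.approx(
            ps.gamma_auto(eta * m2.Rg, m2), rel=1e-12
        )
        assert ps.g0_projected(eta * m1.Rg, m1) == pytest.approx(
            ps.g0_projected(eta * m2.Rg, m2), rel=1e-12
        )
        assert ps.debye_form_factor(eta / m1.Rg, m1) == pytest.approx(
            ps.debye_form_factor(eta / m2.Rg, m2), rel=1e-12
        )


class TestDomainTypes:
    def test_rg_b_consistency_enforced(self):
        with pytest.raises(ValueError):
            ps.GaussianChainModel(Rg=10.0, N=100, b=1.0)
        m = ps.GaussianChainModel.from_bond_length(b=1.0, N=100)
        assert m.Rg == pytest.approx(float(ps.rg_bond_relation(1.0, 100)))

    def test_rg_b_relation_asymptote(self):
        # exact finite-N form within 1% of b sqrt(N/6) for N >= 100
        for N in (100, 1000):
            exact = float(ps.rg_bond_relation(1.0, N))
            assert exact == pytest.approx(math.sqrt(N / 6.0), rel=0.01)

    def test_contrast_validation(self):
        with pytest.raises(ValueError):
            ps.ContrastSpec(N_c=10, phi=1.5, beta_H=1, beta_D=2, n_c=1e-5)
        with pytest.raises(ValueError):
            ps.ContrastSpec(N_c=0, phi=0.5, beta_H=1, beta_D=2, n_c=1e-5)

    def test_instrument_validation(self):
        with pytest.raises(ValueError):
            ps.InstrumentSpec(wavelength=-1.0, thickness=1.0)
        with pytest.raises(ValueError):
            ps.InstrumentSpec(wavelength=1.0, thickness=1.0, opacity=-0.5)


def test_debye_equals_normalized_fourier_of_divergent_correlation(rg1):
    """Forward 3D Fourier transform of the divergent correlation,
    normalized at Q = 0, reproduces the Debye function to 1e-3 for
    Q Rg in [0.1, 10]."""
    Q = np.array([0.1, 0.5, 1.0, 3.0, 10.0]) / rg1.Rg

    def gamma(r):
        return ps.gamma_auto_divergent(np.maximum(r, 1e-300), rg1)

    curve = ps.radial_fourier_transform(gamma, np.concatenate([[0.0], Q]), scale=rg1.Rg)
    normalized = curve.values[1:] / curve.values[0]
    expected = ps.debye_form_factor(Q, rg1)
    assert np.all(np.abs(normalized / expected - 1.0) <= 1e-3)
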