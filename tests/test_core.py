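"""Chord statistics, straggling factor, restricted-LET fraction, variance
budget and parametric straggling laws."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from microyd import born, core
from microyd.constants import I_WATER_KEV
from microyd.core import (
    ChordDistribution,
    TargetSphere,
    delta2,
    delta2_from_shell_spectra,
    f_ion,
    make_straggling_distribution,
    variance_budget,
)

from conftest import CANONICAL_DELTAS_KEV, DELTA2_ENERGIES_MEV


class TestChords:
    @pytest.mark.parametrize("d", [10.0, 100.0, 1000.0, 37.5])
    def test_mean_chord_and_relative_variance(self, d):
        c = ChordDistribution(TargetSphere(d) if d in (10.0, 100.0, 1000.0)
                              else TargetSphere(d, delta_keV=1.0))
        m1 = c.moment(1)
        m2 = c.moment(2)
        assert m1 == pytest.approx(2.0 * d / 3.0, rel=1e-8)
        assert m2 / m1**2 - 1.0 == pytest.approx(0.125, abs=1e-7)
        assert c.mean == 2.0 * d / 3.0
        assert c.relative_variance == 0.125

    def test_pdf_normalized_on_support(self):
        c = ChordDistribution(TargetSphere(100.0))
        assert c.moment(0) == pytest.approx(1.0, abs=1e-9)
        assert np.all(c.pdf(np.array([-1.0, 0.0, 101.0])) == 0.0)

    def test_inverse_cdf_sampler_matches_mean(self):
        sphere = TargetSphere(100.0)
        c = ChordDistribution(sphere)
        rng = np.random.default_rng(2024)
        samples = c.sample(rng, 1_000_000)
        se = samples.std(ddof=1) / math.sqrt(samples.size)
        assert abs(samples.mean() - 2.0 * sphere.d_nm / 3.0) < 3.0 * se
        assert samples.max() <= sphere.d_nm and samples.min() >= 0.0


class TestTargetSphere:
    def test_canonical_cutoffs_bundled(self):
        for d, delta in [(10.0, 0.180), (100.0, 1.37), (1000.0, 5.56)]:
            s = TargetSphere(d)
            assert s.delta_keV == delta
            assert s.lbar_nm == pytest.approx(2.0 * d / 3.0)

    def test_off_anchor_diameter_interpolates_with_warning(self):
        with pytest.warns(UserWarning):
            s = TargetSphere(300.0)
        assert 1.37 < s.delta_keV < 5.56

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            TargetSphere(-1.0)


class TestDelta2:
    def test_kellerer_closed_form(self):
        # 5.56 / (2 ln(5.56/0.078)) evaluated directly
        val = delta2(None, None, 5.56, method="kellerer")
        assert val == pytest.approx(5.56 / (2 * math.log(5.56 / 0.078)), rel=1e-12)
        assert val == pytest.approx(0.652, abs=5e-4)

    def test_xapsos_closed_form(self):
        assert delta2(None, None, 1.37, method="xapsos") == pytest.approx(0.236, abs=5e-4)

    def test_fitted_summary_curve(self):
        assert delta2(None, None, 1.0, method="fitted") == pytest.approx(
            0.0074 + 0.174, rel=1e-12
        )

    def test_toy_inverse_square_spectrum_closed_form(self):
        # single channel, B = 0, dsigma/dE ~ 1/E^2 on [I, E_max]:
        # delta2 = (Delta - I)/ln(Delta/I) exactly
        i_ev = I_WATER_KEV * 1e3
        emax = 229.2e3
        e = np.geomspace(i_ev, emax, 400_000)
        shells = [(0.0, e, 1.0 / e**2)]
        for d_kev in (0.5, 1.37, 5.56):
            got = delta2_from_shell_spectra(shells, d_kev)
            want = (d_kev - I_WATER_KEV) / math.log(d_kev / I_WATER_KEV)
            assert got == pytest.approx(want, rel=2e-4)

    def test_rpwba_monotone_in_cutoff(self, delta2_averages):
        vals = [delta2_averages[d] for d in CANONICAL_DELTAS_KEV]
        assert vals[0] < vals[1] < vals[2]

    def test_kellerer_monotone_in_cutoff(self):
        vals = [delta2(None, None, d, method="kellerer") for d in (0.5, 1.37, 5.56)]
        assert vals == sorted(vals)

    def test_rpwba_below_kellerer_at_canonical_cutoffs(self, delta2_averages):
        for d in CANONICAL_DELTAS_KEV:
            assert delta2_averages[d] < delta2(None, None, d, method="kellerer")

    def test_rpwba_nearly_energy_independent_for_small_sites(self, delta2_grid):
        # < 20% variation across 2-1000 MeV for d <= 100 nm
        for d in (0.180, 1.37):
            vals = np.array([delta2_grid[(t, d)] for t in DELTA2_ENERGIES_MEV])
            assert (vals.max() - vals.min()) / vals.mean() < 0.20

    def test_cutoff_beyond_kinematic_maximum(self, model):
        kin = born.proton_kinematics(2.0)  # E_max ~ 4.36 keV < 5.56 keV
        with pytest.raises(ValueError):
            delta2(model, kin, 5.56, method="rpwba")
        clipped = delta2(model, kin, 5.56, method="rpwba", clip=True)
        at_emax = delta2(model, kin, kin.emax_keV, method="rpwba")
        assert clipped == pytest.approx(at_emax, rel=1e-9)


class TestFion:
    def test_unity_at_kinematic_maximum(self, kin100):
        assert f_ion(kin100, kin100.emax_keV) == pytest.approx(1.0, abs=1e-12)

    def test_reference_value_100mev(self, kin100):
        # direct evaluation of the restricted-LET formula with
        # E_max = 229.2 keV, Delta = 1.37 keV, I = 0.078 keV
        assert f_ion(kin100, 1.37) == pytest.approx(0.72, abs=0.01)

    def test_monotone_in_cutoff(self, kin100):
        vals = [f_ion(kin100, d) for d in (0.180, 1.37, 5.56)]
        assert vals[0] < vals[1] < vals[2] <= 1.0
        assert all(0 < v <= 1 for v in vals)

    def test_out_of_range_cutoff_rejected(self, kin100):
        with pytest.raises(ValueError):
            f_ion(kin100, 0.0)
        with pytest.raises(ValueError):
            f_ion(kin100, kin100.emax_keV * 1.001)


class TestVarianceBudget:
    def test_degenerate_straggling_gives_chord_variance_only(self, kin100):
        b = variance_budget(TargetSphere(1000.0), kin100, 0.75, 0.0)
        assert b.V == pytest.approx(0.125, abs=1e-15)

    def test_straggling_identity(self, kin100):
        b = variance_budget(TargetSphere(100.0), kin100, 0.75, 0.21)
        assert b.V_delta * b.eps_bar_keV == pytest.approx(0.21, rel=1e-12)
        assert b.eps_bar_keV == pytest.approx(
            b.f_ion * 0.75 * (2 * 100.0 / 3) * 1e-3, rel=1e-12
        )
        assert b.V == b.V_delta + 0.125

    def test_smaller_sites_have_larger_straggling_variance(self, kin100, delta2_averages):
        budgets = {
            d: variance_budget(
                TargetSphere(d), kin100, 0.75, delta2_averages[delta]
            )
            for d, delta in [(10.0, 0.180), (1000.0, 5.56)]
        }
        assert budgets[10.0].V_delta > budgets[1000.0].V_delta


class TestStragglingDistributions:
    def test_erlang_gamma_moment_identities(self):
        d = make_straggling_distribution("erlang_gamma", 0.4, 1.6)
        p = d.params
        assert p["kappa"] / p["lambda"] == pytest.approx(0.4, rel=1e-12)
        assert p["kappa"] / p["lambda"] ** 2 == pytest.approx(1.6 * 0.4**2, rel=1e-12)

    def test_erlang_integer_shape_matches_factorial_density(self):
        # kappa = 4 (V = 0.25): the printed factorial-form Erlang density
        d = make_straggling_distribution("erlang_gamma", 2.0, 0.25)
        lam = d.params["lambda"]
        x = np.linspace(0.01, 10.0, 200)
        printed = lam**4 / math.factorial(3) * x**3 * np.exp(-lam * x)
        np.testing.assert_allclose(d.pdf(x), printed, rtol=1e-12)

    def test_logistic_scale_identity(self):
        d = make_straggling_distribution("logistic", 0.4, 1.6)
        s = d.params["s"]
        assert math.pi**2 * s**2 / 3.0 == pytest.approx(1.6 * 0.4**2, rel=1e-12)
        assert d.params["mu_log"] == 0.4

    def test_lognormal_moments_by_quadrature(self):
        d = make_straggling_distribution("lognormal", 1.0, 0.5)
        m1, _ = integrate.quad(lambda x: x * d.pdf(x), 0, 50)
        m2, _ = integrate.quad(lambda x: x * x * d.pdf(x), 0, 80)
        assert m1 == pytest.approx(1.0, rel=1e-6)
        assert m2 / m1**2 - 1.0 == pytest.approx(0.5, rel=1e-5)

    def test_truncated_logistic_density_normalized(self):
        d = make_straggling_distribution("logistic", 0.3, 2.0)
        norm, _ = integrate.quad(d.pdf, 0, 0.3 + 60 * d.params["s"])
        assert norm == pytest.approx(1.0, rel=1e-8)
        assert d.pdf(np.array([-0.1]))[0] == 0.0
        # truncation raises the mean above the untruncated target
        assert d.moment(1) > 0.3

    def test_invalid_parameters_rejected(self):
        for bad in [("lognormal", -1.0, 0.5), ("erlang_gamma", 1.0, 0.0),
                    ("logistic", 1.0, float("nan"))]:
            with pytest.raises(ValueError):
                make_straggling_distribution(*bad)
        with pytest.raises(ValueError):
            make_straggling_distribution("weibull", 1.0, 0.5)
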