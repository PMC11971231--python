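"""Lineal-energy spectra: direct, indirect and total dose-mean values."""

import numpy as np
import pytest
from scipy import integrate

from microyd import born, core, lineal
from microyd.core import TargetSphere
from microyd.lineal import (
    ElectronYdTable,
    direct_yd,
    indirect_yd,
    synth_electron_table,
    total_yd,
    yd_curve,
    yd_point,
)

LET = 0.75  # keV/um, fixed representative unrestricted LET for unit tests
D2 = 0.60   # keV, representative straggling factor for the 1000 nm site


@pytest.fixture(scope="module")
def sphere():
    return TargetSphere(1000.0)


def closed_form_yd_dir(sphere, kin, let, d2):
    fi = core.f_ion(kin, sphere.delta_keV)
    return fi * let * 1.125 + d2 / sphere.lbar_um


class TestDirect:
    @pytest.mark.parametrize("family", ["lognormal", "erlang_gamma"])
    @pytest.mark.parametrize("mode", ["single", "chord_convolved"])
    def test_untruncated_families_match_closed_form(self, sphere, kin100, family, mode):
        _, yd = direct_yd(sphere, kin100, LET, family, D2, mode=mode)
        assert yd == pytest.approx(closed_form_yd_dir(sphere, kin100, LET, D2), rel=1e-9)

    def test_lognormal_and_gamma_practically_identical(self, sphere, kin100):
        _, a = direct_yd(sphere, kin100, LET, "lognormal", D2)
        _, b = direct_yd(sphere, kin100, LET, "erlang_gamma", D2)
        assert a == pytest.approx(b, rel=1e-3)

    def test_frequency_mean_is_restricted_let(self, sphere, kin100):
        spec, _ = direct_yd(sphere, kin100, LET, "erlang_gamma", D2)
        fi = core.f_ion(kin100, sphere.delta_keV)
        assert spec.y_F == pytest.approx(fi * LET, rel=1e-9)

    def test_spectrum_moments_match_quadrature_oracle(self, sphere, kin100):
        # independent check: integrate the reported density directly
        for family in ("lognormal", "erlang_gamma", "logistic"):
            spec, yd = direct_yd(sphere, kin100, LET, family, D2)
            lg = np.log(spec.y)
            m1 = np.trapezoid(spec.y * spec.f * spec.y, lg)
            m2 = np.trapezoid(spec.y**2 * spec.f * spec.y, lg)
            assert m1 == pytest.approx(spec.y_F, rel=5e-3)
            assert m2 / m1 == pytest.approx(spec.y_D, rel=5e-3)
            assert spec.y_F <= spec.y_D

    def test_mode_equivalence_within_half_percent(self, sphere, kin100):
        for family in ("lognormal", "erlang_gamma"):
            _, a = direct_yd(sphere, kin100, LET, family, D2, mode="single")
            _, b = direct_yd(sphere, kin100, LET, family, D2, mode="chord_convolved")
            assert a == pytest.approx(b, rel=5e-3)

    def test_truncated_logistic_departs_from_closed_form(self, sphere, kin100):
        _, yd = direct_yd(sphere, kin100, LET, "logistic", D2)
        closed = closed_form_yd_dir(sphere, kin100, LET, D2)
        assert yd < closed * 0.95  # truncation suppresses the dose-mean

    def test_increasing_straggling_increases_dose_mean(self, sphere, kin100):
        yds = [direct_yd(sphere, kin100, LET, "erlang_gamma", d2)[1]
               for d2 in (0.3, 0.6, 0.9)]
        assert yds[0] < yds[1] < yds[2]


class TestElectronTable:
    def test_round_trip_bit_identical(self, tmp_path):
        t = synth_electron_table(11)
        path = tmp_path / "t.csv"
        t.to_csv(path)
        back = ElectronYdTable.from_csv(path)
        np.testing.assert_array_equal(back.values, t.values)
        np.testing.assert_array_equal(back.energies_keV, t.energies_keV)
        assert back.source == t.source

    def test_interpolation_exact_at_nodes(self):
        t = synth_electron_table(11)
        i, j = 7, 1
        got = t.interp(t.energies_keV[i], t.diameters_nm[j])
        assert got == pytest.approx(t.values[i, j], rel=1e-12)

    def test_seed_determinism(self):
        a = synth_electron_table(5)
        b = synth_electron_table(5)
        c = synth_electron_table(6)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_malformed_inputs_raise_distinct_errors(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("electron_energy_keV,diameter_nm,yD_keV_per_um\n1,10,not_a_number\n")
        with pytest.raises(ValueError, match="malformed"):
            ElectronYdTable.from_csv(p)
        with pytest.raises(ValueError, match="increasing"):
            ElectronYdTable(np.array([1.0, 1.0]), np.array([10.0]),
                            np.ones((2, 1)))
        with pytest.raises(ValueError, match="positive"):
            ElectronYdTable(np.array([1.0, 2.0]), np.array([10.0]),
                            np.array([[1.0], [-2.0]]))


class TestIndirect:
    def test_constant_table_returns_constant(self, model, sphere, kin100):
        e = np.geomspace(1.0, 500.0, 30)
        table = ElectronYdTable(e, np.array([1000.0]), np.full((30, 1), 3.7))
        got = indirect_yd(model, kin100, sphere, table)
        assert got == pytest.approx(3.7, rel=1e-9)

    def test_linear_table_matches_quadrature_oracle(self, model, sphere, kin100):
        alpha = 0.01
        e = np.geomspace(1.0, 500.0, 200)
        table = ElectronYdTable(e, np.array([1000.0]), (alpha * e)[:, None])

        def w(le):
            ev = np.exp(le)
            return born.dics(model, kin100, np.array([ev]), n_q=192).total[0] * ev

        lo, hi = np.log(sphere.delta_keV * 1e3), np.log(kin100.emax_eV)
        num, _ = integrate.quad(lambda le: alpha * np.exp(le) * 1e-3 * w(le),
                                lo, hi, limit=200)
        den, _ = integrate.quad(w, lo, hi, limit=200)
        got = indirect_yd(model, kin100, sphere, table)
        assert got == pytest.approx(num / den, rel=5e-3)

    def test_result_inside_table_range(self, model, sphere, kin100):
        table = synth_electron_table(3)
        got = indirect_yd(model, kin100, sphere, table)
        e_grid = np.geomspace(sphere.delta_keV, kin100.emax_keV, 200)
        vals = table.interp(e_grid, sphere.d_nm)
        assert vals.min() < got < vals.max()

    def test_empty_range_is_an_error_not_zero(self, model):
        kin = born.proton_kinematics(2.0)  # E_max = 4.36 keV < Delta
        with pytest.raises(ValueError, match="empty indirect range"):
            indirect_yd(model, kin, TargetSphere(1000.0), synth_electron_table(1))

    def test_coverage_gap_rejected(self, model, sphere, kin100):
        e = np.geomspace(10.0, 50.0, 10)  # misses [Delta, E_max]
        table = ElectronYdTable(e, np.array([1000.0]), np.ones((10, 1)))
        with pytest.raises(ValueError, match="covers"):
            indirect_yd(model, kin100, sphere, table)


class TestTotal:
    def test_pure_direct_when_fion_is_one(self, sphere):
        b = total_yd(5.0, sphere, "logistic", 1.0, 4.2, 0.0)
        assert b.total == 4.2

    def test_total_is_convex_combination(self, sphere):
        b = total_yd(100.0, sphere, "logistic", 0.7, 4.0, 2.0)
        assert min(4.0, 2.0) <= b.total <= max(4.0, 2.0)
        assert b.total == pytest.approx(0.7 * 4.0 + 0.3 * 2.0, rel=1e-12)

    def test_invalid_weight_rejected(self, sphere):
        with pytest.raises(ValueError):
            total_yd(100.0, sphere, "logistic", 1.5, 4.0, 2.0)

    def test_curve_monotone_decreasing_for_micron_site(self, model, sphere):
        # qualitative shape: y_D falls with proton energy at d = 1000 nm
        table = synth_electron_table(9)
        df = yd_curve(model, [2.0, 10.0, 50.0, 200.0, 1000.0], sphere,
                      "logistic", table=table)
        y = df["yD_total"].to_numpy()
        assert np.all(np.diff(y) < 0)
        assert list(df["energy_MeV"]) == sorted(df["energy_MeV"])

    def test_breakdown_identity(self, model, sphere, kin100):
        table = synth_electron_table(4)
        b = yd_point(model, 100.0, sphere, "erlang_gamma", table=table)
        assert b.total == pytest.approx(
            b.f_ion * b.yd_dir + (1 - b.f_ion) * b.yd_ind, rel=1e-12
        )
        assert 0 < b.f_ion <= 1
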