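"""Mason-Schamp conversions, stepped-field and single-field CCS calibration."""

import math

import numpy as np
import pytest

from marado.ccs import (
    DriftGasState,
    N2_MASS,
    ReferenceIon,
    SingleFieldCalibration,
    SteppedFieldSeries,
    arrival_time_to_ccs,
    ccs_deviation,
    ccs_to_arrival_time,
    ccs_to_k0,
    mason_schamp_ccs,
    reduced_mass,
    single_field_calibrate,
    stepped_field_fit,
)

GAS = DriftGasState()  # N2, 305 K, 3.95 Torr


class TestReducedMass:
    def test_equal_masses_halve(self):
        assert reduced_mass(N2_MASS, N2_MASS) == pytest.approx(N2_MASS / 2, abs=1e-9)

    def test_heavy_ion_limit_is_gas_mass(self):
        assert reduced_mass(1e9, N2_MASS) == pytest.approx(N2_MASS, rel=1e-7)

    def test_lipid_adduct_value(self):
        # 780.5468 * 28.006148 / (780.5468 + 28.006148) evaluated directly
        assert reduced_mass(780.5468, N2_MASS) == pytest.approx(27.03609, abs=1e-4)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            reduced_mass(-1.0, N2_MASS)


class TestMasonSchamp:
    def test_against_hand_evaluated_oracle(self):
        """Independent literal evaluation of the Mason-Schamp equation.

        Omega = (3 z e / 16 N0) * sqrt(2 pi / (mu kB T)) / K0 for
        K0 = 0.55 cm^2/(V s), m = 922.009799 Da, T = 305 K, N2 gas.
        """
        mu_kg = (922.009799 * 28.006148 / (922.009799 + 28.006148)) * 1.66053906660e-27
        omega_m2 = (
            3 * 1.602176634e-19 / (16 * 2.6867811e25)
            * math.sqrt(2 * math.pi / (mu_kg * 1.380649e-23 * 305.0))
            / 0.55e-4
        )
        expected = omega_m2 * 1e20  # 369.625143... A^2
        assert mason_schamp_ccs(0.55, 922.009799, 1, GAS) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(369.6251431, abs=1e-6)

    def test_roundtrip_exact(self):
        for ccs in (150.0, 243.64, 307.67):
            k0 = ccs_to_k0(ccs, 900.0, 1, GAS)
            assert mason_schamp_ccs(k0, 900.0, 1, GAS) == pytest.approx(ccs, rel=1e-12)

    def test_ccs_decreases_with_k0(self):
        k0s = np.linspace(0.4, 1.2, 9)
        ccs = [mason_schamp_ccs(k, 900.0, 1, GAS) for k in k0s]
        assert all(a > b for a, b in zip(ccs, ccs[1:]))

    def test_non_positive_k0_rejected(self):
        with pytest.raises(ValueError):
            mason_schamp_ccs(0.0, 900.0)


def synth_series(k0, voltages, t_fix_ms=0.2, gas=GAS, L=0.7803, noise=None, rng=None):
    """Forward model: t_d = L^2/(K V) + t_fix with K denormalized from K0."""
    k = k0 * 1e-4 * (760.0 / gas.pressure) * (gas.temperature / 273.15)  # m^2/Vs
    t = np.array([L * L / (k * v) * 1e3 + t_fix_ms for v in voltages])
    if noise:
        t = t * (1 + rng.normal(0, noise, t.size))
    return SteppedFieldSeries(tuple(voltages), tuple(t), L, gas)


class TestSteppedField:
    def test_noise_free_recovery_exact(self):
        series = synth_series(0.55, [700, 850, 1000, 1150, 1300, 1450, 1600])
        result = stepped_field_fit(series, 922.009799, 1)
        assert result.k0 == pytest.approx(0.55, rel=1e-9)
        assert result.t_fix_ms == pytest.approx(0.2, abs=1e-9)
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)
        assert result.ccs == pytest.approx(
            mason_schamp_ccs(0.55, 922.009799, 1, GAS), rel=1e-9
        )

    def test_recovery_under_timing_noise(self):
        rng = np.random.default_rng(42)
        series = synth_series(
            0.55, [700, 850, 1000, 1150, 1300, 1450, 1600], noise=0.001, rng=rng
        )
        result = stepped_field_fit(series, 922.009799, 1)
        assert result.k0 == pytest.approx(0.55, rel=0.005)

    def test_too_few_voltages_rejected(self):
        with pytest.raises(ValueError):
            SteppedFieldSeries((800.0, 1600.0), (20.0, 10.0))
        with pytest.raises(ValueError):  # duplicated voltages are not distinct steps
            SteppedFieldSeries((800.0, 800.0, 800.0), (20.0, 20.0, 20.0))


class TestSingleField:
    def make_calib(self, beta=0.02, t_fix=0.5):
        return SingleFieldCalibration(beta=beta, t_fix_ms=t_fix, gas=GAS)

    def test_two_point_exact_recovery(self):
        truth = self.make_calib()
        refs = [
            ReferenceIon(mz, z, ccs, ccs_to_arrival_time(ccs, truth, mz, z))
            for mz, z, ccs in [(922.009799, 1, 243.64), (1033.987012, -1, 255.34)]
        ]
        fitted = single_field_calibrate(refs, GAS)
        assert fitted.beta == pytest.approx(truth.beta, rel=1e-9)
        assert fitted.t_fix_ms == pytest.approx(truth.t_fix_ms, abs=1e-9)
        assert max(abs(r) for r in fitted.residuals_ms) < 1e-9

    def test_single_reference_rejected(self):
        with pytest.raises(ValueError):
            single_field_calibrate([ReferenceIon(922.0, 1, 243.64, 30.0)])

    def test_degenerate_references_rejected(self):
        refs = [ReferenceIon(922.0, 1, 243.64, 30.0)] * 2
        with pytest.raises(ValueError):
            single_field_calibrate(refs, GAS)

    def test_arrival_time_roundtrip_at_reference_ccs(self):
        """A lipid standard CCS survives the arrival-time roundtrip exactly."""
        calib = self.make_calib()
        t = ccs_to_arrival_time(290.60, calib, 808.5780, 1)
        assert arrival_time_to_ccs(t, calib, 808.5780, 1) == pytest.approx(
            290.60, rel=1e-12
        )

    def test_ccs_monotone_in_arrival_time(self):
        calib = self.make_calib()
        times = np.linspace(20.0, 40.0, 11)
        ccs = [arrival_time_to_ccs(t, calib, 900.0, 1) for t in times]
        assert all(a < b for a, b in zip(ccs, ccs[1:]))

    def test_arrival_before_dead_time_rejected(self):
        calib = self.make_calib()
        with pytest.raises(ValueError):
            arrival_time_to_ccs(calib.t_fix_ms, calib, 900.0, 1)

    def test_save_load_roundtrip(self, tmp_path):
        calib = self.make_calib()
        path = tmp_path / "calib.json"
        calib.to_file(path)
        loaded = SingleFieldCalibration.from_file(path)
        assert loaded.beta == calib.beta
        assert loaded.t_fix_ms == calib.t_fix_ms
        assert loaded.gas.temperature == calib.gas.temperature


class TestCcsDeviation:
    @pytest.mark.parametrize(
        "stepped, single, expected",
        [(284.65, 284.40, -0.09), (304.00, 303.13, -0.29), (290.0, 290.0, 0.0)],
    )
    def test_reference_deviations(self, stepped, single, expected):
        assert ccs_deviation(stepped, single) == pytest.approx(expected, abs=0.005)
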