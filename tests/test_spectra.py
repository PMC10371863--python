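"""Spectral synthesis: stick strengths, broadening, convolution, calibration, dOD."""

import numpy as np
import pytest

from txas.constants import FINE_STRUCTURE, HARTREE_EV
from txas.io import TransientMap, TransitionRecord
from txas.spectra import (
    CalibrationConstants,
    LineShapeParams,
    apply_calibration,
    broaden,
    convolve_time,
    correct_reference_ip,
    default_grid,
    delta_od,
    derive_downshift,
    ensemble_map,
    estimate_valence_ip,
    gas_phase_lowering,
    stick_strength,
)


def make_record(w_au=0.4, d=(0.0, 0.0, 0.1), time=0.0, traj="t0"):
    return TransitionRecord(
        time=time, eps_core=-11.0, eps_vac=-11.0 + w_au, dipole=np.array(d), traj_id=traj
    )


class TestStickStrength:
    def test_dark_transition(self):
        energy, s = stick_strength(make_record(d=(0, 0, 0)))
        assert s == 0.0
        assert energy == pytest.approx(0.4 * HARTREE_EV)

    def test_arithmetic_oracle(self):
        # independent arithmetic: (4/3) pi^2 * 10 * alpha * 0.01
        rec = TransitionRecord(time=0, eps_core=-11, eps_vac=-1, dipole=[0, 0, 0.1])
        _, s = stick_strength(rec)
        assert s == pytest.approx(9.603e-3, rel=1e-4)
        assert s == pytest.approx((4 / 3) * np.pi**2 * 10 * FINE_STRUCTURE * 0.01, rel=1e-12)

    def test_dipole_homogeneity(self):
        _, s1 = stick_strength(make_record(d=(0.01, 0.02, 0.03)))
        _, s2 = stick_strength(make_record(d=(0.02, 0.04, 0.06)))
        assert s2 == pytest.approx(4 * s1, rel=1e-12)

    def test_unphysical_ordering(self):
        rec = make_record()
        rec.eps_vac = rec.eps_core  # bypass constructor check
        with pytest.raises(ValueError):
            stick_strength(rec)


class TestBroaden:
    def test_peak_of_unit_area_lorentzian(self):
        grid = default_grid(285, 292, 0.001)
        spec = broaden([(288.0, 2.0)], grid, LineShapeParams(lorentz_width=0.5))
        i = np.argmin(np.abs(grid - 288.0))
        assert spec.sigma[i] == pytest.approx(2.0 * 2 / (np.pi * 0.5), rel=1e-9)

    def test_integral_recovers_strength(self):
        # +-50 Gamma window captures all but ~1.3% of a Lorentzian
        gamma = 0.5
        grid = np.arange(288 - 50 * gamma, 288 + 50 * gamma, 0.005)
        spec = broaden([(288.0, 3.0)], grid, LineShapeParams(lorentz_width=gamma))
        assert np.trapezoid(spec.sigma, grid) == pytest.approx(3.0, rel=0.02)

    def test_linearity_identical_sticks(self):
        grid = default_grid(285, 292, 0.02)
        one = broaden([(288.0, 1.5)], grid)
        two = broaden([(288.0, 1.5)] * 2, grid)
        np.testing.assert_allclose(two.sigma, 2 * one.sigma, rtol=1e-12)

    def test_empty_sticks_zero_spectrum(self):
        grid = default_grid()
        assert not np.any(broaden([], grid).sigma)

    @pytest.mark.parametrize("seed", range(3))
    def test_direct_summation_oracle(self, seed):
        # independent dense-loop evaluation of Eq-style sticks + Lorentzians
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 6)
        sticks = [(float(rng.uniform(286, 290)), float(rng.uniform(0.1, 2))) for _ in range(n)]
        grid = np.linspace(284, 292, 81)
        gamma = 0.5
        expected = np.zeros_like(grid)
        for j, w in enumerate(grid):
            for e0, s in sticks:
                expected[j] += s * (gamma / 2 / np.pi) / ((w - e0) ** 2 + (gamma / 2) ** 2)
        got = broaden(sticks, grid, LineShapeParams(lorentz_width=gamma)).sigma
        np.testing.assert_allclose(got, expected, rtol=1e-10)


class TestEnsembleMap:
    def _traj(self, traj_id, scale=1.0):
        return [make_record(w_au=0.4, d=(0, 0, 0.1 * scale), time=t, traj=traj_id)
                for t in (0.0, 0.5, 1.0)]

    def test_identical_trajectories_equal_single(self):
        grid = default_grid(285, 292, 0.05)
        single = ensemble_map(self._traj("a"), grid)
        triple = ensemble_map(self._traj("a") + self._traj("b") + self._traj("c"), grid)
        np.testing.assert_allclose(triple.values, single.values, rtol=1e-12)

    def test_dark_trajectory_halves_map(self):
        grid = default_grid(285, 292, 0.05)
        bright = ensemble_map(self._traj("a"), grid)
        mixed = ensemble_map(self._traj("a") + self._traj("dark", scale=0.0), grid)
        np.testing.assert_allclose(mixed.values, 0.5 * bright.values, rtol=1e-12)

    def test_ragged_time_grids_rejected(self):
        grid = default_grid(285, 292, 0.1)
        ragged = self._traj("a") + self._traj("b")[:-1]
        with pytest.raises(ValueError, match="resample"):
            ensemble_map(ragged, grid)

    def test_pt_ensemble_band_growth_monotone(self):
        from txas.synthetic import EnsembleConfig, generate_ensemble

        cfg = EnsembleConfig(n_traj=10, pt_fraction=1.0, noise_sd=0.0, vib_amp=0.0,
                             jitter_window=0.0, t_end=500.0, dt=10.0, seed=3)
        ens = generate_ensemble(cfg)
        grid = default_grid(285, 289, 0.05)
        m = ensemble_map(ens.records, grid)
        band_integral = m.values.sum(axis=1)
        assert np.all(np.diff(band_integral) >= -1e-12)


class TestConvolveTime:
    def _map(self, values, dt=1.0):
        values = np.atleast_2d(values).T  # one energy column
        delays = np.arange(values.shape[0]) * dt
        return TransientMap(delays, [287.0], values)

    def test_dc_invariance(self):
        m = self._map(np.full(100, 3.3))
        out = convolve_time(m, 10.0)
        np.testing.assert_allclose(out.values, m.values, rtol=1e-12)

    def test_impulse_response_fwhm(self):
        vals = np.zeros(401)
        vals[200] = 1.0
        m = self._map(vals, dt=0.25)
        out = convolve_time(m, 10.0)
        y = out.values[:, 0]
        t = out.delays
        half = y.max() / 2
        above = np.nonzero(y >= half)[0]
        # interpolate the half crossings
        lo = np.interp(half, y[above[0] - 1:above[0] + 1], t[above[0] - 1:above[0] + 1])
        hi = np.interp(half, y[above[-1] + 1:above[-1] - 1:-1], t[above[-1] + 1:above[-1] - 1:-1])
        assert hi - lo == pytest.approx(10.0, abs=0.3)

    def test_area_conservation_interior(self):
        rng = np.random.default_rng(0)
        vals = np.zeros(200)
        vals[80:120] = rng.uniform(0, 1, 40)
        m = self._map(vals)
        out = convolve_time(m, 10.0)
        assert out.values.sum() == pytest.approx(m.values.sum(), rel=1e-3)

    def test_non_uniform_grid_rejected(self):
        m = TransientMap([0.0, 1.0, 3.0], [287.0], [[1.0], [2.0], [3.0]])
        with pytest.raises(ValueError, match="uniform"):
            convolve_time(m, 10.0)


class TestCalibration:
    def test_downshift_paper_values(self):
        assert derive_downshift(310.21, 294.51) == pytest.approx(15.70, abs=1e-9)
        assert derive_downshift(295.0, 294.51) == pytest.approx(0.49)
        assert derive_downshift(300.0, 300.0) == 0.0

    def test_reference_ip_correction(self):
        assert correct_reference_ip(294.0, 11.16, 11.67) == pytest.approx(294.51)
        assert correct_reference_ip(294.0, 11.16, 11.16) == 294.0
        assert correct_reference_ip(294.0, 11.16, 11.41) == pytest.approx(294.25)

    def test_valence_ip_and_solvation_lowering(self):
        vip = estimate_valence_ip(294.51, 287.6)
        assert vip == pytest.approx(6.91)
        assert f"{vip:.1f}" == "6.9"
        low = gas_phase_lowering(10.28, vip)
        assert low == pytest.approx(3.37)
        assert f"{low:.1f}" == "3.4"
        with pytest.raises(ValueError):
            estimate_valence_ip(287.6, 287.6)
        with pytest.raises(ValueError):
            gas_phase_lowering(6.91, 10.28)

    def test_apply_calibration_net_shift_and_involution(self):
        m = TransientMap([0.0], np.array([300.0, 301.0]), [[1.0, 2.0]])
        cal = CalibrationConstants(downshift=15.7, upshift=3.2)
        out = apply_calibration(m, cal)
        np.testing.assert_allclose(out.energies, m.energies - 12.5)
        np.testing.assert_array_equal(out.values, m.values)
        back = apply_calibration(out, CalibrationConstants(downshift=-15.7, upshift=-3.2))
        np.testing.assert_allclose(back.energies, m.energies)
        ident = apply_calibration(m, CalibrationConstants(downshift=0.0, upshift=0.0))
        np.testing.assert_array_equal(ident.energies, m.energies)

    def test_inconsistent_components_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CalibrationConstants(downshift=10.0, calc_core_binding=310.21, exp_core_ip=294.51)
        cal = CalibrationConstants(downshift=15.7, calc_core_binding=310.21, exp_core_ip=294.51)
        assert cal.net_shift == pytest.approx(-12.5)

    def test_calibration_commutes_with_broadening(self):
        sticks = [(288.0, 1.0), (289.5, 0.5)]
        grid = default_grid(280, 300, 0.02)
        cal = CalibrationConstants(downshift=15.7, upshift=3.2)
        spec_then_shift = broaden(sticks, grid).sigma  # on grid, axis shifted after
        shifted_axis = grid + cal.net_shift
        shifted_sticks = [(e + cal.net_shift, s) for e, s in sticks]
        shift_then_spec = broaden(shifted_sticks, shifted_axis).sigma
        np.testing.assert_allclose(spec_then_shift, shift_then_spec, rtol=1e-10)


class TestDeltaOD:
    def _maps(self, pump, unpump):
        d, e = [0.0], np.arange(len(pump)) + 285.0
        return (TransientMap(d, e, np.atleast_2d(pump)),
                TransientMap(d, e, np.atleast_2d(unpump)))

    def test_identity_gives_zero(self):
        p, u = self._maps([1.0, 2.0], [1.0, 2.0])
        assert not np.any(delta_od(p, u).values)

    def test_decade_definition(self):
        p, u = self._maps([0.1, 1.0], [1.0, 1.0])
        out = delta_od(p, u)
        assert out.values[0, 0] == pytest.approx(1.0)
        assert out.values[0, 1] == 0.0
        assert out.kind == "dod"

    def test_excited_fraction_scales(self):
        p, u = self._maps([0.1, 1.0], [1.0, 1.0])
        out = delta_od(p, u, excited_fraction=0.2)
        assert out.values[0, 0] == pytest.approx(0.2)

    def test_nonpositive_intensity_rejected(self):
        p, u = self._maps([0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="positive"):
            delta_od(p, u)

    def test_bleach_sign_pattern_two_species(self):
        # pump converts a 290 eV absorber into one absorbing at 287 eV:
        # dOD must be negative at the neutral line and positive below it
        grid = default_grid(284, 294, 0.02)
        neutral = broaden([(290.0, 1.0)], grid).sigma
        cation = broaden([(287.0, 0.6)], grid).sigma
        scale = 0.5  # optical depth scale
        i_unpump = np.exp(-scale * neutral)
        i_pump = np.exp(-scale * (0.7 * neutral + 0.3 * cation))
        p = TransientMap([0.0], grid, i_pump[None, :])
        u = TransientMap([0.0], grid, i_unpump[None, :])
        dod = delta_od(p, u).values[0]
        assert dod[np.argmin(np.abs(grid - 290.0))] < 0
        assert dod[np.argmin(np.abs(grid - 287.0))] > 0


class TestChainLinearity:
    def test_synthesis_linear_in_stick_strength(self):
        grid = default_grid(285, 292, 0.05)
        recs = [make_record(d=(0, 0, 0.1), time=t) for t in (0.0, 0.5, 1.0, 1.5)]
        recs2 = [make_record(d=(0, 0, 0.1 * np.sqrt(3)), time=t) for t in (0.0, 0.5, 1.0, 1.5)]
        m1 = convolve_time(ensemble_map(recs, grid), 1.0)
        m3 = convolve_time(ensemble_map(recs2, grid), 1.0)
        np.testing.assert_allclose(m3.values, 3 * m1.values, rtol=1e-10)
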