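"""Circuit model: Cole load, nodal analysis, envelope detection, sweeps."""

import numpy as np
import pytest

from phytosense.circuit import (OPEN_CIRCUIT, CircuitComponents,
                                ColeLoadParameters, SweepConfig,
                                envelope_cutoff, network_response,
                                plant_impedance, sweep_response)


def brute_force_gain(freq, comps, z_plant, node="B"):
    """Independent oracle: assemble and solve the full 2-node admittance
    matrix with a dense linear solver."""
    w = 2 * np.pi * freq
    ys = 1 / comps.r_series
    yt = 1 / (1j * w * comps.l_tank) + 1j * w * comps.c_tank + 1 / comps.r_damp
    yc = 1j * w * comps.c_couple
    yp = 0 if z_plant == OPEN_CIRCUIT else 1 / z_plant
    Y = np.array([[ys + yt + yc, -yc], [-yc, yc + yp]])
    v = np.linalg.solve(Y, np.array([ys, 0.0]))
    return v[0] if node == "A" else v[1]


class TestColeLoad:
    def test_dc_limit_is_r0(self):
        p = ColeLoadParameters(1e6, 1e4, 1e-5, 0.8)
        assert plant_impedance(p, 0.0) == pytest.approx(1e6 + 0j)

    def test_high_frequency_limit_is_r_inf(self):
        p = ColeLoadParameters(1e6, 1e4, 1e-5, 0.8)
        assert abs(plant_impedance(p, 1e15)) == pytest.approx(1e4, rel=1e-3)

    def test_debye_point_matches_hand_computation(self):
        # alpha = 1 at f = 1/(2πτ): Z = r_inf + (r0 − r_inf)/(1 + j)
        p = ColeLoadParameters(1e6, 1e4, 1e-5, 1.0)
        expected = 1e4 + (1e6 - 1e4) / (1 + 1j)
        assert plant_impedance(p, 1 / (2 * np.pi * p.tau)) == pytest.approx(
            expected, rel=1e-12)

    def test_capacitive_phase_for_alpha_below_one(self):
        p = ColeLoadParameters(1e6, 1e4, 1e-5, 0.7)
        z = plant_impedance(p, np.logspace(1, 7, 50))
        assert np.all(z.imag <= 1e-9)
        assert np.all(np.isfinite(z))

    @pytest.mark.parametrize("bad", [
        dict(r0=1e4, r_inf=1e6, tau=1e-5, alpha=0.8),   # r0 < r_inf
        dict(r0=1e6, r_inf=1e4, tau=-1.0, alpha=0.8),   # tau <= 0
        dict(r0=1e6, r_inf=1e4, tau=1e-5, alpha=1.5),   # alpha > 1
        dict(r0=1e6, r_inf=1e4, tau=1e-5, alpha=0.0),   # alpha = 0
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ColeLoadParameters(**bad)


class TestNetworkResponse:
    def test_matches_admittance_matrix_oracle(self, comps):
        rng = np.random.default_rng(42)
        for _ in range(100):
            c = CircuitComponents(
                r_series=rng.uniform(1e3, 50e3),
                l_tank=rng.uniform(1e-3, 100e-3),
                c_tank=rng.uniform(0.1e-9, 10e-9),
                r_damp=rng.uniform(1e3, 20e3),
                c_couple=rng.uniform(1e-9, 100e-9))
            z = rng.uniform(1e3, 1e6) - 1j * rng.uniform(0, 1e5)
            f = rng.uniform(1e3, 1e6)
            node = rng.choice(["A", "B"])
            got = network_response(f, c, z, node=node)
            want = brute_force_gain(f, c, z, node=node)
            assert abs(got - want) <= 1e-9 * abs(want)

    def test_dc_gain_across_plant_is_zero(self, comps):
        assert network_response(0.0, comps, 1e5 + 0j) == 0

    def test_open_circuit_resonance_reduces_to_resistive_divider(self, comps):
        f0 = comps.tank_resonance_hz
        gain = network_response(f0, comps, OPEN_CIRCUIT, node="A")
        assert abs(gain) == pytest.approx(4.7e3 / (10e3 + 4.7e3), rel=1e-9)

    def test_continuity_in_frequency(self, comps, mid_load):
        f = np.linspace(20e3, 250e3, 2000)
        g = np.abs(network_response(f, comps, plant_impedance(mid_load, f)))
        assert np.all(np.abs(np.diff(g)) < 0.01)

    def test_negative_frequency_rejected(self, comps):
        with pytest.raises(ValueError):
            network_response(-1.0, comps, 1e5 + 0j)


class TestEnvelopeCutoff:
    def test_defaults_give_1p6_khz(self):
        assert envelope_cutoff(1e6, 100e-12) == pytest.approx(1591.55, abs=0.01)

    def test_closed_form(self):
        assert envelope_cutoff(1e6, 1e-9) == pytest.approx(159.155, abs=1e-3)

    def test_inverse_proportionality_in_c(self):
        assert envelope_cutoff(1e6, 50e-12) == pytest.approx(
            2 * envelope_cutoff(1e6, 100e-12), rel=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            envelope_cutoff(0.0, 1e-9)


class TestSweepResponse:
    def test_default_grid_has_230_points(self, comps, mid_load):
        assert SweepConfig().n_points == 230
        sweep = sweep_response(SweepConfig(), comps, mid_load)
        assert sweep.shape == (230,)
        assert np.all(sweep >= 0)

    def test_noiseless_sweep_is_deterministic(self, comps, mid_load):
        cfg = SweepConfig()
        a = sweep_response(cfg, comps, mid_load, noise_sd=0.0)
        b = sweep_response(cfg, comps, mid_load, noise_sd=0.0)
        np.testing.assert_array_equal(a, b)

    def test_fundamental_only_composes_network_response(self, comps, mid_load):
        cfg = SweepConfig()
        sweep = sweep_response(cfg, comps, mid_load, excitation="fundamental")
        f = cfg.frequencies
        expected = (4 / np.pi) * np.abs(
            network_response(f, comps, plant_impedance(mid_load, f)))
        np.testing.assert_allclose(sweep, expected, rtol=1e-12)

    def test_bandpass_shape_unimodal_after_smoothing(self, comps, mid_load):
        # fundamental-only: the loaded tank resonance sits inside the grid
        sweep = sweep_response(SweepConfig(), comps, mid_load,
                               excitation="fundamental")
        s = np.convolve(sweep, np.ones(3) / 3, mode="valid")
        d = np.sign(np.diff(s))
        changes = np.sum(np.diff(d[d != 0]) != 0)
        assert changes <= 1  # rises to one maximum, then decays
        assert 0 < np.argmax(s) < len(s) - 1

    def test_square_excitation_sweep_unimodal(self, comps, mid_load):
        sweep = sweep_response(SweepConfig(), comps, mid_load)
        s = np.convolve(sweep, np.ones(3) / 3, mode="valid")
        d = np.sign(np.diff(s))
        assert np.sum(np.diff(d[d != 0]) != 0) <= 1

    def test_load_sensitivity(self, comps, mid_load):
        cfg = SweepConfig()
        base = sweep_response(cfg, comps, mid_load)
        pert = sweep_response(cfg, comps, mid_load.scaled(r0=1.1))
        assert np.max(np.abs(base - pert)) > 0

    def test_noise_seeded(self, comps, mid_load):
        cfg = SweepConfig()
        a = sweep_response(cfg, comps, mid_load, noise_sd=0.05,
                           rng=np.random.default_rng(3))
        b = sweep_response(cfg, comps, mid_load, noise_sd=0.05,
                           rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)
        assert np.any(a != sweep_response(cfg, comps, mid_load))
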