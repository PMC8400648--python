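"""Synthetic-data generators: determinism, statistical laws, toy-engine
conservation properties."""

import numpy as np
import pytest

from glassmd.dynamics import compute_msd, fit_diffusivity, unwrap
from glassmd.synthetic_data import (ScanTruth, ToySystemParams, UnitSystem,
                                    _LJEngine, generate_brownian_trajectory,
                                    generate_caged_trajectory,
                                    generate_thermal_scan,
                                    read_scan_with_truth,
                                    run_thermal_protocol,
                                    simulate_lj_glassformer,
                                    write_scan_with_truth)


class TestBrownian:
    def test_frozen_limit(self):
        traj = generate_brownian_trajectory(5, true_D=0.0, dt=1.0,
                                            n_frames=10, box=20.0, seed=1)
        pos = traj.positions_array()
        for i in range(1, len(traj)):
            np.testing.assert_array_equal(pos[i], pos[0])

    def test_seed_determinism(self):
        a = generate_brownian_trajectory(10, 0.3, 1.0, 50, 30.0, seed=9)
        b = generate_brownian_trajectory(10, 0.3, 1.0, 50, 30.0, seed=9)
        np.testing.assert_array_equal(a.positions_array(),
                                      b.positions_array())
        c = generate_brownian_trajectory(10, 0.3, 1.0, 50, 30.0, seed=10)
        assert not np.array_equal(a.positions_array(),
                                  c.positions_array())

    def test_increment_variance_matches_2Ddt(self):
        """>= 1e5 increments: empirical variance within 3 standard errors
        of 2 D dt per axis."""
        true_D, dt = 0.4, 2.0
        traj = generate_brownian_trajectory(500, true_D, dt, 201, 1000.0,
                                            seed=12)
        inc = np.diff(traj.ground_truth["unwrapped"], axis=0)
        var = inc.var()
        n = inc.size
        se = var * np.sqrt(2.0 / n)
        assert abs(var - 2 * true_D * dt) < 3 * se

    def test_ensemble_msd_recovers_D(self):
        true_D = 0.5
        traj = generate_brownian_trajectory(1000, true_D, 1.0, 500,
                                            2000.0, seed=3)
        msd = compute_msd(unwrap(traj))
        res = fit_diffusivity(msd)
        assert res.D == pytest.approx(true_D, rel=0.05)

    def test_negative_D_rejected(self):
        with pytest.raises(ValueError):
            generate_brownian_trajectory(5, -0.1, 1.0, 10, 20.0, seed=0)


class TestCaged:
    def test_plateau_matches_stationary_value(self):
        """Long-lag MSD within 20% of the OU closed form 2*cage_radius^2."""
        cage = 1.5
        traj = generate_caged_trajectory(300, cage, 1.0, 400, 40.0, seed=6)
        msd = compute_msd(unwrap(traj), max_lag_fraction=0.8)
        tail = msd.msd[msd.lags > 200]
        assert np.mean(tail) == pytest.approx(2 * cage ** 2, rel=0.20)

    def test_near_zero_cage_freezes(self):
        traj = generate_caged_trajectory(50, 1e-4, 1.0, 100, 40.0, seed=2)
        msd = compute_msd(unwrap(traj), max_lag_fraction=1.0)
        assert msd.msd.max() < 1e-6

    def test_einstein_fit_statistically_zero(self):
        traj = generate_caged_trajectory(200, 1.0, 1.0, 300, 40.0, seed=8)
        msd = compute_msd(unwrap(traj), max_lag_fraction=0.8)
        res = fit_diffusivity(msd, window=(120.0, 239.0))
        assert res.subdiffusive

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_caged_trajectory(5, 0.0, 1.0, 10, 20.0, seed=0)
        with pytest.raises(ValueError):
            generate_caged_trajectory(5, 6.0, 1.0, 10, 20.0, seed=0)


class TestScanGenerator:
    def test_zero_noise_lies_on_laws(self):
        truth = ScanTruth(rho_noise_sd=0.0, d_noise_sd=0.0)
        scan = generate_thermal_scan(truth, seed=5)
        np.testing.assert_allclose(scan.rho, truth.rho_law(scan.T),
                                   atol=1e-12)
        np.testing.assert_allclose(scan.D, truth.d_law(scan.T),
                                   atol=1e-15)

    def test_seeds_differ_but_truth_shared(self):
        truth = ScanTruth()
        a = generate_thermal_scan(truth, seed=1)
        b = generate_thermal_scan(truth, seed=2)
        assert not np.array_equal(a.rho, b.rho)
        assert a.truth is b.truth

    def test_grid_margin_enforced(self):
        with pytest.raises(ValueError, match="3 grid points"):
            generate_thermal_scan(
                ScanTruth(true_tg=495.0), seed=0)

    def test_slope_ordering_enforced(self):
        with pytest.raises(ValueError, match="slope"):
            ScanTruth(glass_slope=-9e-4, liquid_slope=-1e-4)

    def test_arrhenius_option(self):
        truth = ScanTruth(d_law_kind="arrhenius", rho_noise_sd=0.0,
                          d_noise_sd=0.0)
        d = truth.d_law(truth.T_grid)
        below = truth.T_grid < truth.true_tg
        np.testing.assert_allclose(d[below], truth.d_floor)
        assert np.all(np.diff(d[~below]) > 0)

    def test_sidecar_round_trip(self, tmp_path):
        truth = ScanTruth()
        scan = generate_thermal_scan(truth, seed=3)
        p = tmp_path / "scan.tsv"
        write_scan_with_truth(scan, p)
        back = read_scan_with_truth(p)
        np.testing.assert_allclose(back.rho, scan.rho)
        np.testing.assert_allclose(back.D, scan.D)
        assert back.truth.true_tg == truth.true_tg


class TestToyEngine:
    def test_zero_steps_initial_configuration(self):
        p = ToySystemParams(seed=1)
        traj, thermo = simulate_lj_glassformer(p, 0)
        assert len(traj) == 1
        assert len(thermo) == 0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            simulate_lj_glassformer(ToySystemParams(seed=1), 10,
                                    mode="NVU")

    def test_determinism(self):
        a, ta = simulate_lj_glassformer(ToySystemParams(seed=4), 200,
                                        sample_every=50)
        b, tb = simulate_lj_glassformer(ToySystemParams(seed=4), 200,
                                        sample_every=50)
        np.testing.assert_array_equal(a.positions_array(),
                                      b.positions_array())
        np.testing.assert_array_equal(ta.potential_energy,
                                      tb.potential_energy)

    def test_nve_energy_conservation(self):
        """Relative total-energy drift bounded in the decoupled ensemble."""
        p = ToySystemParams(seed=3)
        eng = _LJEngine(p)
        eng.run(1000, "NVT", sample_every=1000, store_frames=False)
        _, pot0, _ = eng.forces()
        e0 = pot0 + eng.kinetic()
        _, recs = eng.run(2000, "NVE", sample_every=50, store_frames=False)
        recs = np.array(recs)
        ke = recs[:, 5] - recs[:, 4] - p.pressure * recs[:, 3]
        drift = np.abs(recs[:, 4] + ke - e0) / abs(e0)
        assert drift.max() < 1e-3

    def test_nve_momentum_conservation(self):
        p = ToySystemParams(seed=5)
        eng = _LJEngine(p)
        eng.vel -= (eng.mass[:, None] * eng.vel).sum(0) / eng.mass.sum()
        eng.run(500, "NVE", sample_every=500, store_frames=False)
        mom = (eng.mass[:, None] * eng.vel).sum(axis=0)
        assert np.abs(mom).max() < 1e-8

    def test_nvt_holds_temperature(self):
        """Production mean T within 2% of target after equilibration."""
        p = ToySystemParams(seed=6, temperature=0.9)
        _, thermo = simulate_lj_glassformer(p, 3000, mode="NVT",
                                            sample_every=10,
                                            equil_steps=1000)
        mean_T_red = thermo.temperature.mean() / p.units.epsilon_kelvin
        assert mean_T_red == pytest.approx(0.9, rel=0.02)

    def test_pair_symmetry_under_species_swap(self):
        """Relabeling species with mirrored pair tables leaves the energy
        of a fixed configuration unchanged."""
        p1 = ToySystemParams(n_a=30, n_b=20, eps=(1.0, 1.5, 0.5),
                             sig=(1.0, 0.8, 0.88), seed=7)
        p2 = ToySystemParams(n_a=20, n_b=30, eps=(0.5, 1.5, 1.0),
                             sig=(0.88, 0.8, 1.0), seed=7)
        e1 = _LJEngine(p1)
        e2 = _LJEngine(p2)
        # same configuration, species blocks swapped: B-block first
        e2.pos = np.concatenate([e1.pos[p1.n_a:], e1.pos[:p1.n_a]])
        assert e2.forces()[1] == pytest.approx(e1.forces()[1], rel=1e-12)

    def test_units_conversion_round_numbers(self):
        u = UnitSystem(sigma_angstrom=3.4, epsilon_kelvin=120.0,
                       mass_amu=40.0)
        assert u.time_fs == pytest.approx(2152.0, rel=0.01)
        assert u.energy_kj_per_mol == pytest.approx(0.99774, rel=1e-4)


class TestThermalProtocol:
    def test_single_temperature_grid(self):
        p = ToySystemParams(n_a=40, n_b=10, seed=2)
        scan = run_thermal_protocol(p, [0.8], equil_steps=200,
                                    prod_steps=600)
        assert len(scan) == 1
        assert scan.rho[0] > 0

    def test_determinism(self):
        p = ToySystemParams(n_a=40, n_b=10, seed=3)
        grid = [1.0, 0.8, 0.6]
        s1 = run_thermal_protocol(ToySystemParams(n_a=40, n_b=10, seed=3),
                                  grid, equil_steps=200, prod_steps=600)
        s2 = run_thermal_protocol(ToySystemParams(n_a=40, n_b=10, seed=3),
                                  grid, equil_steps=200, prod_steps=600)
        np.testing.assert_array_equal(s1.rho, s2.rho)
        np.testing.assert_array_equal(s1.D, s2.D)

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            run_thermal_protocol(ToySystemParams(seed=1), [1.0],
                                 equil_steps=0, prod_steps=100)
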