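"""1-D reaction-diffusion model: calibration, profiles, transport and the
washout-wave / inhibitor-scan / kinetochore-gradient protocols."""

import numpy as np
import pytest
from dataclasses import replace

from aurorab.params import OneSiteParams
from aurorab.kinetics import HomogeneousState, IntegrationError, build_coupled_rhs, integrate_adaptive
from aurorab import spatial as SP


@pytest.fixture(scope="module")
def cell_kinetics():
    """Reference constants with the cell-matched phosphatase Michaelis
    constant."""
    return OneSiteParams.defaults().replace(KMp=0.16)


@pytest.fixture(scope="module")
def sp(cell_kinetics):
    return SP.SpatialParams(kinetics=cell_kinetics, grid_dx=0.1)


def zero_kinetics_params():
    return OneSiteParams(kcat=0, KM=1.0, kf=0, kfa=0, KMa=1.0, kcata=0,
                         kcis=0, kfp=0, KMp=1.0, kcatp=0)


class TestCalibration:
    def test_bound_concentration_from_pool_partition(self):
        c = SP.calibrate_bound_concentration(8.6e-3, 5800.0, 23.0, 0.75)
        assert c == pytest.approx(6.4, rel=0.02)

    def test_partition_identity_for_arbitrary_inputs(self, rng):
        for _ in range(20):
            C_sol, Vc, Vcent = rng.uniform(0.001, 10, 3)
            f = rng.uniform(0.05, 0.95)
            Cb = SP.calibrate_bound_concentration(C_sol, Vc, Vcent, f)
            assert f * C_sol * Vc == pytest.approx((1 - f) * Cb * Vcent)

    def test_trivial_symmetric_case(self):
        assert SP.calibrate_bound_concentration(1.0, 5.0, 5.0, 0.5) == \
            pytest.approx(1.0)

    def test_psf_width(self):
        assert SP.psf_width(0.594, 1.4) == pytest.approx(0.21, abs=0.005)

    def test_equilibrium_bound_fraction_near_three_quarters(self):
        assert SP.equilibrium_bound_fraction() == pytest.approx(0.75, abs=0.01)

    def test_association_rate_from_koff_and_kd(self, sp):
        assert sp.kon == pytest.approx(2.9, rel=0.01)

    def test_bound_pair_rates(self, sp):
        assert sp.kfb == pytest.approx(0.01 * sp.kinetics.kfa)
        assert sp.krb == pytest.approx(sp.kfb * sp.kinetics.KMa
                                       - sp.kinetics.kcata)


class TestProfiles:
    def test_centromere_axis_levels(self):
        prof = SP.generate_profile("centromere-axis")
        i0 = np.argmin(np.abs(prof.positions))
        assert prof.sites[i0] == pytest.approx(10.0, rel=0.01)
        inner = np.abs(prof.positions) <= 0.875
        assert prof.sites[inner].mean() == pytest.approx(6.4, rel=0.1)
        # kinetochore region (metaphase Ndc80 at ±0.7 µm): 1-2 µM
        k = np.argmin(np.abs(prof.positions - 0.7))
        assert 1.0 < prof.sites[k] < 3.0

    def test_arm_profile_plateau(self, sp):
        prof = SP.generate_profile("chromosome-arm", sp)
        assert prof.sites[0] == pytest.approx(1.5, rel=0.01)
        assert prof.sites.max() == pytest.approx(10.0, rel=0.01)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            SP.generate_profile("nucleolus")

    def test_stretch_identity(self):
        prof = SP.generate_profile("centromere-axis")
        same = SP.stretch_profile(prof, 1.0)
        np.testing.assert_allclose(same.sites, prof.sites)

    def test_stretch_conserves_sites_and_scales_peak(self):
        prof = SP.generate_profile("centromere-axis")
        pm = SP.stretch_profile(prof, 1.75)
        assert pm.integral() == pytest.approx(prof.integral(), rel=1e-3)
        assert pm.sites.max() == pytest.approx(1.75 * prof.sites.max(),
                                               rel=0.01)


class TestInhibitorScaling:
    def test_zero_dose_is_identity(self, cell_kinetics):
        scaled = SP.scale_params_for_inhibitor(
            cell_kinetics, SP.InhibitorDoseModel(0.0))
        assert scaled.kcis == cell_kinetics.kcis
        assert scaled.kcata == cell_kinetics.kcata

    @pytest.mark.parametrize("z, factor", [
        (0.33, np.exp(-1.0)),
        (2.0, np.exp(-2.0 / 0.33)),
    ])
    def test_exponential_attenuation(self, cell_kinetics, z, factor):
        scaled = SP.scale_params_for_inhibitor(
            cell_kinetics, SP.InhibitorDoseModel(z))
        assert scaled.kcis == pytest.approx(cell_kinetics.kcis * factor)
        assert scaled.kcata == pytest.approx(cell_kinetics.kcata * factor)
        # complex turnover unaffected; other constants untouched
        assert scaled.kra == pytest.approx(cell_kinetics.kra)
        assert scaled.kcatp == cell_kinetics.kcatp

    def test_decay_constant_outside_published_range_rejected(self):
        with pytest.raises(ValueError):
            SP.InhibitorDoseModel(1.0, decay=0.1)


class TestTransport:
    def test_uniform_fields_have_zero_diffusion_flux(self):
        kin = zero_kinetics_params()
        spz = SP.SpatialParams(kinetics=kin, koff=0.0, grid_dx=0.1)
        prof = SP.BindingProfile(np.arange(-3, 3.01, 0.1),
                                 np.zeros(61), "custom")
        rhs, species = SP.build_spatial_rhs(spz, prof)
        y0 = np.tile(np.linspace(0.1, 1.2, len(species)), (61, 1)).ravel()
        np.testing.assert_allclose(rhs(0.0, y0), 0.0, atol=1e-12)

    def test_free_diffusion_matches_gaussian_spreading(self):
        kin = zero_kinetics_params()
        spz = SP.SpatialParams(kinetics=kin, koff=0.0, grid_dx=0.05)
        x = np.arange(-3, 3.001, 0.05)
        prof = SP.BindingProfile(x, np.zeros(x.size), "custom")
        rhs, species = SP.build_spatial_rhs(spz, prof)
        sig0 = 0.3
        y0 = np.zeros((x.size, len(species)))
        y0[:, species.index("A")] = np.exp(-x**2 / (2 * sig0**2))
        t_end = 0.5
        _t, states, _ = SP.integrate_spatial(spz, prof, y0.ravel(), t_end,
                                             rtol=1e-9, atol=1e-12)
        u = states[-1][:, species.index("A")]
        sig2 = sig0**2 + 2 * spz.D * t_end
        expected = (sig0 / np.sqrt(sig2)) * np.exp(-x**2 / (2 * sig2))
        core = np.abs(x) < 1.5  # mid-domain, away from boundaries
        np.testing.assert_allclose(u[core], expected[core], atol=2e-3)
        # no-flux: mass conserved
        assert np.trapezoid(u, x) == pytest.approx(
            np.trapezoid(y0[:, species.index("A")], x), rel=1e-6)

    def test_flat_siteless_domain_reproduces_homogeneous_system(
            self, cell_kinetics):
        # spatial model with zero binding sites == well-mixed coupled system
        spz = SP.SpatialParams(kinetics=cell_kinetics, grid_dx=0.5)
        x = np.arange(-3, 3.01, 0.5)
        prof = SP.BindingProfile(x, np.zeros(x.size), "custom")
        y0 = SP._initial_state(spz, prof, "all_active", 8.0, 0.4, None)
        _t, states, species = SP.integrate_spatial(
            spz, prof, y0, 500.0, rtol=1e-8, atol=1e-11)
        rhs = build_coupled_rhs(cell_kinetics)
        ref = integrate_adaptive(rhs, HomogeneousState(Astar=8.0, PPase=0.4),
                                 500.0, sample_dt=500.0,
                                 conservation_tol=1e-5)
        spatial_astar = states[-1][:, species.index("Astar")].mean()
        assert spatial_astar == pytest.approx(ref.final_state.Astar, rel=0.01)

    def test_total_kinase_conserved_in_reactive_run(self, sp):
        prof = SP.generate_profile("chromosome-arm", sp, grid_dx=0.1)
        Atot = SP.physiological_loading(prof)
        y0 = SP._initial_state(sp, prof, "all_active", Atot, 0.1, None)
        st0 = SP._state_from_flat(prof, sp, y0, SP._species_list(False))
        st1 = SP.simulate_to_steady(sp, prof, "all_active", 0.1, Atot, 1000.0)
        assert st1.total_kinase_integral() == pytest.approx(
            st0.total_kinase_integral(), rel=1e-3)

    def test_explicit_path_needs_cfl_step(self, sp):
        prof = SP.generate_profile("chromosome-arm", sp, grid_dx=0.1)
        y0 = SP._initial_state(sp, prof, "all_active", 1.0, 0.0, None)
        with pytest.raises(IntegrationError, match="dt"):
            SP.integrate_spatial_explicit(sp, prof, y0, 1.0, dt=0.05)

    def test_explicit_and_adaptive_paths_agree(self, sp):
        prof = SP.generate_profile("chromosome-arm", sp, grid_dx=0.1)
        Atot = SP.physiological_loading(prof)
        y0 = SP._initial_state(sp, prof, "all_active", Atot, 0.1, None)
        dt = 0.8 * SP.cfl_dt(sp, 0.1)
        y_exp, species = SP.integrate_spatial_explicit(sp, prof, y0, 5.0, dt)
        _t, states, _ = SP.integrate_spatial(sp, prof, y0, 5.0,
                                             rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(y_exp, states[-1].ravel(), atol=1e-5)


class TestSteadyRelaxation:
    def test_no_phosphatase_all_active_stays_fully_active(self, sp):
        prof = SP.generate_profile("chromosome-arm", sp, grid_dx=0.2)
        st = SP.simulate_to_steady(sp, prof, "all_active", 0.0, 2.0, 1000.0)
        assert SP.active_fraction_integral(st) == pytest.approx(1.0, abs=1e-6)

    def test_steadiness_check_on_converged_run(self, sp):
        prof = SP.generate_profile("chromosome-arm", sp, grid_dx=0.2)
        st = SP.simulate_to_steady(sp, prof, "all_active", 0.0, 2.0, 2000.0,
                                   check_steady=True)
        assert SP.active_fraction_integral(st) > 0.99

    def test_t_max_floor(self, sp):
        prof = SP.generate_profile("chromosome-arm", sp, grid_dx=0.2)
        with pytest.raises(ValueError):
            SP.simulate_to_steady(sp, prof, "all_active", 0.0, 2.0, 10.0)


class TestActiveFractionReadout:
    def _state(self, a, b, astar, bstar):
        x = np.linspace(-1, 1, 5)
        fields = {n: np.zeros(5) for n in SP._species_list(False)}
        fields["A"] += a
        fields["B"] += b
        fields["Astar"] += astar
        fields["Bstar"] += bstar
        return SP.SpatialState(x, fields)

    @pytest.mark.parametrize("a,b,astar,bstar,expected", [
        (0.0, 0.0, 1.0, 2.0, 1.0),   # everything active
        (1.0, 2.0, 0.0, 0.0, 0.0),   # everything partially active
        (1.0, 1.0, 1.0, 1.0, 0.5),   # half active
    ])
    def test_integral_readout(self, a, b, astar, bstar, expected):
        st = self._state(a, b, astar, bstar)
        assert SP.active_fraction_integral(st) == pytest.approx(expected)


class TestWaveAndTiming:
    def test_inhibited_kinase_never_phosphorylates(self, cell_kinetics):
        dead = cell_kinetics.replace(kcis=0.0, kcata=0.0, KMa=1.0, kfa=0.0)
        spd = SP.SpatialParams(kinetics=dead, grid_dx=0.2)
        prof = SP.generate_profile("chromosome-arm", spd, grid_dx=0.2)
        w = SP.simulate_wave(spd, prof, SP.SubstrateParams(), 2000.0, 2.0,
                             n_samples=10)
        assert np.max(w["P"]) < 1e-12

    def test_washout_wave_nucleates_at_centromere_and_fills_domain(self, sp):
        prof = SP.generate_profile("chromosome-arm", sp, grid_dx=0.1)
        Atot = SP.physiological_loading(prof)
        w = SP.simulate_wave(sp, prof, SP.SubstrateParams(), 30000.0, Atot,
                             n_samples=120)
        h = SP.half_max_time_profile(w["P"], w["times"], w["positions"])
        t50, x = h["t50"], w["positions"]
        # centromere activates first, arms later
        arm = np.abs(x) > 2.0
        assert t50[arm].min() > 200.0
        assert np.all(t50 >= -1e-9)
        # near-uniform high activation at the end
        assert w["active_fraction"][-1].min() > 0.85

    def test_uniform_field_gives_zero_t50_profile(self):
        times = np.linspace(0, 100, 50)
        P = np.tile((1 - np.exp(-times / 20))[:, None], (1, 11))
        x = np.linspace(-1, 1, 11)
        h = SP.half_max_time_profile(P, times, x)
        np.testing.assert_allclose(h["t50"], 0.0, atol=1e-9)

    def test_never_crossing_position_rejected(self):
        times = np.linspace(0, 10, 10)
        P = np.zeros((10, 3))
        P[:, :2] = times[:, None]
        with pytest.raises(ValueError):
            SP.half_max_time_profile(P, times, np.array([-1.0, 0.0, 1.0]))


class TestCellScans:
    def test_hysteresis_branches_separated_then_closed(self, sp):
        prof = SP.generate_profile("centromere-axis", sp, grid_dx=0.05)
        Atot = SP.physiological_loading(prof)
        res = SP.cell_hysteresis_scan(sp, prof, 0.1, Atot,
                                      [0.0, 0.25, 2.0], t_max=3000.0)
        # history dependence at low/intermediate dose, none at high dose
        assert res["added"][0] - res["washout"][0] > 0.5
        assert res["added"][1] - res["washout"][1] > 0.1
        assert abs(res["added"][2] - res["washout"][2]) < 0.05

    def test_stretching_weakens_activation(self, sp):
        Atot = SP.physiological_loading(
            SP.generate_profile("centromere-axis", sp, 0.05))
        pm = SP.kinetochore_gradient(sp, "prometaphase", 0.25, Atot,
                                     t_max=1000.0, grid_dx=0.05)
        m = SP.kinetochore_gradient(sp, "metaphase", 0.25, Atot,
                                    t_max=1000.0, grid_dx=0.05)
        f = lambda g: float(np.mean(g["active_fraction"]))
        assert f(pm) > f(m) + 0.2

    def test_prometaphase_centromere_pool_nearly_all_active(self, sp):
        Atot = SP.physiological_loading(
            SP.generate_profile("centromere-axis", sp, 0.05))
        g = SP.kinetochore_gradient(sp, "prometaphase", 0.1, Atot,
                                    t_max=1000.0, grid_dx=0.05)
        x, f = g["positions"], g["active_fraction"]
        center = float(f[np.argmin(np.abs(x))])
        kineto = float(f[np.argmin(np.abs(x - 0.4))])
        assert center > 0.85
        assert kineto < center  # slight decline toward the kinetochore

    def test_threshold_loss_raises_activity_of_stretched_state(
            self, cell_kinetics):
        # without bistability the activity follows kinase concentration
        # instead of collapsing below threshold
        spv = SP.SpatialParams(
            kinetics=cell_kinetics.replace(kcis=7.3e-4), grid_dx=0.1)
        spb = SP.SpatialParams(kinetics=cell_kinetics, grid_dx=0.1)
        Atot = SP.physiological_loading(
            SP.generate_profile("centromere-axis", spb, 0.05))
        gb = SP.kinetochore_gradient(spb, "metaphase", 0.3, Atot,
                                     t_max=1000.0, grid_dx=0.05)
        gv = SP.kinetochore_gradient(spv, "metaphase", 0.3, Atot,
                                     t_max=1000.0, grid_dx=0.05)
        assert np.mean(gv["active_fraction"]) > \
            np.mean(gb["active_fraction"]) + 0.15

    def test_spatial_bistability_requires_phosphatase(self, sp):
        prof = SP.generate_profile("centromere-axis", sp, grid_dx=0.1)
        Atot = SP.physiological_loading(prof)
        m = SP.spatial_bistability_map(sp, prof, [Atot], [1e-6, 0.1],
                                       t_max=8000.0)
        assert not m[0, 0]      # without phosphatase both histories converge
        assert m[0, 1]          # physiological loading is history-dependent
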