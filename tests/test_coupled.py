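"""Steady states, bistability and hysteresis of the coupled
kinase-phosphatase system."""

import numpy as np
import pytest

from aurorab.coupled import (
    bistability_region,
    bistability_threshold,
    bistable_ppase_interval,
    find_steady_states,
    hysteresis_loop,
    ppase_total_at_steady_state,
    simulate_with_pulses,
    steady_state_scan,
)
from aurorab.kinetics import HomogeneousState, build_coupled_rhs, integrate_adaptive


def relaxed_active(params, Atot, ppase, frac0, t_end=2e4):
    """Dynamic-relaxation oracle: long ODE run from a given active fraction."""
    rhs = build_coupled_rhs(params)
    y0 = HomogeneousState(A=Atot * (1 - frac0), Astar=Atot * frac0,
                          PPase=ppase)
    traj = integrate_adaptive(rhs, y0, t_end, sample_dt=t_end / 10,
                              conservation_tol=1e-4)
    return traj.final_state.active_kinase


class TestSteadyStates:
    def test_three_states_at_reference_conditions(self, ref_params):
        states = find_steady_states(ref_params, 8.0, 0.47)
        labels = [lab for _, lab in states]
        assert len(states) == 3
        assert labels.count("stable") == 2 and labels.count("unstable") == 1
        # ordered by active kinase: low stable, unstable, high stable
        act = [s.active_kinase for s, _ in states]
        assert act[0] < act[1] < act[2]

    def test_no_phosphatase_single_fully_active_state(self, ref_params):
        states = find_steady_states(ref_params, 5.0, 0.0)
        assert len(states) == 1
        state, lab = states[0]
        assert lab == "stable"
        assert state.active_kinase == pytest.approx(5.0)

    def test_states_lie_on_conservation_manifold(self, ref_params):
        for state, _ in find_steady_states(ref_params, 8.0, 0.45):
            assert state.total_kinase == pytest.approx(8.0, abs=1e-9)
            assert state.total_phosphatase == pytest.approx(0.45, abs=1e-9)

    def test_rhs_vanishes_at_every_steady_state(self, ref_params):
        rhs = build_coupled_rhs(ref_params)
        for state, _ in find_steady_states(ref_params, 8.0, 0.45):
            d = rhs(state.to_array())
            assert np.max(np.abs(d)) < 1e-8

    def test_stable_states_match_relaxation_oracle(self, ref_params):
        states = find_steady_states(ref_params, 8.0, 0.45)
        stable = sorted(s.active_kinase for s, lab in states
                        if lab == "stable")
        low = relaxed_active(ref_params, 8.0, 0.45, 0.0)
        high = relaxed_active(ref_params, 8.0, 0.45, 1.0)
        assert low == pytest.approx(stable[0], abs=1e-3)
        assert high == pytest.approx(stable[-1], abs=1e-3)

    def test_unstable_state_departs_under_perturbation(self, ref_params):
        states = find_steady_states(ref_params, 8.0, 0.45)
        unstable = [s for s, lab in states if lab == "unstable"][0]
        rhs = build_coupled_rhs(ref_params)
        finals = []
        for sign in (+1.0, -1.0):
            y = unstable.to_array()
            shift = sign * 0.05 * unstable.Astar
            y[1] += shift   # perturb A* along the conservation manifold
            y[0] -= shift
            traj = integrate_adaptive(rhs, y, 2e4, sample_dt=2e3,
                                      conservation_tol=1e-4)
            finals.append(traj.final_state.active_kinase)
        assert finals[0] > unstable.active_kinase + 0.5
        assert finals[1] < unstable.active_kinase - 0.5

    def test_steady_state_relation_consistency(self, ref_params):
        # Ptot(A*) evaluated at a root reproduces the prescribed total
        for state, _ in find_steady_states(ref_params, 8.0, 0.43):
            back = ppase_total_at_steady_state(ref_params, 8.0, state.Astar)
            assert back == pytest.approx(0.43, rel=1e-9)


class TestBistabilityRegion:
    def test_low_kinase_row_never_bistable(self, ref_params):
        m = bistability_region(ref_params, [1.0],
                               np.arange(0.01, 0.81, 0.01))
        assert not m.any()

    def test_reference_row_contains_experimental_window(self, ref_params):
        pp = np.arange(0.01, 0.81, 0.01)
        m = bistability_region(ref_params, [8.0], pp)[0]
        assert m[np.isclose(pp, 0.45)].all()
        # contiguous interval
        idx = np.nonzero(m)[0]
        assert np.all(np.diff(idx) == 1)

    def test_window_widens_with_total_kinase(self, ref_params):
        widths = []
        for Atot in (5.0, 8.0, 12.0):
            lo, hi = bistable_ppase_interval(ref_params, Atot)
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_threshold_near_printed_value(self, ref_params):
        thr = bistability_threshold(ref_params, resolution=0.02)
        assert thr == pytest.approx(3.9, abs=0.2)

    def test_fast_cis_variant_not_bistable_in_physiological_range(
            self, ref_params):
        variant = ref_params.replace(kcis=7.3e-4)
        for Atot in (4.0, 8.0, 10.0):
            assert bistable_ppase_interval(variant, Atot) is None

    def test_threshold_invariant_under_kcatp_ppase_rescaling(self, ref_params):
        # rescaling kcatp shifts the admissible phosphatase range (kill
        # capacity = kcatp*PPase) without moving the onset much; the
        # residual drift comes from kinase sequestered in phosphatase
        # complexes, which scales with the absolute PPase level
        thr = bistability_threshold(ref_params, resolution=0.02)
        for alpha in (0.5, 2.0):
            scaled = ref_params.replace(kcatp=alpha * ref_params.kcatp)
            assert bistability_threshold(scaled, resolution=0.02) == \
                pytest.approx(thr, abs=0.35)


class TestPulses:
    def test_zero_pulse_leaves_trajectory_at_low_state(self, ref_params):
        res = simulate_with_pulses(ref_params, 8.0, 0.47, [(2000.0, 0.0)],
                                   6000.0)
        assert res.label == "low"
        act = res.trajectory["Astar"] + res.trajectory["AAstar"]
        assert act[-1] < 0.1

    def test_subthreshold_pulses_relax_back(self, ref_params):
        res = simulate_with_pulses(ref_params, 8.0, 0.47,
                                   [(2000.0, 0.3), (4000.0, 0.4)], 30000.0)
        assert res.label == "low"

    def test_suprathreshold_pulse_switches_high(self, ref_params):
        res = simulate_with_pulses(
            ref_params, 8.0, 0.47,
            [(2000.0, 0.3), (4000.0, 0.4), (6000.0, 0.5)], 30000.0)
        assert res.label == "high"
        act = res.trajectory["Astar"] + res.trajectory["AAstar"]
        assert act[-1] > 4.0

    def test_unordered_pulses_rejected(self, ref_params):
        with pytest.raises(ValueError):
            simulate_with_pulses(ref_params, 8.0, 0.47,
                                 [(2000.0, 0.1), (1000.0, 0.1)], 5000.0)


class TestHysteresisLoop:
    def test_branches_coincide_below_bistable_interval(self, ref_params):
        loop = hysteresis_loop(ref_params, 8.0, ppase_max=0.3, n_steps=12,
                               cycle_time=1.2e5)
        assert np.max(np.abs(loop["up"] - loop["down"])) < 0.02

    def test_branches_bifurcate_inside_bistable_interval(self, ref_params):
        loop = hysteresis_loop(ref_params, 8.0, ppase_max=1.0, n_steps=40,
                               cycle_time=3.6e5)
        pp, gap = loop["ppase"], loop["up"] - loop["down"]
        inside = (pp > 0.40) & (pp < 0.47)
        outside = (pp < 0.35) | (pp > 0.55)
        assert gap[inside].max() > 0.3
        assert np.abs(gap[outside]).max() < 0.03
        # down-branch stays low throughout the bistable interval and only
        # re-activates once phosphatase drops below it
        assert loop["down"][(pp > 0.41) & (pp < 0.47)].max() < 0.1
        assert loop["down"][pp < 0.2].min() > 0.8

    def test_hysteresis_for_phosphatase_michaelis_family(self, ref_params):
        # window collapses above KMp ~ 3.4 µM at 8 µM kinase, so the family
        # spans the bistable range of the Michaelis constant
        for f in (0.5, 1.0, 1.25, 1.5):
            p = ref_params.replace(KMp=f * 1.95)
            loop = hysteresis_loop(p, 8.0, ppase_max=1.0, n_steps=60,
                                   cycle_time=3.6e5)
            assert (loop["up"] - loop["down"]).max() > 0.05, f


class TestSteadyStateScan:
    def test_reference_protocol_pattern(self, ref_params):
        hi = steady_state_scan(ref_params, 8.0, [0.25, 0.45, 0.5],
                               "initially_high")
        lo = steady_state_scan(ref_params, 8.0, [0.25, 0.45, 0.5],
                               "initially_low")
        # low phosphatase: both converge high (slight decline from 1)
        assert hi[0] > 0.7 and lo[0] > 0.7
        assert abs(hi[0] - lo[0]) < 0.05
        # bistable point: persistent separation
        assert hi[1] - lo[1] > 0.3
        # high phosphatase: initially-low is low; initially-high declining
        assert lo[2] < 0.05
        assert hi[2] < 0.3

    def test_monostable_final_state_independent_of_init(self, ref_params):
        hi = steady_state_scan(ref_params, 2.0, [0.2], "initially_high",
                               t_end=2e4)
        lo = steady_state_scan(ref_params, 2.0, [0.2], "initially_low",
                               t_end=2e4)
        assert abs(hi[0] - lo[0]) < 1e-3

    def test_protocol_guards(self, ref_params):
        with pytest.raises(ValueError):
            steady_state_scan(ref_params, 8.0, [0.1], "initially_high",
                              t_end=100.0)
        with pytest.raises(ValueError):
            steady_state_scan(ref_params, 8.0, [0.1], "sideways")
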