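"""Equilibration and trajectory integration through the stress event."""

import numpy as np
import pytest

import osmoadapt as oa
from osmoadapt.model import compute_observables, evaluate_rhs
from osmoadapt.params import SIDX
from osmoadapt.simulate import (
    StressProtocol,
    presstress_equilibrate,
    simulate,
)


class TestEquilibration:
    def test_equilibrium_state_refeeds_to_small_residuals(
            self, params, eq_state):
        dx = evaluate_rhs(eq_state, 0.0, params)
        scale = np.maximum(np.abs(eq_state), 1.0)
        for name in oa.params.INTRACELLULAR:
            if name in ("Hog1u", "Hog1PP"):
                continue  # moiety drifts at O(mu * Hog1tot) by construction
            assert abs(dx[SIDX[name]]) < 1e-8 * scale[SIDX[name]], name

    def test_equilibrated_wildtype_is_unstressed(self, params, eq_state):
        obs = compute_observables(eq_state, params)
        assert obs.u < 0.05
        assert eq_state[SIDX["Hog1PP"]] < 0.05 * params.Hog1tot

    def test_basal_signaling_matches_root_solve_of_subsystem(
            self, params, eq_state):
        """At the fixed point the two-reaction phosphorylation balance
        holds: k_ph u Hog1u = (k_dp + mu) Hog1PP."""
        obs = compute_observables(eq_state, params)
        lhs = params.k_ph * obs.u * eq_state[SIDX["Hog1u"]]
        rhs = (params.k_dp + obs.mu) * eq_state[SIDX["Hog1PP"]]
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_stl1_removal_barely_shifts_the_prestress_state(self, params,
                                                            eq_state):
        """Pre-stress external glycerol is tiny, so deleting the Stl1
        uptake capacity moves the fixed point only marginally."""
        other = presstress_equilibrate(params.replace(VmSTL=0.0))
        rel = np.abs(other - eq_state) / np.maximum(np.abs(eq_state), 1e-6)
        # Stl1 protein itself is untouched; glycerol-adjacent pools shift
        # by less than a percent
        assert rel[SIDX["Glyi"]] < 1e-2
        assert rel[SIDX["Vos"]] < 1e-3

    def test_infeasible_parameters_raise_equilibration_error(self, params):
        from osmoadapt.simulate import EquilibrationError
        # crippled lower glycolysis leaves triose-phosphate influx without
        # a sink: no fixed point exists
        bad = params.replace(VmLG=params.VmLG * 0.02)
        with pytest.raises(EquilibrationError):
            presstress_equilibrate(bad)


class TestSimulate:
    def test_no_stress_means_no_response(self, params):
        proto = StressProtocol(NaCl_step=0.0, t_end=60.0,
                               t_grid=np.arange(0.0, 61.0, 1.0))
        traj = simulate(params, "WT", proto)
        vos = traj["Vos"]
        assert np.max(np.abs(vos - vos[0])) / vos[0] < 0.005
        assert np.all(traj["Hog1PP"] < 0.05 * params.Hog1tot)

    def test_prestress_quasi_steady_state_despite_growth(self, params):
        """Without stress the culture keeps growing while glycolytic
        intermediate concentrations stay quasi-stationary (within a few
        percent over 30 min; the batch itself is not at strict steady
        state - glucose is consumed and ethanol accumulates)."""
        proto = StressProtocol(NaCl_step=0.0, t_end=180.0)
        traj = simulate(params, "WT", proto)
        sel = traj.t <= 30.0
        for name in ("c_Glci", "c_HexP", "c_FBP", "c_TriP", "c_Pyr",
                     "c_Trei"):
            series = traj[name][sel]
            assert np.max(np.abs(series - series[0])) / series[0] < 0.05, name
        vos = traj["Vos"]
        assert np.max(np.abs(vos - vos[0])) / vos[0] < 0.02
        assert traj["CD"][-1] > 1.5 * traj["CD"][0]

    def test_stress_step_is_applied_exactly_at_t_stress(self, wt_traj):
        assert wt_traj.states["NaCle"].iloc[0] == pytest.approx(0.4)

    def test_wildtype_glycerol_peaks_after_30_minutes(self, wt_traj):
        cg = wt_traj["c_Glyi"]
        sel = wt_traj.t <= 180.0
        assert wt_traj.t[sel][np.argmax(cg[sel])] >= 30.0

    def test_hog1_deletion_glycerol_stays_low_until_60_minutes(
            self, hog1_traj):
        from osmoadapt.fluxana import half_rise_time
        t_half = half_rise_time(hog1_traj.t, hog1_traj["c_Glyi"], 180.0)
        assert t_half >= 60.0

    def test_grid_refinement_stability(self, params, wt_traj):
        """Halving the solver tolerances changes intracellular glycerol by
        less than 0.1% in sup norm."""
        tight = simulate(params, "WT", rtol=5e-9, atol=5e-11)
        a, b = wt_traj["c_Glyi"], tight["c_Glyi"]
        assert np.max(np.abs(a - b) / np.maximum(np.abs(b), 1.0)) < 1e-3

    def test_volume_recovers_without_perfect_adaptation(self, params,
                                                        wt_traj, eq_state):
        """Total volume returns to within 10% of pre-stress by 180 min
        while Gpd1, trehalose and growth rate remain displaced."""
        vtot0 = params.Vb + eq_state[SIDX["Vos"]]
        assert abs(wt_traj["Vtot"][-1] - vtot0) / vtot0 < 0.10
        gpd0 = eq_state[SIDX["Gpd1m"]] + 2 * eq_state[SIDX["Gpd1d"]]
        assert abs(wt_traj["Gpd1tot"][-1] - gpd0) / gpd0 > 0.2
        tre0 = eq_state[SIDX["Trei"]] / eq_state[SIDX["Vos"]]
        assert abs(wt_traj["c_Trei"][-1] - tre0) / tre0 > 0.1
        mu0 = compute_observables(eq_state, params).mu
        assert abs(wt_traj["mu"][-1] - mu0) / mu0 > 0.1

    def test_strain_ordering_of_glycerol_responses(self, wt_traj, hog1_traj,
                                                   fps1_traj):
        sel = wt_traj.t <= 60.0
        assert wt_traj["c_Glyi"][sel].max() > hog1_traj["c_Glyi"][sel].max()
        assert fps1_traj["Glye"][-1] > wt_traj["Glye"][-1]

    def test_hog1_peak_is_monotone_in_stress_dose(self, params):
        peaks = []
        for dose in (0.2, 0.4, 0.6, 0.8):
            proto = StressProtocol(NaCl_step=dose, t_end=60.0,
                                   t_grid=np.arange(0.0, 61.0, 1.0))
            traj = simulate(params, "WT", proto, rtol=1e-7, atol=1e-9)
            peaks.append(traj["Hog1PP"].max())
        assert np.all(np.diff(peaks) >= -1e-12)

    def test_integration_never_goes_meaningfully_negative(self, wt_traj,
                                                          hog1_traj):
        for traj in (wt_traj, hog1_traj):
            assert traj.states.to_numpy().min() > -1e-9

    def test_negative_time_window_covers_prestress_growth(self, params):
        proto = StressProtocol(t_grid=np.arange(-60.0, 91.0, 1.0),
                               t_end=90.0)
        traj = simulate(params, "WT", proto)
        cd = traj["CD"]
        pre = traj.t < 0
        assert np.all(np.diff(np.log(cd[pre])) > 0)
        assert traj.t[0] == -60.0 and traj.t[-1] == 90.0
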