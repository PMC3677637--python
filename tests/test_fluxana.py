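"""Glycerol flux decomposition, ternary coordinates, growth metrics."""

import numpy as np
import pytest

from osmoadapt.fluxana import (
    FluxDecomposition,
    decompose_glycerol_flux,
    doubling_time,
    first_gpd1_dominance,
    flux_shares,
    ternary_coordinates,
)
from osmoadapt.simulate import StressProtocol, simulate


@pytest.fixture(scope="module")
def wt_decomp(wt_traj):
    return decompose_glycerol_flux(wt_traj)


class TestDecomposition:
    @pytest.mark.parametrize("strain_fixture",
                             ["wt_traj", "hog1_traj", "gpd1_traj",
                              "fps1_traj"])
    def test_components_sum_to_concentration_derivative(
            self, strain_fixture, request):
        """J_Gpd1 + J_Fps1 + J_Others equals d(cGlyi)/dt pointwise; the
        oracle differentiates the quotient Glyi/Vos from the trajectory's
        own state derivatives."""
        traj = request.getfixturevalue(strain_fixture)
        d = decompose_glycerol_flux(traj)
        vos = traj["Vos"]
        dglyi = traj.derivatives["d_Glyi"].to_numpy()
        dvos = traj.derivatives["d_Vos"].to_numpy()
        dc_oracle = dglyi / vos - traj["Glyi"] * dvos / vos ** 2
        total = d.J_Gpd1 + d.J_Fps1 + d.J_Others
        assert np.max(np.abs(total - dc_oracle)) < 1e-9

    def test_sum_identity_against_numerical_differentiation(self, wt_traj,
                                                            wt_decomp):
        """Cross-check against central differences of cGlyi(t) itself."""
        c = wt_traj["c_Glyi"]
        t = wt_traj.t
        mid = slice(1, -1)
        num = (c[2:] - c[:-2]) / (t[2:] - t[:-2])
        total = (wt_decomp.J_Gpd1 + wt_decomp.J_Fps1
                 + wt_decomp.J_Others)[mid]
        # the 1-min grid limits the oracle's own accuracy
        mask = np.abs(num) > 1.0
        assert np.median(np.abs(total[mask] - num[mask])
                         / np.abs(num[mask])) < 0.05

    def test_wildtype_t1_production_is_smallest_contribution(
            self, wt_decomp):
        """Immediately after the shock, adaptation is dominated by volume
        loss and Fps1 closure, not by Gpd1-driven production."""
        i = np.searchsorted(wt_decomp.t, 1.0)
        assert wt_decomp.r_Gpd1[i] < wt_decomp.r_Fps1[i]
        assert wt_decomp.r_Gpd1[i] < wt_decomp.r_Others[i]

    def test_gpd1_becomes_dominant_within_15_minutes(self, wt_decomp):
        assert first_gpd1_dominance(wt_decomp) <= 15.0

    def test_open_fps1_strain_keeps_producing(self, fps1_traj, wt_decomp):
        """With Fps1 forced open the system settles in a sustained
        glycerol-production state: the Gpd1 share dominates the residual
        contributions, stays far above its own pre-stress level, and the
        absolute production flux remains high late. (Under absolute-value
        normalization the transport share of an open channel is bounded
        below by the production share at quasi-steady state, so Gpd1
        cannot literally be the largest of the three there.)"""
        d = decompose_glycerol_flux(fps1_traj)
        late = d.t >= 120.0
        assert np.all(d.r_Gpd1[late] > d.r_Others[late])
        assert np.all(d.r_Gpd1[late] > 0.3)
        i60 = np.searchsorted(d.t, 60.0)
        assert np.all(d.J_Gpd1[late] > 0.5 * d.J_Gpd1[i60])
        # and far above the wild type's settled production share
        assert d.r_Gpd1[late].mean() > 2 * d.r_Gpd1[0]

    def test_missing_flux_columns_rejected(self, wt_traj):
        import copy
        broken = copy.copy(wt_traj)
        broken.fluxes = wt_traj.fluxes.drop(columns=["vGPP"])
        with pytest.raises(KeyError, match="vGPP"):
            decompose_glycerol_flux(broken)


class TestTernary:
    def test_coordinates_are_barycentric(self, wt_decomp):
        coords = ternary_coordinates(wt_decomp)
        assert np.all(coords >= 0)
        assert np.allclose(coords.sum(axis=1), 1.0)

    def test_degenerate_single_component(self):
        t = np.array([0.0, 1.0])
        z = np.zeros(2)
        j = np.array([0.0, 2.5])
        d = FluxDecomposition(t, z, z, j, z, z, np.ones(2), np.array(
            [False, False]))
        coords = ternary_coordinates(d)
        assert np.allclose(coords[1], [0.0, 0.0, 1.0])

    def test_all_zero_instant_maps_to_centroid_and_is_flagged(self, wt_traj):
        import copy
        frozen = copy.copy(wt_traj)
        frozen.fluxes = wt_traj.fluxes.copy()
        frozen.fluxes[:] = 0.0
        frozen.derivatives = wt_traj.derivatives.copy()
        frozen.derivatives[:] = 0.0
        frozen.observables = wt_traj.observables.copy()
        frozen.observables["mu"] = 0.0
        d = decompose_glycerol_flux(frozen)
        assert d.all_zero.all()
        assert np.allclose(ternary_coordinates(d), 1.0 / 3.0)

    def test_permuting_components_permutes_coordinates(self, wt_decomp):
        permuted = FluxDecomposition(
            wt_decomp.t, wt_decomp.J_Others, wt_decomp.J_Gpd1,
            wt_decomp.J_Fps1, wt_decomp.r_Others, wt_decomp.r_Gpd1,
            wt_decomp.r_Fps1, wt_decomp.all_zero)
        a = ternary_coordinates(wt_decomp)
        b = ternary_coordinates(permuted)
        assert np.allclose(a[:, [1, 2, 0]], b[:, [0, 1, 2]])


class TestGrowth:
    def test_doubling_time_closed_form_for_constant_growth(self):
        """ln(CD) is exactly linear for constant mu, so the fitted doubling
        time equals ln 2 / mu."""
        import pandas as pd
        from osmoadapt.simulate import Trajectory
        mu = 0.006
        t = np.arange(0.0, 61.0, 1.0)
        empty = pd.DataFrame(index=range(len(t)))
        traj = Trajectory(strain="synthetic", t=t,
                          states=pd.DataFrame({"CD": 1e7 * np.exp(mu * t)}),
                          observables=empty, fluxes=empty,
                          derivatives=empty)
        assert doubling_time(traj, (0.0, 60.0)) == pytest.approx(
            np.log(2) / mu, rel=1e-9)

    def test_short_window_rejected(self, wt_traj):
        with pytest.raises(ValueError, match="3 grid points"):
            doubling_time(wt_traj, (0.0, 1.0))

    def test_stress_slows_wildtype_growth(self, params):
        proto = StressProtocol(t_grid=np.arange(-60.0, 91.0, 1.0),
                               t_end=90.0)
        traj = simulate(params, "WT", proto)
        assert doubling_time(traj, (0.0, 90.0)) > doubling_time(
            traj, (-60.0, 0.0))

    def test_growth_drop_milder_in_gpd1_than_hog1_deletion(self, params):
        proto = StressProtocol(t_grid=np.arange(-60.0, 91.0, 1.0),
                               t_end=90.0)
        ratios = {}
        for strain in ("gpd1D", "hog1D"):
            traj = simulate(params, strain, proto)
            ratios[strain] = (doubling_time(traj, (0.0, 90.0))
                              / doubling_time(traj, (-60.0, 0.0)))
        assert ratios["gpd1D"] < ratios["hog1D"]


class TestFluxShares:
    def test_shares_close_exactly_with_pool_term(self, wt_traj):
        for t in (0.0, 20.0, 90.0):
            s = flux_shares(wt_traj, t)
            total = (s["biomass_share"] + s["glycerol_share"]
                     + s["ethanol_acetate_share"] + s["pool_change_share"])
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_pool_share_matches_carbon_bookkeeping_oracle(self, wt_traj):
        """The residual share equals the carbon-weighted rate of change of
        the upstream pools (plus dilution and trehalose export), assembled
        independently from the stoichiometry table."""
        from osmoadapt.model import CARBON_COUNTS
        i = np.searchsorted(wt_traj.t, 20.0)
        s = flux_shares(wt_traj, 20.0)
        uptake_C = 6.0 * wt_traj["vHXT"][i]
        mu = wt_traj["mu"][i]
        # reaction-driven carbon accumulation in the pools upstream of the
        # two committed branches, plus trehalose export
        oracle = 12.0 * wt_traj["vTret"][i]
        for name in ("Glci", "HexP", "FBP", "TriP", "Trei"):
            dX = wt_traj.derivatives[f"d_{name}"].to_numpy()[i]
            oracle += CARBON_COUNTS[name] * (dX + mu * wt_traj[name][i])
        assert s["pool_change_share"] * uptake_C == pytest.approx(
            oracle, rel=1e-6)

    def test_stress_trades_growth_for_glycerol(self, wt_traj):
        pre = flux_shares(wt_traj, 0.0)
        mid = flux_shares(wt_traj, 20.0)
        assert pre["biomass_share"] > pre["glycerol_share"]
        assert mid["glycerol_share"] > mid["biomass_share"]

    def test_lower_glycolysis_flux_stays_level_through_adaptation(
            self, wt_traj):
        """Carbon flux to pyruvate at 20 min stays within 15% of its
        pre-stress value."""
        vlg = wt_traj["vLG"]
        i = np.searchsorted(wt_traj.t, 20.0)
        assert abs(vlg[i] - vlg[0]) / vlg[0] < 0.15

    def test_zero_uptake_is_an_error(self, wt_traj):
        import copy
        broken = copy.copy(wt_traj)
        broken.fluxes = wt_traj.fluxes.copy()
        broken.fluxes["vHXT"] = 0.0
        with pytest.raises(ValueError, match="undefined|~0"):
            flux_shares(broken, 20.0)
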