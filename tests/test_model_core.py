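"""Core model contracts: state vector, rate laws, carbon bookkeeping."""

import numpy as np
import pytest

import osmoadapt as oa
from osmoadapt import _core
from osmoadapt.model import (
    CARBON_COUNTS,
    STOICHIOMETRY,
    check_carbon_closure,
    compute_observables,
    evaluate_rhs,
    reaction_fluxes,
    state_from_dict,
    state_to_dict,
    validate_state,
)
from osmoadapt.params import SIDX, STATE_NAMES

from conftest import perturbed_state


class TestStateVector:
    def test_state_has_exactly_29_entries(self, eq_state):
        assert len(STATE_NAMES) == 29
        assert eq_state.shape == (29,)
        validate_state(eq_state)

    def test_dict_round_trip(self, eq_state):
        d = state_to_dict(eq_state)
        assert np.array_equal(state_from_dict(d), eq_state)

    @pytest.mark.parametrize("bad, message", [
        ({"Vos": 0.0}, "volume"),
        ({"CD": 0.0}, "CD"),
        ({"Glyi": -1.0}, "negative"),
        ({"Fps1o": 1.5}, "Fps1o"),
    ])
    def test_invariant_violations_are_named(self, eq_state, bad, message):
        x = eq_state.copy()
        for k, v in bad.items():
            x[SIDX[k]] = v
        with pytest.raises(ValueError, match=message):
            validate_state(x)

    def test_nonfinite_entry_rejected_with_index(self, eq_state):
        x = eq_state.copy()
        x[SIDX["Pyr"]] = np.nan
        with pytest.raises(ValueError, match="Pyr"):
            evaluate_rhs(x, 0.0, oa.reference_parameters())


class TestRhs:
    def test_prestress_fixed_point_has_vanishing_derivatives(
            self, params, eq_state):
        """All intracellular derivatives vanish at the equilibrated state,
        except the structural growth-dilution drift of the Hog1 moiety."""
        dx = evaluate_rhs(eq_state, 0.0, params)
        scale = np.maximum(np.abs(eq_state), 1.0)
        rel = np.abs(dx) / scale
        for name in oa.params.INTRACELLULAR:
            if name in ("Hog1u", "Hog1PP"):
                continue
            assert rel[SIDX[name]] < 1e-8, name
        # Hog1: the phosphorylation balance holds; the moiety itself is
        # diluted at rate mu (no synthesis term exists for it)
        mu = compute_observables(eq_state, params).mu
        moiety = eq_state[SIDX["Hog1u"]] + eq_state[SIDX["Hog1PP"]]
        assert dx[SIDX["Hog1u"]] + dx[SIDX["Hog1PP"]] == pytest.approx(
            -mu * moiety, rel=1e-9)

    def test_nacl_step_raises_external_osmolarity_and_shrinks_cell(
            self, params, eq_state):
        x = eq_state.copy()
        obs0 = compute_observables(x, params)
        x[SIDX["NaCle"]] = 0.4
        obs1 = compute_observables(x, params)
        assert obs1.Pi_e - obs0.Pi_e == pytest.approx(params.i_vh * 0.4)
        dx = evaluate_rhs(x, 0.0, params)
        assert dx[SIDX["Vos"]] < 0

    def test_closed_fps1_carries_no_glycerol_flux(self, params, eq_state):
        x = eq_state.copy()
        x[SIDX["Fps1o"]] = 0.0
        x[SIDX["Glyi"]] = 500.0 * x[SIDX["Vos"]]
        v = reaction_fluxes(x, params)
        assert v["vFPS"] == 0.0

    def test_moiety_dilution_identity_at_random_states(
            self, params, eq_state):
        """d(Hog1u+Hog1PP)/dt = -mu (Hog1u+Hog1PP): phosphorylation and
        dephosphorylation cancel exactly in the moiety sum."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = perturbed_state(eq_state, rng)
            dx = evaluate_rhs(x, 0.0, params)
            mu = compute_observables(x, params).mu
            moiety = x[SIDX["Hog1u"]] + x[SIDX["Hog1PP"]]
            v = reaction_fluxes(x, params)
            tol = 1e-12 * max(v["v_ph"], v["v_dp"], 1.0)
            assert abs(dx[SIDX["Hog1u"]] + dx[SIDX["Hog1PP"]]
                       + mu * moiety) < tol

    def test_moiety_conserved_to_machine_precision_without_growth(
            self, params, eq_state):
        """With growth dilution disabled (mu0 = 0) the Hog1 moiety sum is
        constant to machine precision along an entire stress simulation."""
        p0 = params.replace(mu0=0.0)
        traj = oa.simulate(p0, "WT")
        moiety = traj["Hog1u"] + traj["Hog1PP"]
        assert np.max(np.abs(moiety - moiety[0])) < 1e-12 * moiety[0] + 1e-14


class TestObservables:
    def test_prestress_reference_turgor_and_signal(self, params):
        x = np.zeros(29)
        x[SIDX["Vos"]] = params.Vos0 * 1.02   # above the blend zone
        x[SIDX["CD"]] = 1.0
        obs = compute_observables(x, params)
        assert obs.Pi_t == pytest.approx(params.Pi_t0)
        assert obs.u == 0.0

    def test_turgor_loss_limit(self, params):
        x = np.zeros(29)
        x[SIDX["Vos"]] = params.V_lp
        x[SIDX["CD"]] = 1.0
        obs = compute_observables(x, params)
        # C1-smoothed clip: exact limits hold to the blend-zone width
        from osmoadapt._core import CLIP_EPS
        assert obs.Pi_t == pytest.approx(0.0, abs=CLIP_EPS * params.Pi_t0)
        assert obs.u == pytest.approx(1.0, abs=CLIP_EPS)

    def test_unstressed_growth_rate(self, params):
        x = np.zeros(29)
        x[SIDX["Vos"]] = params.Vos0 * 1.02
        x[SIDX["CD"]] = 1.0
        obs = compute_observables(x, params)
        assert obs.mu == pytest.approx(params.mu0)
        assert 0.0 <= obs.mu <= params.mu0

    def test_degenerate_volume_raises(self, params):
        x = np.zeros(29)
        with pytest.raises(ValueError, match="volume"):
            compute_observables(x, params)


class TestReactionFluxes:
    def test_pfk_unmodulated_without_activator(self, params, eq_state):
        x = eq_state.copy()
        x[SIDX["F26DP"]] = 0.0
        v = reaction_fluxes(x, params)
        c = x[SIDX["HexP"]] / x[SIDX["Vos"]]
        assert v["vPFK"] == pytest.approx(
            params.VmPFK * c / (params.KPFK + c))

    def test_pfk_saturation_limit_of_f26dp_boost(self, params, eq_state):
        x = eq_state.copy()
        x[SIDX["F26DP"]] = 1e9
        v = reaction_fluxes(x, params)
        c = x[SIDX["HexP"]] / x[SIDX["Vos"]]
        expected = (1 + params.aF) * params.VmPFK * c / (params.KPFK + c)
        assert v["vPFK"] == pytest.approx(expected, rel=1e-6)

    def test_gpd1_flux_linear_in_dimer(self, params, eq_state):
        x = eq_state.copy()
        v1 = reaction_fluxes(x, params)["vGPD1"]
        x[SIDX["Gpd1d"]] *= 2.0
        v2 = reaction_fluxes(x, params)["vGPD1"]
        assert v2 == pytest.approx(2.0 * v1, rel=1e-12)

    def test_stl1_uptake_is_irreversible(self, params, eq_state):
        x = eq_state.copy()
        x[SIDX["Glyi"]] = 1000.0 * x[SIDX["Vos"]]   # steep outward gradient
        x[SIDX["Glye"]] = 0.01
        assert reaction_fluxes(x, params)["vSTL"] >= 0.0


class TestCarbonBookkeeping:
    def test_aldolase_and_tps_rows_balance(self):
        res = check_carbon_closure()
        assert res["vALD"] == 0          # 6 - 2*3
        assert res["vTPS"] == 0          # 2*6 - 12

    def test_every_reaction_is_carbon_balanced(self):
        res = check_carbon_closure()
        assert all(v == 0 for v in res.values()), res

    def test_stoichiometry_matches_rhs_assembly(self, params, eq_state):
        """The hand-assembled metabolite derivatives in the numeric core
        agree with an independent assembly from the stoichiometry table."""
        rng = np.random.default_rng(3)
        metabolites = ("Glci", "HexP", "FBP", "TriP", "G3P", "Glyi",
                       "Pyr", "EtOHi", "AcOi", "Trei")
        for _ in range(10):
            x = perturbed_state(eq_state, rng)
            v = reaction_fluxes(x, params)
            mu = compute_observables(x, params).mu
            dx = evaluate_rhs(x, 0.0, params)
            for sp in metabolites:
                expected = -mu * x[SIDX[sp]]
                for rxn, stoich in STOICHIOMETRY.items():
                    expected += stoich.get(sp, 0) * v[rxn]
                assert dx[SIDX[sp]] == pytest.approx(
                    expected, rel=1e-10, abs=1e-10), sp

    @pytest.mark.parametrize("strain", ["WT", "hog1D", "gpd1D", "pfk26/27D",
                                        "HOG1-att", "FPS1-D1", "stl1D"])
    def test_closed_culture_conserves_carbon(self, params, strain):
        """Medium + cells + released CO2 + biomass drain hold total carbon
        constant over 180 min within integrator tolerance."""
        from osmoadapt.fluxana import total_carbon_series
        t, c = total_carbon_series(params, strain)
        assert np.max(np.abs(c - c[0])) / c[0] < 1e-6


class TestSymbolicOracle:
    def test_symbolic_rhs_matches_numeric_core(self, params, eq_state):
        """The sympy model layer (used for SBML export) reproduces the
        numeric right-hand side at random states."""
        import sympy as sp
        from osmoadapt.symbolic import (param_symbols, state_symbols,
                                        symbolic_rhs)
        x_syms = [state_symbols()[n] for n in STATE_NAMES]
        exprs = [symbolic_rhs()[n] for n in STATE_NAMES]
        psub = {param_symbols()[n]: getattr(params, n)
                for n in oa.PARAM_NAMES}
        funcs = sp.lambdify(x_syms, [e.subs(psub) for e in exprs], "numpy")
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = perturbed_state(eq_state, rng)
            sym = np.array(funcs(*x), dtype=float)
            num = _core.rhs(0.0, x, params.to_array(), np.ones(29))
            assert np.allclose(sym, num, rtol=1e-9, atol=1e-12)
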