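"""ODE assembly, integration, plateau detection and steady-state search."""

import numpy as np
import pytest

from ribokinetics.model import (
    Metabolite,
    PathwayModel,
    RateLaw,
    RateLawKind,
    Reaction,
    mm_rate,
    reaction_rate,
)
from ribokinetics.simulation import (
    SimulationOptions,
    assemble_odes,
    detect_plateau,
    simulate,
    steady_state,
)
from ribokinetics.stoichiometry import (
    predict_boundary_fluxes,
    stoichiometric_matrix,
)
from ribokinetics.synthetic import toy_linear_chain


def _mm1(vmax, km):
    return RateLaw(kind=RateLawKind.MM1, vmax=vmax, km_a=km)


def _single_mm_model(vmax=1.0, km=100.0, s0=1000.0):
    """Closed S -> P conversion (both species dynamic)."""
    mets = (Metabolite("S", "substrate", s0), Metabolite("P", "product", 0.0))
    reactions = (
        Reaction("CONV", "E", (("S", 1),), (("P", 1),), _mm1(vmax, km)),
    )
    return PathwayModel(metabolites=mets, reactions=reactions)


from tests_helpers import rk4_reference as _rk4_reference


class TestAssembleOdes:
    def test_all_rates_zero_gives_zero_derivative(self):
        model = _single_mm_model(vmax=0.0)
        rhs = assemble_odes(model)
        assert np.allclose(rhs(0.0, np.array([1000.0, 0.0])), 0.0)

    def test_single_reaction_signs(self):
        model = _single_mm_model(vmax=2.0, km=50.0)
        rhs = assemble_odes(model)
        dy = rhs(0.0, np.array([50.0, 0.0]))
        assert dy[0] == pytest.approx(-1.0)  # half-saturation
        assert dy[1] == pytest.approx(+1.0)

    def test_boundary_species_have_zero_derivative(self):
        chain = toy_linear_chain(1, [5.0], [100.0], import_flux=1.0)
        rhs = assemble_odes(chain)
        mids = chain.metabolite_ids()
        dy = rhs(0.0, np.array([100.0 if m != "SINK" else 0.0 for m in mids]))
        assert dy[mids.index("SINK")] == 0.0

    def test_unresolved_boundary_flux_raises_with_reaction_name(self, default_model):
        with pytest.raises(ValueError, match="GTP_IMPORT"):
            assemble_odes(default_model)

    def test_default_model_matches_matrix_vector_oracle(self, resolved_model):
        """dC/dt equals S times the independently evaluated flux vector."""
        rhs = assemble_odes(resolved_model)
        state = resolved_model.initial_state()
        smat = stoichiometric_matrix(resolved_model)
        v = np.array([reaction_rate(r, state) for r in resolved_model.reactions])
        expected = smat.matrix.astype(float) @ v
        mids = resolved_model.metabolite_ids()
        dy = rhs(0.0, np.array([state[m] for m in mids]))
        internal = [mids.index(m) for m in smat.rows]
        assert np.allclose(dy[internal], expected, rtol=1e-12, atol=1e-12)


class TestSimulate:
    def test_zero_rate_model_stays_at_initial_conditions(self):
        model = _single_mm_model(vmax=0.0, s0=123.0)
        traj = simulate(model, t_end=100.0)
        assert np.allclose(traj.concentrations[:, 0], 123.0)
        assert np.allclose(traj.concentrations[:, 1], 0.0)
        assert traj.times[0] == 0.0 and traj.times[-1] == 100.0

    def test_first_row_equals_initial_conditions(self, resolved_model):
        traj = simulate(resolved_model, t_end=10.0)
        y0 = [m.initial_concentration for m in resolved_model.metabolites]
        assert np.allclose(traj.concentrations[0], y0, rtol=0, atol=0)

    def test_stiff_solver_matches_fine_step_rk4_oracle(self):
        """LSODA agrees with a dt=1e-3 fixed-step RK4 reference within 1e-4."""
        model = _single_mm_model(vmax=1.0, km=100.0, s0=1000.0)
        traj = simulate(model, t_end=500.0, options=SimulationOptions(rtol=1e-8, atol=1e-10))
        ref = _rk4_reference(assemble_odes(model), [1000.0, 0.0], 500.0, dt=1e-3)
        assert traj.concentrations[-1, 0] == pytest.approx(ref[0], rel=1e-4)
        assert traj.concentrations[-1, 1] == pytest.approx(ref[1], rel=1e-4)

    def test_chain_agrees_with_rk4_oracle(self):
        chain = toy_linear_chain(2, [5.0, 4.0], [200.0, 300.0], import_flux=1.0)
        traj = simulate(chain, t_end=200.0, options=SimulationOptions(rtol=1e-8, atol=1e-10))
        mids = chain.metabolite_ids()
        y0 = np.array([chain.metabolite(m).initial_concentration for m in mids])
        ref = _rk4_reference(assemble_odes(chain), y0, 200.0, dt=1e-3)
        assert np.allclose(traj.concentrations[-1], ref, rtol=1e-4)

    def test_output_grid_density_does_not_change_values(self, resolved_model):
        """Dense output decouples reported values from the output grid."""
        coarse = simulate(resolved_model, t_end=300.0, options=SimulationOptions(n_points=11))
        fine = simulate(resolved_model, t_end=300.0, options=SimulationOptions(n_points=21))
        shared = np.intersect1d(coarse.times, fine.times)
        ci = [list(coarse.times).index(t) for t in shared]
        fi = [list(fine.times).index(t) for t in shared]
        denom = np.maximum(np.abs(coarse.concentrations[ci]), 1e-30)
        rel = np.abs(coarse.concentrations[ci] - fine.concentrations[fi]) / denom
        assert np.max(rel) < 1e-8

    def test_default_model_riboflavin_plateaus_by_1500s(self, resolved_model):
        traj = simulate(resolved_model, t_end=1500.0)
        assert detect_plateau(traj, "RIBO", rel_tol=1e-3, window=150.0) is not None

    def test_trajectories_stay_non_negative(self, resolved_model):
        opts = SimulationOptions()
        traj = simulate(resolved_model, t_end=1500.0, options=opts)
        assert np.min(traj.concentrations) >= 0.0  # clipped at -10*atol worst case

    def test_rejects_non_positive_horizon(self, resolved_model):
        with pytest.raises(ValueError, match="t_end"):
            simulate(resolved_model, t_end=0.0)

    def test_divergence_raises(self):
        """An import with no consumer grows without bound and trips the ceiling."""
        mets = (Metabolite("A", "A", 0.0), Metabolite("B", "B", 1.0))
        reactions = (
            Reaction("IMP", "t", (), (("A", 1),),
                     RateLaw(kind=RateLawKind.BOUNDARY_FLUX, flux=1e9)),
            Reaction("AB", "e", (("A", 1),), (("B", 1),), _mm1(1e-3, 1.0)),
            Reaction("BX", "e", (("B", 1),), (), _mm1(1e-3, 1.0)),
        )
        model = PathwayModel(metabolites=mets, reactions=reactions)
        with pytest.raises(RuntimeError, match="diverged"):
            simulate(model, t_end=1e6, options=SimulationOptions(conc_ceiling=1e10))


class TestDetectPlateau:
    def _traj_from_series(self, times, values):
        from ribokinetics.simulation import Trajectory

        model = _single_mm_model()
        return Trajectory(
            times=np.asarray(times, float),
            concentrations=np.column_stack([values, np.zeros_like(values)]),
            metabolite_ids=("S", "P"),
            model=model,
        )

    def test_constant_series_plateaus_immediately(self):
        t = np.linspace(0, 1000, 101)
        traj = self._traj_from_series(t, np.full_like(t, 42.0))
        assert detect_plateau(traj, "S", rel_tol=1e-3, window=100.0) == 0.0

    def test_steep_linear_series_never_plateaus(self):
        t = np.linspace(0, 1000, 101)
        traj = self._traj_from_series(t, 1.0 + t)  # relative slope >> tolerance
        assert detect_plateau(traj, "S", rel_tol=1e-3, window=100.0) is None

    def test_exponential_approach_matches_exhaustive_scan(self):
        t = np.linspace(0, 1000, 2001)
        c = 100.0 * (1.0 - np.exp(-t / 50.0))
        traj = self._traj_from_series(t, c)
        rel_tol, window = 0.01, 100.0
        found = detect_plateau(traj, "S", rel_tol=rel_tol, window=window)
        # independent brute-force scan over the sampled grid
        expected = None
        for i, t0 in enumerate(t):
            if t0 + window > t[-1]:
                break
            seg = c[(t >= t0) & (t <= t0 + window)]
            if np.max(np.abs(seg - c[i])) / max(c[i], 1e-12) < rel_tol:
                expected = t0
                break
        assert found == pytest.approx(expected)

    def test_unknown_species_raises(self, resolved_model):
        traj = simulate(resolved_model, t_end=10.0)
        with pytest.raises(KeyError, match="NADH"):
            detect_plateau(traj, "NADH", window=1.0)

    def test_window_must_fit_in_trajectory(self, resolved_model):
        traj = simulate(resolved_model, t_end=10.0)
        with pytest.raises(ValueError, match="window"):
            detect_plateau(traj, "RIBO", window=20.0)


class TestSteadyState:
    def test_zero_rate_model_converges_at_initial_state(self):
        model = _single_mm_model(vmax=0.0, s0=55.0)
        res = steady_state(model)
        assert res.converged
        assert res.residual == 0.0
        assert res.state["S"] == pytest.approx(55.0)

    def test_chain_steady_state_matches_closed_form(self):
        """For import flux f and MM consumption, A_ss = f*km/(vmax-f)."""
        f, vmax, km = 0.8, 2.0, 150.0
        chain = toy_linear_chain(1, [vmax], [km], import_flux=f)
        res = steady_state(chain, t_max=1e5)
        assert res.converged
        assert res.state["M1"] == pytest.approx(f * km / (vmax - f), rel=1e-6)

    def test_three_step_chain_matches_per_step_closed_form(self):
        f = 0.5
        vmaxes, kms = [2.0, 1.5, 3.0], [100.0, 250.0, 50.0]
        chain = toy_linear_chain(3, vmaxes, kms, import_flux=f)
        res = steady_state(chain, t_max=1e5)
        assert res.converged
        for i, (v, k) in enumerate(zip(vmaxes, kms), start=1):
            assert res.state[f"M{i}"] == pytest.approx(f * k / (v - f), rel=1e-6)

    def test_overloaded_chain_does_not_converge(self):
        """Import above the weakest Vmax cannot be carried: the pool accumulates."""
        chain = toy_linear_chain(1, [1.0], [100.0], import_flux=2.0)
        res = steady_state(chain, t_max=500.0)
        assert not res.converged
        assert res.state["M1"] > 100.0  # linear accumulation

    def test_default_model_converges_within_1500s(self, resolved_model):
        res = steady_state(resolved_model, tol=1e-6, t_max=1500.0)
        assert res.converged
        assert res.residual < 1e-6

    def test_steady_state_balances_production_and_consumption(self, resolved_model):
        """At steady state every internal pool's production equals consumption."""
        res = steady_state(resolved_model, tol=1e-9, t_max=1e5)
        assert res.converged
        state = res.state
        smat = stoichiometric_matrix(resolved_model)
        for i, mid in enumerate(smat.rows):
            production = consumption = 0.0
            for j, r in enumerate(resolved_model.reactions):
                flux = reaction_rate(r, state)
                coeff = smat.matrix[i, j]
                if coeff > 0:
                    production += coeff * flux
                elif coeff < 0:
                    consumption += -coeff * flux
            assert production == pytest.approx(consumption, rel=1e-6, abs=1e-9)
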