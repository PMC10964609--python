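"""Stoichiometric matrix, mass-balance closure, and the LP flux mode."""


import numpy as np
import pytest

from ribokinetics.model import (
    Metabolite,
    PathwayModel,
    RateLaw,
    RateLawKind,
    Reaction,
    reaction_rate,
)
from ribokinetics.stoichiometry import (
    FluxVector,
    fba_fluxes,
    predict_boundary_fluxes,
    stoichiometric_matrix,
)
from ribokinetics.synthetic import toy_linear_chain


def _mm1(vmax, km):
    return RateLaw(kind=RateLawKind.MM1, vmax=vmax, km_a=km)


def _bf(flux=None):
    return RateLaw(kind=RateLawKind.BOUNDARY_FLUX, flux=flux)


@pytest.fixture
def toy_chain_model():
    """import -> A -> B -> export with a kinetic middle step."""
    mets = (
        Metabolite("A", "A", 100.0),
        Metabolite("B", "B", 50.0),
    )
    reactions = (
        Reaction("IMP", "transport", (), (("A", 1),), _bf()),
        Reaction("MID", "E", (("A", 1),), (("B", 1),), _mm1(vmax=6.0, km=100.0)),
        Reaction("EXP", "transport", (("B", 1),), (), _bf()),
    )
    return PathwayModel(metabolites=mets, reactions=reactions)


class TestMatrix:
    def test_toy_chain_matrix(self, toy_chain_model):
        smat = stoichiometric_matrix(toy_chain_model)
        assert smat.rows == ("A", "B")
        assert smat.cols == ("IMP", "MID", "EXP")
        assert smat.matrix.tolist() == [[1, -1, 0], [0, 1, -1]]

    def test_default_model_rows_balanced(self, default_model):
        """Every internal metabolite has at least one producer and consumer."""
        smat = stoichiometric_matrix(default_model)
        assert smat.matrix.shape == (12, 14)
        for i, mid in enumerate(smat.rows):
            row = smat.matrix[i]
            assert (row > 0).any(), f"{mid} has no producer"
            assert (row < 0).any(), f"{mid} has no consumer"

    def test_orphan_metabolite_gives_zero_row(self, toy_chain_model):
        model = PathwayModel(
            metabolites=toy_chain_model.metabolites + (Metabolite("C", "C", 1.0),),
            reactions=toy_chain_model.reactions,
        )
        smat = stoichiometric_matrix(model)
        assert not smat.row("C").any()

    def test_column_permutation_invariance(self, default_model):
        """Reaction declaration order only permutes the columns."""
        shuffled = PathwayModel(
            metabolites=default_model.metabolites,
            reactions=tuple(reversed(default_model.reactions)),
        )
        s1 = stoichiometric_matrix(default_model)
        s2 = stoichiometric_matrix(shuffled)
        perm = [s2.cols.index(c) for c in s1.cols]
        assert np.array_equal(s2.matrix[:, perm], s1.matrix)
        assert s1.rows == s2.rows


class TestClosure:
    def test_toy_chain_import_export_match_middle_flux(self, toy_chain_model):
        fv = predict_boundary_fluxes(toy_chain_model)
        middle = reaction_rate(toy_chain_model.reaction("MID"), {"A": 100.0, "B": 50.0})
        assert middle == pytest.approx(3.0)
        assert fv["IMP"] == pytest.approx(3.0)
        assert fv["EXP"] == pytest.approx(3.0)
        assert fv.residual < 1e-9

    def test_default_gtp_import_equals_gtpchii_rate(self, default_model):
        """GTP has a single producer and consumer, so closure copies the rate."""
        fv = predict_boundary_fluxes(default_model)
        gtpchii = reaction_rate(
            default_model.reaction("GTPCHII"), default_model.initial_state()
        )
        assert fv["GTP_IMPORT"] == pytest.approx(gtpchii, rel=1e-12)

    def test_closure_exact_on_default_model(self, default_model):
        """S.v = 0 on the closure system, to numerical precision."""
        fv = predict_boundary_fluxes(default_model)
        smat = stoichiometric_matrix(default_model)
        sv = smat.matrix.astype(float) @ fv.values
        predicted_cols = [
            j for j, p in enumerate(fv.provenance) if p == "predicted"
        ]
        touched = np.any(smat.matrix[:, predicted_cols] != 0, axis=1)
        assert np.max(np.abs(sv[touched])) < 1e-9

    def test_matches_dense_gaussian_elimination_oracle(self):
        """Closure on a random branched 4-metabolite network equals np.linalg.solve."""
        rng = np.random.default_rng(7)
        # diamond: unknown import into A, kinetic A->B, A->C, B->D, C->D,
        # unknown export of D; closure rows are the A and D balances
        mets = tuple(Metabolite(m, m, float(rng.uniform(50, 500))) for m in "ABCD")
        reactions = (
            Reaction("IMP_A", "t", (), (("A", 1),), _bf()),
            Reaction("AB", "e1", (("A", 1),), (("B", 1),), _mm1(5.0, 200.0)),
            Reaction("AC", "e2", (("A", 1),), (("C", 1),), _mm1(3.0, 150.0)),
            Reaction("BD", "e3", (("B", 1),), (("D", 1),), _mm1(4.0, 100.0)),
            Reaction("CD", "e4", (("C", 1),), (("D", 1),), _mm1(2.0, 400.0)),
            Reaction("EXP_D", "t", (("D", 1),), (), _bf()),
        )
        model = PathwayModel(metabolites=mets, reactions=reactions)
        fv = predict_boundary_fluxes(model)

        state = model.initial_state()
        kinetic = {r.id: reaction_rate(r, state) for r in reactions if r.id not in ("IMP_A", "EXP_D")}
        # rows A and D contain the unknowns; solve the 2x2 system explicitly
        A = np.array([[1.0, 0.0], [0.0, -1.0]])  # columns IMP_A, EXP_D
        b = np.array(
            [
                kinetic["AB"] + kinetic["AC"],  # A balance
                -(kinetic["BD"] + kinetic["CD"]),  # D balance
            ]
        )
        expected = np.linalg.solve(A, b)
        assert fv["IMP_A"] == pytest.approx(expected[0], rel=1e-12)
        assert fv["EXP_D"] == pytest.approx(expected[1], rel=1e-12)

    def test_singular_closure_raises(self):
        """Two unknown imports feeding the same single balance are unconstrained."""
        mets = (Metabolite("A", "A", 10.0),)
        reactions = (
            Reaction("IMP1", "t", (), (("A", 1),), _bf()),
            Reaction("IMP2", "t", (), (("A", 1),), _bf()),
            Reaction("SINK", "e", (("A", 1),), (), _mm1(2.0, 10.0)),
        )
        model = PathwayModel(metabolites=mets, reactions=reactions)
        with pytest.raises(ValueError, match="singular"):
            predict_boundary_fluxes(model)


from tests_helpers import enumerate_vertices as _enumerate_vertices


class TestFBA:
    def test_toy_chain_hits_upper_bound(self, toy_chain_model):
        smat = stoichiometric_matrix(toy_chain_model)
        bounds = {r: (0.0, 10.0) for r in smat.cols}
        fv = fba_fluxes(smat, bounds, objective="EXP")
        assert fv["EXP"] == pytest.approx(10.0)

    def test_branched_network_sums_path_capacities(self):
        """Two parallel routes into a sink: optimum is the sum of the caps."""
        mets = (Metabolite("A", "A"), Metabolite("B", "B"), Metabolite("D", "D"))
        reactions = (
            Reaction("IMP_A", "t", (), (("A", 1),), _bf(0.0)),
            Reaction("IMP_B", "t", (), (("B", 1),), _bf(0.0)),
            Reaction("AD", "e", (("A", 1),), (("D", 1),), _mm1(1.0, 1.0)),
            Reaction("BD", "e", (("B", 1),), (("D", 1),), _mm1(1.0, 1.0)),
            Reaction("EXP_D", "t", (("D", 1),), (), _bf(0.0)),
        )
        model = PathwayModel(metabolites=mets, reactions=reactions)
        smat = stoichiometric_matrix(model)
        bounds = {r: (0.0, 10.0) for r in smat.cols}
        bounds["AD"] = (0.0, 3.0)  # one path capped at 3
        bounds["BD"] = (0.0, 4.0)
        fv = fba_fluxes(smat, bounds, objective="EXP_D")
        assert fv["EXP_D"] == pytest.approx(7.0)
        best = max(v[smat.cols.index("EXP_D")] for v in _enumerate_vertices(smat, bounds))
        assert fv["EXP_D"] == pytest.approx(best)

    def test_cycle_without_import_carries_nothing(self):
        mets = (Metabolite("A", "A"), Metabolite("B", "B"))
        reactions = (
            Reaction("IMP", "t", (), (("A", 1),), _bf(0.0)),
            Reaction("AB", "e", (("A", 1),), (("B", 1),), _mm1(1.0, 1.0)),
            Reaction("BA", "e", (("B", 1),), (("A", 1),), _mm1(1.0, 1.0)),
            Reaction("EXP", "t", (("A", 1),), (), _bf(0.0)),
        )
        model = PathwayModel(metabolites=mets, reactions=reactions)
        smat = stoichiometric_matrix(model)
        bounds = {"IMP": (0.0, 0.0), "AB": (0.0, 5.0), "BA": (0.0, 5.0), "EXP": (0.0, 5.0)}
        fv = fba_fluxes(smat, bounds, objective="EXP")
        assert fv["EXP"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_vertex_enumeration_on_random_small_networks(self, chain3):
        smat = stoichiometric_matrix(chain3)
        rng = np.random.default_rng(11)
        for _ in range(5):
            bounds = {r: (0.0, float(rng.uniform(1.0, 10.0))) for r in smat.cols}
            fv = fba_fluxes(smat, bounds, objective="EXPORT")
            vertices = _enumerate_vertices(smat, bounds)
            best = max(v[smat.cols.index("EXPORT")] for v in vertices)
            assert fv["EXPORT"] == pytest.approx(best, rel=1e-9, abs=1e-9)

    def test_infeasible_bounds_raise(self, toy_chain_model):
        smat = stoichiometric_matrix(toy_chain_model)
        bounds = {"IMP": (5.0, 10.0), "MID": (0.0, 1.0), "EXP": (0.0, 10.0)}
        with pytest.raises(ValueError, match="infeasible"):
            fba_fluxes(smat, bounds, objective="EXP")
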