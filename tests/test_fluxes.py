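import numpy as np
import pytest

import glk
from glk.errors import InfeasibleProblem, UnboundedProblem
from glk.fluxes import (
    center_fluxes,
    fit_target_fluxes,
    flux_variability,
    minimize_total_flux,
    solve_fba,
)

from conftest import centred_problem


def _chain_problem(size=3, uptake=None):
    net, _ = glk.make_fixture(glk.FixtureSpec("chain", size=size))
    p = glk.problem_from_network(net, objective_reaction=f"R{size - 1}")
    if uptake is not None:
        p.upper_bounds[p.column("R0")] = uptake
    return p


def _diamond_problem(**kw):
    net, known = glk.make_fixture(glk.FixtureSpec("diamond"))
    p = glk.problem_from_network(net, **kw)
    return p, known


class TestFBA:
    def test_chain_capacity_bound(self):
        p = _chain_problem(uptake=1.0)
        z, v = solve_fba(p)
        assert z == pytest.approx(1.0)
        assert np.allclose(p.N @ v, 0, atol=1e-9)

    def test_blocked_reaction_zero(self):
        # a side reaction with no route back to the boundary carries no flux
        from glk import Species, Reaction, MetabolicNetwork, Compartment

        net = MetabolicNetwork(
            [Species("X", compartment="e", is_boundary=True),
             Species("A", compartment="c"), Species("D", compartment="c")],
            [Reaction("R_in", stoichiometry={"X": -1, "A": 1}),
             Reaction("R_out", stoichiometry={"A": -1, "X": 1}),
             Reaction("R_dead", stoichiometry={"A": -1, "D": 1})],
            [Compartment("c", 1.0, "intracellular"),
             Compartment("e", 1.0, "extracellular")],
        )
        p = glk.problem_from_network(net, objective_reaction="R_dead")
        z, _ = solve_fba(p)
        assert z == pytest.approx(0.0, abs=1e-9)

    def test_diamond_parallel_routes(self):
        p, _ = _diamond_problem(objective_reaction="R_out")
        p.upper_bounds[p.column("R_in")] = 1.5
        p.upper_bounds[p.column("R_b1")] = 1.0
        p.upper_bounds[p.column("R_b2")] = 1.0
        z, _ = solve_fba(p)
        assert z == pytest.approx(1.5)

    def test_infeasible_signalled(self):
        p = _chain_problem()
        p.lower_bounds[p.column("R0")] = 2.0
        p.upper_bounds[p.column("R0")] = 2.0
        p.upper_bounds[p.column("R1")] = 1.0
        with pytest.raises(InfeasibleProblem):
            solve_fba(p)

    def test_unbounded_signalled(self):
        # reversible 2-cycle with no bounds: objective grows without limit
        from glk import Species, Reaction, MetabolicNetwork, Compartment

        net = MetabolicNetwork(
            [Species("A", compartment="c"), Species("B", compartment="c")],
            [Reaction("R1", stoichiometry={"A": -1, "B": 1},
                      reversible=True),
             Reaction("R2", stoichiometry={"B": -1, "A": 1},
                      reversible=True)],
            [Compartment("c", 1.0, "intracellular")],
        )
        p = glk.problem_from_network(net, objective_reaction="R1",
                                     default_bound=1.0)
        p.lower_bounds[:] = -np.inf
        p.upper_bounds[:] = np.inf
        with pytest.raises(UnboundedProblem):
            solve_fba(p)


class TestTargetFitting:
    def test_achievable_target(self):
        p = _chain_problem()
        p.targets = {"R1": 0.7}
        d, v = fit_target_fluxes(p)
        assert d == pytest.approx(0.0, abs=1e-9)
        assert v[p.column("R1")] == pytest.approx(0.7)

    def test_coupled_chain_conflicting_targets(self):
        # fluxes on a 2-step chain are equal; targets 1 and 2 leave a
        # piecewise-linear misfit minimized at 1 anywhere in [1, 2]
        p = _chain_problem(size=2)
        p.targets = {"R0": 1.0, "R1": 2.0}
        d, v = fit_target_fluxes(p)
        assert d == pytest.approx(1.0)
        assert 1.0 - 1e-9 <= v[0] <= 2.0 + 1e-9

    def test_l2_norm_option(self):
        p = _chain_problem(size=2)
        p.targets = {"R0": 1.0, "R1": 2.0}
        d, v = fit_target_fluxes(p, norm="l2")
        # least squares puts the common flux at the mean 1.5
        assert v[0] == pytest.approx(1.5, abs=1e-6)
        assert d == pytest.approx(0.5, abs=1e-6)

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_target_fluxes(_chain_problem())


class TestTotalFlux:
    def test_chain_forced_export(self):
        net, _ = glk.make_fixture(glk.FixtureSpec("chain", size=4))
        p = glk.problem_from_network(net)
        p.lower_bounds[p.column("R3")] = 1.0
        p.upper_bounds[p.column("R3")] = 1.0
        z1, _ = minimize_total_flux(p)
        assert z1 == pytest.approx(4.0)

    def test_diamond_forced_export(self):
        p, known = _diamond_problem()
        p.lower_bounds[p.column("R_out")] = 1.0
        p.upper_bounds[p.column("R_out")] = 1.0
        z1, _ = minimize_total_flux(p)
        assert z1 == pytest.approx(known["Z_1_at_export_1"])

    def test_zero_flux_feasible(self):
        p, _ = _diamond_problem()
        z1, v = minimize_total_flux(p)
        assert z1 == pytest.approx(0.0, abs=1e-9)


class TestFluxVariability:
    def test_pointlike_chain(self):
        net, _ = glk.make_fixture(glk.FixtureSpec("chain", size=3))
        p = glk.problem_from_network(net)
        p.lower_bounds[p.column("R2")] = 1.0
        p.upper_bounds[p.column("R2")] = 1.0
        lo, hi = flux_variability(p)
        assert np.allclose(lo, 1.0, atol=1e-9)
        assert np.allclose(hi, 1.0, atol=1e-9)

    def test_diamond_branches_under_total_flux_budget(self):
        p, _ = _diamond_problem()
        p.lower_bounds[p.column("R_out")] = 1.0
        p.upper_bounds[p.column("R_out")] = 1.0
        from glk.fluxes import _LPModel

        model = _LPModel(p)
        model.add_l1_budget(np.arange(p.n), np.zeros(p.n), 3.0 + 1e-9)
        lo, hi = flux_variability(p, model)
        for rid in ("R_b1", "R_b2"):
            j = p.column(rid)
            assert lo[j] == pytest.approx(0.0, abs=1e-7)
            assert hi[j] == pytest.approx(1.0, abs=1e-7)

    def test_idempotent_on_point(self):
        net, _ = glk.make_fixture(glk.FixtureSpec("chain", size=2))
        p = glk.problem_from_network(net)
        p.lower_bounds[:] = 1.0
        p.upper_bounds[:] = 1.0
        lo1, hi1 = flux_variability(p)
        lo2, hi2 = flux_variability(p)
        assert np.array_equal(lo1, lo2) and np.array_equal(hi1, hi2)


class TestCentering:
    def test_diamond_symmetric_split(self, diamond):
        net, known = diamond
        p = centred_problem(net, known)
        res = center_fluxes(p)
        assert res.converged
        for rid, expected in known["centred_fluxes"].items():
            assert res.flux(rid) == pytest.approx(expected, abs=1e-6)

    def test_bounds_nested_and_monotone(self, diamond):
        net, known = diamond
        res = center_fluxes(centred_problem(net, known))
        for (lo0, hi0, _), (lo1, hi1, _) in zip(res.iterations,
                                                res.iterations[1:]):
            assert np.all(lo1 >= lo0 - 1e-7)
            assert np.all(hi1 <= hi0 + 1e-7)
        widths = [float(np.max(hi - lo)) for lo, hi, _ in res.iterations]
        assert all(b <= a + 1e-9 for a, b in zip(widths, widths[1:]))

    def test_pointlike_converges_in_one_iteration(self, chain3):
        net, known = chain3
        p = glk.problem_from_network(net)
        j = p.column(known["uptake_reaction"])
        p.lower_bounds[j] = 1.0
        p.upper_bounds[j] = 1.0
        res = center_fluxes(p)
        assert res.converged and len(res.iterations) == 1
        assert np.allclose(res.v_star, known["v_star"], atol=1e-9)

    def test_steady_state_residual(self, diamond):
        net, known = diamond
        p = centred_problem(net, known)
        res = center_fluxes(p)
        assert np.max(np.abs(p.N @ res.v_star)) <= 1e-9

    def test_total_flux_bound_respected(self, diamond):
        net, known = diamond
        res = center_fluxes(centred_problem(net, known))
        assert np.sum(np.abs(res.v_star)) <= res.Z_1 + 1e-5

    def test_relabelling_invariance(self, diamond):
        net, known = diamond
        p = centred_problem(net, known)
        res = center_fluxes(p)
        perm = [2, 0, 3, 1]
        q = glk.FluxProblem(
            N=p.N[:, perm],
            reaction_ids=[p.reaction_ids[j] for j in perm],
            objective=p.objective[perm],
            lower_bounds=p.lower_bounds[perm],
            upper_bounds=p.upper_bounds[perm],
            targets=dict(p.targets),
        )
        res_p = center_fluxes(q)
        for rid in p.reaction_ids:
            assert res_p.flux(rid) == pytest.approx(res.flux(rid),
                                                    abs=1e-6)

    def test_lexicographic_stages_with_objective_and_targets(self):
        p = _chain_problem(size=3, uptake=2.0)
        p.targets = {"R1": 0.5}
        res = center_fluxes(p)
        # growth optimality takes precedence: fluxes pinned at the maximum
        assert res.Z_star == pytest.approx(2.0)
        assert np.allclose(res.v_star, 2.0, atol=1e-5)
        assert res.target_misfit == pytest.approx(1.5, abs=1e-5)

    def test_targets_first_ordering_drops_growth(self):
        p = _chain_problem(size=3, uptake=2.0)
        p.targets = {"R1": 0.5}
        res = center_fluxes(p, objective_ordering="targets-first")
        assert res.Z_star is None
        assert np.allclose(res.v_star, 0.5, atol=1e-5)

    def test_moiety_cycle_targets(self, moiety_cycle):
        net, known = moiety_cycle
        p = centred_problem(net, known)
        res = center_fluxes(p)
        assert res.converged
        assert np.allclose(res.v_star, known["v_star"], atol=1e-6)
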