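"""FBA/FVA/essentiality/gap-fill against independent oracles.

The vertex-enumeration oracle solves small bounded LPs exactly by walking
every basic solution; the gap-fill oracle enumerates candidate subsets.
cobrapy (its own stack: optlang/GLPK) serves as an external cross-check of
FBA optima read back from our SBML output.
"""

import itertools

import numpy as np
import pytest

from fluxcouple import (
    GPR,
    Metabolite,
    MetabolicModel,
    Reaction,
    ReactionKind,
    UnboundedObjectiveError,
    compare_to_mfa,
    essentiality_screen,
    fba,
    fva,
    megs_design,
    min_additions_gapfill,
    node_balance_report,
    uptake_sweep,
    write_model,
)
from fluxcouple.fba import knockout_bounds
from fluxcouple.synth import PlantedNetworkSpec, make_toy_model

# ------------------------------------------------------------- oracles ----

def enumerate_vertices_optimum(S, lb, ub, c):
    """Exact LP optimum max c.v s.t. S v = 0, lb <= v <= ub by enumerating
    basic solutions (nonbasic variables pinned to a bound)."""
    m, n = S.shape
    best = None
    for nonbasic in itertools.combinations(range(n), n - m):
        basic = [j for j in range(n) if j not in nonbasic]
        B = S[:, basic]
        if abs(np.linalg.det(B)) < 1e-10:
            continue
        for choices in itertools.product((0, 1), repeat=len(nonbasic)):
            x = np.zeros(n)
            for j, ch in zip(nonbasic, choices):
                x[j] = lb[j] if ch == 0 else ub[j]
            rhs = -S[:, nonbasic] @ x[list(nonbasic)]
            x_b = np.linalg.solve(B, rhs)
            x[basic] = x_b
            if np.all(x >= lb - 1e-8) and np.all(x <= ub + 1e-8):
                val = float(c @ x)
                if best is None or val > best:
                    best = val
    return best


def random_bounded_model(seed):
    """S = [I | R] with finite bounds: full row rank, bounded, feasible."""
    rng = np.random.default_rng(seed)
    m, n = 3, 7
    R = rng.integers(-2, 3, size=(m, n - m)).astype(float)
    S = np.hstack([np.eye(m), R])
    mets = [Metabolite(f"m{i}_c", formula="C") for i in range(m)]
    rxns = []
    for j in range(n):
        stoich = {f"m{i}_c": S[i, j] for i in range(m) if S[i, j] != 0}
        if not stoich:
            stoich = {"m0_c": 1.0}
            S[0, j] = 1.0
        lb = float(-rng.integers(0, 5))
        ub = float(rng.integers(0, 6))
        rxns.append(Reaction(f"R{j}", stoich, lb, ub,
                             kind=ReactionKind.SINK if len(stoich) == 1
                             else ReactionKind.METABOLIC))
    model = MetabolicModel(id=f"lp{seed}", metabolites=mets, reactions=rxns)
    return model, S


# ----------------------------------------------------------------- FBA ----

class TestFBA:
    def test_stoichiometric_doubling(self, fermentation_model):
        sol = fba(fermentation_model, "EX_eth_e")
        # glc uptake 10 -> 2 pyr -> 2 ethanol
        assert sol.objective_value == pytest.approx(20.0)
        assert sol.fluxes["GLY"] == pytest.approx(10.0)

    def test_steady_state_and_bounds(self, fermentation_model):
        sol = fba(fermentation_model)
        S = fermentation_model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r.id] for r in fermentation_model.reactions])
        assert np.abs(S @ v).max() <= 1e-6
        lb, ub = fermentation_model.bounds()
        assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)

    def test_lactate_style_zero_constraint(self, fermentation_model):
        sol = fba(fermentation_model, "EX_eth_e",
                  extra_constraints=[("BIOMASS", 0.0)])
        assert sol.fluxes["BIOMASS"] == pytest.approx(0.0)
        assert sol.objective_value == pytest.approx(20.0)

    def test_infeasible_is_reported_not_raised(self, chain_model):
        # force biomass while the only pathway is closed
        sol = fba(chain_model, extra_constraints=[("GLY", (0.0, 0.0)),
                                                  ("BIOMASS", (1.0, 1.0))])
        assert not sol.feasible and sol.objective_value == 0.0

    def test_unbounded_objective_names_a_ray_member(self):
        mets = [Metabolite("a_c", formula="C")]
        rxns = [
            Reaction("SRC_a", {"a_c": 1.0}, 0.0, np.inf, kind=ReactionKind.SINK),
            Reaction("OBJ", {"a_c": -1.0}, 0.0, np.inf, kind=ReactionKind.SINK),
        ]
        model = MetabolicModel(id="unb", metabolites=mets, reactions=rxns)
        with pytest.raises(UnboundedObjectiveError):
            fba(model, "OBJ")

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_vertex_enumeration_oracle(self, seed):
        model, S = random_bounded_model(seed)
        lb, ub = model.bounds()
        c = np.zeros(len(model.reactions))
        c[-1] = 1.0
        expected = enumerate_vertices_optimum(S, lb, ub, c)
        sol = fba(model, model.reactions[-1].id)
        assert sol.feasible and expected is not None
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    def test_cobra_cross_check(self, fermentation_model, tmp_path):
        cobra = pytest.importorskip("cobra")
        path = str(tmp_path / "ferm.xml")
        write_model(fermentation_model, path, "sbml")
        cmodel = cobra.io.read_sbml_model(path)
        ours = fba(fermentation_model).objective_value
        theirs = cmodel.optimize().objective_value
        assert ours == pytest.approx(theirs, rel=1e-6)


# ----------------------------------------------------------------- FVA ----

class TestFVA:
    def test_linear_chain_fully_determined(self, chain_model):
        ranges = fva(chain_model)
        for fr in ranges:
            assert fr.minimum == pytest.approx(fr.maximum, abs=1e-6)

    def test_parallel_branches_share_range(self, fermentation_model):
        # split FERM into two equivalent branches -> each ranges [0, total]
        rxns = [r for r in fermentation_model.reactions if r.id != "FERM"]
        for rid in ("FERM_A", "FERM_B"):
            rxns.append(Reaction(rid, {"pyr_c": -1.0, "eth_c": 1.0, "co2_c": 1.0},
                                 0.0, 1000.0))
        model = fermentation_model.with_reactions(rxns)
        ranges = {fr.reaction_id: fr
                  for fr in fva(model, "EX_eth_e", reactions=["FERM_A", "FERM_B"])}
        for rid in ("FERM_A", "FERM_B"):
            assert ranges[rid].minimum == pytest.approx(0.0, abs=1e-6)
            assert ranges[rid].maximum == pytest.approx(20.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_direct_two_lp_oracle(self, seed):
        from scipy.optimize import linprog

        model, S = random_bounded_model(seed)
        lb, ub = model.bounds()
        obj_id = model.reactions[-1].id
        opt = fba(model, obj_id).objective_value
        lb_fix = lb.copy()
        lb_fix[-1] = opt - 1e-9
        got = {fr.reaction_id: fr for fr in fva(model, obj_id)}
        for j, r in enumerate(model.reactions):
            c = np.zeros(len(lb))
            c[j] = 1.0
            lo = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                         bounds=np.column_stack([lb_fix, ub]), method="highs")
            hi = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                         bounds=np.column_stack([lb_fix, ub]), method="highs")
            assert got[r.id].minimum == pytest.approx(lo.fun, abs=1e-6)
            assert got[r.id].maximum == pytest.approx(-hi.fun, abs=1e-6)


# -------------------------------------------------------- essentiality ----

class TestEssentiality:
    def test_isozyme_survives_and_subunit_does_not(self, fermentation_model):
        calls = {c.gene_id: c for c in essentiality_screen(fermentation_model)}
        assert calls["adhA"].phenotype == "Growth"      # OR partner remains
        assert calls["adhB"].phenotype == "Growth"
        assert calls["eda"].phenotype == "NoGrowth"     # AND subunit
        assert calls["glf"].phenotype == "NoGrowth"     # sole transporter

    def test_gene_on_blocked_reaction_is_not_essential(self, fermentation_model):
        # a dead-end reaction can never carry flux; deleting its gene is free
        mets = list(fermentation_model.metabolites) + [
            Metabolite("dead_c", formula="C", compartment="c")
        ]
        rxns = list(fermentation_model.reactions) + [
            Reaction("DEADRXN", {"pyr_c": -1.0, "dead_c": 1.0}, 0.0, 1000.0,
                     gpr=GPR.parse("gDead")),
        ]
        model = MetabolicModel(id="dead", metabolites=mets, reactions=rxns,
                               biomass_reaction_id="BIOMASS")
        calls = {c.gene_id: c for c in essentiality_screen(model, genes=["gDead"])}
        assert calls["gDead"].phenotype == "Growth"

    def test_knockout_bounds_follow_gpr(self, fermentation_model):
        closed = dict(knockout_bounds(fermentation_model, ["adhA"]))
        assert closed == {}
        closed = dict(knockout_bounds(fermentation_model, ["adhA", "adhB"]))
        assert "FERM" in closed


# -------------------------------------------------------- uptake sweep ----

def maintenance_toy():
    """Yield model with an energy drain: growth = uptake - ngam above it."""
    mets = [Metabolite("s_e", formula="C", compartment="e"),
            Metabolite("e_c", formula="C", compartment="c")]
    rxns = [
        Reaction("EX_s_e", {"s_e": -1.0}, -10.0, 1000.0, kind=ReactionKind.EXCHANGE),
        Reaction("GEN", {"s_e": -1.0, "e_c": 1.0}, 0.0, 1000.0),
        Reaction("ATPM", {"e_c": -1.0}, 2.0, 1000.0, kind=ReactionKind.MAINTENANCE),
        Reaction("BIOMASS", {"e_c": -1.0}, 0.0, 1000.0, kind=ReactionKind.BIOMASS),
    ]
    return MetabolicModel(id="maint", metabolites=mets, reactions=rxns,
                          biomass_reaction_id="BIOMASS",
                          maintenance_reaction_id="ATPM")


class TestUptakeSweep:
    def test_closed_form_yield_line(self):
        model = maintenance_toy()
        grid = [0.0, 1.0, 2.0, 3.0, 5.0, 8.0]
        rows = uptake_sweep(model, "EX_s_e", grid)
        for row in rows:
            expected = max(row["uptake"] - 2.0, 0.0)
            assert row["growth"] == pytest.approx(expected, abs=1e-6)

    def test_growth_monotone_in_uptake(self, fermentation_model):
        rows = uptake_sweep(fermentation_model, "EX_glc_e",
                            np.linspace(0, 20, 9), tracked=["EX_eth_e"])
        growth = [r["growth"] for r in rows]
        assert all(b >= a - 1e-9 for a, b in zip(growth, growth[1:]))


# ---------------------------------------------------------------- MFA -----

class TestCompareToMFA:
    def test_identical_vectors_no_outliers(self, fermentation_model):
        sol = fba(fermentation_model, "EX_eth_e")
        table = {rid: v for rid, v in sol.fluxes.items() if abs(v) > 1e-9}
        out = compare_to_mfa(sol, table)
        assert out and all(ratio == pytest.approx(1.0) for _, ratio, _ in out)
        assert not any(flag for _, _, flag in out)

    def test_planted_two_fold_outliers(self):
        sol_fluxes = {f"R{i}": float(i + 1) for i in range(10)}
        sol = __import__("fluxcouple").FluxDistribution(sol_fluxes, 0.0, "R0")
        measured = dict(sol_fluxes)
        planted = {"R2", "R5", "R7"}
        for rid in planted:
            measured[rid] = sol_fluxes[rid] / 4.0  # predicted 4x measured
        out = compare_to_mfa(sol, measured)
        assert {rid for rid, _, flag in out if flag} == planted

    def test_zero_prediction_reported_at_floor(self):
        from fluxcouple import FluxDistribution

        sol = FluxDistribution({"R0": 0.0}, 0.0, "R0")
        [(rid, ratio, flag)] = compare_to_mfa(sol, {"R0": 1.0})
        assert ratio == pytest.approx(1e-4) and flag


# ------------------------------------------------------------- gapfill ----

def exhaustive_gapfill_minimum(model, candidates, max_size=3):
    from fluxcouple.fba import GAPFILL_GROWTH_THRESHOLD

    for size in range(0, max_size + 1):
        for combo in itertools.combinations(candidates, size):
            ext = model.with_reactions(list(model.reactions) + list(combo))
            sol = fba(ext)
            if sol.feasible and sol.objective_value >= GAPFILL_GROWTH_THRESHOLD:
                return size
    return None


class TestGapfill:
    def test_already_growing_returns_empty(self, fermentation_model):
        res = min_additions_gapfill(fermentation_model, [])
        assert res.fillable and res.additions == []

    def test_prefers_single_fill_over_double(self, chain_model):
        broken = chain_model.with_bounds({"GLY": (0.0, 0.0)})
        mid = Metabolite("x_c", formula="C", compartment="c")
        broken = MetabolicModel(
            id="broken",
            metabolites=list(broken.metabolites) + [mid],
            reactions=list(broken.reactions),
            biomass_reaction_id="BIOMASS",
        )
        cands = [
            Reaction("FIX1", {"g6p_c": -1.0, "pyr_c": 2.0}, 0.0, 1000.0),
            Reaction("HALF_A", {"g6p_c": -1.0, "x_c": 1.0}, 0.0, 1000.0),
            Reaction("HALF_B", {"x_c": -1.0, "pyr_c": 2.0}, 0.0, 1000.0),
        ]
        res = min_additions_gapfill(broken, cands)
        assert res.fillable and res.size == 1 and res.additions == ["FIX1"]

    def test_unfillable_is_explicit(self, chain_model):
        broken = chain_model.with_bounds({"GLY": (0.0, 0.0)})
        useless = [Reaction("NOP", {"glc_e": -1.0, "g6p_c": 1.0}, 0.0, 1000.0)]
        res = min_additions_gapfill(broken, useless)
        assert not res.fillable

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        model, truth = make_toy_model(PlantedNetworkSpec(
            n_pathways=3, pathway_length=3, seed=seed))
        chain = sorted(itertools.chain.from_iterable(truth.module_partition))
        removed = list(rng.choice(chain, size=int(rng.integers(1, 3)),
                                  replace=False))
        broken = model.with_bounds({rid: (0.0, 0.0) for rid in removed})
        # candidates: re-opened copies of the removed steps + distractor
        # sinks on intermediates that cannot restore growth
        candidates = [
            Reaction(f"CAND_{rid}", dict(model.reaction(rid).stoichiometry),
                     0.0, 1000.0)
            for rid in removed
        ]
        inner = [m.id for m in model.metabolites if m.id.startswith("M")][:3]
        candidates += [
            Reaction(f"SINK_dis_{met}", {met: -1.0}, 0.0, 1000.0,
                     kind=ReactionKind.SINK)
            for met in inner
        ]
        expected = exhaustive_gapfill_minimum(broken, candidates)
        res = min_additions_gapfill(broken, candidates)
        assert expected is not None and res.fillable
        assert res.size == expected


# ---------------------------------------------------------------- MEGS ----

def bypass_host():
    """Target reaction T has a gene-bearing bypass; knocking the bypass out
    makes the target conditionally essential."""
    mets = [Metabolite("a_e", formula="C", compartment="e"),
            Metabolite("a_c", formula="C", compartment="c"),
            Metabolite("p_c", formula="C", compartment="c")]
    rxns = [
        Reaction("EX_a_e", {"a_e": -1.0}, -10.0, 1000.0, kind=ReactionKind.EXCHANGE),
        Reaction("AT", {"a_e": -1.0, "a_c": 1.0}, 0.0, 1000.0,
                 gpr=GPR.parse("gT"), kind=ReactionKind.TRANSPORT),
        Reaction("TARGET", {"a_c": -1.0, "p_c": 1.0}, 0.0, 1000.0),
        Reaction("BYPASS", {"a_c": -1.0, "p_c": 1.0}, 0.0, 1000.0,
                 gpr=GPR.parse("gBypass")),
        Reaction("BIOMASS", {"p_c": -1.0}, 0.0, 1000.0, kind=ReactionKind.BIOMASS),
    ]
    return MetabolicModel(id="megs", metabolites=mets, reactions=rxns,
                          biomass_reaction_id="BIOMASS")


class TestMEGS:
    def test_bypass_knockout_design_found(self):
        host = bypass_host()
        media = [("minimal_a", {"EX_a_e": (-10.0, 1000.0)})]
        designs = megs_design(host, "TARGET", media, max_knockouts=1)
        assert (("gBypass",), "minimal_a") in designs
        assert ((), "minimal_a") not in designs  # bypass rescues wild type

    def test_already_essential_target_needs_no_knockout(self):
        host = bypass_host()
        host = host.with_bounds({"BYPASS": (0.0, 0.0)})
        media = [("minimal_a", {"EX_a_e": (-10.0, 1000.0)})]
        designs = megs_design(host, "TARGET", media, max_knockouts=1)
        assert ((), "minimal_a") in designs

    def test_matches_exhaustive_single_knockout_search(self):
        host = bypass_host()
        media = [("minimal_a", {"EX_a_e": (-10.0, 1000.0)})]
        designs = set(megs_design(host, "TARGET", media, max_knockouts=1))
        expected = set()
        for ko in [()] + [(g,) for g in host.genes]:
            conditioned = host.with_bounds(
                dict((rid, (0.0, 0.0))
                     for rid, _ in knockout_bounds(host, ko)))
            grows = fba(conditioned).objective_value > 1e-9
            no_target = fba(conditioned,
                            extra_constraints=[("TARGET", (0.0, 0.0))])
            dies = (not no_target.feasible) or no_target.objective_value <= 1e-9
            if grows and dies:
                expected.add((ko, "minimal_a"))
        assert designs == expected


# ---------------------------------------------------- node balance -------

def locked_node_toy():
    """Node F: locked production 2 mu (via precursor B), locked consumption
    0.5 mu (via precursor C), one free sink carrying the balance."""
    mets = [Metabolite(x, formula="C") for x in ("a_c", "f_c", "b_c", "c_c")]
    rxns = [
        Reaction("SRC_a", {"a_c": 1.0}, 0.0, 1000.0, kind=ReactionKind.SINK),
        Reaction("P1", {"a_c": -1.0, "b_c": 1.0, "f_c": 2.0}, 0.0, 1000.0),
        Reaction("C2", {"a_c": -1.0, "f_c": -0.5, "c_c": 1.0}, 0.0, 1000.0),
        Reaction("SINK_f", {"f_c": -1.0}, 0.0, 1000.0, kind=ReactionKind.SINK),
        Reaction("BIOMASS", {"b_c": -1.0, "c_c": -1.0}, 0.0, 1000.0,
                 kind=ReactionKind.BIOMASS),
    ]
    return MetabolicModel(id="node", metabolites=mets, reactions=rxns,
                          biomass_reaction_id="BIOMASS")


class TestNodeBalance:
    def test_locked_arithmetic(self):
        report = node_balance_report(locked_node_toy(), "f_c", growth_rate=1.0)
        assert set(report.locked) == {"P1", "C2"}
        assert report.free == ["SINK_f"]
        assert report.balancing_flux == pytest.approx(1.5, abs=1e-6)

    def test_node_without_locked_reactions_balances_zero(self, fermentation_model):
        report = node_balance_report(fermentation_model, "co2_c",
                                     growth_rate=1.0)
        assert report.balancing_flux == pytest.approx(0.0, abs=1e-6)
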