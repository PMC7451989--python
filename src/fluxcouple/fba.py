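"""LP/MILP core: FBA, FVA, gene deletions, uptake sweeps, gap-filling, MEGS.

Flux balance analysis maximises an objective flux (usually biomass) over the
steady-state polytope {v : S v = 0, lb <= v <= ub}. All linear programs are
solved with the HiGHS solvers behind :mod:`scipy.optimize`, which are
deterministic for fixed input. A gene knockout is simulated by closing every
reaction whose GPR evaluates inactive under the deletion; a gene is called
essential (NoGrowth) when the maximal biomass flux falls below the
zero-growth tolerance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model import Medium, MetabolicModel, Reaction, ReactionKind, apply_medium

#: Biomass optimum below this value counts as "no growth".
ZERO_GROWTH_TOL = 1e-9
#: Minimal growth a gap-fill must restore (strictly positive but small).
GAPFILL_GROWTH_THRESHOLD = 1e-3
#: Steady-state residual tolerance |S v| per metabolite.
MASS_BALANCE_TOL = 1e-6


class UnboundedObjectiveError(RuntimeError):
    """The FBA objective is unbounded; carries one culprit reaction id."""

    def __init__(self, reaction_id: str):
        super().__init__(f"objective unbounded; e.g. along reaction {reaction_id}")
        self.reaction_id = reaction_id


@dataclass
class FluxDistribution:
    fluxes: Dict[str, float]
    objective_value: float
    objective_id: str
    feasible: bool = True

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass(frozen=True)
class FluxRange:
    reaction_id: str
    minimum: float
    maximum: float

    def __post_init__(self):
        if self.minimum > self.maximum + 1e-6:
            raise ValueError(f"{self.reaction_id}: min {self.minimum} > max {self.maximum}")


@dataclass(frozen=True)
class EssentialityCall:
    gene_id: str
    phenotype: str  # "Growth" | "NoGrowth"
    residual_growth: float


ExtraConstraint = Tuple[str, Union[float, Tuple[float, float]]]


def _solve_lp(model, c_sense, objective_idx, lb, ub):
    """Maximise (c_sense=-1) or minimise (+1) v[objective_idx] over S v = 0."""
    n = len(model.reactions)
    c = np.zeros(n)
    c[objective_idx] = c_sense
    S = model.stoichiometric_matrix()
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    return res


def _bounds_with_constraints(
    model: MetabolicModel, extra: Optional[Sequence[ExtraConstraint]]
) -> Tuple[np.ndarray, np.ndarray]:
    lb, ub = model.bounds()
    if extra:
        idx = {r.id: i for i, r in enumerate(model.reactions)}
        for rid, spec in extra:
            if rid not in idx:
                raise KeyError(f"unknown reaction in constraint: {rid}")
            i = idx[rid]
            if isinstance(spec, (tuple, list)):
                lb[i], ub[i] = spec
            else:
                lb[i] = ub[i] = float(spec)
    return lb, ub


def fba(
    model: MetabolicModel,
    objective_id: Optional[str] = None,
    extra_constraints: Optional[Sequence[ExtraConstraint]] = None,
) -> FluxDistribution:
    """Maximise the objective flux; infeasibility is a legitimate outcome.

    Returns a :class:`FluxDistribution` with ``feasible=False`` and zero
    objective when the constraints admit no steady state (e.g. an essential
    reaction deleted). Raises :class:`UnboundedObjectiveError` when the
    objective can grow without bound.
    """
    objective_id = objective_id or model.biomass_reaction_id
    if objective_id is None:
        raise ValueError("no objective reaction given and model has no biomass")
    obj_idx = [r.id for r in model.reactions].index(objective_id)
    lb, ub = _bounds_with_constraints(model, extra_constraints)
    res = _solve_lp(model, -1.0, obj_idx, lb, ub)
    if res.status == 3:  # unbounded
        raise UnboundedObjectiveError(_unbounded_member(model, obj_idx, lb, ub))
    if res.status == 2:  # infeasible
        return FluxDistribution({}, 0.0, objective_id, feasible=False)
    if res.status != 0:
        raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxDistribution(fluxes, float(-res.fun), objective_id)


def _unbounded_member(model, obj_idx, lb, ub) -> str:
    # Find one reaction on an unbounded ray by maximising the objective with
    # all bounds clipped, then naming a reaction sitting at a clipped bound.
    big = 1e6
    lb2, ub2 = np.maximum(lb, -big), np.minimum(ub, big)
    res = _solve_lp(model, -1.0, obj_idx, lb2, ub2)
    if res.status == 0:
        at_clip = [
            model.reactions[i].id
            for i in range(len(lb))
            if (np.isinf(ub[i]) and res.x[i] > big * 0.5)
            or (np.isinf(-lb[i]) and res.x[i] < -big * 0.5)
        ]
        if at_clip:
            return at_clip[0]
    return model.reactions[obj_idx].id


def fva(
    model: MetabolicModel,
    objective_id: Optional[str] = None,
    fraction_of_optimum: float = 1.0,
    reactions: Optional[Sequence[str]] = None,
    extra_constraints: Optional[Sequence[ExtraConstraint]] = None,
) -> List[FluxRange]:
    """Per-reaction flux ranges with the objective held at a fraction of its
    optimum (1.0 reproduces variability at the optimal growth rate)."""
    objective_id = objective_id or model.biomass_reaction_id
    sol = fba(model, objective_id, extra_constraints)
    if not sol.feasible:
        raise RuntimeError("FVA requested on an infeasible model")
    lb, ub = _bounds_with_constraints(model, extra_constraints)
    rids = [r.id for r in model.reactions]
    obj_idx = rids.index(objective_id)
    # Fix the objective with a hair of slack for LP numerics.
    target = fraction_of_optimum * sol.objective_value
    lb = lb.copy()
    lb[obj_idx] = max(lb[obj_idx], target - 1e-9 - 1e-9 * abs(target))
    wanted = rids if reactions is None else list(reactions)
    out = []
    for rid in wanted:
        i = rids.index(rid)
        lo = _solve_lp(model, 1.0, i, lb, ub)
        hi = _solve_lp(model, -1.0, i, lb, ub)
        if lo.status == 2 or hi.status == 2:
            raise RuntimeError(f"FVA infeasible at fraction {fraction_of_optimum}")
        vmin = float(lo.fun) if lo.status == 0 else -np.inf
        vmax = float(-hi.fun) if hi.status == 0 else np.inf
        out.append(FluxRange(rid, min(vmin, vmax), max(vmin, vmax)))
    return out


def knockout_bounds(
    model: MetabolicModel, deleted_genes: Iterable[str]
) -> List[ExtraConstraint]:
    """Constraints closing every reaction inactivated by the deletions."""
    deleted = frozenset(deleted_genes)
    out: List[ExtraConstraint] = []
    for r in model.reactions:
        if not r.gpr.is_empty and not r.gpr.evaluate(deleted):
            out.append((r.id, (0.0, 0.0)))
    return out


def essentiality_screen(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    genes: Optional[Sequence[str]] = None,
    tolerance: float = ZERO_GROWTH_TOL,
) -> List[EssentialityCall]:
    """Single-gene deletion screen: NoGrowth iff max biomass <= tolerance."""
    work = apply_medium(model, medium) if medium is not None else model
    calls = []
    for gene in genes if genes is not None else work.genes:
        closed = knockout_bounds(work, [gene])
        if closed:
            sol = fba(work, extra_constraints=closed)
            mu = sol.objective_value if sol.feasible else 0.0
        else:  # deletion touches nothing: growth is the wild-type optimum
            mu = fba(work).objective_value
        calls.append(
            EssentialityCall(gene, "NoGrowth" if mu <= tolerance else "Growth", mu)
        )
    return calls


def uptake_sweep(
    model: MetabolicModel,
    substrate_exchange_id: str,
    grid: Sequence[float],
    tracked: Sequence[str] = (),
    extra_constraints: Optional[Sequence[ExtraConstraint]] = None,
) -> List[Dict[str, float]]:
    """FBA growth and tracked production fluxes over a grid of uptake rates.

    Grid values are uptake magnitudes (>= 0); each sets the substrate
    exchange lower bound to -rate. Infeasible points (e.g. maintenance not
    payable at zero uptake) are reported with zero growth.
    """
    rows = []
    for rate in grid:
        if rate < 0:
            raise ValueError("uptake rates must be non-negative")
        constraints = list(extra_constraints or [])
        constraints.append((substrate_exchange_id, (-float(rate), 0.0)))
        sol = fba(model, extra_constraints=constraints)
        row = {"uptake": float(rate), "growth": sol.objective_value if sol.feasible else 0.0}
        for rid in tracked:
            row[rid] = sol.fluxes.get(rid, 0.0) if sol.feasible else 0.0
        rows.append(row)
    return rows


def compare_to_mfa(
    fba_solution: FluxDistribution,
    mfa_table: Mapping[str, float],
    fold: float = 2.0,
    floor: float = 1e-4,
) -> List[Tuple[str, float, bool]]:
    """Fold-deviation of predicted vs measured fluxes with an outlier flag.

    Both fluxes are oriented to the measured direction before comparison;
    predictions at (or against) zero are floored at ``floor`` so they appear
    at a finite position, mirroring log-scale scatter plots. A reaction is
    an outlier when the fold-deviation leaves the [1/fold, fold] band.
    """
    out = []
    for rid, measured in mfa_table.items():
        if rid not in fba_solution.fluxes or measured == 0:
            continue
        oriented = fba_solution.fluxes[rid] * np.sign(measured)
        oriented = max(oriented, floor)
        ratio = oriented / abs(measured)
        out.append((rid, float(ratio), bool(ratio > fold or ratio < 1.0 / fold)))
    return out


@dataclass
class GapfillResult:
    additions: List[str]
    size: int
    fillable: bool
    growth: float = 0.0


def min_additions_gapfill(
    model: MetabolicModel,
    candidates: Sequence[Reaction],
    objective_id: Optional[str] = None,
    growth_threshold: float = GAPFILL_GROWTH_THRESHOLD,
) -> GapfillResult:
    """Minimal-additions gap-filling as a MILP.

    Finds a smallest subset of candidate reactions whose addition restores
    growth above the threshold; binary indicators gate candidate bounds via
    big-M rows and the indicator sum is minimised. Returns an explicit
    "unfillable" result when no subset works. If the model already grows,
    the empty set is returned.
    """
    objective_id = objective_id or model.biomass_reaction_id
    base = fba(model, objective_id)
    if base.feasible and base.objective_value >= growth_threshold:
        return GapfillResult([], 0, True, base.objective_value)

    extended = model.with_reactions(list(model.reactions) + list(candidates))
    rids = [r.id for r in extended.reactions]
    n = len(rids)
    k = len(candidates)
    cand_idx = [rids.index(c.id) for c in candidates]
    lb, ub = extended.bounds()
    obj_idx = rids.index(objective_id)

    S = extended.stoichiometric_matrix()
    # variables: v (n) then y (k binaries)
    A_eq = sparse.hstack([S, sparse.csr_matrix((S.shape[0], k))])
    constraints = [LinearConstraint(A_eq, 0.0, 0.0)]
    # v_i - ub_i * y_i <= 0  and  v_i - lb_i * y_i >= 0 for candidates
    rows_u = sparse.lil_matrix((k, n + k))
    rows_l = sparse.lil_matrix((k, n + k))
    for j, i in enumerate(cand_idx):
        rows_u[j, i] = 1.0
        rows_u[j, n + j] = -max(ub[i], 0.0) if np.isfinite(ub[i]) else -1e4
        rows_l[j, i] = 1.0
        rows_l[j, n + j] = -min(lb[i], 0.0) if np.isfinite(lb[i]) else 1e4
    constraints.append(LinearConstraint(rows_u.tocsr(), -np.inf, 0.0))
    constraints.append(LinearConstraint(rows_l.tocsr(), 0.0, np.inf))

    var_lb = np.concatenate([lb, np.zeros(k)])
    var_ub = np.concatenate([ub, np.ones(k)])
    for i in cand_idx:  # gating rows, not the box, switch candidates off
        var_lb[i] = min(lb[i], 0.0)
        var_ub[i] = max(ub[i], 0.0)
    var_lb[obj_idx] = max(lb[obj_idx], growth_threshold)

    c = np.zeros(n + k)
    c[n:] = 1.0
    integrality = np.zeros(n + k)
    integrality[n:] = 1
    res = milp(
        c,
        constraints=constraints,
        bounds=Bounds(var_lb, var_ub),
        integrality=integrality,
    )
    if res.status != 0 or res.x is None:
        return GapfillResult([], 0, False)
    y = res.x[n:]
    chosen = [candidates[j].id for j in range(k) if y[j] > 0.5]
    return GapfillResult(chosen, len(chosen), True, float(res.x[obj_idx]))


def megs_design(
    host_model: MetabolicModel,
    target_reaction_id: str,
    media_catalog: Sequence[Tuple[str, Medium]],
    max_knockouts: int = 2,
    tolerance: float = ZERO_GROWTH_TOL,
) -> List[Tuple[Tuple[str, ...], str]]:
    """Search for (knockout set, medium) pairs making a target reaction
    conditionally essential.

    A valid design grows with the knockouts applied, and stops growing when
    the target reaction is additionally disabled — the selection condition
    used to fish genes for orphan reactions out of genomic libraries. The
    search is exhaustive over gene subsets up to ``max_knockouts`` crossed
    with the media catalog.
    """
    if not host_model.has_reaction(target_reaction_id):
        raise KeyError(f"target reaction {target_reaction_id} not in host model")
    designs = []
    genes = host_model.genes
    subsets: List[Tuple[str, ...]] = [()]
    for size in range(1, max_knockouts + 1):
        subsets.extend(itertools.combinations(genes, size))
    for medium_name, medium in media_catalog:
        conditioned = apply_medium(host_model, medium)
        for ko in subsets:
            closed = knockout_bounds(conditioned, ko)
            sol = fba(conditioned, extra_constraints=closed)
            if not sol.feasible or sol.objective_value <= tolerance:
                continue
            closed_target = closed + [(target_reaction_id, (0.0, 0.0))]
            sol2 = fba(conditioned, extra_constraints=closed_target)
            if not sol2.feasible or sol2.objective_value <= tolerance:
                designs.append((ko, medium_name))
    return designs


@dataclass
class NodeReport:
    metabolite_id: str
    locked: Dict[str, float]        # reaction id -> fixed flux at the node
    free: List[str]                 # reactions free to balance the node
    balancing_flux: float           # net locked imbalance the free set carries


def node_balance_report(
    model: MetabolicModel,
    node_metabolite_id: str,
    growth_rate: float,
    tolerance: float = 1e-6,
) -> NodeReport:
    """Partition the reactions at a metabolite node into biomass-ratio-locked
    and free, and report the balancing flux the free reactions must carry.

    With the biomass flux fixed at the given growth rate, the node
    metabolite's own steady-state constraint is *removed* and flux
    variability is computed for every reaction touching the node: reactions
    still pinned to a single value are locked by the rest of the network
    (typically a fixed ratio with the biomass equation); the others are free.
    The balancing flux is the net production of the node by the locked set,
    which the free reactions must drain (or supply) to restore steady state.
    """
    if node_metabolite_id not in {m.id for m in model.metabolites}:
        raise KeyError(f"unknown metabolite {node_metabolite_id}")
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    touching = [r for r in model.reactions_of_metabolite(node_metabolite_id)]
    # Relax the node's mass-balance row with an unbounded relief flux —
    # equivalent to dropping the steady-state constraint at this node only.
    relief = Reaction(
        f"RELAX_{node_metabolite_id}",
        {node_metabolite_id: 1.0},
        -np.inf,
        np.inf,
        kind=ReactionKind.SINK,
    )
    relaxed = model.with_reactions(list(model.reactions) + [relief])
    fix = [(model.biomass_reaction_id, float(growth_rate))]
    ranges = {
        fr.reaction_id: fr
        for fr in fva(
            relaxed,
            objective_id=model.biomass_reaction_id,
            reactions=[r.id for r in touching],
            extra_constraints=fix,
        )
    }
    locked: Dict[str, float] = {}
    free: List[str] = []
    for r in touching:
        fr = ranges[r.id]
        span = fr.maximum - fr.minimum
        if span <= tolerance * (1.0 + abs(fr.maximum)):
            locked[r.id] = 0.5 * (fr.minimum + fr.maximum)
        else:
            free.append(r.id)
    net = sum(
        model.reaction(rid).stoichiometry[node_metabolite_id] * v
        for rid, v in locked.items()
    )
    return NodeReport(node_metabolite_id, locked, free, abs(float(net)))
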