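"""Flux Coupling Finder: ratio-extreme LPs, coupling classes, and modules.

Two reaction components i, j are coupled according to the extremes of the
flux ratio v_i/v_j over the steady-state flux cone {S v = 0, v >= 0} of the
reversible-split network. With every component non-negative the ratio
extremes are obtained from two LPs after normalising v_j = 1:

* fully coupled      — Rmin = Rmax > 0 (fixed nonzero ratio)
* partially coupled  — 0 < Rmin < Rmax < inf (variable but mutual)
* directional i -> j — Rmin = 0, Rmax < inf (flux through i forces j)
* directional j -> i — Rmin > 0, Rmax = inf
* uncoupled          — Rmin = 0, Rmax = inf

Full coupling is an equivalence relation, which the module search exploits:
each component is only compared against one representative per class.
Modules are fully coupled equivalence classes (size >= 2); partially coupled
modules are maximal connected sets under partial-or-full edges containing at
least one partial pair. Sink reactions for individual biomass components
keep the biomass equation from gluing unrelated pathways into one module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .gpr import GPR
from .model import (
    DEFAULT_BOUND,
    Metabolite,
    MetabolicModel,
    Reaction,
    ReactionKind,
)

RATIO_EPS = 1e-6     # relative tolerance for ratio equality
ZERO_TOL = 1e-8      # below this a ratio extreme counts as zero
INF = float("inf")


@dataclass(frozen=True)
class CouplingResult:
    i: str
    j: str
    rmin: float
    rmax: float  # may be +inf

    @property
    def classification(self) -> str:
        zero_min = self.rmin <= ZERO_TOL
        inf_max = not np.isfinite(self.rmax)
        if not zero_min and not inf_max:
            if self.rmax - self.rmin <= RATIO_EPS * max(1.0, abs(self.rmax)):
                return "fully"
            return "partially"
        if zero_min and not inf_max:
            return "directionally_i_to_j"
        if not zero_min and inf_max:
            return "directionally_j_to_i"
        return "uncoupled"


@dataclass
class ReactionModule:
    id: str
    kind: str                      # "fully" | "partially"
    components: List[str]
    genes: List[str] = field(default_factory=list)
    mutants: List[str] = field(default_factory=list)


@dataclass
class ComponentModel:
    """Reversible-split network: every component carries non-negative flux."""

    model: MetabolicModel
    parent: MetabolicModel
    to_parent: Dict[str, Tuple[str, str]]  # component -> (reaction id, f/r)

    def __post_init__(self):
        self._S = None

    def stoichiometric_matrix(self):
        if self._S is None:
            self._S = self.model.stoichiometric_matrix().tocsc()
        return self._S

    @property
    def component_ids(self) -> List[str]:
        return [r.id for r in self.model.reactions]

    def parent_reaction(self, component_id: str) -> Reaction:
        return self.parent.reaction(self.to_parent[component_id][0])

    def with_closed(self, closed: Iterable[str]) -> "ComponentModel":
        closed = set(closed)
        rxns = [
            replace(r, lower_bound=0.0, upper_bound=0.0) if r.id in closed else r
            for r in self.model.reactions
        ]
        return ComponentModel(self.model.with_reactions(rxns), self.parent, dict(self.to_parent))


def split_reversible(model: MetabolicModel) -> ComponentModel:
    """Split each reversible reaction into forward (_f) and reverse (_r)
    non-negative components; irreversible reactions become single ``_f``
    components (reverse-only reactions a single ``_r``)."""
    comp_rxns: List[Reaction] = []
    mapping: Dict[str, Tuple[str, str]] = {}
    for r in model.reactions:
        if r.upper_bound > 0:
            cid = f"{r.id}_f"
            comp_rxns.append(
                replace(r, id=cid, lower_bound=0.0, upper_bound=r.upper_bound)
            )
            mapping[cid] = (r.id, "f")
        if r.lower_bound < 0:
            cid = f"{r.id}_r"
            comp_rxns.append(
                replace(
                    r,
                    id=cid,
                    stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                    lower_bound=0.0,
                    upper_bound=-r.lower_bound,
                )
            )
            mapping[cid] = (r.id, "r")
    comp_model = MetabolicModel(
        id=f"{model.id}_split",
        metabolites=list(model.metabolites),
        reactions=comp_rxns,
        biomass_reaction_id=None,
        maintenance_reaction_id=None,
    )
    return ComponentModel(comp_model, model, mapping)


def augment_with_sinks(
    model: MetabolicModel,
    biomass_components: Sequence[str] = (),
    terminal_products: Sequence[str] = (),
) -> MetabolicModel:
    """Add per-metabolite sink reactions and open all exchanges both ways.

    One irreversible sink (metabolite -> nothing, bounds [0, 1000]) is added
    per listed biomass component / terminal product so coupling to an
    individual precursor can be seen instead of coupling to aggregate
    biomass; every exchange is opened to [-1000, 1000] (full in-silico
    medium).
    """
    met_ids = {m.id for m in model.metabolites}
    new_rxns = list(model.reactions)
    existing = {r.id for r in model.reactions}
    for met_id in list(biomass_components) + list(terminal_products):
        if met_id not in met_ids:
            raise KeyError(f"unknown metabolite for sink: {met_id}")
        sid = f"SINK_{met_id}"
        if sid in existing:
            continue
        new_rxns.append(
            Reaction(
                id=sid,
                stoichiometry={met_id: -1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                kind=ReactionKind.SINK,
            )
        )
        existing.add(sid)
    opened = [
        replace(r, lower_bound=-DEFAULT_BOUND, upper_bound=DEFAULT_BOUND)
        if r.kind == ReactionKind.EXCHANGE
        else r
        for r in new_rxns
    ]
    return model.with_reactions(opened)


def _cone_bounds(cm: ComponentModel) -> List[Tuple[float, Optional[float]]]:
    # Coupling lives on the flux cone: finite capacities scale out, only
    # open (ub > 0) vs closed (ub == 0) matters.
    return [
        (0.0, 0.0) if r.upper_bound <= ZERO_TOL else (0.0, None)
        for r in cm.model.reactions
    ]


def blocked_components(cm: ComponentModel, tol: float = 1e-9) -> Set[str]:
    """Components that can never carry flux (one capped LP per component)."""
    S = cm.stoichiometric_matrix()
    bounds = [
        (0.0, 0.0) if r.upper_bound <= ZERO_TOL else (0.0, 1.0)
        for r in cm.model.reactions
    ]
    blocked = set()
    n = len(bounds)
    for i, cid in enumerate(cm.component_ids):
        if bounds[i] == (0.0, 0.0):
            blocked.add(cid)
            continue
        c = np.zeros(n)
        c[i] = -1.0
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
        if res.status != 0 or -res.fun <= tol:
            blocked.add(cid)
    return blocked


class BlockedComponentError(ValueError):
    """Normalising component is blocked; prefilter with blocked_components."""


def coupling_pair(cm: ComponentModel, i: str, j: str) -> CouplingResult:
    """Ratio extremes Rmin/Rmax of v_i/v_j over the flux cone (v_j = 1)."""
    if i == j:
        raise ValueError("coupling_pair needs two distinct components")
    ids = cm.component_ids
    ii, jj = ids.index(i), ids.index(j)
    S = cm.stoichiometric_matrix()
    bounds = _cone_bounds(cm)
    bounds = list(bounds)
    if bounds[jj] == (0.0, 0.0):
        raise BlockedComponentError(f"component {j} is closed/blocked")
    bounds[jj] = (1.0, 1.0)
    n = len(bounds)
    b_eq = np.zeros(S.shape[0])

    c = np.zeros(n)
    c[ii] = 1.0
    lo = linprog(c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
    if lo.status == 2:
        raise BlockedComponentError(
            f"component {j} cannot carry flux; prefilter blocked components"
        )
    rmin = float(lo.fun)

    hi = linprog(-c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
    rmax = INF if hi.status == 3 else float(-hi.fun)
    rmin = max(rmin, 0.0)
    return CouplingResult(i, j, rmin, rmax)


def coupling_all(
    cm: ComponentModel,
    min_module_size: int = 2,
) -> List[ReactionModule]:
    """Fully and partially coupled modules over all unblocked components.

    Fully coupled classes are built incrementally against class
    representatives (full coupling is transitive); partial edges are then
    resolved between class representatives only, since coupling class is
    invariant within a fully coupled class.
    """
    blocked = blocked_components(cm)
    comps = [c for c in cm.component_ids if c not in blocked]

    classes: List[List[str]] = []
    for comp in comps:
        placed = False
        for cls in classes:
            if coupling_pair(cm, comp, cls[0]).classification == "fully":
                cls.append(comp)
                placed = True
                break
        if not placed:
            classes.append([comp])

    reps = [cls[0] for cls in classes]
    partial_edges = []
    for a, b in itertools.combinations(range(len(reps)), 2):
        if coupling_pair(cm, reps[a], reps[b]).classification == "partially":
            partial_edges.append((a, b))

    modules: List[ReactionModule] = []
    counter = itertools.count(1)
    for cls in classes:
        if len(cls) >= min_module_size:
            modules.append(
                ReactionModule(f"M{next(counter)}", "fully", sorted(cls))
            )

    g = nx.Graph()
    g.add_nodes_from(range(len(classes)))
    g.add_edges_from(partial_edges)
    for cc in nx.connected_components(g):
        if not any(a in cc and b in cc for a, b in partial_edges):
            continue
        members = sorted(itertools.chain.from_iterable(classes[a] for a in cc))
        if len(members) >= min_module_size:
            modules.append(ReactionModule(f"M{next(counter)}", "partially", members))
    return modules


def map_modules_to_genes(
    modules: Sequence[ReactionModule],
    cm: ComponentModel,
    fitness_genes: Optional[Iterable[str]] = None,
) -> List[ReactionModule]:
    """Attach gene and mutant sets to modules via member-reaction GPRs.

    Genes behind a top-level OR (isozymes) are excluded, as are reactions
    without a GPR (orphans contribute no gene). The mutant set is the gene
    set intersected with the fitness dataset's gene list when given.
    """
    fit = set(fitness_genes) if fitness_genes is not None else None
    out = []
    for mod in modules:
        genes: Set[str] = set()
        for comp in mod.components:
            gpr = cm.parent_reaction(comp).gpr
            if gpr.is_empty or gpr.is_isozyme():
                continue
            genes |= gpr.genes()
        mutants = sorted(genes & fit) if fit is not None else sorted(genes)
        out.append(replace_module(mod, genes=sorted(genes), mutants=mutants))
    return out


def replace_module(mod: ReactionModule, **kw) -> ReactionModule:
    data = dict(id=mod.id, kind=mod.kind, components=mod.components,
                genes=mod.genes, mutants=mod.mutants)
    data.update(kw)
    return ReactionModule(**data)


def apply_condition(
    cm: ComponentModel, constraints: Mapping[str, Tuple[float, float]]
) -> ComponentModel:
    """Close/limit components according to bounds on parent reactions
    (e.g. oxygen exchange fixed to zero for the anaerobic condition)."""
    closed = []
    for comp, (rid, direction) in cm.to_parent.items():
        if rid not in constraints:
            continue
        lb, ub = constraints[rid]
        cap = ub if direction == "f" else -lb
        if cap <= ZERO_TOL:
            closed.append(comp)
    return cm.with_closed(closed)


def condition_coupling(
    cm: ComponentModel,
    constraints: Mapping[str, Tuple[float, float]],
    baseline_modules: Sequence[ReactionModule],
) -> Dict[str, List[str]]:
    """Condition-dependent couplings gained by each baseline module.

    Recomputes coupling under the constrained condition and reports, per
    baseline fully coupled module, the components newly fully coupled into
    it. Constraining the network can only add full couplings (the feasible
    cone shrinks), never remove them.
    """
    constrained = apply_condition(cm, constraints)
    new_modules = [m for m in coupling_all(constrained) if m.kind == "fully"]
    additions: Dict[str, List[str]] = {}
    for base in baseline_modules:
        if base.kind != "fully":
            continue
        base_set = set(base.components)
        gained: Set[str] = set()
        for nm in new_modules:
            if base_set & set(nm.components):
                gained |= set(nm.components) - base_set
        additions[base.id] = sorted(gained)
    return additions
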