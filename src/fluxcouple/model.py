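"""In-memory representation of a constraint-based metabolic model.

A model is a stoichiometric matrix S (metabolites x reactions) together with
flux bounds, gene-protein-reaction associations, and the biomass /
ATP-maintenance bookkeeping needed for growth simulations. All fluxes are in
mmol/gDW/h and growth rates in 1/h; the growth-associated maintenance (GAM)
is an ATP stoichiometry inside the biomass equation (mmol ATP/gDW) while the
non-growth-associated maintenance (NGAM, mmol ATP/gDW/h) is encoded as the
lower bound of the maintenance reaction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from .gpr import GPR

DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class FormulaError(ValueError):
    """Raised when an elemental formula cannot be parsed."""


class ReactionKind(str, Enum):
    METABOLIC = "metabolic"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"
    SINK = "sink"
    BIOMASS = "biomass"
    MAINTENANCE = "maintenance"


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into element counts."""
    if formula is None:
        raise FormulaError("missing formula")
    formula = formula.strip()
    if formula in ("", "X", "R"):  # generic placeholder: no elements
        return {}
    counts: Dict[str, int] = {}
    consumed = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != consumed:
            raise FormulaError(f"unparseable formula {formula!r}")
        consumed = m.end()
        n = int(m.group(2)) if m.group(2) else 1
        counts[m.group(1)] = counts.get(m.group(1), 0) + n
    if consumed != len(formula):
        raise FormulaError(f"unparseable formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = "c"

    def elements(self) -> Dict[str, int]:
        try:
            return parse_formula(self.formula)
        except FormulaError as exc:
            raise FormulaError(f"metabolite {self.id}: {exc}") from exc

    @property
    def species(self) -> str:
        """Compartment-stripped id (``glc_c`` and ``glc_e`` -> ``glc``)."""
        suffix = f"_{self.compartment}"
        return self.id[: -len(suffix)] if self.id.endswith(suffix) else self.id


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GPR = field(default_factory=GPR)
    subsystem: str = ""
    kind: ReactionKind = ReactionKind.METABOLIC
    name: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_boundary(self) -> bool:
        return self.kind in (ReactionKind.EXCHANGE, ReactionKind.SINK)


def infer_kind(
    rxn_id: str,
    stoichiometry: Mapping[str, float],
    compartments: Mapping[str, str],
    annotation: Optional[str] = None,
) -> ReactionKind:
    """Infer a reaction's kind from id prefixes, falling back to annotation.

    ``EX_`` marks exchanges, ``SINK_``/``DM_`` sinks/demands; ids containing
    ``biomass`` mark the biomass reaction and ``ATPM`` the maintenance
    reaction. A reaction moving a species between compartments is a
    transport reaction.
    """
    if annotation:
        return ReactionKind(annotation)
    rid = rxn_id.lower()
    if rxn_id.startswith("EX_"):
        return ReactionKind.EXCHANGE
    if rxn_id.startswith(("SINK_", "DM_")):
        return ReactionKind.SINK
    if "biomass" in rid:
        return ReactionKind.BIOMASS
    if rid == "atpm" or rid.startswith("atpm_"):
        return ReactionKind.MAINTENANCE
    comps = {compartments.get(m) for m in stoichiometry}
    if len(comps - {None}) > 1:
        return ReactionKind.TRANSPORT
    return ReactionKind.METABOLIC


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) metabolic model."""

    id: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    biomass_reaction_id: Optional[str] = None
    maintenance_reaction_id: Optional[str] = None
    gam: Optional[float] = None
    ngam: Optional[float] = None

    def __post_init__(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.validate()

    # -- accessors -----------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def genes(self) -> List[str]:
        out = set()
        for r in self.reactions:
            out |= r.gpr.genes()
        return sorted(out)

    @property
    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.kind == ReactionKind.EXCHANGE]

    def reactions_for_gene(self, gene: str) -> List[Reaction]:
        return [r for r in self.reactions if gene in r.gpr.genes()]

    def reactions_of_metabolite(self, met_id: str) -> List[Reaction]:
        return [r for r in self.reactions if met_id in r.stoichiometry]

    # -- structure -----------------------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with shape (#metabolites, #reactions)."""
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for met_id, coef in r.stoichiometry.items():
                rows.append(self._met_index[met_id])
                cols.append(j)
                vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def validate(self) -> None:
        if not self.reactions:
            raise ModelValidationError(f"model {self.id}: empty reaction list")
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError(f"model {self.id}: duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError(f"model {self.id}: duplicate reaction ids")
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id}: unknown metabolite {met_id}"
                    )
            if r.is_boundary and len(r.stoichiometry) != 1:
                raise ModelValidationError(
                    f"{r.kind.value} reaction {r.id} must touch exactly one "
                    f"metabolite, touches {len(r.stoichiometry)}"
                )
        if self.biomass_reaction_id is not None and not self.has_reaction(
            self.biomass_reaction_id
        ):
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id} not in model"
            )
        if self.maintenance_reaction_id is not None:
            if not self.has_reaction(self.maintenance_reaction_id):
                raise ModelValidationError(
                    f"maintenance reaction {self.maintenance_reaction_id} not in model"
                )
            if self.ngam is None:
                self.ngam = self.reaction(self.maintenance_reaction_id).lower_bound

    def validate_gprs(self, known_genes: Optional[Iterable[str]] = None) -> None:
        """Check every GPR leaf against a gene list (defaults to the union)."""
        universe = set(known_genes) if known_genes is not None else set(self.genes)
        for r in self.reactions:
            unknown = r.gpr.genes() - universe
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id}: GPR references unknown genes {sorted(unknown)}"
                )

    # -- editing (copy-on-write helpers) -------------------------------
    def with_reactions(self, reactions: Sequence[Reaction], **overrides) -> "MetabolicModel":
        kwargs = dict(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=list(reactions),
            biomass_reaction_id=self.biomass_reaction_id,
            maintenance_reaction_id=self.maintenance_reaction_id,
            gam=self.gam,
            ngam=self.ngam,
        )
        kwargs.update(overrides)
        return MetabolicModel(**kwargs)

    def with_bounds(self, new_bounds: Mapping[str, Tuple[float, float]]) -> "MetabolicModel":
        reactions = [
            replace(r, lower_bound=new_bounds[r.id][0], upper_bound=new_bounds[r.id][1])
            if r.id in new_bounds
            else r
            for r in self.reactions
        ]
        return self.with_reactions(reactions)


Medium = Dict[str, Tuple[float, float]]


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy of the model with exchange bounds set from a medium.

    Exchanges listed in the medium get the given (lb, ub); all other
    exchanges are closed to uptake (lb = 0). Every exchange keeps an open
    secretion bound (ub = 1000) so any extracellular compound may be
    secreted. Uptake is a negative lower bound.
    """
    for ex_id in medium:
        if not model.has_reaction(ex_id):
            raise ModelValidationError(f"medium references unknown reaction {ex_id}")
        if model.reaction(ex_id).kind != ReactionKind.EXCHANGE:
            raise ModelValidationError(
                f"medium entry {ex_id} is not an exchange reaction"
            )
    new_bounds: Dict[str, Tuple[float, float]] = {}
    for r in model.reactions:
        if r.kind != ReactionKind.EXCHANGE:
            continue
        if r.id in medium:
            new_bounds[r.id] = (medium[r.id][0], medium[r.id][1])
        else:
            new_bounds[r.id] = (0.0, DEFAULT_BOUND)
    return model.with_bounds(new_bounds)


def full_medium(model: MetabolicModel, bound: float = DEFAULT_BOUND) -> Medium:
    """The full in-silico medium: every exchange open in both directions."""
    return {r.id: (-bound, bound) for r in model.exchange_reactions}


def evaluate_gpr(gpr: GPR, deleted) -> bool:
    """Module-level convenience wrapper around :meth:`GPR.evaluate`."""
    return gpr.evaluate(frozenset(deleted))


def check_balance(model: MetabolicModel) -> List[Tuple[str, Dict[str, float]]]:
    """Mass/charge-balance every internal reaction.

    Exchange, sink, and biomass (and maintenance-free ATP hydrolysis is a
    normal balanced reaction, so it is checked) reactions are excluded.
    Returns ``(reaction_id, {element_or_'charge': net_imbalance})`` records;
    an empty list means the model is balanced. Proton/water imbalances are
    reported, not auto-corrected.
    """
    skip = {ReactionKind.EXCHANGE, ReactionKind.SINK, ReactionKind.BIOMASS}
    out = []
    for r in model.reactions:
        if r.kind in skip:
            continue
        net: Dict[str, float] = {}
        for met_id, coef in r.stoichiometry.items():
            met = model.metabolite(met_id)
            for elem, n in met.elements().items():
                net[elem] = net.get(elem, 0.0) + coef * n
            net["charge"] = net.get("charge", 0.0) + coef * met.charge
        imbalance = {k: v for k, v in net.items() if abs(v) > 1e-9}
        if imbalance:
            out.append((r.id, imbalance))
    return out
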