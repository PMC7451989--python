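"""Synthetic metabolic networks and pooled fitness matrices with ground truth.

The toy networks plant a known module structure — parallel linear pathways,
each ending in a biomass precursor — so that flux coupling should recover
exactly the planted partition. The fitness simulator emulates the
statistical structure of pooled Bar-seq data: per-experiment module
essentiality, a strongly negative essential effect (log2 scores around -4)
against near-zero neutral scores, per-gene measurement noise, mixed-genotype
mutants whose biological effect is attenuated toward zero (wild-type gene
copies masking the knockout), mis-mapped barcodes that inherit another
gene's trajectory, and missing mutants. An orphan reaction carries no GPR in
the model while its true gene still responds with the module, which is what
cofitness candidate ranking must rediscover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .gpr import GPR
from .model import (
    DEFAULT_BOUND,
    Metabolite,
    MetabolicModel,
    Reaction,
    ReactionKind,
)
from .fitness import FitnessMatrix


@dataclass
class PlantedNetworkSpec:
    n_pathways: int = 5
    pathway_length: int = 4
    shared_hub: bool = False
    orphan_positions: Sequence[Tuple[int, int]] = ()    # (pathway, step)
    isozyme_positions: Sequence[Tuple[int, int]] = ()   # (pathway, step)
    reversible_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pathways < 1 or self.pathway_length < 1:
            raise ValueError("need at least one pathway with one step")
        for p, s in list(self.orphan_positions) + list(self.isozyme_positions):
            if not (0 <= p < self.n_pathways and 0 <= s < self.pathway_length):
                raise ValueError(f"position ({p}, {s}) outside the network")


@dataclass
class GroundTruth:
    module_partition: List[Set[str]]                  # reaction ids per pathway
    module_genes: List[Set[str]]                      # incl. orphan genes
    orphan_assignments: Dict[str, str]                # reaction -> true gene
    precursors: List[str]
    essentiality: Optional[pd.DataFrame] = None       # module x experiment bool
    gene_module: Dict[str, int] = field(default_factory=dict)
    mixed_genotype: List[str] = field(default_factory=list)
    mismapped: Dict[str, str] = field(default_factory=dict)
    missing: List[str] = field(default_factory=list)


def make_toy_model(spec: PlantedNetworkSpec) -> Tuple[MetabolicModel, GroundTruth]:
    """Build a growth-feasible toy model with a planted module partition.

    Each pathway p is a chain S_p -> M_p1 -> ... -> PRE_p feeding a biomass
    reaction that consumes one unit of every precursor. One gene per
    non-orphan reaction; isozyme positions get an OR of two genes. All
    metabolites carry the placeholder formula "C" so chain reactions are
    mass balanced by construction.
    """
    rng = np.random.default_rng(spec.seed)
    mets: List[Metabolite] = []
    rxns: List[Reaction] = []
    partition: List[Set[str]] = []
    module_genes: List[Set[str]] = []
    orphans: Dict[str, str] = {}
    gene_module: Dict[str, int] = {}
    precursors: List[str] = []
    orphan_set = set(map(tuple, spec.orphan_positions))
    isozyme_set = set(map(tuple, spec.isozyme_positions))

    hub_id = "hub_c"
    if spec.shared_hub:
        mets.append(Metabolite("src_e", formula="C", compartment="e"))
        mets.append(Metabolite(hub_id, formula="C", compartment="c"))
        rxns.append(
            Reaction("EX_src_e", {"src_e": -1.0}, -DEFAULT_BOUND, DEFAULT_BOUND,
                     kind=ReactionKind.EXCHANGE)
        )
        rxns.append(Reaction("HUB_SYNTH", {"src_e": -1.0, hub_id: 1.0},
                             0.0, DEFAULT_BOUND))

    for p in range(spec.n_pathways):
        chain: Set[str] = set()
        genes: Set[str] = set()
        if spec.shared_hub:
            prev = hub_id
        else:
            sub = f"S{p}_e"
            mets.append(Metabolite(sub, formula="C", compartment="e"))
            rxns.append(
                Reaction(f"EX_S{p}_e", {sub: -1.0}, -DEFAULT_BOUND, DEFAULT_BOUND,
                         kind=ReactionKind.EXCHANGE)
            )
            prev = sub
        for s in range(spec.pathway_length):
            last = s == spec.pathway_length - 1
            nxt = f"PRE{p}_c" if last else f"M{p}_{s}_c"
            mets.append(Metabolite(nxt, formula="C", compartment="c"))
            rid = f"P{p}R{s}"
            reversible = rng.random() < spec.reversible_fraction
            if (p, s) in orphan_set:
                gpr = GPR(None)
                true_gene = f"orf{p}_{s}"
                orphans[rid] = true_gene
                genes.add(true_gene)
                gene_module[true_gene] = p
            elif (p, s) in isozyme_set:
                ga, gb = f"g{p}_{s}a", f"g{p}_{s}b"
                gpr = GPR.parse(f"{ga} or {gb}")
                genes |= {ga, gb}
                gene_module[ga] = gene_module[gb] = p
            else:
                g = f"g{p}_{s}"
                gpr = GPR.parse(g)
                genes.add(g)
                gene_module[g] = p
            rxns.append(
                Reaction(
                    rid,
                    {prev: -1.0, nxt: 1.0},
                    -DEFAULT_BOUND if reversible else 0.0,
                    DEFAULT_BOUND,
                    gpr=gpr,
                )
            )
            chain.add(rid)
            prev = nxt
        precursors.append(prev)
        partition.append(chain)
        module_genes.append(genes)

    rxns.append(
        Reaction(
            "BIOMASS",
            {pre: -1.0 for pre in precursors},
            0.0,
            DEFAULT_BOUND,
            kind=ReactionKind.BIOMASS,
        )
    )
    model = MetabolicModel(
        id=f"toy_{spec.n_pathways}x{spec.pathway_length}_seed{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
    )
    truth = GroundTruth(partition, module_genes, orphans, precursors,
                        gene_module=gene_module)
    return model, truth


@dataclass
class FitnessSimSpec:
    n_genes: int = 200
    n_experiments: int = 100
    module_essential_prob: float = 0.3
    essential_mean: float = -4.0
    essential_sd: float = 0.5
    neutral_sd: float = 0.3
    gene_noise_sd: float = 0.25
    mixed_genotype_fraction: float = 0.05
    attenuation: float = 0.4
    mismapped_fraction: float = 0.005
    missing_fraction: float = 0.05
    anaerobic_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("module_essential_prob", "mixed_genotype_fraction",
                     "mismapped_fraction", "missing_fraction",
                     "anaerobic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation must be in (0, 1]")


def simulate_fitness(
    model: MetabolicModel,
    truth: GroundTruth,
    spec: FitnessSimSpec,
) -> Tuple[FitnessMatrix, GroundTruth]:
    """Simulate a pooled fitness matrix over the planted modules.

    Per experiment each module is essential with the spec's probability;
    genes of an essential module draw a shared module effect around the
    essential mean, others a near-zero neutral effect, and every gene adds
    its own measurement noise. Mixed-genotype mutants attenuate the
    *biological effect* before noise is added (a pure post-hoc rescaling
    would leave Pearson cofitness untouched); mis-mapped mutants inherit
    another random gene's trajectory; missing mutants are dropped.
    """
    rng = np.random.default_rng(spec.seed)
    module_genes = [sorted(gs) for gs in truth.module_genes]
    planted = [g for gs in module_genes for g in gs]
    n_background = max(spec.n_genes - len(planted), 0)
    background = [f"bg{i:04d}" for i in range(n_background)]
    genes = planted + background
    experiments = [f"exp{e:03d}" for e in range(spec.n_experiments)]
    n_mod = len(module_genes)

    essential = rng.random((n_mod, spec.n_experiments)) < spec.module_essential_prob
    # shared per-module-per-experiment effect plus per-gene wobble
    module_effect = np.where(
        essential,
        rng.normal(spec.essential_mean, spec.essential_sd, essential.shape),
        rng.normal(0.0, spec.neutral_sd, essential.shape),
    )

    effect = np.zeros((len(genes), spec.n_experiments))
    for gi, g in enumerate(genes):
        if g in truth.gene_module:
            effect[gi] = module_effect[truth.gene_module[g]]
        else:
            effect[gi] = rng.normal(0.0, spec.neutral_sd, spec.n_experiments)

    mixed = [g for g in genes if rng.random() < spec.mixed_genotype_fraction]
    att = np.ones(len(genes))
    mixed_set = set(mixed)
    for gi, g in enumerate(genes):
        if g in mixed_set:
            att[gi] = spec.attenuation

    # A mis-mapped barcode attributes another locus's phenotype to this
    # gene: the biological effect is the donor's, the counting noise stays
    # the gene's own (scores are averages over this gene's barcodes).
    mismapped: Dict[str, str] = {}
    for gi, g in enumerate(genes):
        if rng.random() < spec.mismapped_fraction:
            donor = int(rng.integers(len(genes)))
            if donor != gi:
                effect[gi] = effect[donor]
                mismapped[g] = genes[donor]

    noise = rng.normal(0.0, spec.gene_noise_sd, effect.shape)
    scores = att[:, None] * effect + noise

    # Missing mutants emulate genes essential during library construction;
    # orphan candidate genes keep their mutants (candidate ranking
    # presupposes the candidate's mutant exists in the collection).
    protected = set(truth.orphan_assignments.values())
    missing = [
        g for g in genes
        if rng.random() < spec.missing_fraction and g not in protected
    ]
    frame = pd.DataFrame(scores, index=genes, columns=experiments)
    frame = frame.drop(index=missing)

    anaerobic = rng.random(spec.n_experiments) < spec.anaerobic_fraction
    metadata = pd.DataFrame(
        {"anaerobic": anaerobic, "medium": "synthetic-minimal"},
        index=pd.Index(experiments, name="experiment"),
    )
    fm = FitnessMatrix(frame, metadata)
    out = GroundTruth(
        module_partition=truth.module_partition,
        module_genes=truth.module_genes,
        orphan_assignments=dict(truth.orphan_assignments),
        precursors=truth.precursors,
        essentiality=pd.DataFrame(
            essential, index=[f"module{m}" for m in range(n_mod)], columns=experiments
        ),
        gene_module=dict(truth.gene_module),
        mixed_genotype=mixed,
        mismapped=mismapped,
        missing=missing,
    )
    return fm, out


def random_flux_network(
    n_internal: int = 6,
    n_metabolites: int = 4,
    n_boundary: int = 3,
    reversible_fraction: float = 0.25,
    seed: int = 0,
) -> MetabolicModel:
    """A random stoichiometric network for coupling/FBA stress tests.

    Internal reactions draw 2-3 random metabolites with unit/double
    coefficients; boundary reactions are single-metabolite sources and
    sinks that open the flux cone. No biological realism intended — the
    point is exercising the LP machinery on arbitrary cones.
    """
    rng = np.random.default_rng(seed)
    mets = [Metabolite(f"m{i}_c", formula="C") for i in range(n_metabolites)]
    rxns: List[Reaction] = []
    for i in range(n_internal):
        size = int(rng.integers(2, 4))
        chosen = rng.choice(n_metabolites, size=min(size, n_metabolites), replace=False)
        stoich = {}
        for pos, mi in enumerate(chosen):
            sign = -1.0 if pos == 0 else (1.0 if rng.random() < 0.7 else -1.0)
            stoich[f"m{mi}_c"] = sign * float(rng.integers(1, 3))
        reversible = rng.random() < reversible_fraction
        rxns.append(
            Reaction(f"R{i}", stoich,
                     -DEFAULT_BOUND if reversible else 0.0, DEFAULT_BOUND)
        )
    for b in range(n_boundary):
        mi = int(rng.integers(n_metabolites))
        if rng.random() < 0.5:
            rxns.append(Reaction(f"SRC_b{b}", {f"m{mi}_c": 1.0},
                                 0.0, DEFAULT_BOUND, kind=ReactionKind.SINK))
        else:
            rxns.append(Reaction(f"SINK_b{b}", {f"m{mi}_c": -1.0},
                                 0.0, DEFAULT_BOUND, kind=ReactionKind.SINK))
    return MetabolicModel(
        id=f"random_net_seed{seed}", metabolites=mets, reactions=rxns
    )


def two_state_fitness(
    n_genes: int = 400,
    essential_fraction: float = 0.5,
    n_replicates: int = 2,
    essential_mean: float = -4.0,
    essential_sd: float = 0.5,
    neutral_sd: float = 0.5,
    seed: int = 0,
) -> Tuple[FitnessMatrix, Dict[str, str]]:
    """Two-Gaussian replicate fitness (neutral around 0, essential around
    -4) with ground-truth growth predictions, for cutoff optimisation."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    is_essential = rng.random(n_genes) < essential_fraction
    cols = {}
    for r in range(n_replicates):
        cols[f"rep{r}"] = np.where(
            is_essential,
            rng.normal(essential_mean, essential_sd, n_genes),
            rng.normal(0.0, neutral_sd, n_genes),
        )
    frame = pd.DataFrame(cols, index=genes)
    metadata = pd.DataFrame(
        {"anaerobic": True, "medium": "synthetic-minimal"},
        index=pd.Index(list(cols), name="experiment"),
    )
    predictions = {
        g: ("NoGrowth" if e else "Growth") for g, e in zip(genes, is_essential)
    }
    return FitnessMatrix(frame, metadata), predictions
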