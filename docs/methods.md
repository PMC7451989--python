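# Methods

This note documents the models, algorithms, and numerical choices behind
`fluxcouple`, and what the synthetic benchmarks do and do not demonstrate.

## Constraint-based model core

A model is a stoichiometric matrix S (metabolites × reactions) with flux
bounds in mmol/gDW/h, boolean gene–protein–reaction (GPR) trees, and
biomass bookkeeping. Growth-associated maintenance (GAM, mmol ATP/gDW) is
an ATP coefficient inside the biomass equation; non-growth-associated
maintenance (NGAM, mmol ATP/gDW/h) is the lower bound of the ATP
maintenance reaction — `ngam` on the model object is taken from that bound
when not set explicitly.

GPR grammar: parenthesised infix with case-insensitive `and`/`or`, AND
binding tighter than OR (matching common SBML-fbc flattening). Deletion
evaluation is monotone by construction: AND needs all children, OR any,
and an empty GPR is unaffected by deletions. A GPR whose *root* is an OR
marks the reaction as isozyme-backed; only this top-level case excludes
genes from module gene sets, since a nested OR inside a complex does not
make the whole reaction redundant per gene.

Reaction kinds are inferred from id conventions (`EX_` exchange,
`SINK_`/`DM_` sink, ids containing `biomass`, `ATPM` maintenance,
cross-compartment stoichiometry = transport) with an explicit per-reaction
annotation column as fallback in the tabular dialect. Exchange and sink
reactions must touch exactly one metabolite. Mass/charge balance is
checked for every non-exchange/sink/biomass reaction by summing element
counts (simple `ElementN` formula parsing) weighted by stoichiometry;
proton/water imbalances are reported, never auto-corrected.

Media are maps exchange-id → (lb, ub): uptake is a negative lower bound;
applying a medium closes unlisted uptakes and leaves every secretion open
at 1000 mmol/gDW/h, so any extracellular compound may be secreted. I/O
supports SBML Level 3 + fbc (via libsbml) and a two-sheet TSV dialect
(`reactions.tsv` with equation strings, `metabolites.tsv`, optional
`model.tsv` key/value sheet); write→read round-trips preserve
stoichiometry, bounds, GPRs, and kinds.

## LP/MILP engine

All LPs use scipy's HiGHS interface (deterministic for fixed input; dual
simplex defaults, feasibility tolerances ~1e-9). Choices that matter:

* **Zero-growth tolerance 1e-9 1/h** — a gene is essential when the
  deletion optimum falls at or below it. The binary essentiality rule
  needs a numeric floor; 1e-9 sits far below any biological growth rate
  and far above solver noise.
* **FVA at fraction 1.0** of the optimum, implemented by raising the
  objective reaction's lower bound to the optimum minus a 1e-9 slack
  (absolute + relative) to keep the fixed-objective LPs feasible.
* **Gap-fill growth threshold 1e-3 1/h** — strictly positive but small;
  feasibility restoration, not yield optimisation. The MILP gates each
  candidate reaction's bounds with a binary via big-M rows (M = the
  candidate's own bound, 1e4 when infinite) and minimises the indicator
  sum; HiGHS branch-and-bound is deterministic, and minimality is verified
  against exhaustive subset enumeration in the tests.
* **Conditional-essentiality (MEGS-style) search** is exhaustive over gene
  subsets up to 2 knockouts crossed with a media catalog: a design is a
  (knockout set, medium) pair where the host grows and additionally
  disabling the target reaction abolishes growth. Exhaustive search is
  verifiable at desk scale; heuristic strain design is out of scope.
* **MFA comparison** orients predicted flux to the measured direction,
  floors it at 1e-4 (so zero or wrong-sign predictions appear at a finite
  log-scale position), and flags deviations outside the 2-fold band.
* **Node balance reports** fix biomass at a given growth rate, relax the
  node metabolite's steady-state row with an unbounded relief flux, and
  FVA the reactions touching the node: reactions still pinned to a point
  are locked by the rest of the network (typically a fixed ratio with the
  biomass equation); the net node production of the locked set is the
  balancing flux the free reactions must carry. Relaxing the row (rather
  than testing ratios reaction-by-reaction) also classifies correctly
  when only one free route exists, which would itself be pinned if the
  node constraint were kept.

## Flux coupling

Reversible reactions are split into non-negative forward/reverse
components (`_f`/`_r`); component count = #irreversible + 2·#reversible.
Coupling is evaluated on the flux *cone* {S·v = 0, v ≥ 0} — finite
capacities scale out, only closed components (ub = 0) are excluded — by
normalising v_j = 1 and solving two LPs for Rmin/Rmax of v_i/v_j.
Classification tolerance: ratio equality within 1e-6 relative, zero below
1e-8; an unbounded max-LP encodes Rmax = +∞ explicitly. Blocked
components are prefiltered by one capped LP each (bounds clipped to
[0, 1]), both because the normalisation is undefined for them and to cut
the LP count.

Module extraction exploits that full coupling is an equivalence relation:
each component is compared only against one representative per existing
class, and partial edges are then resolved between class representatives
only (coupling class is invariant within a fully coupled class). Fully
coupled modules are the classes of size ≥ 2; a partially coupled module is
a maximal connected set under partial∪full edges containing at least one
partial pair — the convention that reproduces mixed-suffix module tables.
Directional couplings are computed but do not form modules.

Sink augmentation adds one irreversible sink per biomass component /
terminal product and opens every exchange to [−1000, 1000] (full
in-silico medium). Without the sinks the biomass equation glues all
precursor pathways into a single module (the tests assert exactly this);
with them each pathway couples to its own precursor drain. Note that the
split components of a reversible exchange form a futile two-cycle, which
is why exchanges end up only directionally coupled to the pathways they
feed — a standard property of coupling on the split cone.

Condition-dependent coupling closes components per condition constraints
(e.g. oxygen exchange fixed to zero), recomputes modules, and reports the
components newly fully coupled into each baseline module. Shrinking the
cone can only add full couplings among still-unblocked components, never
remove them; blocked components drop out of their modules.

## Fitness integration

Phenotype classification at cutoff c is strict: a gene grows iff *every*
replicate score is > c, has no growth iff all are ≤ c, is Inconsistent
when replicates straddle c, and Unavailable with no scores. Inconsistent
and Unavailable genes are tallied separately and excluded from the
agreement cells (GG/GNG/NGG/NGNG). The error curve reports, per cutoff,
GNG and NGG as fractions of consistent genes (total error = their sum)
and the inconsistent fraction of classified genes; the optimum is the
total-error argmin with ties broken toward the most negative cutoff
(conservative toward calling growth). The default grid −3.0…0.0 in steps
of 0.01 brackets the operating range of log2 pooled fitness scores.
Association is a Pearson chi-squared on the consistent 2×2 (df = 1, no
continuity correction), which errors on zero marginals.

A consequence of the two-replicate design worth knowing: genes straddling
a very negative cutoff become Inconsistent rather than errors, so the
zero-error tie region can extend to the negative end of the grid and the
tie-break then reports its most negative point.

## Cofitness statistics

Cofitness is pairwise-complete Pearson correlation of gene fitness
vectors (pandas `corr`), with a minimum overlap of 10 shared experiments
per pair (smaller overlaps give unstable r and are reported missing);
zero-variance genes are flagged and their pairs missing; missing entries
are excluded pairwise, not listwise. Module average cofitness is the mean
over defined pairs of the k·(k−1)/2 combinations.

The null threshold τ_k is the empirical 95th percentile (linear
interpolation between order statistics) of average cofitness over
k-gene sets sampled without replacement from a configurable pool —
defaulting to the model's genes present in the fitness matrix, mirroring
a metabolic-gene null. Sampling is vectorised (random-key argpartition in
chunks) and bit-reproducible from the seed. For i.i.d. null data τ_k
decreases in k, since averaging more pairs shrinks the upper tail.

Candidate ranking scores every non-member gene by its mean cofitness to
the module's known genes (missing pairs dropped), descending, with ties
broken by locus tag for determinism. Outlier listing orders module
members by ascending mean cofitness to the other members. Significance
uses the strict comparison (average > τ_k).

## Synthetic data: what it emulates, and what it does not

The toy networks plant parallel linear pathways (default 5 pathways of 4
reactions, optionally sharing a source hub) ending in biomass precursors,
with one gene per reaction, optional isozyme pairs (OR GPRs), optional
orphan reactions (no GPR), and placeholder single-carbon formulas so
chains are balanced by construction. Pathway length 4 gives the orphan's
module three known genes, in the lower-middle of the 2–19-reaction range
real coupling modules span.

The fitness simulator draws, per experiment, each module essential with
probability 0.3; genes of an essential module share a module effect
~N(−4, 0.5) (else ~N(0, 0.3)) and add per-gene noise ~N(0, 0.25),
emulating the bimodal score distribution of pooled data (modes near 0 and
−4). Corruption modes:

* **Mixed genotypes** (fraction 0.05, attenuation 0.4): wild-type gene
  copies mask the knockout, shrinking the *biological effect* toward
  zero before measurement noise is added. The order matters: attenuating
  the realised scores after noise would be a pure per-gene affine map and
  leave Pearson cofitness untouched; attenuating the effect degrades
  correlation, which is the observable consequence the simulation needs.
* **Mis-mapped barcodes** (fraction 0.005): the gene inherits another
  locus's biological effect with its own counting noise — not a verbatim
  copy of the donor's realised scores, because per-gene scores average
  several independently mapped insertion strains (the same averaging is
  why a fully mis-mapped gene is rare).
* **Missing mutants** (fraction 0.05): dropped rows, emulating genes
  essential during library construction. Orphan candidate genes are never
  dropped: candidate ranking presupposes the candidate's mutant exists.

Experiments are flagged anaerobic with probability 0.1. All draws come
from one seeded generator; the same seed yields bit-identical output.

What passing the synthetic benchmarks shows: the pipeline recovers
planted coupling partitions exactly, ranks a planted orphan first in
≥95% of replicates, and separates planted modules from resampled nulls
under realistic noise and corruption. What it does not show: robustness
to correlated experimental batches, condition-specific essentiality
structure beyond a single Bernoulli rate, polar effects spanning operons,
or the GPR complexity of a curated genome-scale reconstruction — real
datasets can be harder in all four ways.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: 50 random networks of
≤ 12 components for coupling-oracle equivalence (every pair checked
against an independently assembled two-LP oracle); 20 generator seeds for
planted-module recovery; 100 simulation replicates at 200 genes × 100
experiments for orphan ranking and module significance with τ_k from
10,000 null samples (the τ estimator is checked to be stable within 0.01
between 10,000 and 100,000 samples); 20 seeds of 400-gene bimodal
fitness for cutoff optimisation; and 50 seeded gap-fill instances with
≤ 12 candidates verified against exhaustive enumeration. These sizes give
tight Monte-Carlo error on the reported rates while keeping a full run in
minutes on one CPU.

## Known limitations

* Coupling on the split cone reports exchange components as only
  directionally coupled to the pathways they feed (futile-cycle
  artifact); network compression (F2C2-style) is not implemented.
* The tabular dialect stores no compartment topology beyond the
  metabolite compartment field.
* `infer_kind` trusts id conventions; models with unconventional ids need
  the explicit kind column.
* The MEGS search is exhaustive and therefore limited to ≤ 2 knockouts at
  genome scale.
* GAM is carried as model metadata only; editing the biomass ATP
  coefficient is left to the model author.
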