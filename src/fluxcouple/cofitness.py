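"""Cofitness statistics: pairwise Pearson correlations of gene fitness
vectors, module averages, resampling null thresholds, and candidate ranking.

Cofitness of two genes is the Pearson correlation of their fitness-score
vectors across experiments (pairwise-complete over missing entries). A
module's average cofitness is the mean over all k-choose-2 gene pairs; its
significance is judged against tau_k, the 95th percentile of average
cofitness of randomly sampled k-gene sets from a null pool (the metabolic
genes present in the fitness data). Candidate genes for an orphan reaction
are ranked by mean cofitness to the module's known genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitness import FitnessMatrix

MIN_OVERLAP = 10  # experiments a pair must share for a defined correlation


@dataclass
class CofitnessMatrix:
    r: pd.DataFrame                 # gene x gene Pearson correlations
    n_obs: pd.DataFrame             # per-pair complete-observation counts
    flagged_zero_variance: List[str] = field(default_factory=list)

    @property
    def genes(self) -> List[str]:
        return list(self.r.index)

    def pair(self, a: str, b: str) -> float:
        return float(self.r.at[a, b])


def cofitness(
    fm: FitnessMatrix,
    experiments: Optional[Sequence[str]] = None,
    min_overlap: int = MIN_OVERLAP,
) -> CofitnessMatrix:
    """Pairwise-complete Pearson cofitness over (a subset of) experiments.

    Pairs sharing fewer than ``min_overlap`` complete observations are
    missing; genes with zero variance are flagged and their pairs missing.
    """
    scores = fm.scores if experiments is None else fm.scores[list(experiments)]
    x = scores.T  # experiments x genes: pandas corr() correlates columns
    r = x.corr(method="pearson", min_periods=min_overlap)
    present = x.notna().astype(np.int64)
    n_obs = pd.DataFrame(
        present.T.to_numpy() @ present.to_numpy(),
        index=r.index,
        columns=r.columns,
    )
    stds = x.std(ddof=0)
    flagged = sorted(stds.index[(stds == 0) | stds.isna()])
    np.fill_diagonal(r.values, 1.0)
    return CofitnessMatrix(r, n_obs, flagged)


@dataclass(frozen=True)
class ModuleCofitness:
    module_id: str
    k: int
    average: float
    threshold: Optional[float]
    significant: Optional[bool]
    n_pairs: int


def average_cofitness(cof: CofitnessMatrix, genes: Sequence[str]) -> Tuple[float, int]:
    """Mean cofitness over all defined pairs of a gene set; NaN pairs are
    dropped from the mean. Returns (average, number of defined pairs)."""
    genes = [g for g in genes if g in cof.r.index]
    vals = [
        cof.r.at[a, b]
        for a, b in itertools.combinations(genes, 2)
    ]
    arr = np.array(vals, dtype=float)
    defined = arr[~np.isnan(arr)]
    if defined.size == 0:
        return float("nan"), 0
    return float(defined.mean()), int(defined.size)


def module_cofitness(
    cof: CofitnessMatrix,
    modules: Dict[str, Sequence[str]],
    thresholds: Optional[Dict[int, float]] = None,
) -> List[ModuleCofitness]:
    """Average cofitness per module, flagged against the size-k threshold
    when one is supplied (strictly greater counts as significant)."""
    out = []
    for mid, genes in modules.items():
        genes = list(genes)
        avg, n_pairs = average_cofitness(cof, genes)
        tau = thresholds.get(len(genes)) if thresholds else None
        sig = None if tau is None or np.isnan(avg) else bool(avg > tau)
        out.append(ModuleCofitness(mid, len(genes), avg, tau, sig, n_pairs))
    return out


@dataclass(frozen=True)
class NullThreshold:
    k: int
    n_samples: int
    percentile: float
    threshold: float
    seed: int
    pool_size: int


def null_threshold(
    cof: CofitnessMatrix,
    k: int,
    pool: Sequence[str],
    n_samples: int = 100_000,
    percentile: float = 95.0,
    seed: int = 0,
) -> NullThreshold:
    """tau_k: the empirical percentile of average cofitness over randomly
    sampled k-gene sets (sampling without replacement within each set).

    The percentile uses linear interpolation between order statistics and
    the draw is reproducible from the seed.
    """
    pool = [g for g in pool if g in cof.r.index]
    m = len(pool)
    if k > m:
        raise ValueError(f"module size {k} exceeds pool size {m}")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    rng = np.random.default_rng(seed)
    idx_of = {g: i for i, g in enumerate(cof.r.index)}
    pool_idx = np.array([idx_of[g] for g in pool])
    C = cof.r.to_numpy()
    pairs = list(itertools.combinations(range(k), 2))
    averages = np.empty(n_samples)
    chunk = 20_000
    pos = 0
    while pos < n_samples:
        size = min(chunk, n_samples - pos)
        keys = rng.random((size, m))
        take = np.argpartition(keys, k - 1, axis=1)[:, :k]
        sel = pool_idx[take]  # (size, k) gene indices
        vals = np.stack([C[sel[:, a], sel[:, b]] for a, b in pairs])
        averages[pos : pos + size] = np.nanmean(vals, axis=0)
        pos += size
    tau = float(np.percentile(averages, percentile))  # linear interpolation
    return NullThreshold(k, n_samples, percentile, tau, seed, m)


@dataclass
class CandidateRanking:
    module_genes: List[str]
    ranking: List[Tuple[str, float]]   # (gene, mean cofitness), descending

    def rank_of(self, gene: str) -> Optional[int]:
        """1-based rank of a gene, or None if absent from the ranking."""
        for i, (g, _) in enumerate(self.ranking, start=1):
            if g == gene:
                return i
        return None


def rank_candidates(
    cof: CofitnessMatrix,
    module_genes: Sequence[str],
    search_pool: Optional[Sequence[str]] = None,
) -> CandidateRanking:
    """Rank non-member genes by mean cofitness to the module's known genes.

    Missing pairs are dropped from each mean; genes with no defined pair
    rank last. Ties break by locus-tag lexicographic order for determinism.
    """
    module_genes = sorted(set(module_genes))
    if not module_genes:
        raise ValueError("module gene set is empty")
    pool = list(search_pool) if search_pool is not None else cof.genes
    members = set(module_genes)
    sub = cof.r.loc[[g for g in module_genes if g in cof.r.index]]
    scores: List[Tuple[str, float]] = []
    for gene in pool:
        if gene in members or gene not in cof.r.columns:
            continue
        mean = float(sub[gene].mean(skipna=True))
        scores.append((gene, mean))
    scores.sort(key=lambda t: (-(t[1] if not np.isnan(t[1]) else -np.inf), t[0]))
    return CandidateRanking(module_genes, scores)


def outlier_genes(
    cof: CofitnessMatrix, module_genes: Sequence[str]
) -> List[Tuple[str, float]]:
    """Members ordered by ascending mean cofitness to the other members —
    the poorly correlated genes that drag a module's average down."""
    module_genes = sorted(set(g for g in module_genes if g in cof.r.index))
    if len(module_genes) < 3:
        raise ValueError("outlier detection needs a module of size >= 3")
    out = []
    for gene in module_genes:
        others = [g for g in module_genes if g != gene]
        mean = float(cof.r.loc[gene, others].mean(skipna=True))
        out.append((gene, mean))
    out.sort(key=lambda t: (t[1], t[0]))
    return out
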