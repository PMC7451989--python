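"""Pooled transposon-mutant fitness data and model/phenotype comparison.

A fitness score is the average log2 change in abundance of a gene's barcoded
mutant over a pooled growth experiment; strongly negative scores mean the
mutant failed to grow. Mutants are classified into growth / no-growth
phenotypes at a score cutoff, compared against FBA essentiality predictions
in a GG/GNG/NGG/NGNG confusion taxonomy, and the cutoff is chosen to
minimise the total misprediction rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


class FitnessParseError(ValueError):
    pass


@dataclass
class FitnessMatrix:
    """Gene x experiment fitness scores with per-experiment metadata.

    ``scores`` is indexed by locus tag with experiment-id columns; missing
    entries are NaN. ``metadata`` is indexed by experiment id and carries at
    least an ``anaerobic`` flag and a ``medium`` label.
    """

    scores: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        if self.scores.index.duplicated().any():
            dups = self.scores.index[self.scores.index.duplicated()].tolist()
            raise FitnessParseError(f"duplicate gene rows: {dups}")
        if self.scores.columns.duplicated().any():
            raise FitnessParseError("duplicate experiment columns")
        missing_meta = set(self.scores.columns) - set(self.metadata.index)
        if missing_meta:
            raise FitnessParseError(
                f"experiments without metadata: {sorted(missing_meta)}"
            )

    @property
    def genes(self) -> List[str]:
        return list(self.scores.index)

    @property
    def experiments(self) -> List[str]:
        return list(self.scores.columns)

    def anaerobic_experiments(self) -> List[str]:
        flags = self.metadata.loc[self.scores.columns, "anaerobic"]
        return [e for e, a in flags.items() if bool(a)]

    def subset(self, experiments: Sequence[str]) -> "FitnessMatrix":
        return FitnessMatrix(
            self.scores[list(experiments)], self.metadata.loc[list(experiments)]
        )


def read_fitness(scores_path: str, metadata_path: Optional[str] = None) -> FitnessMatrix:
    """Read a fitness TSV (rows = locus tags, columns = experiment ids) and
    its metadata sidecar; non-numeric cells become missing."""
    raw = pd.read_csv(scores_path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].tolist()
        raise FitnessParseError(f"duplicate gene rows in {scores_path}: {dups}")
    scores = raw.apply(pd.to_numeric, errors="coerce")
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        if "anaerobic" in metadata:
            metadata["anaerobic"] = metadata["anaerobic"].astype(bool)
    else:
        metadata = pd.DataFrame(
            {"anaerobic": False, "medium": ""}, index=scores.columns
        )
    return FitnessMatrix(scores, metadata)


def write_fitness(fm: FitnessMatrix, scores_path: str, metadata_path: str) -> None:
    fm.scores.to_csv(scores_path, sep="\t", index_label="gene")
    fm.metadata.to_csv(metadata_path, sep="\t", index_label="experiment")


GROWTH, NOGROWTH, INCONSISTENT, UNAVAILABLE = (
    "Growth",
    "NoGrowth",
    "Inconsistent",
    "Unavailable",
)


@dataclass(frozen=True)
class PhenotypeCall:
    gene_id: str
    phenotype: str


def classify_growth(
    fm: FitnessMatrix,
    replicate_experiments: Sequence[str],
    cutoff: float,
    genes: Optional[Sequence[str]] = None,
) -> List[PhenotypeCall]:
    """Growth-phenotype calls from replicate experiments at a score cutoff.

    A gene grows if every replicate score is strictly above the cutoff, has
    no growth if every score is at or below it, is Inconsistent when the
    replicates disagree, and Unavailable when no replicate score exists.
    """
    missing = [e for e in replicate_experiments if e not in fm.scores.columns]
    if missing:
        raise KeyError(f"unknown experiment ids: {missing}")
    if not replicate_experiments:
        raise ValueError("need at least one replicate experiment")
    genes = fm.genes if genes is None else list(genes)
    sub = fm.scores.reindex(genes)[list(replicate_experiments)]
    calls = []
    for gene, row in sub.iterrows():
        vals = row.dropna().to_numpy()
        if vals.size == 0:
            calls.append(PhenotypeCall(gene, UNAVAILABLE))
        elif (vals > cutoff).all():
            calls.append(PhenotypeCall(gene, GROWTH))
        elif (vals <= cutoff).all():
            calls.append(PhenotypeCall(gene, NOGROWTH))
        else:
            calls.append(PhenotypeCall(gene, INCONSISTENT))
    return calls


@dataclass
class ConfusionTable:
    gg: int = 0
    gng: int = 0
    ngg: int = 0
    ngng: int = 0
    gi: int = 0
    ngi: int = 0
    unavailable_predicted_growth: int = 0
    unavailable_predicted_nogrowth: int = 0

    @property
    def consistent(self) -> int:
        return self.gg + self.gng + self.ngg + self.ngng

    def as_dict(self) -> Dict[str, int]:
        return {
            "GG": self.gg,
            "GNG": self.gng,
            "NGG": self.ngg,
            "NGNG": self.ngng,
            "GI": self.gi,
            "NGI": self.ngi,
            "unavailable_predicted_growth": self.unavailable_predicted_growth,
            "unavailable_predicted_nogrowth": self.unavailable_predicted_nogrowth,
        }


def confusion(
    predictions: Mapping[str, str] | Iterable,
    phenotypes: Iterable[PhenotypeCall],
) -> ConfusionTable:
    """Cross-tabulate model predictions against pooled growth phenotypes.

    ``predictions`` maps gene -> "Growth"/"NoGrowth" (EssentialityCall
    sequences are accepted). Genes with Inconsistent or Unavailable
    phenotypes are tallied separately and excluded from the agreement cells.
    """
    pred = _prediction_map(predictions)
    pheno = {c.gene_id: c.phenotype for c in phenotypes}
    table = ConfusionTable()
    for gene in sorted(pred):
        p = pred[gene]
        e = pheno.get(gene, UNAVAILABLE)
        if e == UNAVAILABLE:
            if p == GROWTH:
                table.unavailable_predicted_growth += 1
            else:
                table.unavailable_predicted_nogrowth += 1
        elif e == INCONSISTENT:
            if p == GROWTH:
                table.gi += 1
            else:
                table.ngi += 1
        elif p == GROWTH:
            table.gg += 1 if e == GROWTH else 0
            table.gng += 1 if e == NOGROWTH else 0
        else:
            table.ngg += 1 if e == GROWTH else 0
            table.ngng += 1 if e == NOGROWTH else 0
    return table


def _prediction_map(predictions) -> Dict[str, str]:
    if isinstance(predictions, Mapping):
        return dict(predictions)
    out = {}
    for item in predictions:
        out[item.gene_id] = item.phenotype
    return out


@dataclass
class ErrorCurve:
    cutoffs: np.ndarray
    fp_fraction: np.ndarray       # GNG / consistent
    fn_fraction: np.ndarray       # NGG / consistent
    inconsistent_fraction: np.ndarray
    total_error: np.ndarray
    best_cutoff: float
    best_total_error: float


def error_curve(
    fm: FitnessMatrix,
    replicate_experiments: Sequence[str],
    predictions: Mapping[str, str] | Iterable,
    cutoff_grid: Optional[Sequence[float]] = None,
) -> ErrorCurve:
    """False-positive / false-negative / inconsistent fractions over a grid
    of cutoffs, with the total-error-minimising cutoff (ties break toward
    the most negative cutoff)."""
    if cutoff_grid is None:
        cutoff_grid = np.round(np.arange(-3.0, 0.0 + 1e-12, 0.01), 10)
    grid = np.asarray(list(cutoff_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty cutoff grid")
    pred = _prediction_map(predictions)
    fp, fn, inc, tot = [], [], [], []
    for c in grid:
        table = confusion(pred, classify_growth(fm, replicate_experiments, c, genes=list(pred)))
        n_cons = table.consistent
        n_classified = n_cons + table.gi + table.ngi
        fp.append(table.gng / n_cons if n_cons else 0.0)
        fn.append(table.ngg / n_cons if n_cons else 0.0)
        inc.append((table.gi + table.ngi) / n_classified if n_classified else 0.0)
        tot.append(fp[-1] + fn[-1])
    tot_arr = np.array(tot)
    tied = np.flatnonzero(tot_arr == tot_arr.min())
    best_cutoff = float(grid[tied].min())  # ties break to most negative
    return ErrorCurve(
        grid,
        np.array(fp),
        np.array(fn),
        np.array(inc),
        tot_arr,
        best_cutoff,
        float(tot_arr.min()),
    )


def association_test(table: ConfusionTable) -> Tuple[float, float]:
    """Pearson chi-squared (df = 1, no continuity correction) on the 2x2
    consistent-phenotype table; significant association means the model's
    essentiality predictions track the pooled phenotypes."""
    obs = np.array([[table.gg, table.gng], [table.ngg, table.ngng]], dtype=float)
    if obs.sum() <= 0:
        raise ValueError("empty confusion table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in confusion table")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    assert dof == 1
    return float(stat), float(p)
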