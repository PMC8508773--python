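"""Relative quantification of a target gene by the 2^-ddCt method.

For each sample, dCt = Ct_target - Ct_ref where Ct_ref is the arithmetic
mean Ct of the chosen reference genes (equivalent to geometric-mean
normalization on the quantity scale).  dCt is averaged within each sample
group, referenced to a calibrator group (ddCt = group dCt - calibrator
dCt), and reported as fold change 2^-ddCt.  Perfect doubling per cycle is
assumed (no efficiency correction).

Replicate dispersion is the SD of per-replicate dCt within the group,
propagated to a fold-change range 2^-(ddCt -/+ SD).

``compare_normalizations`` quantifies how much the choice of reference
genes matters: the divergence between two reference sets is the maximum
over groups of the absolute log2 ratio of the fold changes they produce.
An unstable reference with condition-dependent expression shows up as a
large divergence; stable references give divergence near zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .ct_data import AnalysisGroup, CtDataError, CtMatrix, SampleAnnotation

__all__ = [
    "DdctResult",
    "ddct",
    "ComparisonResult",
    "compare_normalizations",
    "DeltaDeltaCt",
]


@dataclass
class DdctResult:
    """Fold changes of one target under one reference-gene set."""

    table: pd.DataFrame          # per group: n, mean_dct, sd_dct, ddct, fold,
                                 # fold_lo, fold_hi
    target: str
    references: list[str]
    calibrator: str

    def summary(self) -> str:
        head = (f"2^-ddCt quantification of {self.target} "
                f"(references: {', '.join(self.references)}; "
                f"calibrator: {self.calibrator})")
        return head + "\n" + self.table.round(4).to_string()


def _group_dct(matrix: CtMatrix, target: str, references: Sequence[str],
               labels: pd.Series) -> pd.DataFrame:
    ct = matrix.data
    ref_ct = ct.loc[list(references)].mean(axis=0)
    dct = ct.loc[target] - ref_ct
    grouped = dct.groupby(labels.loc[dct.index])
    return pd.DataFrame({
        "n": grouped.size(),
        "mean_dct": grouped.mean(),
        "sd_dct": grouped.std(ddof=1),
    })


def ddct(matrix: CtMatrix, target: str, references: Sequence[str],
         calibrator: str, annot: SampleAnnotation,
         group_by: str = "sample_class",
         sample_ids: Sequence[str] | None = None) -> DdctResult:
    """2^-ddCt fold change of ``target`` per sample group vs a calibrator.

    ``calibrator`` is a level of the ``group_by`` annotation column.
    ``sample_ids`` restricts the analysis (e.g. one cultivar); default all
    samples of the matrix.
    """
    references = list(references)
    if not references:
        raise CtDataError("at least one reference gene is required")
    if target in references:
        raise CtDataError(
            f"target {target!r} cannot be among its own references"
        )
    missing = [g for g in [target, *references] if g not in matrix.gene_ids]
    if missing:
        raise CtDataError(f"genes not in matrix: {missing}")
    sub = matrix.select_samples(list(sample_ids)) if sample_ids else matrix
    labels = annot.labels_for(sub.sample_ids, group_by)
    if calibrator not in set(labels):
        raise CtDataError(
            f"calibrator group {calibrator!r} not among {sorted(set(labels))}"
        )
    table = _group_dct(sub, target, references, labels)
    cal = table.at[calibrator, "mean_dct"]
    table["ddct"] = table["mean_dct"] - cal
    table["fold"] = np.power(2.0, -table["ddct"])
    sd = table["sd_dct"].fillna(0.0)
    table["fold_lo"] = np.power(2.0, -(table["ddct"] + sd))
    table["fold_hi"] = np.power(2.0, -(table["ddct"] - sd))
    table.index.name = group_by
    return DdctResult(table=table, target=target, references=references,
                      calibrator=calibrator)


@dataclass
class ComparisonResult:
    """Fold changes under several reference sets, with divergence summary."""

    table: pd.DataFrame            # rows: group, columns: one per ref set
    divergence: pd.DataFrame       # ref_set x ref_set max |log2 fold ratio|
    results: dict[str, DdctResult]

    @property
    def max_divergence(self) -> float:
        return float(self.divergence.to_numpy().max())

    def summary(self) -> str:
        return ("fold change by reference set\n"
                + self.table.round(4).to_string()
                + "\n\nmax |log2 fold ratio| between reference sets\n"
                + self.divergence.round(4).to_string())


def _ref_label(refs: Sequence[str]) -> str:
    return "+".join(refs)


def compare_normalizations(matrix: CtMatrix, target: str,
                           ref_sets: Sequence[Sequence[str]], calibrator: str,
                           annot: SampleAnnotation,
                           group_by: str = "sample_class",
                           sample_ids: Sequence[str] | None = None
                           ) -> ComparisonResult:
    """Fold changes of ``target`` under each reference set, plus divergence.

    Divergence between two reference sets is the maximum over sample
    groups of |log2(fold_A / fold_B)|.
    """
    if len(ref_sets) < 2:
        raise CtDataError("need at least 2 reference sets to compare")
    results = {}
    folds = {}
    for refs in ref_sets:
        label = _ref_label(refs)
        res = ddct(matrix, target, refs, calibrator, annot,
                   group_by=group_by, sample_ids=sample_ids)
        results[label] = res
        folds[label] = res.table["fold"]
    table = pd.DataFrame(folds)
    labels = list(table.columns)
    div = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        d = float(np.abs(np.log2(table[a] / table[b])).max())
        div.loc[a, b] = div.loc[b, a] = d
    return ComparisonResult(table=table, divergence=div, results=results)


class DeltaDeltaCt:
    """Model-style wrapper around :func:`ddct` / :func:`compare_normalizations`.

    ``references`` may be one gene list or a list of lists; with several
    reference sets ``fit()`` returns a :class:`ComparisonResult`.
    """

    def __init__(self, matrix: CtMatrix, annot: SampleAnnotation, target: str,
                 references: Sequence[str] | Sequence[Sequence[str]],
                 calibrator: str, group_by: str = "sample_class",
                 sample_ids: Sequence[str] | None = None):
        self.matrix = matrix
        self.annot = annot
        self.target = target
        if references and isinstance(references[0], str):
            self.ref_sets = [list(references)]  # type: ignore[list-item]
        else:
            self.ref_sets = [list(r) for r in references]
        self.calibrator = calibrator
        self.group_by = group_by
        self.sample_ids = list(sample_ids) if sample_ids else None

    def fit(self) -> DdctResult | ComparisonResult:
        if len(self.ref_sets) == 1:
            return ddct(self.matrix, self.target, self.ref_sets[0],
                        self.calibrator, self.annot, group_by=self.group_by,
                        sample_ids=self.sample_ids)
        return compare_normalizations(self.matrix, self.target, self.ref_sets,
                                      self.calibrator, self.annot,
                                      group_by=self.group_by,
                                      sample_ids=self.sample_ids)
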