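"""geNorm expression-stability analysis.

The geNorm statistic for a candidate reference gene j is the average
pairwise variation

    M_j = mean_{k != j} V_jk,      V_jk = SD_s[ log2(Q_js / Q_ks) ]

(sample SD, n-1 denominator) over all other candidates k: a gene whose
expression ratio to every other candidate is constant across samples gets
M = 0.  Genes are ranked by stepwise elimination — recompute M on the
remaining panel, drop the gene with the largest M, repeat until two genes
remain; those two cannot be resolved further and share rank 1.

The number of reference genes worth using is decided by the pairwise
variation of normalization factors: with NF_n,s the geometric mean of the
n most stable genes' quantities in sample s,

    V_{n/n+1} = SD_s[ log2(NF_n,s / NF_{n+1},s) ],  n = 2 .. k-1,

and the smallest n with V below the 0.15 cutoff suffices.  M below 1.5 is
the conventional acceptability screen; it is reported as a flag and never
used to drop genes silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_data import CtDataError, CtMatrix, RelativeQuantityMatrix, to_relative_quantity

__all__ = [
    "GenormTrace",
    "pairwise_variation",
    "pairwise_variation_matrix",
    "m_values",
    "stepwise_ranking",
    "v_series",
    "GeNorm",
    "GeNormResults",
    "M_ACCEPT_THRESHOLD",
    "V_CUTOFF",
]

M_ACCEPT_THRESHOLD = 1.5
V_CUTOFF = 0.15


def _log2q(q: RelativeQuantityMatrix) -> pd.DataFrame:
    return q.log2()


def pairwise_variation(q: RelativeQuantityMatrix, gene_j: str, gene_k: str) -> float:
    """SD over samples of the log2 expression ratio of two genes.

    Symmetric in its gene arguments; needs at least 3 samples for a
    meaningful sample SD.
    """
    a = _log2q(q)
    if a.shape[1] < 3:
        raise CtDataError("pairwise variation needs at least 3 samples")
    ratios = a.loc[gene_j] - a.loc[gene_k]
    return float(ratios.std(ddof=1))


def pairwise_variation_matrix(q: RelativeQuantityMatrix) -> pd.DataFrame:
    """All V_jk at once (symmetric, zero diagonal)."""
    a = _log2q(q).to_numpy()
    if a.shape[1] < 3:
        raise CtDataError("pairwise variation needs at least 3 samples")
    diffs = a[:, None, :] - a[None, :, :]          # (k, k, n)
    v = diffs.std(axis=2, ddof=1)
    return pd.DataFrame(v, index=q.gene_ids, columns=q.gene_ids)


def m_values(q: RelativeQuantityMatrix) -> pd.Series:
    """Average expression stability M_j = mean_{k != j} V_jk per gene."""
    if len(q.gene_ids) < 3:
        raise CtDataError("geNorm M needs at least 3 genes")
    v = pairwise_variation_matrix(q)
    k = v.shape[0]
    m = (v.sum(axis=1)) / (k - 1)   # diagonal is 0
    m.name = "M"
    return m


@dataclass
class GenormTrace:
    """Full record of a geNorm run.

    ``ranks`` is a dense ranking: the final unresolvable pair shares rank 1,
    genes eliminated earlier get ranks 2 .. k-1 in reverse removal order.
    """

    initial_m: pd.Series
    elimination_order: list[str]
    final_pair: tuple[str, str]
    ranks: pd.Series
    steps: list[dict] = field(default_factory=list)
    v_series: pd.Series | None = None
    optimal_n: int | None = None
    m_acceptable: pd.Series | None = None


def stepwise_ranking(q: RelativeQuantityMatrix,
                     m_threshold: float = M_ACCEPT_THRESHOLD) -> GenormTrace:
    """Rank genes by iterative exclusion of the least stable candidate.

    Ties in the maximal M are broken by removing the lexicographically last
    gene name (a determinism rule with no statistical content).
    """
    genes = list(q.gene_ids)
    if len(genes) < 3:
        raise CtDataError("stepwise geNorm ranking needs at least 3 genes")
    initial = m_values(q)
    a_full = _log2q(q)

    remaining = list(genes)
    elimination: list[str] = []
    steps: list[dict] = []
    while len(remaining) > 2:
        # recompute M on the remaining panel straight from the log2 table
        m = _m_from_log2(a_full.loc[remaining])
        worst = m.max()
        ties = sorted(m.index[m == worst])
        victim = ties[-1]
        steps.append({"removed": victim, "m": m.copy()})
        elimination.append(victim)
        remaining.remove(victim)

    final_pair = tuple(sorted(remaining))
    k = len(genes)
    ranks = pd.Series(index=pd.Index(genes, name="gene"), dtype=int)
    for g in final_pair:
        ranks[g] = 1
    for pos, g in enumerate(elimination):   # first removed = least stable
        ranks[g] = k - 1 - pos
    return GenormTrace(
        initial_m=initial,
        elimination_order=elimination,
        final_pair=final_pair,  # type: ignore[arg-type]
        ranks=ranks.astype(int),
        steps=steps,
        m_acceptable=initial < m_threshold,
    )


def _m_from_log2(a: pd.DataFrame) -> pd.Series:
    arr = a.to_numpy()
    diffs = arr[:, None, :] - arr[None, :, :]
    v = diffs.std(axis=2, ddof=1)
    return pd.Series(v.sum(axis=1) / (arr.shape[0] - 1), index=a.index)


def v_series(q: RelativeQuantityMatrix, trace: GenormTrace | None = None,
             cutoff: float = V_CUTOFF) -> tuple[pd.Series, int | None]:
    """Pairwise variation V_{n/n+1} of successive normalization factors.

    Genes enter NF_n in order of ascending full-panel initial M (ties
    alphabetical).  Returns the series for n = 2 .. k-1 and the smallest n
    with V below ``cutoff`` (None when no n passes).
    """
    genes = list(q.gene_ids)
    k = len(genes)
    if k < 3:
        raise CtDataError("V series needs at least 3 genes")
    initial = trace.initial_m if trace is not None else m_values(q)
    order = sorted(genes, key=lambda g: (initial[g], g))
    a = _log2q(q)
    # log2 NF_n = mean of log2 Q over the n most stable genes
    vs = {}
    for n in range(2, k):
        nf_n = a.loc[order[:n]].mean(axis=0)
        nf_n1 = a.loc[order[: n + 1]].mean(axis=0)
        vs[n] = float((nf_n - nf_n1).std(ddof=1))
    series = pd.Series(vs, name="V_n/n+1")
    series.index.name = "n"
    passing = [n for n, v in series.items() if v < cutoff]
    optimal = min(passing) if passing else None
    if trace is not None:
        trace.v_series = series
        trace.optimal_n = optimal
    return series, optimal


class GeNorm:
    """geNorm stability model for a panel of candidate reference genes.

    Parameters
    ----------
    data : CtMatrix or RelativeQuantityMatrix
        Ct input is converted to relative quantities with the given
        amplification efficiency (per-cycle factor, default perfect
        doubling).
    efficiency : float or per-gene mapping
    v_cutoff : float
        Threshold on V_{n/n+1} deciding the optimal reference count.
    m_threshold : float
        Acceptability screen on M, reported as a flag.
    """

    def __init__(self, data: CtMatrix | RelativeQuantityMatrix,
                 efficiency: float = 2.0,
                 v_cutoff: float = V_CUTOFF,
                 m_threshold: float = M_ACCEPT_THRESHOLD):
        if isinstance(data, CtMatrix):
            self.q = to_relative_quantity(data, efficiency)
        else:
            self.q = data
        self.v_cutoff = float(v_cutoff)
        self.m_threshold = float(m_threshold)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, orientation: str = "genes-as-rows",
                       **kwargs) -> "GeNorm":
        return cls(CtMatrix.from_dataframe(df, orientation), **kwargs)

    def fit(self) -> "GeNormResults":
        trace = stepwise_ranking(self.q, m_threshold=self.m_threshold)
        v_series(self.q, trace, cutoff=self.v_cutoff)
        return GeNormResults(model=self, trace=trace)


@dataclass
class GeNormResults:
    """Fitted geNorm analysis: M values, elimination ranking, V series."""

    model: GeNorm
    trace: GenormTrace

    @property
    def m(self) -> pd.Series:
        return self.trace.initial_m

    @property
    def ranks(self) -> pd.Series:
        return self.trace.ranks

    @property
    def optimal_n(self) -> int | None:
        return self.trace.optimal_n

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "M": self.trace.initial_m,
            "rank": self.trace.ranks,
            "acceptable": self.trace.m_acceptable,
        })
        order = sorted(df.index,
                       key=lambda g: (df.at[g, "rank"], df.at[g, "M"], g))
        return df.loc[order]

    def v_frame(self) -> pd.DataFrame:
        vs = self.trace.v_series
        return pd.DataFrame({
            "V": vs,
            "passes_cutoff": vs < self.model.v_cutoff,
        })

    def summary(self) -> str:
        lines = [
            "geNorm expression stability",
            f"  genes: {len(self.m)}, samples: {len(self.model.q.sample_ids)}",
            f"  most stable pair: {self.trace.final_pair[0]}, "
            f"{self.trace.final_pair[1]}",
            f"  optimal reference count (V < {self.model.v_cutoff:g}): "
            f"{self.optimal_n if self.optimal_n is not None else 'none pass'}",
            "",
            self.to_frame().round(4).to_string(),
            "",
            self.v_frame().round(4).to_string(),
        ]
        return "\n".join(lines)
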