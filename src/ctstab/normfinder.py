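"""NormFinder model-based stability estimation.

NormFinder treats log-scale expression of gene i in sample j as

    y_ij = alpha_i + beta_j + eps_ij,        eps_ij ~ (0, sigma_i^2)

with a gene level alpha, a shared per-sample loading beta, and gene-specific
noise.  The stability value is an estimate of sigma_i: genes whose residual
variation around the common sample profile is small are stable.

Ungrouped estimator (two-way centering):

    r_ij      = y_ij - mean_j y_ij - mean_i y_ij + mean_ij y_ij
    v_i       = sum_j r_ij^2 / (n - 1)
    sigma2_i  = max(0, k/(k-2) * (v_i - sum_l v_l / (k (k-1))))
    S_i       = sqrt(sigma2_i)

The k/(k-2) factor undoes the shrinkage the double centering induces
(each gene contributes 1/k of the sample means it is centred by), and the
subtracted term removes the leak of the other genes' noise into v_i; the
result is first-order unbiased for sigma_i^2.

Grouped estimator: within each sample group g the same machinery yields
sigma2_ig; the systematic between-group expression difference of gene i,

    d_ig = (mean of y_i in g - group mean) centred across groups,

is shrunk towards zero with an empirical-Bayes factor built from the
method-of-moments variance gamma^2 of d across genes and groups, and

    S_i = mean_g ( |d_ig~| + sqrt(sigma2_ig / n_g) )

combines bias (group-dependence) and variance into one score per gene.
Lower S = more stable.  Log base 2 is used so units match geNorm's log2
ratios; any base gives identical ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_data import (
    AnalysisGroup,
    CtDataError,
    CtMatrix,
    RelativeQuantityMatrix,
    to_relative_quantity,
)

__all__ = [
    "NormFinderResult",
    "normfinder_stability",
    "normfinder_ranks",
    "NormFinder",
    "NormFinderResults",
]


@dataclass
class NormFinderResult:
    """Per-gene stability S plus the variance decomposition behind it."""

    stability: pd.Series                    # S, log2 units
    intragroup_var: pd.DataFrame            # genes x groups sigma2 (>= 0)
    intergroup_diff: pd.DataFrame | None    # shrunken d~, grouped mode only
    ranks: pd.Series
    grouped: bool


def _corrected_sigma2(y: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene residual variance from two-way centering."""
    k, n = y.shape
    r = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    v = (r ** 2).sum(axis=1) / (n - 1)
    sigma2 = (k / (k - 2)) * (v - v.sum() / (k * (k - 1)))
    return np.maximum(sigma2, 0.0)


def normfinder_stability(q: RelativeQuantityMatrix,
                         groups: pd.Series | None = None) -> NormFinderResult:
    """Estimate NormFinder stability values on log2 relative quantities.

    Parameters
    ----------
    groups : pandas.Series, optional
        Per-sample categorical factor (indexed by sample id).  When given,
        the grouped model with intra/inter-group decomposition is used;
        every level needs at least 2 samples (8+ recommended by the method's
        authors for trustworthy group contrasts).
    """
    y = q.log2()
    k, n = y.shape
    if k < 3:
        raise CtDataError(
            "NormFinder needs at least 3 genes (variance correction factor "
            "k/(k-2) is undefined otherwise)"
        )

    if groups is None:
        if n < 4:
            raise CtDataError("ungrouped NormFinder needs at least 4 samples")
        sigma2 = _corrected_sigma2(y.to_numpy())
        s = pd.Series(np.sqrt(sigma2), index=y.index, name="S")
        intravar = pd.DataFrame({"all": sigma2}, index=y.index)
        if np.allclose(sigma2, 0.0):
            warnings.warn("zero-variance panel: all stability values are 0",
                          stacklevel=2)
        result = NormFinderResult(stability=s, intragroup_var=intravar,
                                  intergroup_diff=None,
                                  ranks=normfinder_ranks(s), grouped=False)
        return result

    labels = groups.loc[y.columns]
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise CtDataError("grouped NormFinder needs at least 2 groups")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise CtDataError(
            f"groups with < 2 samples: {sorted(counts[counts < 2].index)}"
        )

    sigma2 = pd.DataFrame(index=y.index, columns=levels, dtype=float)
    z = pd.DataFrame(index=y.index, columns=levels, dtype=float)
    n_g = {}
    for g in levels:
        cols = labels.index[labels == g]
        block = y[cols]
        n_g[g] = block.shape[1]
        sigma2[g] = _corrected_sigma2(block.to_numpy())
        z[g] = block.mean(axis=1) - float(block.to_numpy().mean())
    # centre the gene-by-group contrasts across groups
    d = z.sub(z.mean(axis=1), axis=0)

    samp_var = sigma2.div(pd.Series(n_g))            # sigma2_ig / n_g
    ngroups = len(levels)
    var_d = float((d.to_numpy() ** 2).sum()) / ((k - 1) * (ngroups - 1))
    gamma2 = max(0.0, var_d - float(samp_var.to_numpy().mean()))
    denom = gamma2 + samp_var
    with np.errstate(invalid="ignore"):
        shrink = np.where(denom.to_numpy() > 0,
                          gamma2 / denom.to_numpy(), 0.0)
    d_tilde = pd.DataFrame(d.to_numpy() * shrink, index=d.index,
                           columns=d.columns)
    s_values = (d_tilde.abs() + np.sqrt(samp_var)).mean(axis=1)
    s_values.name = "S"
    if np.allclose(s_values, 0.0):
        warnings.warn("zero-variance panel: all stability values are 0",
                      stacklevel=2)
    return NormFinderResult(stability=s_values, intragroup_var=sigma2,
                            intergroup_diff=d_tilde,
                            ranks=normfinder_ranks(s_values), grouped=True)


def normfinder_ranks(stability: pd.Series | NormFinderResult) -> pd.Series:
    """Dense rank by ascending S (rank 1 = most stable, ties share rank)."""
    s = stability.stability if isinstance(stability, NormFinderResult) else stability
    ranks = s.rank(method="dense").astype(int)
    ranks.name = "rank"
    return ranks


class NormFinder:
    """NormFinder stability model.

    ``groups`` may be a per-sample Series, an :class:`AnalysisGroup` with a
    factor attached, or None for the ungrouped (single-condition) model.
    """

    def __init__(self, data: CtMatrix | RelativeQuantityMatrix,
                 groups: pd.Series | AnalysisGroup | None = None,
                 efficiency: float = 2.0):
        if isinstance(data, CtMatrix):
            self.q = to_relative_quantity(data, efficiency)
        else:
            self.q = data
        if isinstance(groups, AnalysisGroup):
            groups = groups.group_labels
        self.groups = groups

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, orientation: str = "genes-as-rows",
                       **kwargs) -> "NormFinder":
        return cls(CtMatrix.from_dataframe(df, orientation), **kwargs)

    def fit(self) -> "NormFinderResults":
        return NormFinderResults(model=self,
                                 result=normfinder_stability(self.q, self.groups))


@dataclass
class NormFinderResults:
    model: NormFinder
    result: NormFinderResult

    @property
    def stability(self) -> pd.Series:
        return self.result.stability

    @property
    def ranks(self) -> pd.Series:
        return self.result.ranks

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"S": self.result.stability,
                           "rank": self.result.ranks})
        if self.result.grouped:
            for g in self.result.intragroup_var.columns:
                df[f"sigma2[{g}]"] = self.result.intragroup_var[g]
                df[f"d[{g}]"] = self.result.intergroup_diff[g]
        # deterministic output order: ascending S, ties alphabetical
        order = sorted(df.index, key=lambda g: (df.at[g, "S"], g))
        return df.loc[order]

    def summary(self) -> str:
        mode = "grouped" if self.result.grouped else "ungrouped"
        best = self.result.stability.idxmin()
        return "\n".join([
            f"NormFinder stability ({mode} model)",
            f"  genes: {len(self.stability)}, "
            f"samples: {len(self.model.q.sample_ids)}",
            f"  most stable: {best} (S = {self.stability[best]:.4f})",
            "",
            self.to_frame().round(4).to_string(),
        ])
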