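"""BestKeeper descriptive-statistics stability analysis on raw Ct.

Unlike geNorm and NormFinder, BestKeeper works directly on the Ct scale:
per gene it reports n, arithmetic and geometric mean Ct, min/max, the Ct
standard deviation (SD) and the coefficient of variation CV = 100*SD/mean.
A gene with SD above 1 cycle is flagged as unusable as a reference.  The
BestKeeper index — the per-sample geometric mean of the retained (SD <= 1)
genes' Ct values — serves as a consensus profile; each candidate's Pearson
correlation with the index (with a t-distribution two-sided p) measures how
well it tracks the consensus.

Because raw Ct is used, shared per-sample loading differences (template
amount) do NOT cancel here; this is the methodological asymmetry between
BestKeeper and the ratio/model-based methods, and it is asserted in the
test suite rather than hidden.

``sd_mode`` selects the dispersion statistic: ``sample_sd`` (n-1
denominator, the default) or ``mean_abs_dev`` (the original tool's mean
absolute deviation from the arithmetic mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import CtDataError, CtMatrix

__all__ = [
    "bestkeeper_stats",
    "bestkeeper_index",
    "bestkeeper_correlations",
    "BestKeeper",
    "BestKeeperResults",
    "SD_LIMIT",
]

SD_LIMIT = 1.0
_SD_MODES = ("sample_sd", "mean_abs_dev")


def _dispersion(values: np.ndarray, sd_mode: str) -> float:
    if sd_mode == "sample_sd":
        return float(np.std(values, ddof=1))
    return float(np.mean(np.abs(values - values.mean())))


def bestkeeper_stats(matrix: CtMatrix, sd_mode: str = "sample_sd") -> pd.DataFrame:
    """Per-gene descriptive statistics on raw Ct.

    Returns a frame with n, mean, geo_mean, min, max, sd, cv and a dense
    ``rank`` by ascending SD (ties broken by ascending CV, then name, for
    row order).
    """
    if sd_mode not in _SD_MODES:
        raise CtDataError(f"sd_mode must be one of {_SD_MODES}, got {sd_mode!r}")
    if matrix.n_samples < 3:
        raise CtDataError("BestKeeper needs at least 3 samples")
    ct = matrix.data
    if (ct.to_numpy() <= 0).any():
        raise CtDataError("non-positive Ct breaks the geometric mean")
    rows = {}
    for gene in matrix.gene_ids:
        x = ct.loc[gene].to_numpy()
        sd = _dispersion(x, sd_mode)
        mean = float(x.mean())
        rows[gene] = {
            "n": len(x),
            "mean": mean,
            "geo_mean": float(np.exp(np.log(x).mean())),
            "min": float(x.min()),
            "max": float(x.max()),
            "sd": sd,
            "cv": 100.0 * sd / mean,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    df["rank"] = df["sd"].rank(method="dense").astype(int)
    order = sorted(df.index, key=lambda g: (df.at[g, "sd"], df.at[g, "cv"], g))
    return df.loc[order]


def bestkeeper_index(matrix: CtMatrix, retained: list[str]) -> pd.Series:
    """Per-sample geometric mean Ct over the retained genes."""
    if len(retained) < 2:
        raise CtDataError(
            "fewer than 2 genes with SD within the limit; the BestKeeper "
            "index is not meaningful — select retained genes manually"
        )
    sub = matrix.select_genes(retained).data
    index = np.exp(np.log(sub).mean(axis=0))
    index.name = "bestkeeper_index"
    return index


def bestkeeper_correlations(matrix: CtMatrix, index: pd.Series) -> pd.DataFrame:
    """Pearson r of each gene's Ct against the index, with two-sided p.

    A zero-variance gene has no defined correlation; r and p are reported
    as missing with a warning, never fabricated.
    """
    if matrix.n_samples < 4:
        raise CtDataError("correlation p-values need at least 4 samples")
    idx = index.loc[matrix.sample_ids].to_numpy()
    out = {}
    for gene in matrix.gene_ids:
        x = matrix.data.loc[gene].to_numpy()
        if np.ptp(x) == 0 or np.ptp(idx) == 0:
            warnings.warn(
                f"gene {gene!r}: zero variance, correlation undefined",
                stacklevel=2,
            )
            out[gene] = {"r": np.nan, "p": np.nan}
            continue
        r, p = stats.pearsonr(x, idx)
        out[gene] = {"r": float(r), "p": float(p)}
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "gene"
    return df


class BestKeeper:
    """BestKeeper model: descriptive stability of candidate genes on raw Ct."""

    def __init__(self, data: CtMatrix, sd_mode: str = "sample_sd",
                 sd_limit: float = SD_LIMIT):
        if not isinstance(data, CtMatrix):
            raise CtDataError("BestKeeper operates on a CtMatrix (raw Ct)")
        self.matrix = data
        self.sd_mode = sd_mode
        self.sd_limit = float(sd_limit)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, orientation: str = "genes-as-rows",
                       **kwargs) -> "BestKeeper":
        return cls(CtMatrix.from_dataframe(df, orientation), **kwargs)

    def fit(self) -> "BestKeeperResults":
        table = bestkeeper_stats(self.matrix, self.sd_mode)
        excluded = list(table.index[table["sd"] > self.sd_limit])
        retained = [g for g in table.index if g not in excluded]
        index = bestkeeper_index(self.matrix, retained)
        corr = bestkeeper_correlations(self.matrix, index)
        table = table.join(corr)
        return BestKeeperResults(model=self, table=table, index=index,
                                 excluded=excluded, retained=retained)


@dataclass
class BestKeeperResults:
    """Fitted BestKeeper analysis (stats table, index, exclusions)."""

    model: BestKeeper
    table: pd.DataFrame
    index: pd.Series
    excluded: list[str]
    retained: list[str]

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]

    def summary(self) -> str:
        lines = [
            f"BestKeeper descriptive stability (sd_mode={self.model.sd_mode})",
            f"  genes: {len(self.table)}, "
            f"samples: {self.model.matrix.n_samples}",
            f"  excluded (SD > {self.model.sd_limit:g}): "
            f"{self.excluded if self.excluded else 'none'}",
            "",
            self.table.round(4).to_string(),
        ]
        return "\n".join(lines)
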