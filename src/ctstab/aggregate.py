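"""Comprehensive rank aggregation of the three stability methods.

The three algorithms judge stability from different angles (pairwise
ratios, a variance model, raw-Ct dispersion) and rarely agree perfectly.
The comprehensive score of gene i is the plain rank sum

    S_sum(i) = G(i) + N(i) + B(i)

of its dense ranks under geNorm (G), NormFinder (N) and BestKeeper (B);
smaller is more stable.  The final comprehensive ranking is the dense rank
of S_sum; row order within ties is decided by ascending geNorm initial M,
then gene name, a documented determinism rule only.

``run_group`` / :class:`StabilityStudy` execute all three methods on one or
many sample groups (cultivars, tissue panels, fruit developmental series)
and aggregate, mirroring the multi-group screening workflow of reference
gene studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .bestkeeper import BestKeeper, BestKeeperResults
from .ct_data import (
    AnalysisGroup,
    CtDataError,
    CtMatrix,
    SampleAnnotation,
    subset,
)
from .genorm import GeNorm, GeNormResults
from .normfinder import NormFinder, NormFinderResults

__all__ = [
    "ComprehensiveRanking",
    "rank_sum",
    "AnalysisConfig",
    "GroupAnalysis",
    "run_group",
    "standard_groups",
    "StabilityStudy",
    "StabilityStudyResults",
    "FRUIT_CLASSES",
]

#: sample classes treated as fruit developmental stages by default
FRUIT_CLASSES = ("green_fruit", "immature_fruit", "mature_fruit")


@dataclass
class ComprehensiveRanking:
    """Per-gene method ranks, rank sum, and final comprehensive order."""

    table: pd.DataFrame  # columns G, N, B, S_sum, final_rank; ordered rows

    @property
    def final_order(self) -> list[str]:
        return list(self.table.index)

    @property
    def s_sum(self) -> pd.Series:
        return self.table["S_sum"]

    def summary(self) -> str:
        return "comprehensive ranking (rank sum of geNorm/NormFinder/BestKeeper)\n" \
            + self.table.to_string()


def rank_sum(G: pd.Series, N: pd.Series, B: pd.Series,
             m_values: pd.Series | None = None) -> ComprehensiveRanking:
    """Aggregate three per-gene rank maps into the comprehensive ranking.

    The three maps must cover the identical gene set.  Ties in the rank sum
    are ordered by ascending geNorm initial M when given, then by name.
    """
    sets = [set(G.index), set(N.index), set(B.index)]
    if not (sets[0] == sets[1] == sets[2]):
        union = sets[0] | sets[1] | sets[2]
        common = sets[0] & sets[1] & sets[2]
        raise CtDataError(
            f"rank maps cover different gene sets; not shared by all: "
            f"{sorted(union - common)}"
        )
    genes = sorted(sets[0])
    df = pd.DataFrame({
        "G": G.loc[genes].astype(int),
        "N": N.loc[genes].astype(int),
        "B": B.loc[genes].astype(int),
    })
    df["S_sum"] = df["G"] + df["N"] + df["B"]
    df["final_rank"] = df["S_sum"].rank(method="dense").astype(int)

    def key(g: str):
        m = float(m_values[g]) if m_values is not None else 0.0
        return (df.at[g, "S_sum"], m, g)

    df = df.loc[sorted(genes, key=key)]
    df.index.name = "gene"
    return ComprehensiveRanking(table=df)


@dataclass
class AnalysisConfig:
    """Thresholds and options shared by every per-group analysis.

    Defaults are the conventional values of the three tools: M
    acceptability 1.5, V cutoff 0.15, BestKeeper SD limit 1.0 cycle.
    ``normfinder_factor`` chooses the grouping factor for NormFinder
    ("sample_class", "cultivar", or None for the ungrouped model); when the
    chosen factor is degenerate inside a group (fewer than two levels with
    two samples each), the ungrouped model is used with a warning.
    """

    efficiency: float = 2.0
    v_cutoff: float = 0.15
    m_threshold: float = 1.5
    sd_limit: float = 1.0
    sd_mode: str = "sample_sd"
    normfinder_factor: str | None = "sample_class"

    def __post_init__(self) -> None:
        for name in ("efficiency", "v_cutoff", "m_threshold", "sd_limit"):
            if getattr(self, name) <= 0:
                raise CtDataError(f"config threshold {name} must be positive")


@dataclass
class GroupAnalysis:
    """All three method results plus the aggregate, for one sample group."""

    name: str
    group: AnalysisGroup
    genorm: GeNormResults | None = None
    normfinder: NormFinderResults | None = None
    bestkeeper: BestKeeperResults | None = None
    comprehensive: ComprehensiveRanking | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _normfinder_labels(group: AnalysisGroup, annot: SampleAnnotation | None,
                       config: AnalysisConfig) -> pd.Series | None:
    if config.normfinder_factor is None:
        return None
    if group.group_labels is not None:
        labels = group.group_labels
    elif annot is not None:
        labels = annot.labels_for(group.sample_ids, config.normfinder_factor)
    else:
        return None
    counts = labels.value_counts()
    usable = counts[counts >= 2]
    if len(usable) < 2:
        warnings.warn(
            f"group {group.name!r}: factor {config.normfinder_factor!r} has "
            "fewer than 2 usable levels; falling back to the ungrouped "
            "NormFinder model", stacklevel=2)
        return None
    return labels


def run_group(matrix: CtMatrix, group: AnalysisGroup,
              annot: SampleAnnotation | None = None,
              config: AnalysisConfig | None = None) -> GroupAnalysis:
    """Run geNorm, NormFinder and BestKeeper on one group and aggregate."""
    config = config or AnalysisConfig()
    out = GroupAnalysis(name=group.name, group=group)
    try:
        sub = matrix.select_samples(group.sample_ids)
        gn = GeNorm(sub, efficiency=config.efficiency,
                    v_cutoff=config.v_cutoff,
                    m_threshold=config.m_threshold).fit()
        labels = _normfinder_labels(group, annot, config)
        nf = NormFinder(sub, groups=labels,
                        efficiency=config.efficiency).fit()
        bk = BestKeeper(sub, sd_mode=config.sd_mode,
                        sd_limit=config.sd_limit).fit()
        out.genorm, out.normfinder, out.bestkeeper = gn, nf, bk
        out.comprehensive = rank_sum(gn.ranks, nf.ranks, bk.ranks,
                                     m_values=gn.m)
    except Exception as exc:  # structured per-group failure
        out.error = f"{type(exc).__name__}: {exc}"
    return out


def standard_groups(annot: SampleAnnotation,
                    fruit_classes: tuple[str, ...] = FRUIT_CLASSES,
                    blackberry: str = "blackberry") -> list[tuple[str, dict]]:
    """The canonical 12 experimental groupings of a 4-cultivar design.

    All samples; the three raspberry cultivars; all fruit stages; raspberry
    fruit stages; per-cultivar tissue panels; per-cultivar fruit stage
    series.  Returns (name, selector) pairs consumable by
    :func:`ctstab.ct_data.subset`.
    """
    cultivars = sorted(annot.data["cultivar"].unique())
    classes = set(annot.data["sample_class"].unique())
    fruit = [c for c in fruit_classes if c in classes]
    raspberries = [c for c in cultivars if c != blackberry]
    groups: list[tuple[str, dict]] = [
        ("all_samples", {"cultivar": cultivars}),
        ("three_raspberries", {"cultivar": raspberries}),
        ("all_fruit_stages", {"cultivar": cultivars, "sample_class": fruit}),
        ("raspberry_fruit_stages",
         {"cultivar": raspberries, "sample_class": fruit}),
    ]
    for cult in cultivars:
        groups.append((f"{cult}_tissues", {"cultivar": [cult]}))
    for cult in cultivars:
        groups.append((f"{cult}_fruit_stages",
                       {"cultivar": [cult], "sample_class": fruit}))
    return groups


class StabilityStudy:
    """End-to-end multi-group reference-gene stability screen.

    Parameters
    ----------
    matrix : CtMatrix
        Candidate genes x samples Ct table.
    annotation : SampleAnnotation
    groups : list of (name, selector), optional
        Defaults to :func:`standard_groups` over the annotation.
    config : AnalysisConfig, optional
    """

    def __init__(self, matrix: CtMatrix, annotation: SampleAnnotation,
                 groups: list[tuple[str, dict]] | None = None,
                 config: AnalysisConfig | None = None):
        annotation.check_matrix(matrix)
        self.matrix = matrix
        self.annotation = annotation
        self.group_defs = groups if groups is not None else standard_groups(annotation)
        names = [n for n, _ in self.group_defs]
        if len(set(names)) != len(names):
            raise CtDataError("group names must be unique")
        self.config = config or AnalysisConfig()

    @classmethod
    def from_dataframes(cls, ct: pd.DataFrame, annotation: pd.DataFrame,
                        orientation: str = "genes-as-rows",
                        **kwargs) -> "StabilityStudy":
        return cls(CtMatrix.from_dataframe(ct, orientation),
                   SampleAnnotation(annotation), **kwargs)

    def fit(self) -> "StabilityStudyResults":
        results: dict[str, GroupAnalysis] = {}
        for name, selector in self.group_defs:
            try:
                # NormFinder labels are resolved inside run_group from the
                # annotation and config.normfinder_factor
                group, _ = subset(self.matrix, self.annotation, selector,
                                  name=name)
            except CtDataError as exc:
                results[name] = GroupAnalysis(
                    name=name,
                    group=AnalysisGroup(name=name,
                                        sample_ids=list(self.matrix.sample_ids)),
                    error=f"{type(exc).__name__}: {exc}")
                continue
            results[name] = run_group(self.matrix, group,
                                      annot=self.annotation,
                                      config=self.config)
        return StabilityStudyResults(model=self, groups=results)


@dataclass
class StabilityStudyResults:
    """Per-group bundles of method results and comprehensive rankings."""

    model: StabilityStudy
    groups: dict[str, GroupAnalysis] = field(default_factory=dict)

    @property
    def failed(self) -> list[str]:
        return [n for n, g in self.groups.items() if not g.ok]

    def comprehensive(self, name: str) -> ComprehensiveRanking:
        g = self.groups[name]
        if not g.ok:
            raise CtDataError(f"group {name!r} failed: {g.error}")
        return g.comprehensive

    def summary(self) -> str:
        lines = [f"reference-gene stability study: {len(self.groups)} groups"]
        for name, g in self.groups.items():
            if not g.ok:
                lines.append(f"  {name}: FAILED ({g.error})")
                continue
            order = g.comprehensive.final_order
            opt = g.genorm.optimal_n
            lines.append(
                f"  {name}: top {order[0]}, {order[1]}; bottom {order[-1]}; "
                f"geNorm optimal n = {opt if opt is not None else 'none'}"
            )
        return "\n".join(lines)
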