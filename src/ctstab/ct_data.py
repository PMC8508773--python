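"""Data model and I/O for RT-qPCR quantification-cycle (Ct) matrices.

The universal input of every downstream stability method is a genes x samples
table of Ct values together with a sample annotation table (cultivar,
sample class, biological replicate).  This module holds the validated
containers, delimited-text readers/writers, analysis-group subsetting, and the
Ct -> relative-quantity transform that geNorm-style methods operate on.

Conventions
-----------
* Ct values are in cycles and must lie in ``(0, 45]`` — a 40-cycle protocol
  plus headroom; anything else is a data error, never silently clipped.
* Relative quantities are ``Q = E**(Ct_min - Ct)`` per gene, with per-gene
  calibrator the minimum Ct, so ``max_s Q_gs == 1`` exactly.
* Table orientation is always explicit; it is never guessed from the shape.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CT_MIN",
    "CT_MAX",
    "CtDataError",
    "CtMatrix",
    "SampleAnnotation",
    "AnalysisGroup",
    "RelativeQuantityMatrix",
    "DescribeResult",
    "read_ct_table",
    "write_ct_table",
    "read_annotation",
    "subset",
    "to_relative_quantity",
    "describe",
]

CT_MIN = 0.0
CT_MAX = 45.0

_ORIENTATIONS = ("genes-as-rows", "samples-as-rows")


class CtDataError(ValueError):
    """Raised for invalid Ct tables, annotations, or selections."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise CtDataError(f"duplicate {what}: {dups}")


@dataclass
class CtMatrix:
    """A genes x samples matrix of quantification-cycle values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are genes, columns are samples, cells are Ct in cycles.

    All values must be finite and in ``(0, 45]``; ids must be unique; at
    least 2 genes and 2 samples are required.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise CtDataError(
                f"need at least 2 genes and 2 samples, got shape {df.shape}"
            )
        _check_unique(list(df.index), "gene ids")
        _check_unique(list(df.columns), "sample ids")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise CtDataError(f"non-numeric Ct value: {exc}") from exc
        bad = ~np.isfinite(values) | (values <= CT_MIN) | (values > CT_MAX)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise CtDataError(
                f"Ct out of range ({CT_MIN}, {CT_MAX}] at "
                f"(gene={df.index[g]!r}, sample={df.columns[s]!r}): "
                f"{df.iat[g, s]!r}"
            )
        self.data = pd.DataFrame(values, index=df.index.astype(str),
                                 columns=df.columns.astype(str))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_genes(self, genes: Sequence[str]) -> "CtMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise CtDataError(f"genes not in matrix: {missing}")
        return CtMatrix(self.data.loc[list(genes)])

    def select_samples(self, samples: Sequence[str]) -> "CtMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise CtDataError(f"samples not in matrix: {missing}")
        return CtMatrix(self.data[list(samples)])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       orientation: str = "genes-as-rows") -> "CtMatrix":
        if orientation not in _ORIENTATIONS:
            raise CtDataError(
                f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}"
            )
        if orientation == "samples-as-rows":
            df = df.T
        return cls(df)


@dataclass
class SampleAnnotation:
    """Per-sample design factors: cultivar, sample class, replicate.

    ``data`` must carry columns ``sample_id``, ``cultivar``, ``sample_class``,
    ``replicate``; sample ids and (cultivar, sample_class, replicate) triples
    must be unique.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "cultivar", "sample_class", "replicate")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise CtDataError(f"annotation missing columns: {missing}")
        _check_unique(list(df["sample_id"]), "annotation sample ids")
        triples = df[["cultivar", "sample_class", "replicate"]]
        if triples.duplicated().any():
            dup = triples[triples.duplicated()].iloc[0].tolist()
            raise CtDataError(
                f"duplicate (cultivar, sample_class, replicate) triple: {dup}"
            )
        reps = pd.to_numeric(df["replicate"], errors="raise")
        if (reps < 1).any():
            raise CtDataError("replicate numbers must be positive integers")
        df = df.copy()
        df["replicate"] = reps.astype(int)
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"].astype(str))

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("sample_id")

    def check_matrix(self, matrix: CtMatrix) -> None:
        """Every matrix sample must be annotated exactly once."""
        annotated = set(self.sample_ids)
        missing = [s for s in matrix.sample_ids if s not in annotated]
        if missing:
            raise CtDataError(f"samples without annotation: {missing}")

    def labels_for(self, sample_ids: Sequence[str], column: str) -> pd.Series:
        if column not in self.data.columns:
            raise CtDataError(f"no annotation column {column!r}")
        idx = self.indexed()
        return idx.loc[list(sample_ids), column]


@dataclass
class AnalysisGroup:
    """A named subset of samples, optionally with a grouping factor.

    ``group_labels`` (indexed by sample id) feeds NormFinder's grouped model;
    when present, each level needs at least 2 samples.
    """

    name: str
    sample_ids: list[str]
    group_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise CtDataError(f"analysis group {self.name!r} is empty")
        _check_unique(self.sample_ids, f"samples in group {self.name!r}")
        if self.group_labels is not None:
            labels = self.group_labels.loc[self.sample_ids]
            counts = labels.value_counts()
            small = counts[counts < 2]
            if not small.empty:
                raise CtDataError(
                    f"group {self.name!r}: factor levels with < 2 samples: "
                    f"{sorted(small.index)}"
                )
            self.group_labels = labels


@dataclass
class RelativeQuantityMatrix:
    """Unitless relative quantities ``Q = E**(Ct_min - Ct)``, per-gene max 1."""

    data: pd.DataFrame
    efficiency: pd.Series = field(default=None)  # per-gene E

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if (values <= 0).any() or (values > 1 + 1e-12).any():
            raise CtDataError("relative quantities must lie in (0, 1]")
        if not np.allclose(values.max(axis=1), 1.0, rtol=0, atol=1e-12):
            raise CtDataError("per-gene maximum quantity must equal 1")
        if self.efficiency is None:
            self.efficiency = pd.Series(2.0, index=self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.data)


def _sep_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_ct_table(path: str | os.PathLike, orientation: str,
                  missing: str = "reject",
                  annotation: SampleAnnotation | None = None) -> CtMatrix:
    """Read a delimited Ct table (one header row, one id column).

    Parameters
    ----------
    orientation : {"genes-as-rows", "samples-as-rows"}
        Layout of the file; mandatory and never guessed.
    missing : {"reject", "impute"}
        ``reject`` (default) makes any missing cell a hard error naming the
        offending (gene, sample).  ``impute`` replaces a missing Ct with the
        mean of the gene's replicates within the same (cultivar,
        sample_class) cell and requires ``annotation``.
    """
    if orientation not in _ORIENTATIONS:
        raise CtDataError(
            f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}"
        )
    if missing not in ("reject", "impute"):
        raise CtDataError(f"missing policy must be reject|impute, got {missing!r}")
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                      float_precision="round_trip")
    if orientation == "samples-as-rows":
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise CtDataError(
            f"non-numeric Ct at (gene={raw.index[g]!r}, "
            f"sample={raw.columns[s]!r}): {raw.iat[g, s]!r}"
        )
    hole = numeric.isna()
    if hole.to_numpy().any():
        if missing == "reject":
            g, s = np.argwhere(hole.to_numpy())[0]
            raise CtDataError(
                f"missing Ct at (gene={raw.index[g]!r}, "
                f"sample={raw.columns[s]!r}); pass missing='impute' with an "
                "annotation to fill from within-(cultivar, class) replicates"
            )
        if annotation is None:
            raise CtDataError("missing='impute' requires an annotation")
        numeric = _impute(numeric, annotation)
    return CtMatrix(numeric)


def _impute(df: pd.DataFrame, annotation: SampleAnnotation) -> pd.DataFrame:
    """Replicate-mean imputation within (cultivar, sample_class) cells."""
    idx = annotation.indexed()
    out = df.copy()
    for gene, sample in zip(*np.where(df.isna().to_numpy())):
        g, s = df.index[gene], df.columns[sample]
        if s not in idx.index:
            raise CtDataError(f"cannot impute {g!r}/{s!r}: sample unannotated")
        cult, cls = idx.loc[s, "cultivar"], idx.loc[s, "sample_class"]
        mates = idx[(idx["cultivar"] == cult)
                    & (idx["sample_class"] == cls)].index
        mates = [m for m in mates if m in df.columns and m != s]
        vals = df.loc[g, mates].dropna()
        if vals.empty:
            raise CtDataError(
                f"cannot impute (gene={g!r}, sample={s!r}): no observed "
                f"replicate in cultivar={cult!r}, class={cls!r}"
            )
        out.loc[g, s] = float(vals.mean())
    return out


def write_ct_table(matrix: CtMatrix, path: str | os.PathLike,
                   orientation: str = "genes-as-rows") -> None:
    """Write a Ct table with full float precision (round-trips bit-exactly)."""
    df = matrix.data if orientation == "genes-as-rows" else matrix.data.T
    df.to_csv(path, sep=_sep_for(path), float_format=None)


def read_annotation(path: str | os.PathLike) -> SampleAnnotation:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    return SampleAnnotation(df)


Selector = Callable[[pd.Series], bool] | Mapping[str, Iterable[str]]


def _matches(row: pd.Series, selector: Selector) -> bool:
    if callable(selector):
        return bool(selector(row))
    return all(row[col] in set(allowed) for col, allowed in selector.items())


def subset(matrix: CtMatrix, annot: SampleAnnotation, selector: Selector,
           name: str = "subset",
           label_by: str | None = None) -> tuple[AnalysisGroup, CtMatrix]:
    """Select samples by a predicate over annotation rows.

    ``selector`` is either a callable over an annotation row or a mapping
    like ``{"cultivar": {"blackberry"}, "sample_class": fruit_stages}``
    (conjunction over columns).  Sample order of the matrix is preserved.
    ``label_by`` attaches that annotation column as the group's factor.
    """
    annot.check_matrix(matrix)
    idx = annot.indexed()
    chosen = [s for s in matrix.sample_ids if _matches(idx.loc[s], selector)]
    if len(chosen) < 2:
        raise CtDataError(
            f"selector for group {name!r} matched {len(chosen)} samples; "
            "need at least 2"
        )
    labels = idx.loc[chosen, label_by] if label_by else None
    group = AnalysisGroup(name=name, sample_ids=chosen, group_labels=labels)
    return group, matrix.select_samples(chosen)


def to_relative_quantity(matrix: CtMatrix,
                         efficiency: float | Mapping[str, float] | pd.Series = 2.0
                         ) -> RelativeQuantityMatrix:
    """Transform Ct to relative quantities ``Q = E**(Ct_min - Ct)`` per gene.

    The calibrator is the per-gene minimum Ct (the most abundant sample), so
    each gene's maximum Q is exactly 1.  ``efficiency`` is the per-cycle
    amplification factor, scalar or per-gene, and must lie in [1.5, 2.2].
    """
    if isinstance(efficiency, (int, float)):
        eff = pd.Series(float(efficiency), index=matrix.data.index)
    else:
        eff = pd.Series(efficiency, dtype=float).reindex(matrix.data.index)
        if eff.isna().any():
            raise CtDataError(
                f"efficiency missing for genes: {list(eff[eff.isna()].index)}"
            )
    out_of_range = eff[(eff < 1.5) | (eff > 2.2)]
    if not out_of_range.empty:
        raise CtDataError(
            "amplification efficiency must lie in [1.5, 2.2]; offending "
            f"genes: {dict(out_of_range)}"
        )
    ct = matrix.data
    expo = ct.min(axis=1).to_numpy()[:, None] - ct.to_numpy()
    q = np.power(eff.to_numpy()[:, None], expo)
    # exponent is exactly 0 at the calibrator sample -> max is exactly 1
    return RelativeQuantityMatrix(
        pd.DataFrame(q, index=ct.index, columns=ct.columns), efficiency=eff
    )


@dataclass
class DescribeResult:
    """Per-gene and global descriptive Ct summaries."""

    per_gene: pd.DataFrame  # n, mean, sd, min, max, median, range_width
    overall: dict[str, float]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = ["Ct summary",
                 "  global: " + ", ".join(f"{k}={v:.3f}"
                                          for k, v in self.overall.items()),
                 self.per_gene.round(3).to_string()]
        return "\n".join(lines)


def describe(matrix: CtMatrix) -> DescribeResult:
    """Descriptive Ct statistics per gene and over all cells."""
    df = matrix.data
    per_gene = pd.DataFrame({
        "n": df.notna().sum(axis=1),
        "mean": df.mean(axis=1),
        "sd": df.std(axis=1, ddof=1),
        "min": df.min(axis=1),
        "max": df.max(axis=1),
        "median": df.median(axis=1),
    })
    per_gene["range_width"] = per_gene["max"] - per_gene["min"]
    flat = df.to_numpy().ravel()
    overall = {
        "n": float(flat.size),
        "mean": float(flat.mean()),
        "sd": float(flat.std(ddof=1)),
        "min": float(flat.min()),
        "max": float(flat.max()),
        "median": float(np.median(flat)),
    }
    return DescribeResult(per_gene=per_gene, overall=overall)
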