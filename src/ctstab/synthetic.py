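"""Seeded generator of Ct matrices with known ground-truth stability.

Raw Ct data behind published reference-gene screens are rarely deposited,
so every stage of this package is exercised on synthetic data whose
stability structure is known exactly.  The generative model for gene i in
sample s of design cell (cultivar, class, replicate) is

    Ct_is = b_i + delta_{i, class(s)} - u_s + eps_is

with per-gene baseline b_i (cycles), class-specific expression shifts
delta (a systematic instability: the gene responds to the condition),
a shared per-sample loading term u_s ~ N(0, tau^2) entering with a minus
sign (more template -> earlier Ct), and gene-specific noise
eps_is ~ N(0, sigma_i^2).  Loading affects all genes of a sample equally,
so ratio- and model-based methods cancel it while raw-Ct dispersion does
not — the generator reproduces exactly the asymmetry that distinguishes
BestKeeper from geNorm/NormFinder.

``default_paper_mimic`` returns the canonical screen design: 12 candidate
genes, 4 cultivars x 6 sample classes (3 fruit developmental stages, leaf,
stem, stem apex) x 3 biological replicates = 72 samples, baselines spanning
roughly 22-31 cycles, two designed-stable genes (sigma = 0.1) and one
designed-unstable gene (sigma = 1.2 plus a 1.5-cycle fruit-stage shift).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ct_data import CtDataError, CtMatrix, SampleAnnotation

__all__ = [
    "GeneSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "default_paper_mimic",
    "with_validation_target",
    "write_fixture",
    "DEFAULT_CULTIVARS",
    "DEFAULT_CLASSES",
]

DEFAULT_CULTIVARS = ("blackberry", "black_raspberry", "red_raspberry",
                     "yellow_raspberry")
DEFAULT_CLASSES = ("green_fruit", "immature_fruit", "mature_fruit",
                   "leaf", "stem", "stem_apex")


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth generative parameters of one gene."""

    name: str
    baseline: float                      # cycles
    sigma: float                         # gene noise SD, cycles
    effects: dict[str, float] = field(default_factory=dict)  # class -> shift
    is_target: bool = False              # validation target, not a candidate

    def __post_init__(self) -> None:
        if not (15.0 < self.baseline < 35.0):
            raise CtDataError(
                f"gene {self.name!r}: baseline {self.baseline} outside (15, 35)"
            )
        if self.sigma < 0:
            raise CtDataError(f"gene {self.name!r}: negative sigma")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full generative specification of a synthetic Ct experiment."""

    genes: tuple[GeneSpec, ...]
    cultivars: tuple[str, ...] = DEFAULT_CULTIVARS
    sample_classes: tuple[str, ...] = DEFAULT_CLASSES
    replicates: int = 3
    loading_sd: float = 0.15             # tau, cycles
    efficiency: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise CtDataError("spec needs at least 2 genes")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise CtDataError("duplicate gene names in spec")
        if self.replicates < 1:
            raise CtDataError("replicates must be >= 1")
        if self.loading_sd < 0:
            raise CtDataError("loading_sd must be >= 0")
        known = set(self.sample_classes)
        for g in self.genes:
            unknown = set(g.effects) - known
            if unknown:
                raise CtDataError(
                    f"gene {g.name!r}: effects reference unknown sample "
                    f"classes {sorted(unknown)}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.cultivars) * len(self.sample_classes) * self.replicates

    # --- JSON round trip (CLI input format) -------------------------------
    def to_json(self) -> str:
        payload = asdict(self)
        payload["genes"] = [asdict(g) for g in self.genes]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CtDataError(f"spec is not valid JSON: {exc}") from exc
        if not isinstance(payload, dict):
            raise CtDataError("spec JSON must be an object")
        if "genes" not in payload:
            raise CtDataError("spec JSON missing field 'genes'")
        genes = []
        for i, entry in enumerate(payload["genes"]):
            for req in ("name", "baseline", "sigma"):
                if req not in entry:
                    raise CtDataError(
                        f"spec JSON: genes[{i}] missing field {req!r}"
                    )
            genes.append(GeneSpec(
                name=str(entry["name"]),
                baseline=float(entry["baseline"]),
                sigma=float(entry["sigma"]),
                effects={str(k): float(v)
                         for k, v in entry.get("effects", {}).items()},
                is_target=bool(entry.get("is_target", False)),
            ))
        kwargs = {}
        for name, conv in (("cultivars", tuple), ("sample_classes", tuple),
                           ("replicates", int), ("loading_sd", float),
                           ("efficiency", float), ("seed", int)):
            if name in payload:
                try:
                    kwargs[name] = conv(payload[name])
                except (TypeError, ValueError) as exc:
                    raise CtDataError(
                        f"spec JSON: bad value for field {name!r}: {exc}"
                    ) from exc
        return cls(genes=tuple(genes), **kwargs)


@dataclass
class GroundTruth:
    """Deterministic stability oracle derived from a SyntheticSpec.

    ``stability_order`` sorts candidate genes most-stable-first by
    (sigma, max |class effect|, name).
    """

    table: pd.DataFrame                  # sigma, max_abs_effect, is_target
    stability_order: list[str]

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index[~self.table["is_target"]])

    @property
    def designed_stable_pair(self) -> tuple[str, str]:
        return tuple(self.stability_order[:2])  # type: ignore[return-value]

    @property
    def designed_unstable(self) -> str:
        return self.stability_order[-1]

    def to_json(self) -> str:
        return json.dumps({
            "stability_order": self.stability_order,
            "genes": {
                g: {"sigma": float(self.table.at[g, "sigma"]),
                    "max_abs_effect": float(self.table.at[g, "max_abs_effect"]),
                    "is_target": bool(self.table.at[g, "is_target"])}
                for g in self.table.index
            },
        }, indent=2)


def _ground_truth(spec: SyntheticSpec) -> GroundTruth:
    rows = {}
    for g in spec.genes:
        effects = [abs(v) for v in g.effects.values()]
        rows[g.name] = {
            "sigma": g.sigma,
            "max_abs_effect": max(effects) if effects else 0.0,
            "is_target": g.is_target,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    order = sorted(
        (g for g in table.index if not table.at[g, "is_target"]),
        key=lambda g: (table.at[g, "sigma"], table.at[g, "max_abs_effect"], g),
    )
    return GroundTruth(table=table, stability_order=order)


def generate(spec: SyntheticSpec
             ) -> tuple[CtMatrix, SampleAnnotation, GroundTruth]:
    """Draw one synthetic experiment; identical seed -> identical output.

    Draw order is fixed (loading vector first, then per-gene noise in spec
    order), so the same seed with a different ``loading_sd`` keeps every
    eps draw identical — handy for paired method-contrast experiments.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cult in spec.cultivars:
        for cls in spec.sample_classes:
            for rep in range(1, spec.replicates + 1):
                rows.append({
                    "sample_id": f"{cult}.{cls}.r{rep}",
                    "cultivar": cult,
                    "sample_class": cls,
                    "replicate": rep,
                })
    annot = SampleAnnotation(pd.DataFrame(rows))
    sample_ids = annot.sample_ids
    classes = annot.data["sample_class"].to_numpy()
    n = len(sample_ids)

    u = rng.standard_normal(n) * spec.loading_sd
    ct = np.empty((len(spec.genes), n))
    for i, g in enumerate(spec.genes):
        eps = rng.standard_normal(n) * g.sigma
        delta = np.array([g.effects.get(c, 0.0) for c in classes])
        ct[i] = g.baseline + delta - u + eps
    matrix = CtMatrix(pd.DataFrame(
        ct, index=[g.name for g in spec.genes], columns=sample_ids))
    return matrix, annot, _ground_truth(spec)


def default_paper_mimic(seed: int = 10533) -> SyntheticSpec:
    """The canonical 12-gene x 72-sample screen design.

    Baselines span ~22-31 cycles; gene noise grades from 0.1 (the two
    designed-stable elongation-factor/rRNA-like genes) to 1.2 cycles for
    the designed-unstable glycolytic-enzyme-like gene, which additionally
    carries a 1.5-cycle fruit-ripening shift.  Two mid-panel genes carry
    small tissue shifts so condition dependence is not confined to the
    worst gene.
    """
    genes = (
        GeneSpec("RuEEF1A", 25.0, 0.10),
        GeneSpec("Ru18S", 23.5, 0.10),
        GeneSpec("RuTUBA", 24.9, 0.30),
        GeneSpec("RuEF4A", 25.2, 0.35),
        GeneSpec("RuUBC", 24.2, 0.40),
        GeneSpec("RuEEF1B", 24.6, 0.45),
        GeneSpec("RuUBQ", 27.1, 0.55),
        GeneSpec("Ru40S", 25.2, 0.65),
        GeneSpec("Ru30S", 24.6, 0.75),
        GeneSpec("RuF-box", 29.5, 0.85, {"leaf": 0.5}),
        GeneSpec("RuPA", 26.0, 1.00, {"stem_apex": 0.7}),
        GeneSpec("RuPGK", 25.3, 1.20,
                 {"immature_fruit": 0.75, "mature_fruit": 1.5}),
    )
    return SyntheticSpec(genes=genes, seed=seed)


def with_validation_target(spec: SyntheticSpec,
                           name: str = "RuCYP73A") -> SyntheticSpec:
    """Append a differentially expressed target gene for ddCt validation.

    The target emulates a ripening-regulated pathway enzyme: strongly
    induced through fruit development and moderately variable elsewhere.
    It is flagged ``is_target`` so it never enters candidate rankings.
    """
    target = GeneSpec(name, 28.0, 0.25,
                      {"immature_fruit": -1.2, "mature_fruit": -2.5,
                       "leaf": 0.8, "stem": 0.4, "stem_apex": 1.0},
                      is_target=True)
    return SyntheticSpec(genes=spec.genes + (target,),
                         cultivars=spec.cultivars,
                         sample_classes=spec.sample_classes,
                         replicates=spec.replicates,
                         loading_sd=spec.loading_sd,
                         efficiency=spec.efficiency,
                         seed=spec.seed)


def write_fixture(spec: SyntheticSpec, outdir: str | os.PathLike) -> dict[str, str]:
    """Generate and write ct.csv / annotations.csv / truth.json."""
    from .ct_data import write_ct_table

    matrix, annot, truth = generate(spec)
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "ct": os.path.join(outdir, "ct.csv"),
        "annotations": os.path.join(outdir, "annotations.csv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_ct_table(matrix, paths["ct"])
    annot.data.to_csv(paths["annotations"], index=False)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
    return paths
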