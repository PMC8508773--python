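import numpy as np
import pandas as pd
import pytest

from ctstab import CtMatrix, SampleAnnotation, default_paper_mimic, generate


def make_ct(values, genes=None, samples=None) -> CtMatrix:
    """Build a small CtMatrix from a nested list (genes x samples)."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CtMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def random_ct(rng, n_genes, n_samples, lo=20.0, hi=30.0) -> CtMatrix:
    vals = rng.uniform(lo, hi, size=(n_genes, n_samples))
    return make_ct(vals)


@pytest.fixture(scope="session")
def mimic():
    """Default 12-gene x 72-sample synthetic screen (fixed seed)."""
    spec = default_paper_mimic(seed=10533)
    matrix, annot, truth = generate(spec)
    return spec, matrix, annot, truth


@pytest.fixture()
def tiny_annot():
    """Two cultivars x two classes x two replicates (8 samples)."""
    rows = []
    for cult in ("cvA", "cvB"):
        for cls in ("leaf", "fruit"):
            for rep in (1, 2):
                rows.append({"sample_id": f"{cult}.{cls}.r{rep}",
                             "cultivar": cult, "sample_class": cls,
                             "replicate": rep})
    return SampleAnnotation(pd.DataFrame(rows))
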