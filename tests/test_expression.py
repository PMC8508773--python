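"""2^-ddCt quantification and reference-choice divergence."""

import numpy as np
import pandas as pd
import pytest

from ctstab import (
    CtDataError,
    DeltaDeltaCt,
    SampleAnnotation,
    compare_normalizations,
    ddct,
    default_paper_mimic,
    generate,
    with_validation_target,
)

from conftest import make_ct


def _annot_two_groups(n_per=3):
    rows = []
    for cls in ("cal", "treat"):
        for rep in range(1, n_per + 1):
            rows.append({"sample_id": f"{cls}.r{rep}", "cultivar": "cv",
                         "sample_class": cls, "replicate": rep})
    return SampleAnnotation(pd.DataFrame(rows))


def _matrix_two_groups(target_cal, target_treat, ref_rows, n_per=3):
    samples = [f"{cls}.r{r}" for cls in ("cal", "treat")
               for r in range(1, n_per + 1)]
    rows = [[target_cal] * n_per + [target_treat] * n_per] + ref_rows
    genes = ["tgt"] + [f"ref{i}" for i in range(len(ref_rows))]
    return make_ct(rows, genes=genes, samples=samples)


class TestDdct:
    def test_calibrator_fold_is_one(self):
        annot = _annot_two_groups()
        m = _matrix_two_groups(25.0, 24.0, [[26.0] * 6])
        res = ddct(m, "tgt", ["ref0"], "cal", annot)
        assert res.table.at["cal", "fold"] == 1.0

    def test_two_cycle_shift_gives_fold_four(self):
        annot = _annot_two_groups()
        m = _matrix_two_groups(25.0, 23.0, [[25.0] * 6])
        res = ddct(m, "tgt", ["ref0"], "cal", annot)
        assert res.table.at["treat", "fold"] == pytest.approx(4.0)

    def test_two_references_equal_single_pseudo_reference(self):
        annot = _annot_two_groups()
        m = _matrix_two_groups(25.0, 23.0, [[24.0] * 6, [26.0] * 6,
                                            [25.0] * 6])
        pair = ddct(m, "tgt", ["ref0", "ref1"], "cal", annot)
        single = ddct(m, "tgt", ["ref2"], "cal", annot)
        assert np.allclose(pair.table["fold"], single.table["fold"])

    def test_reference_copy_of_target_gives_fold_one(self):
        rng = np.random.default_rng(61)
        annot = _annot_two_groups()
        target = rng.uniform(23, 27, 6)
        m = make_ct([target, target], genes=["tgt", "copy"],
                    samples=annot.sample_ids)
        res = ddct(m, "tgt", ["copy"], "cal", annot)
        assert np.allclose(res.table["fold"], 1.0)

    def test_loading_shift_invariance(self):
        rng = np.random.default_rng(62)
        annot = _annot_two_groups()
        base = rng.uniform(23, 27, size=(3, 6))
        m = make_ct(base, genes=["tgt", "r1", "r2"],
                    samples=annot.sample_ids)
        f0 = ddct(m, "tgt", ["r1", "r2"], "cal", annot).table["fold"]
        loaded = base + rng.normal(0, 1.0, 6)  # per-sample constants
        m2 = make_ct(loaded, genes=["tgt", "r1", "r2"],
                     samples=annot.sample_ids)
        f1 = ddct(m2, "tgt", ["r1", "r2"], "cal", annot).table["fold"]
        assert np.allclose(f0, f1, atol=1e-12)

    def test_target_among_references_is_error(self):
        annot = _annot_two_groups()
        m = _matrix_two_groups(25.0, 24.0, [[26.0] * 6])
        with pytest.raises(CtDataError, match="own references"):
            ddct(m, "tgt", ["tgt", "ref0"], "cal", annot)

    def test_dispersion_propagates_to_fold_range(self):
        annot = _annot_two_groups()
        m = _matrix_two_groups(25.0, 23.0, [[25.0] * 6])
        # perturb one treat replicate: nonzero SD -> fold_lo < fold < fold_hi
        data = m.data.copy()
        data.loc["tgt", "treat.r1"] += 0.5
        res = ddct(make_ct(data.to_numpy(), genes=m.gene_ids,
                           samples=m.sample_ids),
                   "tgt", ["ref0"], "cal", annot)
        row = res.table.loc["treat"]
        assert row["fold_lo"] < row["fold"] < row["fold_hi"]


class TestCompareNormalizations:
    def test_identical_ref_sets_zero_divergence(self):
        annot = _annot_two_groups()
        m = _matrix_two_groups(25.0, 23.0, [[25.0] * 6, [26.0] * 6])
        res = compare_normalizations(m, "tgt", [["ref0"], ["ref0"]],
                                     "cal", annot)
        assert res.max_divergence == 0.0

    def test_loading_tracking_stable_refs_agree(self):
        # both stable refs follow sample loading exactly: divergence ~ 0
        rng = np.random.default_rng(63)
        annot = _annot_two_groups()
        loading = rng.normal(0, 0.5, 6)
        tgt = 25.0 + loading + rng.normal(0, 0.05, 6)
        r1 = 24.0 + loading + rng.normal(0, 0.05, 6)
        r2 = 26.0 + loading + rng.normal(0, 0.05, 6)
        m = make_ct([tgt, r1, r2], genes=["tgt", "r1", "r2"],
                    samples=annot.sample_ids)
        res = compare_normalizations(m, "tgt", [["r1"], ["r1", "r2"]],
                                     "cal", annot)
        assert res.max_divergence < 0.2

    def test_group_confounded_reference_distorts_folds(self):
        # noise-free construction: a reference with a 1.5-cycle shift in the
        # treatment group biases log2 fold by exactly 1.5
        annot = _annot_two_groups()
        m = _matrix_two_groups(25.0, 25.0,
                               [[25.0] * 6,
                                [25.0] * 3 + [26.5] * 3])
        res = compare_normalizations(m, "tgt", [["ref0"], ["ref1"]],
                                     "cal", annot)
        assert res.max_divergence == pytest.approx(1.5, abs=1e-9)

    def test_needs_two_ref_sets(self):
        annot = _annot_two_groups()
        m = _matrix_two_groups(25.0, 24.0, [[26.0] * 6])
        with pytest.raises(CtDataError, match="2 reference sets"):
            compare_normalizations(m, "tgt", [["ref0"]], "cal", annot)

    def test_top_pair_vs_singles_on_mimic(self):
        """Stable references used singly or jointly give near-identical
        expression patterns (log2 fold within 0.3 per group)."""
        spec = with_validation_target(default_paper_mimic(seed=777))
        matrix, annot, truth = generate(spec)
        g1, g2 = truth.designed_stable_pair
        black = [s for s in matrix.sample_ids if s.startswith("blackberry.")]
        res = compare_normalizations(
            matrix, "RuCYP73A", [[g1], [g2], [g1, g2]], "green_fruit",
            annot, sample_ids=black)
        assert res.max_divergence < 0.3

    def test_unstable_reference_fluctuates_on_mimic(self):
        spec = with_validation_target(default_paper_mimic(seed=777))
        matrix, annot, truth = generate(spec)
        stable = list(truth.designed_stable_pair)
        black = [s for s in matrix.sample_ids if s.startswith("blackberry.")]
        res = compare_normalizations(
            matrix, "RuCYP73A", [stable, [truth.designed_unstable]],
            "green_fruit", annot, sample_ids=black)
        # the designed 1.5-cycle ripening shift must show up, minus noise
        assert res.max_divergence > 0.75


class TestModelWrapper:
    def test_single_and_multi_ref_dispatch(self):
        annot = _annot_two_groups()
        m = _matrix_two_groups(25.0, 23.0, [[25.0] * 6, [26.0] * 6])
        single = DeltaDeltaCt(m, annot, "tgt", ["ref0"], "cal").fit()
        assert hasattr(single, "table") and not hasattr(single, "divergence")
        multi = DeltaDeltaCt(m, annot, "tgt", [["ref0"], ["ref1"]],
                             "cal").fit()
        assert hasattr(multi, "divergence")
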