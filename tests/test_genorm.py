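"""geNorm: pairwise variation, M values, elimination ranking, V series."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctstab import (
    CtDataError,
    GeNorm,
    m_values,
    pairwise_variation,
    stepwise_ranking,
    to_relative_quantity,
    v_series,
)
from ctstab.genorm import pairwise_variation_matrix

from conftest import make_ct, random_ct


def brute_force_m(q):
    """Independent oracle: double loop, SD of elementwise log2 ratios."""
    a = np.log2(q.data.to_numpy())
    genes = q.gene_ids
    out = {}
    for j, gj in enumerate(genes):
        vs = []
        for k_, gk in enumerate(genes):
            if j == k_:
                continue
            vs.append(statistics.stdev(a[j] - a[k_]))
        out[gj] = sum(vs) / len(vs)
    return out


class TestPairwiseVariation:
    def test_constant_ratio_gives_zero(self):
        # genes differing by a constant Ct offset: ratio constant, V = 0
        m = make_ct([[24.0, 25.0, 26.0], [26.0, 27.0, 28.0]])
        q = to_relative_quantity(m)
        assert pairwise_variation(q, "g0", "g1") == pytest.approx(0.0, abs=1e-12)

    def test_known_log_ratio_sd(self):
        # Q_j = [1, .5, .25] vs Q_k = [1, 1, 1]: A = [0, -1, -2], SD = 1
        m = make_ct([[24.0, 25.0, 26.0], [25.0, 25.0, 25.0]])
        q = to_relative_quantity(m)
        assert pairwise_variation(q, "g0", "g1") == pytest.approx(1.0)

    def test_symmetry_and_oracle(self):
        rng = np.random.default_rng(21)
        q = to_relative_quantity(random_ct(rng, 2, 6))
        v = pairwise_variation(q, "g0", "g1")
        assert v == pytest.approx(pairwise_variation(q, "g1", "g0"))
        a = np.log2(q.data.to_numpy())
        assert v == pytest.approx(statistics.stdev(a[0] - a[1]), abs=1e-12)

    def test_needs_three_samples(self):
        q = to_relative_quantity(make_ct([[24.0, 25.0], [25.0, 26.0]]))
        with pytest.raises(CtDataError, match="3 samples"):
            pairwise_variation(q, "g0", "g1")


class TestMValues:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        q = to_relative_quantity(random_ct(rng, 5, 8))
        m = m_values(q)
        oracle = brute_force_m(q)
        for g in q.gene_ids:
            assert m[g] == pytest.approx(oracle[g], abs=1e-12)

    def test_identical_genes_all_zero(self):
        m = make_ct([[24.0, 25.0, 26.0]] * 3)
        assert (m_values(to_relative_quantity(m)) == 0).all()

    def test_offset_pair_more_stable_than_noisy_gene(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(24, 26, 10)
        noisy = base + rng.normal(0, 1.5, 10)
        q = to_relative_quantity(make_ct([base, base + 1.0, noisy]))
        m = m_values(q)
        assert m["g0"] == pytest.approx(m["g1"], abs=1e-12)
        assert m["g0"] < m["g2"]

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(shift=st.floats(-3, 3), seed=st.integers(0, 50))
    def test_scale_invariance(self, shift, seed):
        """Shifting one gene's Ct by a constant leaves all M unchanged."""
        rng = np.random.default_rng(seed)
        ct = rng.uniform(23, 27, size=(4, 7))
        m0 = m_values(to_relative_quantity(make_ct(ct)))
        ct2 = ct.copy()
        ct2[2] += shift
        m1 = m_values(to_relative_quantity(make_ct(ct2)))
        assert np.allclose(m0.to_numpy(), m1.to_numpy(), atol=1e-9)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(9)
        m = random_ct(rng, 4, 8)
        perm = rng.permutation(m.sample_ids).tolist()
        m_perm = m.select_samples(perm)
        assert np.allclose(
            m_values(to_relative_quantity(m)).to_numpy(),
            m_values(to_relative_quantity(m_perm)).to_numpy())


class TestStepwiseRanking:
    def test_three_genes_single_step(self):
        rng = np.random.default_rng(1)
        q = to_relative_quantity(random_ct(rng, 3, 6))
        trace = stepwise_ranking(q)
        assert len(trace.elimination_order) == 1
        assert sorted(trace.ranks.tolist()) == [1, 1, 2]

    def test_initial_m_equals_full_panel_m(self):
        rng = np.random.default_rng(2)
        q = to_relative_quantity(random_ct(rng, 6, 9))
        trace = stepwise_ranking(q)
        assert np.allclose(trace.initial_m.to_numpy(),
                           m_values(q).to_numpy())

    def test_group_confounded_gene_removed_first(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(24, 25, 12)
        shifted = base.copy()
        shifted[:6] += 2.0  # large group-confounded shift
        panel = [base + rng.normal(0, 0.05, 12) for _ in range(3)]
        panel.append(shifted + rng.normal(0, 0.05, 12))
        trace = stepwise_ranking(to_relative_quantity(make_ct(panel)))
        assert trace.elimination_order[0] == "g3"

    @pytest.mark.parametrize("seed", range(20))
    def test_inflated_noise_gene_eliminated_first(self, seed):
        rng = np.random.default_rng(100 + seed)
        sigmas = [0.2, 0.2, 0.2, 0.2, 1.0]  # one gene's sigma inflated 5x
        panel = [25 + rng.normal(0, s, 30) for s in sigmas]
        trace = stepwise_ranking(to_relative_quantity(make_ct(panel)))
        assert trace.elimination_order[0] == "g4"

    def test_tie_break_removes_lexicographically_last(self):
        # all-constant panel: every M is 0 at every step
        m = make_ct([[25.0] * 4] * 4, genes=["a", "b", "c", "d"])
        trace = stepwise_ranking(to_relative_quantity(m))
        assert trace.elimination_order == ["d", "c"]
        assert trace.final_pair == ("a", "b")

    def test_m_acceptability_flag_never_drops_genes(self):
        rng = np.random.default_rng(8)
        panel = [25 + rng.normal(0, s, 20) for s in (0.1, 0.1, 2.2)]
        trace = stepwise_ranking(to_relative_quantity(make_ct(panel)))
        assert len(trace.ranks) == 3          # nothing silently dropped
        assert not trace.m_acceptable["g2"]
        assert trace.m_acceptable["g0"]


class TestVSeries:
    def test_identical_genes_v_zero_optimal_two(self):
        m = make_ct([[24.0, 25.0, 26.0]] * 3)
        series, optimal = v_series(to_relative_quantity(m))
        assert series[2] == pytest.approx(0.0, abs=1e-12)
        assert optimal == 2

    def test_noisy_third_gene_fails_cutoff(self):
        rng = np.random.default_rng(4)
        clean = 25 + rng.normal(0, 0.02, 40)
        panel = [clean, clean + 0.5, 25 + rng.normal(0, 1.5, 40)]
        q = to_relative_quantity(make_ct(panel))
        series, optimal = v_series(q)
        # forcing the 1.5-cycle-SD gene into NF_3 costs ~sigma/3 log2 units
        assert series[2] > 0.15
        assert optimal is None

    def test_v_direct_evaluation(self):
        rng = np.random.default_rng(6)
        q = to_relative_quantity(random_ct(rng, 4, 10))
        m = m_values(q)
        order = sorted(q.gene_ids, key=lambda g: (m[g], g))
        a = np.log2(q.data.to_numpy())
        idx = [q.gene_ids.index(g) for g in order]
        nf2 = a[idx[:2]].mean(axis=0)
        nf3 = a[idx[:3]].mean(axis=0)
        series, _ = v_series(q)
        assert series[2] == pytest.approx(statistics.stdev(nf2 - nf3), abs=1e-12)


class TestGeNormModel:
    def test_fit_bundles_everything(self, mimic):
        _, matrix, _, truth = mimic
        res = GeNorm(matrix).fit()
        assert set(res.trace.final_pair) == set(truth.designed_stable_pair)
        assert res.optimal_n == 2
        assert res.ranks[truth.designed_unstable] == 11  # rank k-1 of 12
        text = res.summary()
        assert "optimal reference count" in text
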