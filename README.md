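# ctstab — reference-gene stability analysis for RT-qPCR Ct data

Relative quantification by RT-qPCR stands or falls with the reference
("housekeeping") genes used for normalization: a reference whose own
expression drifts across tissues, developmental stages or cultivars biases
every fold change computed against it. Before a quantification study,
candidate references are therefore screened for expression stability.
`ctstab` implements the complete screening workflow used throughout the
plant and animal qPCR literature on a plain Ct table
(samples × genes) plus a sample annotation (cultivar / sample class /
replicate):

- **geNorm** — for each gene j the average pairwise variation
  `M_j = mean_{k≠j} SD_s[log2(Q_js/Q_ks)]` over all other candidates, with
  stepwise elimination of the least stable gene until an unresolvable top
  pair remains, and the normalization-factor pairwise variation
  `V_{n/n+1} = SD_s[log2(NF_n/NF_{n+1})]` that decides how many reference
  genes are worth using (cutoff 0.15; acceptability screen M < 1.5).
- **NormFinder** — a variance-decomposition model on log2 expression:
  per-gene noise variance estimated by two-way centering with a `k/(k−2)`
  bias correction, plus (in grouped mode) empirical-Bayes-shrunken
  between-group expression differences; stability
  `S_i = mean_g(|d̃_ig| + √(σ̂²_ig/n_g))`, lower is more stable.
- **BestKeeper** — descriptive statistics on raw Ct: SD, CV = 100·SD/mean,
  the SD > 1 exclusion rule, the per-sample geometric-mean index over
  retained genes, and each gene's Pearson correlation with the index.
- **Comprehensive ranking** — the rank sum `S = G + N + B` of the three
  methods' dense ranks, the usual way the three verdicts are merged into a
  final order.
- **2^−ΔΔCt validation** — fold changes of a target gene normalized to
  competing reference choices, with a divergence summary that quantifies
  how much the reference choice distorts the expression pattern.
- **Synthetic screens** — a seeded generator
  (`Ct_is = b_i + δ_i,class(s) − u_s + ε_is`) emulating a 12-gene,
  4-cultivar × 6-class × 3-replicate design with known ground-truth
  stability, so the whole pipeline is testable end to end.

The API follows the statsmodels idiom: model objects (`GeNorm`,
`NormFinder`, `BestKeeper`, `DeltaDeltaCt`, `StabilityStudy`) are built
from data and `fit()` returns a results object with the estimates,
diagnostics and a `summary()`. A thin CLI (`ctstab simulate | analyze |
ddct`) covers shell use.

## Worked example

```python
import ctstab as cs

matrix, annot, truth = cs.generate(cs.default_paper_mimic(seed=42))
print(cs.GeNorm(matrix).fit().summary())
```

```
geNorm expression stability
  genes: 12, samples: 72
  most stable pair: Ru18S, RuEEF1A
  optimal reference count (V < 0.15): 2

              M  rank  acceptable
RuEEF1A  0.6258     1        True
Ru18S    0.6285     1        True
RuTUBA   0.7120     2        True
...
RuPGK    1.3810    11        True
```

The two designed-stable genes share rank 1 with M ≈ 0.63 (well under the
1.5 acceptability threshold), the designed-unstable gene is eliminated
first, and every `V_{n/n+1}` is below 0.15, so two reference genes
suffice. Aggregating all three methods:

```python
from ctstab.ct_data import AnalysisGroup
bundle = cs.run_group(matrix, AnalysisGroup("all_samples", matrix.sample_ids),
                      annot=annot)
print(bundle.comprehensive.summary())
```

```
          G   N   B  S_sum  final_rank
gene
RuEEF1A   1   1   2      4           1
Ru18S     1   2   1      4           1
RuTUBA    2   3   3      8           2
...
RuPGK    11  12  12     35          10
```

i.e. the rank sum puts the designed-stable pair on top (S = 4 each) and
the designed-unstable gene last (S = 35 = 3 × 12 − 1). From the shell, the
same screen over the standard 12 sample groupings:

```sh
ctstab simulate --seed 42 --outdir fixture --with-target
ctstab analyze --ct fixture/ct.csv --annotations fixture/annotations.csv \
               --outdir report
ctstab ddct --ct fixture/ct.csv --annotations fixture/annotations.csv \
            --target RuCYP73A --refs RuEEF1A,Ru18S --refs RuPGK \
            --cultivar blackberry --outdir expr
```

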