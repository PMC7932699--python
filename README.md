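# hourglass-kit

Tools for comparing developmental gene expression and open chromatin between
distantly related species — built around the kind of question asked when a
shark pectoral fin bud is compared with a mouse forelimb bud over
developmental time: *which stages are conserved, which genes shifted their
timing, and do regulatory sequences show the same pattern?*

The package is aimed at comparative developmental biologists and
computational people supporting them. It covers four pieces of machinery:

1. **Ortholog assignment** from BLAST-style tabular homology hits. A query's
   single best hit across a panel of bridge species (*cross-species best
   hit*) is confirmed from the other species' side (*species-wise best hit*);
   queries with no panel hit fall back to a closely related lineage. A plain
   reciprocal-best-hit (RBH) baseline is included for comparison.
2. **Expression scaling and heterochrony.** Replicate TPMs are aggregated,
   genes with max TPM < 1 are dropped, and per-gene stage profiles are scaled
   by one of four methods — for gene *g*, species *s*, time *t* with intact
   TPM `x_{g,s,t}` over `T_s` stages:

   | method | definition |
   |---|---|
   | Max-1 | `M = x / max_t x` |
   | z-score | `Z = (x − mean_t x) / sd_t x` |
   | unit vector | `U = x / ‖x‖₂` |
   | log10 | `L = log10(x + 1)` |

   Heterochronic genes are called from the Pearson correlation (PCC) between
   mean TPM and stage rank: PCC > 0.5 in one species and < −0.5 in the other.
3. **Hourglass analytics.** Stage-by-stage cross-species distance matrices
   over shared orthologs under four metrics (Euclidean, correlation `1 − r`,
   a generalized Jensen–Shannon "Shannon distance", and standardized
   Euclidean), stage PCA, Ward clustering of concatenated
   `T_a + T_b`-dimensional gene vectors, stage-associated gene counts
   (TPM ≥ 1, |z| ≥ 1) and Shannon-entropy tissue-specificity counts
   (TPM ≥ 1, H ≥ 0.65).
4. **Open-chromatin (ATAC-seq) analytics.** Peaks are re-distributed onto
   500-bp / 100-bp genome bins under a reciprocal 40 %-overlap rule; the kit
   computes one-hot Euclidean distances between samples, the fraction of peak
   bases covered by alignment hits scoring ≥ 40 (conservation), FRiP quality
   control (pass at ≥ 0.2), differential-bin counts between consecutive
   stages (two-sided Student's t), PWM motif counts at ≥ 75 % of the maximal
   log-odds score, and tissue-specific peak detection.

Every input the analyses consume can be generated by `hourglass_kit.synthetic`
with planted ground truth (gene classes, ortholog pairs, conserved bins), so
the whole pipeline is testable without any downloads.

## Worked example

```python
from hourglass_kit import (
    ExpressionSimConfig, simulate_expression, filter_expressed, scale,
    stage_distance, min_distance_summary,
)

ma, mb, truth = simulate_expression(ExpressionSimConfig(seed=1))
sa = scale(ma.subset(filter_expressed(ma)), "max1")
sb = scale(mb.subset(filter_expressed(mb)), "max1")
pairs = sorted(truth.ortholog_truth)
d = stage_distance(sa, sb, pairs, "euclidean")
s = min_distance_summary(d)
print(truth.planted_conserved_stage_pair, s.global_pair, round(s.global_value, 3))
```

prints

```
('st29', 'E10.5') ('st29', 'E10.5') 5.761
```

i.e. the simulation plants mid-stage conservation at shark stage 29 / mouse
E10.5, and the Euclidean stage-distance matrix over 1 800 expressed ortholog
pairs finds exactly that pair as its global minimum (distance 5.761) — the
hourglass pattern. The same recovery holds for the other three metrics and
after projecting stages onto the top three principal components.

The end-to-end drivers are also available from the shell:

```bash
hourglass-kit run --workflow transcriptome --seed 1 --out results_t
hourglass-kit run --workflow ocr --seed 1 --out results_o
```

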