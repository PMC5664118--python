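# dnbkit

Dynamic network biomarker (DNB) analysis for staged expression data:
detecting the tipping point of a disease progression from collective gene
fluctuations, with the surrounding differential-expression, network and
survival analyses.

## The problem

Many chronic diseases progress through ordered stages — for hepatitis-driven
liver cancer: normal liver → cirrhosis → low-grade dysplastic nodules →
high-grade dysplastic nodules → carcinoma — and deteriorate abruptly once a
critical transition is passed. Just before that transition, differential
expression is typically silent: the pre-disease stage looks like the normal
state in mean expression. The DNB model instead looks for a *module* of
genes whose collective behaviour changes: at the tipping point its members
become

1. strongly mutually correlated — high mean absolute Pearson correlation
   among members, `PCC_in`;
2. decoupled from the rest of the transcriptome — low mean absolute
   correlation between members and non-members, `PCC_out`;
3. highly fluctuating — high mean member standard deviation, `SD_in`.

These combine into a composite index, computed per stage:

```
CI = SD_in · PCC_in / PCC_out
```

Detection runs five steps per stage *t* (samples grouped by stage): build the
|PCC| matrix and take the 0.05-quantile of the descending-order pairwise
|PCC| as the stage's high-correlation threshold; keep genes whose SD is
above the stage's 50th percentile; cluster the retained genes hierarchically
with distance 1 − |PCC|, cutting the tree at the threshold; score each
surviving module by CI and keep the stage's best; the stage whose best
module maximises CI over all stages is the tipping point and its module the
DNB. Downstream, the package counts differentially expressed genes (DEGs)
between stage pairs (pooled-variance t-tests with Benjamini–Hochberg FDR, or
a one-way ANOVA screen), tests hypergeometric enrichment of DEGs in the
DNB's first-neighbour protein-interaction subnetwork, and evaluates the DNB
as a prognostic signature (two-group k-means stratification and per-gene
median splits, Kaplan–Meier curves, log-rank tests).

A synthetic generator plants a ground-truth DNB (a module whose correlation
and variance spike at one known stage while its coupling to the background
collapses, plus a block of genes mean-shifted after the tipping stage), so
the whole pipeline is testable without external data. See
`docs/methods.md` for the generative model and all defaults.

## Worked example

Simulate the default five-stage study (stage sizes 10/13/10/7/8, 500 genes,
a 20-gene module planted at stage 3) and run detection:

```bash
$ dnb simulate --seed 1 --out demo/sim
wrote demo/sim/expression.tsv, demo/sim/stage_design.tsv, demo/sim/ground_truth.json

$ dnb detect --expr demo/sim/expression.tsv --design demo/sim/stage_design.tsv --out demo/det
tipping stage: stage3 (21 DNB genes, contrast 2.67)

$ cat demo/det/stage_scores.tsv   # abridged to 3 significant digits
stage    n_genes  sd_in  pcc_in  pcc_out  ci
stage1   3        1.22   0.786   0.236    4.07
stage2   3        1.25   0.723   0.234    3.85
stage3   21       3.39   0.839   0.277    10.3
stage4   3        1.41   0.895   0.334    3.77
stage5   3        1.32   0.855   0.306    3.70
```

Stage 3's best module scores CI ≈ 10.3 against a ≈ 3.7–4.1 background —
the planted tipping stage, recovered with 21 of ~20 planted genes.  The CI
peak is driven by the module's tripled SD (`sd_in` 3.39 vs ≈ 1.3) and high
internal correlation, exactly the three DNB conditions.  The DEG burst sits
across the tipping boundary:

```bash
$ dnb deg --expr demo/sim/expression.tsv --design demo/sim/stage_design.tsv \
      --contrast stage2:stage4 --alpha 0.05 --out demo/deg.tsv
49 DEGs at FDR q < 0.05
```

49 of the 50 planted post-tipping shifts are recovered between the stages
flanking the tipping point.  `dnb run --config run.yaml` chains detection,
DEG counting, network enrichment and survival stratification into one
reproducible run with a JSON manifest; `dnb enrich` and `dnb survival`
expose the individual stages.

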