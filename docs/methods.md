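# Methods

## The detection model

A staged expression study is a gene-by-sample matrix whose samples are
grouped into T ordered stages, each with a handful of biological replicates
(here 7–13). Within one stage the model treats samples as i.i.d. draws, so
every statistic is cross-sectional: per-gene standard deviation `SD` and the
pairwise absolute Pearson correlation matrix `|PCC|`, both estimated over
that stage's samples only.

A gene module `c` at stage `t` is scored by the composite index

    CI(c, t) = SD_in · PCC_in / PCC_out

with `SD_in` the mean member SD (expression units), `PCC_in` the mean |PCC|
over member pairs, and `PCC_out` the mean |PCC| over member × non-member
pairs. All three correlation terms use absolute values: the clustering
distance is 1 − |PCC|, and anti-correlated co-fluctuation counts as
coupling for all three DNB conditions.

Per stage, detection (i) computes |PCC| and the stage's high-correlation
threshold — the k-th largest off-diagonal |PCC| with k = ⌈q·P⌉ over P
pairs, q = 0.05 by default (the "descending-order quantile" convention:
the top 5 % of pairs count as highly correlated); (ii) retains genes with
SD strictly above the stage's 50th SD percentile; (iii) clusters retained
genes by average-linkage agglomeration on 1 − |PCC|, cutting the tree at
height 1 − threshold, and discards clusters below `min_module_size` = 3;
(iv) scores each module and keeps the stage argmax (ties go to the larger
module, then to the lexicographically smallest gene set); (v) the stage
whose candidate maximises CI is the tipping point (exact cross-stage ties
resolve to the earliest stage). A diagnostic `signal contrast` = max CI /
median CI over the T stage scores is reported alongside; no p-value is
attached to the peak.

### Numerical and degenerate-case policies

* Constant genes get |PCC| = 0 against everything (diagonal stays 1) and
  are flagged; an all-constant stage is an error.
* `PCC_out` is floored at ε = 10⁻⁶ before division; floored candidates are
  flagged `isolated` rather than scoring infinity.
* The SD filter is strictly-above-median, so boundary ties are excluded;
  the percentile is configurable.
* Correlation matrices are built over the SD-retained genes by default
  (`pcc_scope="filtered"`), with the threshold taken over the pairs
  actually formed; this keeps whole-transcriptome inputs tractable, since
  the full pair set is quadratic in gene count. `pcc_scope="all"` computes
  matrix and threshold over every gene pair.
* Stages need ≥ 3 samples (hard floor for correlation estimation; a warning
  is logged below 5).

## Downstream analyses

Pairwise stage contrasts use the classical pooled-variance two-sample
t-test (Welch by flag) with Benjamini–Hochberg adjustment across genes;
significance means q < 0.05. Rows with zero variance in both groups give
t = 0, p = 1 when means agree. The omnibus screen is a per-gene one-way
ANOVA at *unadjusted* p < 0.01 — deliberately uncorrected, preserving the
asymmetry between the two screens. Sample clustering uses the *signed*
correlation distance 1 − PCC between sample profiles (heat-map convention),
unlike the gene-module step's |PCC|.

Network context: an undirected score-filtered edge list (default min score
0.7, the conventional "high confidence" cutoff), gene symbols upper-cased,
self-loops dropped, duplicate edges keeping the maximal score. The
DNB-associated network is the DNB plus its first neighbours (one hop).
Enrichment of a DEG set in it is the upper-tail hypergeometric probability
P(X ≥ k) — not P(X > k) — drawing n = |DEGs| from a universe N with K
successes; the default universe is genes present in both the expression
matrix and the network.

Survival: Kaplan–Meier product-limit curves (events before censorings at
tied times) and the standard two-group log-rank χ² on 1 df. Signature
stratification z-scores each gene, then runs k-means with k = 2, 20
restarts, seeded; group 1 is the higher-mean-signature cluster, fixing the
label order. The per-gene screen median-splits each gene (strictly above
the median → "high"), skips genes with more than half the cohort tied at
the median, and applies no multiplicity correction — the screen reports raw
p < 0.05 flags. Times are used in the units supplied (days).

## The synthetic generator

The generator emulates the study conditions: T = 5 ordered stages with
samples (10, 13, 10, 7, 8), 500 genes (reduced from genome scale so a full
detection run stays interactive), a 20-gene module planted at stage 3, and
50 background genes mean-shifted after the tipping stage. Per stage, a
shared standard-normal latent factor z induces exchangeable correlation
`rho_base` = 0.1 among all genes; at the tipping stage the module switches
to its own factor w with weight √`rho_in` (`rho_in` = 0.8) and SD
`sd_scale`·`baseline_sd` (`sd_scale` = 3), and corr(w, z) is set to
`rho_out`/√(`rho_in`·`rho_base`) so that module–background correlation is
exactly `rho_out` = 0.05. Gene means are drawn once (N(8, 1), a log2-like
scale) and are stage-independent except for the planted shifts, so the
differential ground truth is exactly the shifted set.

Post-tipping shifts are ±`deg_effect`·`baseline_sd` with a random sign per
gene, `deg_effect` = 2.5. The magnitude is deliberately strong: the burst
this emulates is the drastic cross-transition change that follows a tipping
point, and mixed directions match how real cross-transition DEGs move (an
all-one-direction shift would also be invisible to correlation-based sample
clustering, since Pearson distance ignores a constant offset per sample).
The survival generator draws two latent patient groups with exponential
event times (hazard ratio `effect` for group 2), independent uniform
censoring, and signature genes separated by 2 SD units between groups.

What the generator does *not* emulate: probe-level microarray structure and
normalisation artefacts, heavy-tailed or count-valued expression, gene-gene
correlation beyond exchangeable blocks, stage-to-stage drift of means
(samples are independent across stages, not longitudinal), or any true
bifurcation dynamics — stages are independent cross-sectional draws. Tests
passing on these data show the algorithmic chain is correct and calibrated
under the stated moment structure, not that the method is robust to real
microarray noise.

## Calibration results and known limitations

With the defaults above, the planted stage is recovered in ~98 % of seeds
with median detected-vs-planted Jaccard ≈ 0.8, and planted DEG recovery at
the cross-tipping contrast is ~95 % with the pairwise DEG-count matrix
peaking on boundary-straddling pairs.

Two small-sample properties of the CI statistic are worth knowing. First,
under a null with no planted module, the argmax stage is not uniform: with
unequal per-stage sample counts the larger stages are selected more often
(up to ~0.4 for n = 13, down to ~0.03 for n = 7–8 in 100-seed runs). The
|PCC| noise floor scales as ~n^{-1/2} and enters numerator and denominator
differently, so CI is not n-invariant; cross-stage comparisons are cleanest
with balanced designs. Second, the max/median CI contrast has a hard floor
of 1 and its planted-signal value is capped by the same noise floor:
`PCC_out` cannot drop below the mean absolute sample correlation (~0.3 at
n = 10) however small the true module–background correlation is, which caps
the tipping CI near 7.5 against a ~3.7–4 chance-module background, i.e. a
mean contrast near 2 against a null mean near 1.08. The contrast is a
useful diagnostic but not a large-gap separator at these sample sizes.

The per-stage candidate CI is a maximum over many modules and is therefore
extreme-value inflated; CI values should be compared across stages within
one run, not across datasets. The detector reports every stage's score so
that a flat profile (low signal contrast) is visible rather than hidden
behind a single argmax.

## Problem sizes used in the shipped checks

Simulation-based checks run at the study scale (500 genes, 48 samples)
with 20–100 seeds per experiment, and the acceptance script uses 25 signal,
50 null and 10 differential-expression seeds plus one 122-patient survival
cohort; brute-force oracle comparisons run on 6–20 gene instances where
exhaustive enumeration is exact. Seed streams are fixed per experiment so
every reported number is reproducible bit-for-bit.
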