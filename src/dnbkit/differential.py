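"""Differential expression between stages and sample clustering.

Pairwise contrasts use the classical pooled-variance two-sample t-test with
Benjamini-Hochberg FDR control across genes (Welch available by flag); the
omnibus screen is a per-gene one-way ANOVA at an unadjusted p cutoff --
deliberately uncorrected, matching the screen it reproduces.  Sample
clustering is agglomerative on the signed-correlation distance 1 - PCC
between sample expression profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import ExpressionMatrix, StagedExpression

logger = logging.getLogger(__name__)


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise t of b vs a with degenerate-row policy.

    Zero pooled variance with zero mean difference gives t = 0, p = 1
    (identical constant groups carry no evidence); zero variance with a
    nonzero difference gives t = +/-inf, p = 0.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = st.ttest_ind(b, a, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    diff = b.mean(axis=1) - a.mean(axis=1)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.info("%d gene(s) with zero variance in both groups", int(degenerate.sum()))
        zero_diff = degenerate & (diff == 0)
        t[zero_diff], p[zero_diff] = 0.0, 1.0
        nz = degenerate & (diff != 0)
        t[nz] = np.sign(diff[nz]) * np.inf
        p[nz] = 0.0
    return t, p


def ttest_deg(
    expr: StagedExpression,
    stage_a: str,
    stage_b: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sided t-test of stage_b vs stage_a with BH adjustment.

    Returns a table with columns gene, statistic (t for the b - a
    contrast), p, q (BH across all tested genes), direction (sign of the
    mean difference) and significant (q < alpha).
    """
    a = expr.stage_values(stage_a).to_numpy(dtype=float)
    b = expr.stage_values(stage_b).to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("both stages need >= 2 samples for a t-test")
    t, p = _two_sample_t(a, b, equal_var)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    diff = b.mean(axis=1) - a.mean(axis=1)
    return pd.DataFrame({
        "gene": expr.gene_ids,
        "statistic": t,
        "p": p,
        "q": q,
        "direction": np.sign(diff).astype(int),
        "significant": q < alpha,
        "contrast": f"{stage_a}:{stage_b}",
    })


def anova_table(expr: StagedExpression) -> pd.DataFrame:
    """Per-gene one-way F test across all stages (unadjusted p)."""
    groups = [expr.stage_values(s).to_numpy(dtype=float) for s in expr.stages]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 stages")
    if any(g.shape[1] < 2 for g in groups):
        raise ValidationError("every stage needs >= 2 samples for ANOVA")
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = st.f_oneway(*groups, axis=1)
    f = np.asarray(f, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(f)
    if degenerate.any():
        # all-constant rows: no between- or within-stage variation -> no evidence
        means = np.array([g.mean(axis=1) for g in groups])
        flat = degenerate & (np.ptp(means, axis=0) == 0)
        f[flat], p[flat] = 0.0, 1.0
        rest = degenerate & ~flat
        f[rest], p[rest] = np.inf, 0.0
    return pd.DataFrame({"gene": expr.gene_ids, "statistic": f, "p": p})


def anova_deg(expr: StagedExpression, alpha: float = 0.01) -> set[str]:
    """Genes with omnibus one-way ANOVA p < alpha (no FDR, by design)."""
    table = anova_table(expr)
    return set(table.loc[table["p"] < alpha, "gene"])


def pairwise_deg_counts(expr: StagedExpression, alpha: float = 0.05) -> pd.DataFrame:
    """Symmetric stage-by-stage matrix of FDR-significant gene counts."""
    stages = expr.stages
    if len(stages) < 2:
        raise ValidationError("need >= 2 stages")
    counts = pd.DataFrame(0, index=stages, columns=stages, dtype=int)
    for i, s1 in enumerate(stages):
        for s2 in stages[i + 1:]:
            n = int(ttest_deg(expr, s1, s2, alpha=alpha)["significant"].sum())
            counts.loc[s1, s2] = counts.loc[s2, s1] = n
    return counts


@dataclass
class SampleClustering:
    """Agglomerative merge tree over samples (distance 1 - PCC)."""

    sample_ids: list[str]
    linkage_matrix: np.ndarray
    constant_samples: list[str]

    def cut(self, k: int) -> pd.Series:
        """Cluster labels at a k-group cut."""
        labels = sch.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")


def cluster_samples(
    matrix: ExpressionMatrix | pd.DataFrame, linkage: str = "average"
) -> SampleClustering:
    """Hierarchically cluster samples on their expression profiles.

    Distance is 1 - PCC with the *signed* correlation between sample
    profiles (heat-map convention; anticorrelated samples are maximally
    distant at 2).  Constant profiles get correlation 0 and are flagged.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 2 or values.shape[0] < 2:
        raise ValidationError("need >= 2 samples and >= 2 genes")
    arr = values.to_numpy(dtype=float).T  # samples as rows
    sds = arr.std(axis=1, ddof=1)
    constant = sds == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    if constant.any():
        logger.warning("%d constant sample profile(s); correlations set to 0",
                       int(constant.sum()))
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    Z = sch.linkage(squareform(dist, checks=False), method=linkage)
    return SampleClustering(
        sample_ids=list(values.columns),
        linkage_matrix=Z,
        constant_samples=[s for s, c in zip(values.columns, constant) if c],
    )
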