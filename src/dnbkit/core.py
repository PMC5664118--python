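"""Dynamic network biomarker (DNB) detection.

The DNB model identifies the tipping point of a staged progression from the
collective behaviour of a gene module rather than from differential
expression.  A module is a candidate DNB at stage t when its members are

1. strongly mutually correlated (high mean absolute Pearson correlation
   among members, ``PCC_in``),
2. decoupled from the rest of the transcriptome (low mean absolute
   correlation between members and non-members, ``PCC_out``), and
3. highly fluctuating (high mean member standard deviation, ``SD_in``).

The three conditions combine into one composite index

    CI = SD_in * PCC_in / PCC_out

and the detection loop runs five steps per stage: (1) absolute-PCC matrix
and its high-correlation threshold (the top-5%-of-pairs order statistic);
(2) retain genes whose SD exceeds the stage's 50th percentile; (3) cluster
retained genes hierarchically with distance 1 - |PCC|, cutting the tree at
the threshold from step 1; (4) score every surviving module by CI and keep
the stage's argmax; (5) the stage whose best module has the maximal CI over
all stages is the tipping point and its module the DNB.

Whole-transcriptome correlation matrices are quadratic in gene count, so by
default the matrix is built only over SD-retained genes (steps 1-2 swapped
for the matrix build; the threshold is still the 0.05-quantile order
statistic over the pairs actually formed).  ``pcc_scope="all"`` computes
both over all genes instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .io import StagedExpression

logger = logging.getLogger(__name__)

_LINKAGES = ("single", "complete", "average")


@dataclass(frozen=True)
class DNBConfig:
    """Tunable parameters of the detection algorithm.

    sd_percentile
        Per-stage SD filter: genes strictly above this percentile of the
        per-gene SD distribution are retained (50 = median split).
    pcc_quantile
        Fraction of gene pairs counted as "highly correlated"; the
        threshold is the k-th largest absolute PCC with k = ceil(q * P).
    linkage
        Agglomeration rule for the 1 - |PCC| distance tree.
    min_module_size
        Modules smaller than this are discarded (pairs give degenerate
        within-module statistics).
    pcc_scope
        "filtered": correlations over SD-retained genes (default, scales);
        "all": correlations and threshold over every gene pair.
    eps
        Floor applied to PCC_out before division; floored candidates are
        flagged ``isolated`` instead of scoring infinity.
    """

    sd_percentile: float = 50.0
    pcc_quantile: float = 0.05
    linkage: str = "average"
    min_module_size: int = 3
    pcc_scope: str = "filtered"
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.pcc_quantile < 1:
            raise ValidationError("pcc_quantile must be in (0, 1)")
        if not 0 <= self.sd_percentile < 100:
            raise ValidationError("sd_percentile must be in [0, 100)")
        if self.linkage not in _LINKAGES:
            raise ValidationError(f"linkage must be one of {_LINKAGES}")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")
        if self.pcc_scope not in ("filtered", "all"):
            raise ValidationError("pcc_scope must be 'filtered' or 'all'")


@dataclass
class StageStats:
    """Per-stage correlation/fluctuation statistics.

    ``sd`` covers every gene of the input matrix; ``genes`` lists the
    correlation universe (all genes, or the SD-retained subset under the
    default scope) indexing the rows/columns of ``abs_pcc``.
    """

    stage: str
    sd: pd.Series
    sd_cutoff: float
    genes: list[str]
    abs_pcc: np.ndarray
    pcc_threshold: float
    constant_genes: list[str]
    n_samples: int

    def index_of(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise ValidationError(
                f"gene(s) outside the stage's correlation universe: {missing[:5]}"
            )
        return np.fromiter((pos[g] for g in genes), dtype=int, count=len(genes))


@dataclass
class ModuleCandidate:
    """A gene module scored at one stage by the composite index."""

    stage: str
    genes: tuple[str, ...]
    sd_in: float
    pcc_in: float
    pcc_out: float
    ci: float
    isolated: bool = False  # PCC_out hit the eps floor


@dataclass
class DNBResult:
    """Output of the cross-stage detection loop."""

    per_stage: dict[str, ModuleCandidate | None]
    scores: dict[str, float]
    tipping_stage: str
    dnb_genes: tuple[str, ...]
    filtered_sets: dict[str, tuple[str, ...]]
    module_lists: dict[str, list[tuple[str, ...]]]
    signal_contrast: float
    config: DNBConfig = field(default_factory=DNBConfig)


# ---------------------------------------------------------------------------
# step 1-2: per-stage statistics
# ---------------------------------------------------------------------------

def absolute_correlation(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """|PCC| matrix over rows; constant rows get 0 against everything.

    Returns (abs_pcc, constant_row_mask).  The diagonal is 1 even for
    constant rows, matching the unit-diagonal invariant.
    """
    sds = values.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.all():
        raise ValidationError("all genes constant in this stage; PCC undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.abs(corr)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, 0.0, 1.0, out=corr)
    return corr, constant


def threshold_from_pairs(pair_values: np.ndarray, quantile: float) -> float:
    """The k-th largest value, k = ceil(quantile * n_pairs).

    This is the descending-order quantile convention: the top ``quantile``
    fraction of pairs counts as highly correlated.
    """
    pairs = np.asarray(pair_values, dtype=float).ravel()
    if pairs.size == 0:
        raise ValidationError("no correlation pairs to threshold")
    k = max(int(np.ceil(quantile * pairs.size)), 1)
    return float(np.partition(pairs, pairs.size - k)[pairs.size - k])


def high_pcc_threshold(abs_pcc: np.ndarray, quantile: float) -> float:
    """Descending-order quantile threshold over all off-diagonal |PCC| pairs."""
    n = abs_pcc.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 genes to form correlation pairs")
    iu = np.triu_indices(n, k=1)
    return threshold_from_pairs(abs_pcc[iu], quantile)


def compute_stage_stats(
    expr: StagedExpression, stage: str, config: DNBConfig = DNBConfig()
) -> StageStats:
    """Steps 1-2 for one stage: SD profile, |PCC| matrix, both thresholds."""
    data = expr.stage_values(stage)
    n_samples = data.shape[1]
    if n_samples < 3:
        raise ValidationError(f"stage {stage!r} has {n_samples} samples; need >= 3")
    arr = data.to_numpy(dtype=float)
    sd = pd.Series(arr.std(axis=1, ddof=1), index=data.index)
    if (sd == 0).all():
        raise ValidationError(f"all genes constant at stage {stage!r}")
    sd_cutoff = float(np.percentile(sd.to_numpy(), config.sd_percentile))

    if config.pcc_scope == "filtered":
        universe = [g for g in data.index if sd[g] > sd_cutoff]
        if len(universe) < 2:
            raise ValidationError(
                f"stage {stage!r}: fewer than 2 genes above the SD percentile; "
                "lower sd_percentile"
            )
    else:
        universe = list(data.index)
    sub = data.loc[universe].to_numpy(dtype=float)
    abs_pcc, const_mask = absolute_correlation(sub)
    constant = [g for g, c in zip(universe, const_mask) if c]
    if constant:
        logger.info("stage %r: %d constant gene(s) assigned PCC 0", stage, len(constant))
    threshold = high_pcc_threshold(abs_pcc, config.pcc_quantile)
    return StageStats(
        stage=stage,
        sd=sd,
        sd_cutoff=sd_cutoff,
        genes=list(universe),
        abs_pcc=abs_pcc,
        pcc_threshold=threshold,
        constant_genes=constant,
        n_samples=n_samples,
    )


def filter_by_sd(stats: StageStats, min_module_size: int = 3) -> set[str]:
    """Step 2's gene set M_t: genes with SD strictly above the stage cutoff."""
    retained = {g for g in stats.sd.index if stats.sd[g] > stats.sd_cutoff}
    if len(retained) < min_module_size:
        raise ValidationError(
            f"stage {stats.stage!r}: only {len(retained)} gene(s) pass the SD filter "
            f"(need >= {min_module_size}); use a smaller SD percentile"
        )
    return retained


# ---------------------------------------------------------------------------
# step 3: correlation-module clustering
# ---------------------------------------------------------------------------

def cluster_correlated_modules(
    stats: StageStats,
    retained: set[str] | Sequence[str],
    linkage: str = "average",
    min_module_size: int = 3,
) -> list[tuple[str, ...]]:
    """Hierarchical modules over distance 1 - |PCC|, cut at 1 - threshold.

    Clusters whose pairwise (cophenetic) distances all sit at or below
    1 - pcc_threshold survive; those smaller than ``min_module_size`` are
    discarded.  Returned modules are disjoint, each a sorted gene tuple,
    ordered by size (desc) then lexicographically.
    """
    genes = [g for g in stats.genes if g in set(retained)]
    if len(genes) < min_module_size:
        return []
    idx = stats.index_of(genes)
    dist = 1.0 - stats.abs_pcc[np.ix_(idx, idx)]
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    cut = 1.0 - stats.pcc_threshold
    condensed = squareform(dist, checks=False)
    Z = sch.linkage(condensed, method=linkage)
    labels = sch.fcluster(Z, t=cut, criterion="distance")
    modules: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        modules.setdefault(int(lab), []).append(g)
    out = [tuple(sorted(m)) for m in modules.values() if len(m) >= min_module_size]
    out.sort(key=lambda m: (-len(m), m))
    return out


# ---------------------------------------------------------------------------
# step 4: composite-index scoring and per-stage selection
# ---------------------------------------------------------------------------

def composite_index(
    stats: StageStats, genes: Sequence[str], eps: float = 1e-6
) -> ModuleCandidate:
    """Score a module: CI = SD_in * PCC_in / max(PCC_out, eps).

    SD_in is the mean member SD, PCC_in the mean over member pairs of
    |PCC|, PCC_out the mean over member x non-member pairs (non-members
    drawn from the stage's correlation universe).
    """
    genes = tuple(sorted(set(genes)))
    if len(genes) < 2:
        raise ValidationError("composite_index needs >= 2 member genes")
    idx = stats.index_of(genes)
    n = len(stats.genes)
    member_mask = np.zeros(n, dtype=bool)
    member_mask[idx] = True
    if member_mask.all():
        raise ValidationError("no non-member genes; PCC_out undefined")
    inner = stats.abs_pcc[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    pcc_in = float(inner[iu].mean())
    cross = stats.abs_pcc[np.ix_(idx, np.flatnonzero(~member_mask))]
    pcc_out = float(cross.mean())
    sd_in = float(stats.sd[list(genes)].mean())
    isolated = pcc_out < eps
    ci = sd_in * pcc_in / max(pcc_out, eps)
    if isolated:
        logger.info("stage %r: module of %d genes has PCC_out < eps; flagged isolated",
                    stats.stage, len(genes))
    return ModuleCandidate(
        stage=stats.stage, genes=genes, sd_in=sd_in,
        pcc_in=pcc_in, pcc_out=pcc_out, ci=float(ci), isolated=isolated,
    )


def select_stage_candidate(
    stats: StageStats, modules: Sequence[Sequence[str]], eps: float = 1e-6
) -> ModuleCandidate | None:
    """The stage's candidate DNB: maximal CI, ties to the larger module,
    then the lexicographically smallest gene set.  None when no modules."""
    if not modules:
        return None
    scored = [composite_index(stats, m, eps=eps) for m in modules]
    scored.sort(key=lambda c: (-c.ci, -len(c.genes), c.genes))
    return scored[0]


# ---------------------------------------------------------------------------
# step 5: cross-stage tipping-point selection
# ---------------------------------------------------------------------------

def detect_tipping_point(
    expr: StagedExpression, config: DNBConfig = DNBConfig()
) -> DNBResult:
    """Run the five-step detection over all stages; argmax CI is the tipping
    point.  Also reports every stage's score (the score vector a progression
    plot would show) and a signal-contrast diagnostic max CI / median CI."""
    stages = expr.stages
    if len(stages) < 2:
        raise ValidationError(f"need >= 2 stages, got {len(stages)}")
    per_stage: dict[str, ModuleCandidate | None] = {}
    scores: dict[str, float] = {}
    filtered_sets: dict[str, tuple[str, ...]] = {}
    module_lists: dict[str, list[tuple[str, ...]]] = {}
    for stage in stages:
        stats = compute_stage_stats(expr, stage, config)
        retained = filter_by_sd(stats, config.min_module_size)
        filtered_sets[stage] = tuple(sorted(retained))
        modules = cluster_correlated_modules(
            stats, retained, linkage=config.linkage,
            min_module_size=config.min_module_size,
        )
        module_lists[stage] = modules
        cand = select_stage_candidate(stats, modules, eps=config.eps)
        per_stage[stage] = cand
        scores[stage] = cand.ci if cand is not None else 0.0
        logger.info("stage %r: %d module(s), CI = %.4g", stage, len(modules), scores[stage])
    if all(c is None for c in per_stage.values()):
        raise ValidationError("no stage produced a candidate module")
    # earliest stage wins exact CI ties (stage order is the progression order)
    tipping = max(stages, key=lambda s: scores[s])
    winner = per_stage[tipping]
    assert winner is not None
    score_vec = np.array([scores[s] for s in stages])
    med = float(np.median(score_vec))
    contrast = float(score_vec.max() / max(med, config.eps))
    return DNBResult(
        per_stage=per_stage,
        scores=scores,
        tipping_stage=tipping,
        dnb_genes=winner.genes,
        filtered_sets=filtered_sets,
        module_lists=module_lists,
        signal_contrast=contrast,
        config=config,
    )


def stage_scores_table(result: DNBResult) -> pd.DataFrame:
    """Per-stage candidate statistics as a tidy table (stage score vector)."""
    rows = []
    for stage, cand in result.per_stage.items():
        if cand is None:
            rows.append({"stage": stage, "n_genes": 0, "sd_in": np.nan,
                         "pcc_in": np.nan, "pcc_out": np.nan, "ci": 0.0})
        else:
            rows.append({"stage": stage, "n_genes": len(cand.genes),
                         "sd_in": cand.sd_in, "pcc_in": cand.pcc_in,
                         "pcc_out": cand.pcc_out, "ci": cand.ci})
    return pd.DataFrame(rows)
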