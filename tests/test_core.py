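"""The five-step detection algorithm: thresholds, clustering, CI, argmax."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_stage_stats
from _oracles import average_linkage_partition, composite_index_direct

from dnbkit import (
    DNBConfig,
    StageDesign,
    StagedExpression,
    SyntheticSpec,
    ValidationError,
    cluster_correlated_modules,
    composite_index,
    compute_stage_stats,
    detect_tipping_point,
    filter_by_sd,
    generate_staged_expression,
    select_stage_candidate,
)
from dnbkit.core import threshold_from_pairs


def staged_from_array(arr, stage="t"):
    genes = [f"g{i:02d}" for i in range(arr.shape[0])]
    samples = [f"s{i:02d}" for i in range(arr.shape[1])]
    design = StageDesign(stages=[stage], assignment={s: stage for s in samples})
    return StagedExpression(pd.DataFrame(arr, index=genes, columns=samples), design)


# ---------------------------------------------------------------------------
# step 1-2: stats and SD filter
# ---------------------------------------------------------------------------

def test_descending_quantile_threshold_is_kth_largest():
    values = np.arange(1, 101) / 100.0  # exactly {0.01, ..., 1.00}
    assert threshold_from_pairs(values, 0.05) == pytest.approx(0.96)
    # sort-based oracle on random pair sets
    rng = np.random.default_rng(0)
    for _ in range(20):
        pairs = rng.random(rng.integers(5, 400))
        k = int(np.ceil(0.05 * pairs.size))
        assert threshold_from_pairs(pairs, 0.05) == sorted(pairs, reverse=True)[k - 1]


def test_identical_genes_have_unit_abs_pcc():
    rng = np.random.default_rng(1)
    base = rng.standard_normal(8)
    arr = np.vstack([base, base, rng.standard_normal((3, 8))])
    expr = staged_from_array(arr)
    stats = compute_stage_stats(expr, "t", DNBConfig(pcc_scope="all"))
    assert stats.abs_pcc[0, 1] == pytest.approx(1.0)
    assert np.all(stats.abs_pcc >= 0) and np.all(stats.abs_pcc <= 1)


def test_constant_gene_gets_zero_pcc_and_is_flagged():
    rng = np.random.default_rng(2)
    arr = rng.standard_normal((5, 8))
    arr[3] = 7.0
    expr = staged_from_array(arr)
    stats = compute_stage_stats(expr, "t", DNBConfig(pcc_scope="all"))
    assert stats.constant_genes == ["g03"]
    off = np.delete(stats.abs_pcc[3], 3)
    assert np.all(off == 0.0)
    assert stats.abs_pcc[3, 3] == 1.0


def test_all_constant_stage_is_an_error():
    expr = staged_from_array(np.full((4, 6), 3.0))
    with pytest.raises(ValidationError, match="constant"):
        compute_stage_stats(expr, "t", DNBConfig(pcc_scope="all"))


def test_sd_filter_is_strictly_above_median():
    stats = make_stage_stats(sd=[1.0, 2.0, 3.0, 4.0], abs_pcc=np.eye(4))
    assert stats.sd_cutoff == pytest.approx(2.5)
    assert filter_by_sd(stats, min_module_size=2) == {"g2", "g3"}
    flat = make_stage_stats(sd=[2.0] * 4, abs_pcc=np.eye(4))
    with pytest.raises(ValidationError, match="SD"):
        filter_by_sd(flat)


def test_sd_filter_matches_sort_oracle_on_synthetic_stage():
    expr, _ = generate_staged_expression(SyntheticSpec(seed=4))
    stats = compute_stage_stats(expr, "stage1")
    retained = filter_by_sd(stats)
    sd = expr.stage_values("stage1").std(axis=1, ddof=1)
    cutoff = np.median(np.sort(sd.to_numpy()))
    oracle = set(sd.index[sd > cutoff])
    assert retained == oracle
    assert len(retained) <= int(np.ceil(len(sd) / 2))


# ---------------------------------------------------------------------------
# step 3: clustering
# ---------------------------------------------------------------------------

def _block_pcc(blocks, inside, outside):
    n = sum(blocks)
    pcc = np.full((n, n), outside)
    start = 0
    for b in blocks:
        pcc[start:start + b, start:start + b] = inside
        start += b
    np.fill_diagonal(pcc, 1.0)
    return pcc


def test_two_clean_blocks_cluster_separately():
    stats = make_stage_stats(sd=[1.0] * 6, abs_pcc=_block_pcc([3, 3], 0.9, 0.1),
                             threshold=0.5)
    modules = cluster_correlated_modules(stats, set(stats.genes), min_module_size=3)
    assert sorted(len(m) for m in modules) == [3, 3]
    assert set(modules[0]) | set(modules[1]) == set(stats.genes)


def test_no_high_correlations_yields_no_module():
    stats = make_stage_stats(sd=[1.0] * 5, abs_pcc=_block_pcc([5], 0.2, 0.2),
                             threshold=0.5)
    assert cluster_correlated_modules(stats, set(stats.genes), min_module_size=3) == []


def test_small_clusters_are_discarded():
    pcc = _block_pcc([5, 1, 1, 1], 0.95, 0.05)
    stats = make_stage_stats(sd=[1.0] * 8, abs_pcc=pcc, threshold=0.5)
    modules = cluster_correlated_modules(stats, set(stats.genes), min_module_size=3)
    assert len(modules) == 1 and len(modules[0]) == 5


def test_clustering_matches_exhaustive_merge_oracle():
    rng = np.random.default_rng(7)
    for _ in range(40):
        n = int(rng.integers(6, 9))
        data = rng.standard_normal((n, 10))
        pcc = np.abs(np.corrcoef(data))
        threshold = float(rng.uniform(0.3, 0.8))
        stats = make_stage_stats(sd=np.ones(n), abs_pcc=pcc, threshold=threshold)
        got = cluster_correlated_modules(stats, set(stats.genes), min_module_size=1)
        dist = 1.0 - pcc
        np.fill_diagonal(dist, 0.0)
        expected = average_linkage_partition(dist, 1.0 - threshold)
        expected_modules = sorted(
            tuple(sorted(stats.genes[i] for i in part)) for part in expected
        )
        assert sorted(got) == expected_modules


# ---------------------------------------------------------------------------
# step 4: composite index and per-stage candidate
# ---------------------------------------------------------------------------

def test_composite_index_direct_arithmetic():
    # sd_in = 2, pcc_in = 0.9, pcc_out = 0.3 -> ci = 2 * 0.9 / 0.3 = 6
    pcc = _block_pcc([2, 2], 0.9, 0.3)
    stats = make_stage_stats(sd=[2.0, 2.0, 1.0, 1.0], abs_pcc=pcc)
    cand = composite_index(stats, ["g0", "g1"])
    assert cand.sd_in == pytest.approx(2.0)
    assert cand.pcc_in == pytest.approx(0.9)
    assert cand.pcc_out == pytest.approx(0.3)
    assert cand.ci == pytest.approx(6.0)
    assert not cand.isolated


def test_composite_index_isolated_module_uses_eps_floor():
    pcc = _block_pcc([2, 2], 0.9, 0.0)
    stats = make_stage_stats(sd=[2.0, 2.0, 1.0, 1.0], abs_pcc=pcc)
    cand = composite_index(stats, ["g0", "g1"])
    assert cand.isolated
    assert cand.ci == pytest.approx(2.0 * 0.9 / 1e-6)
    with pytest.raises(ValidationError, match="non-member"):
        composite_index(stats, stats.genes)


def test_composite_index_matches_direct_oracle():
    rng = np.random.default_rng(11)
    for _ in range(30):
        data = rng.standard_normal((20, 8))
        pcc = np.abs(np.corrcoef(data))
        np.fill_diagonal(pcc, 1.0)
        sd = data.std(axis=1, ddof=1)
        stats = make_stage_stats(sd=sd, abs_pcc=pcc)
        members = sorted(rng.choice(20, size=5, replace=False))
        cand = composite_index(stats, [stats.genes[i] for i in members])
        ci, sd_in, pcc_in, pcc_out = composite_index_direct(sd, pcc, members)
        assert abs(cand.ci - ci) < 1e-10
        assert abs(cand.pcc_out - pcc_out) < 1e-12


def test_stage_candidate_selection_and_tie_breaks():
    pcc = _block_pcc([3, 3, 4], 0.9, 0.1)
    sd = np.array([1.0] * 3 + [3.0] * 3 + [1.0] * 4)
    stats = make_stage_stats(sd=sd, abs_pcc=pcc)
    mods = [tuple(stats.genes[:3]), tuple(stats.genes[3:6]), tuple(stats.genes[6:])]
    best = select_stage_candidate(stats, mods)
    assert best.genes == tuple(stats.genes[3:6])  # highest SD_in wins on CI
    assert select_stage_candidate(stats, []) is None
    # exact CI tie: both blocks identical statistics, sizes 3 vs 4
    pcc_tie = _block_pcc([3, 4], 0.9, 0.0)
    pcc_tie[:3, 3:] = pcc_tie[3:, :3] = 0.2
    pad = np.pad(pcc_tie, ((0, 2), (0, 2)), constant_values=0.2)
    np.fill_diagonal(pad, 1.0)
    stats_tie = make_stage_stats(sd=np.ones(9), abs_pcc=pad)
    a, b = tuple(stats_tie.genes[:3]), tuple(stats_tie.genes[3:7])
    got = select_stage_candidate(stats_tie, [a, b])
    assert got.genes == b  # equal CI -> larger module


# ---------------------------------------------------------------------------
# step 5 and invariances
# ---------------------------------------------------------------------------

def test_single_stage_input_is_an_error():
    expr = staged_from_array(np.random.default_rng(0).standard_normal((10, 6)))
    with pytest.raises(ValidationError, match="2 stages"):
        detect_tipping_point(expr)


def test_ci_invariant_under_relabeling_and_sample_permutation():
    expr, truth = generate_staged_expression(SyntheticSpec(n_genes=60, module_size=10, n_deg_post=10, seed=9))
    stats = compute_stage_stats(expr, "stage3")
    members = [g for g in truth.planted_module if g in stats.genes][:5]
    base = composite_index(stats, members).ci

    rng = np.random.default_rng(0)
    perm_cols = list(rng.permutation(expr.values.columns))
    permuted = StagedExpression(expr.values[perm_cols], expr.design)
    assert composite_index(
        compute_stage_stats(permuted, "stage3"), members
    ).ci == pytest.approx(base, abs=1e-12)

    relabel = {g: f"x_{g}" for g in expr.gene_ids}
    renamed = StagedExpression(expr.values.rename(index=relabel), expr.design)
    assert composite_index(
        compute_stage_stats(renamed, "stage3"), [relabel[g] for g in members]
    ).ci == pytest.approx(base, abs=1e-12)


def test_ci_scales_linearly_in_member_sd():
    """Scaling member-gene expression by c scales SD_in and CI by c while
    leaving both correlation terms unchanged."""
    expr, truth = generate_staged_expression(SyntheticSpec(n_genes=60, module_size=10, n_deg_post=10, seed=10))
    stats = compute_stage_stats(expr, "stage3")
    members = [g for g in truth.planted_module if g in stats.genes][:5]
    base = composite_index(stats, members)
    c = 2.5
    scaled_values = expr.values.copy()
    cols = expr.design.samples_for("stage3")
    scaled_values.loc[members, cols] *= c
    scaled = StagedExpression(scaled_values, expr.design)
    cand = composite_index(compute_stage_stats(scaled, "stage3"), members)
    assert cand.sd_in == pytest.approx(c * base.sd_in)
    assert cand.pcc_in == pytest.approx(base.pcc_in, abs=1e-12)
    assert cand.pcc_out == pytest.approx(base.pcc_out, abs=1e-12)
    assert cand.ci == pytest.approx(c * base.ci, rel=1e-12)


def test_detect_reports_all_stage_scores_and_disjoint_modules():
    expr, truth = generate_staged_expression(SyntheticSpec(seed=12))
    result = detect_tipping_point(expr)
    assert set(result.scores) == set(expr.stages)
    assert result.scores[result.tipping_stage] == max(result.scores.values())
    assert set(result.dnb_genes) <= set(result.filtered_sets[result.tipping_stage])
    for stage, modules in result.module_lists.items():
        seen = set()
        for m in modules:
            assert seen.isdisjoint(m)
            seen.update(m)
            assert set(m) <= set(result.filtered_sets[stage])
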