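"""Stage contrasts: pooled t with BH, ANOVA screen, sample clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stn

from _oracles import bh_reject, bh_stepup, pooled_t

from dnbkit import (
    StageDesign,
    StagedExpression,
    SyntheticSpec,
    ValidationError,
    anova_deg,
    anova_table,
    cluster_samples,
    generate_staged_expression,
    pairwise_deg_counts,
    ttest_deg,
)
from statsmodels.stats.multitest import multipletests


def two_stage(a, b):
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    genes = [f"g{i}" for i in range(a.shape[0])]
    cols = [f"a{i}" for i in range(a.shape[1])] + [f"b{i}" for i in range(b.shape[1])]
    design = StageDesign(
        stages=["A", "B"],
        assignment={c: ("A" if c.startswith("a") else "B") for c in cols},
    )
    values = pd.DataFrame(np.hstack([a, b]), index=genes, columns=cols)
    return StagedExpression(values, design)


def test_t_statistic_matches_pooled_formula():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([6.0, 7.0, 8.0])
    table = ttest_deg(two_stage(a, b), "A", "B")
    assert abs(abs(table.loc[0, "statistic"]) - abs(pooled_t(a, b))) < 1e-10
    rng = np.random.default_rng(3)
    for _ in range(30):
        x = rng.standard_normal(5)
        y = rng.standard_normal(7) + rng.normal()
        t = ttest_deg(two_stage(x, y), "A", "B").loc[0, "statistic"]
        assert abs(t - pooled_t(x, y)) < 1e-10


def test_identical_groups_are_not_significant():
    x = np.array([2.0, 3.0, 4.0])
    table = ttest_deg(two_stage(x, x.copy()), "A", "B")
    assert table.loc[0, "statistic"] == pytest.approx(0.0)
    assert table.loc[0, "p"] == pytest.approx(1.0)
    assert not table.loc[0, "significant"]
    const = np.full(3, 5.0)
    degenerate = ttest_deg(two_stage(const, const.copy()), "A", "B")
    assert degenerate.loc[0, "p"] == 1.0  # zero variance, zero difference


def test_contrast_direction_flips_with_order():
    rng = np.random.default_rng(8)
    x, y = rng.standard_normal((4, 5)), rng.standard_normal((4, 6)) + 1.0
    expr = two_stage(x, y)
    ab = ttest_deg(expr, "A", "B")
    ba = ttest_deg(expr, "B", "A")
    np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-14)
    assert (ab["direction"] == -ba["direction"]).all()


def test_bh_qvalues_match_hand_stepup_and_are_order_invariant():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    _, q, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-14)
    rng = np.random.default_rng(5)
    pv = rng.random(200)
    _, q1, _, _ = multipletests(pv, method="fdr_bh")
    np.testing.assert_allclose(q1, bh_stepup(pv), atol=1e-12)
    perm = rng.permutation(200)
    _, q2, _, _ = multipletests(pv[perm], method="fdr_bh")
    np.testing.assert_allclose(q2, q1[perm], atol=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(stn.lists(stn.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60),
       stn.floats(min_value=0.01, max_value=0.2))
def test_bh_significant_set_equals_classical_stepup_rule(pvals, alpha):
    p = np.array(pvals)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    assert set(np.flatnonzero(reject)) == bh_reject(p, alpha)


def test_anova_power_and_preconditions():
    rng = np.random.default_rng(9)
    arr = rng.standard_normal((50, 25))
    arr[7, 20:] += 5.0  # one gene shifted by 5 SD in the last stage
    genes = [f"g{i}" for i in range(50)]
    cols = [f"s{i}" for i in range(25)]
    design = StageDesign(stages=[f"t{k}" for k in range(5)],
                         assignment={f"s{i}": f"t{i // 5}" for i in range(25)})
    expr = StagedExpression(pd.DataFrame(arr, index=genes, columns=cols), design)
    assert "g7" in anova_deg(expr, alpha=0.01)
    table = anova_table(expr)
    assert ((table["p"] >= 0) & (table["p"] <= 1)).all()

    single = StagedExpression(
        pd.DataFrame(arr[:, :5], index=genes, columns=cols[:5]),
        StageDesign(stages=["t0"], assignment={f"s{i}": "t0" for i in range(5)}),
    )
    with pytest.raises(ValidationError):
        anova_table(single)


def test_duplicated_stage_produces_zero_degs():
    rng = np.random.default_rng(10)
    block = rng.standard_normal((100, 5))
    arr = np.hstack([block, block, rng.standard_normal((100, 5)) + 2.0])
    genes = [f"g{i}" for i in range(100)]
    cols = [f"s{i}" for i in range(15)]
    design = StageDesign(stages=["a", "b", "c"],
                         assignment={f"s{i}": "abc"[i // 5] for i in range(15)})
    expr = StagedExpression(pd.DataFrame(arr, index=genes, columns=cols), design)
    counts = pairwise_deg_counts(expr, alpha=0.05)
    assert counts.loc["a", "b"] == 0
    assert (counts.to_numpy() == counts.to_numpy().T).all()
    assert np.diag(counts).sum() == 0


def test_sample_clustering_separates_groups_and_merges_duplicates():
    rng = np.random.default_rng(11)
    profile1 = rng.standard_normal(30)
    profile2 = rng.standard_normal(30)
    cols = {}
    for i in range(3):
        cols[f"x{i}"] = profile1 + 0.05 * rng.standard_normal(30)
        cols[f"y{i}"] = profile2 + 0.05 * rng.standard_normal(30)
    values = pd.DataFrame(cols)
    clustering = cluster_samples(values)
    labels = clustering.cut(2)
    assert len(set(labels[[f"x{i}" for i in range(3)]])) == 1
    assert len(set(labels[[f"y{i}" for i in range(3)]])) == 1
    assert labels["x0"] != labels["y0"]

    dup = values.copy()
    dup["x_copy"] = dup["x0"]
    Z = cluster_samples(dup).linkage_matrix
    assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)  # first merge at height 0


def test_post_tipping_samples_cluster_apart_on_planted_degs():
    """A 2-cut of the sample tree on the planted differential genes splits
    pre- from post-tipping samples in nearly all runs."""
    agree = []
    for seed in range(20):
        expr, truth = generate_staged_expression(
            SyntheticSpec(n_genes=200, seed=40000 + seed)
        )
        sub = expr.values.loc[list(truth.deg_genes)]
        labels = cluster_samples(sub).cut(2)
        post_stages = {"stage4", "stage5"}
        truth_labels = np.array([
            1 if expr.design.assignment[s] in post_stages else 0
            for s in labels.index
        ])
        got = labels.to_numpy() - 1
        match = max((got == truth_labels).mean(), (got != truth_labels).mean())
        agree.append(match)
    assert np.mean(agree) >= 0.9
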