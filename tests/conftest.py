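import numpy as np
import pandas as pd
import pytest

from dnbkit import StageDesign, StagedExpression, StageStats


@pytest.fixture
def small_staged():
    """Deterministic 12-gene, 2-stage matrix for plumbing tests."""
    rng = np.random.default_rng(42)
    genes = [f"g{i:02d}" for i in range(12)]
    samples = [f"s{i:02d}" for i in range(12)]
    values = pd.DataFrame(rng.standard_normal((12, 12)) + 5.0,
                          index=genes, columns=samples)
    design = StageDesign(
        stages=["early", "late"],
        assignment={s: ("early" if i < 6 else "late") for i, s in enumerate(samples)},
    )
    return StagedExpression(values, design)


def make_stage_stats(sd, abs_pcc, threshold=0.5, stage="t", genes=None):
    """Assemble a StageStats by hand for unit tests."""
    n = len(sd)
    genes = genes if genes is not None else [f"g{i}" for i in range(n)]
    return StageStats(
        stage=stage,
        sd=pd.Series(np.asarray(sd, float), index=genes),
        sd_cutoff=float(np.median(sd)),
        genes=list(genes),
        abs_pcc=np.asarray(abs_pcc, float),
        pcc_threshold=float(threshold),
        constant_genes=[],
        n_samples=8,
    )
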