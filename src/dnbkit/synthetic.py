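"""Synthetic staged-expression and survival-cohort generators.

Every downstream step of the pipeline is testable without external data
because the generator plants a ground-truth DNB: a module whose members
become strongly mutually correlated and highly fluctuating at exactly one
stage while decoupling from the rest of the transcriptome, plus a block of
background genes whose means shift after the tipping stage (the analogue of
the large post-tipping differential-expression burst).

Generative model (per stage, independent draws across stages)
-------------------------------------------------------------
A shared latent factor per stage induces exchangeable correlation:

* background gene g, sample s:  x = mu_g + sd * (sqrt(rho_base) * z_s
  + sqrt(1 - rho_base) * eps_gs), with z_s a stage-wide standard-normal
  factor -- all background pairs correlate at rho_base.
* module genes at the tipping stage:  x = mu_g + sigma * (sqrt(rho_in) * w_s
  + sqrt(1 - rho_in) * eps_gs), sigma = sd_scale * baseline_sd, with the
  module factor w correlated with the background factor z at
  c = rho_out / sqrt(rho_in * rho_base), so module-background pairs
  correlate at rho_out.  At every other stage module genes behave exactly
  like background genes.
* ``n_deg_post`` background genes gain ``deg_effect * baseline_sd`` on their
  means at every stage after the tipping stage; no other gene's mean moves,
  so the differential-expression ground truth is exactly that set.

Gene means are drawn once and are stage-independent apart from the planted
shifts.  The within-block correlation structure is exchangeable, which keeps
each of the three DNB conditions independently controllable and easy to
verify against closed-form moments.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    ExpressionMatrix,
    StageDesign,
    StagedExpression,
    write_expression_table,
    write_stage_design,
)
from .survival import SurvivalRecord

#: study-scale default stage sizes (five ordered disease stages)
DEFAULT_SAMPLES_PER_STAGE = (10, 13, 10, 7, 8)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-DNB generator.

    Defaults mirror the study scale: T = 5 ordered stages with small,
    unequal sample counts, a 20-gene module spiking at stage 3, and 500
    genes total (reduced from genome scale so that a full detection run
    stays interactive).
    """

    n_genes: int = 500
    n_stages: int = 5
    samples_per_stage: tuple[int, ...] = DEFAULT_SAMPLES_PER_STAGE
    module_size: int = 20
    tipping_stage: int = 3          # 1-based stage index
    rho_in: float = 0.8             # within-module correlation at tipping
    rho_base: float = 0.1           # baseline pairwise correlation
    rho_out: float = 0.05           # module-background correlation at tipping
    sd_scale: float = 3.0           # fold-increase of module SD at tipping
    n_deg_post: int = 50            # background genes mean-shifted post-tipping
    deg_effect: float = 2.5         # shift magnitude in baseline-SD units
    baseline_sd: float = 1.0        # expression-unit SD
    mean_center: float = 8.0        # location of the drawn gene means
    mean_spread: float = 1.0        # SD of the drawn gene means
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_stage) != self.n_stages:
            raise ValidationError("samples_per_stage length must equal n_stages")
        if not 1 <= self.tipping_stage <= self.n_stages:
            raise ValidationError("tipping_stage must be in 1..n_stages")
        if not 3 <= self.module_size < self.n_genes:
            raise ValidationError("module_size must satisfy 3 <= m < n_genes")
        if not 0 <= self.rho_base <= self.rho_in <= 1:
            raise ValidationError("require 0 <= rho_base <= rho_in <= 1")
        if not 0 <= self.rho_out <= self.rho_base or (
            self.rho_base > 0 and self.rho_out > math.sqrt(self.rho_in * self.rho_base)
        ):
            raise ValidationError("require 0 <= rho_out <= rho_base (and attainable)")
        if any(n < 4 for n in self.samples_per_stage):
            raise ValidationError("every samples_per_stage entry must be >= 4")
        if self.sd_scale < 1:
            raise ValidationError("sd_scale must be >= 1")
        if self.n_deg_post < 0 or self.n_deg_post > self.n_genes - self.module_size:
            raise ValidationError("n_deg_post must fit among background genes")
        if self.baseline_sd <= 0:
            raise ValidationError("baseline_sd must be > 0")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return SyntheticSpec(**{**asdict(self), **kwargs})


def null_spec(seed: int = 0, **kwargs) -> SyntheticSpec:
    """A no-signal variant: no correlation spike, no SD spike, no planted
    differential genes -- every stage is statistically exchangeable."""
    fields = {f.name: f.default for f in dataclasses.fields(SyntheticSpec)}
    fields.update(kwargs, seed=seed)
    rho = fields["rho_base"]
    fields.update(rho_in=rho, rho_out=rho, sd_scale=1.0, n_deg_post=0)
    return SyntheticSpec(**fields)


@dataclass
class GroundTruth:
    """What was planted: the module, the tipping stage, the shifted genes."""

    planted_module: tuple[str, ...]
    tipping_stage: str
    deg_genes: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _stage_labels(n_stages: int) -> list[str]:
    return [f"stage{t}" for t in range(1, n_stages + 1)]


def generate_staged_expression(spec: SyntheticSpec) -> tuple[StagedExpression, GroundTruth]:
    """Draw a staged matrix with the planted DNB; bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    labels = _stage_labels(spec.n_stages)
    gene_ids = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]

    perm = rng.permutation(spec.n_genes)
    module_idx = np.sort(perm[: spec.module_size])
    deg_idx = np.sort(perm[spec.module_size: spec.module_size + spec.n_deg_post])
    module_mask = np.zeros(spec.n_genes, dtype=bool)
    module_mask[module_idx] = True

    mu = rng.normal(spec.mean_center, spec.mean_spread, size=spec.n_genes)
    # post-tipping shifts go both ways, as real cross-transition DEGs do
    deg_sign = rng.choice([-1.0, 1.0], size=spec.n_deg_post)

    # module factor w = c * z + sqrt(1 - c^2) * u gives corr(module, background)
    # = sqrt(rho_in * rho_base) * c = rho_out at the tipping stage
    if spec.rho_in > 0 and spec.rho_base > 0:
        c = spec.rho_out / math.sqrt(spec.rho_in * spec.rho_base)
    else:
        c = 0.0

    blocks, columns, assignment = [], [], {}
    for t, (label, n_t) in enumerate(zip(labels, spec.samples_per_stage), start=1):
        z = rng.standard_normal(n_t)
        eps = rng.standard_normal((spec.n_genes, n_t))
        u = rng.standard_normal(n_t)
        sd = spec.baseline_sd
        noise = sd * (math.sqrt(spec.rho_base) * z[None, :]
                      + math.sqrt(1.0 - spec.rho_base) * eps)
        if t == spec.tipping_stage:
            w = c * z + math.sqrt(max(0.0, 1.0 - c * c)) * u
            sigma = spec.sd_scale * sd
            noise[module_mask] = sigma * (
                math.sqrt(spec.rho_in) * w[None, :]
                + math.sqrt(1.0 - spec.rho_in) * eps[module_mask]
            )
        block = mu[:, None] + noise
        if t > spec.tipping_stage and spec.n_deg_post:
            block[deg_idx] += deg_sign[:, None] * spec.deg_effect * sd
        blocks.append(block)
        for j in range(n_t):
            sid = f"{label}_s{j + 1:02d}"
            columns.append(sid)
            assignment[sid] = label

    values = pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=columns)
    design = StageDesign(stages=labels, assignment=assignment)
    truth = GroundTruth(
        planted_module=tuple(gene_ids[i] for i in module_idx),
        tipping_stage=labels[spec.tipping_stage - 1],
        deg_genes=tuple(gene_ids[i] for i in deg_idx),
    )
    meta = {"generator": "dnbkit.synthetic", "seed": spec.seed}
    return StagedExpression(values, design, meta), truth


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

@dataclass
class SurvivalTruth:
    """Latent two-group labels of a simulated cohort."""

    groups: dict[str, int] = field(default_factory=dict)
    signature_genes: tuple[str, ...] = ()


def generate_survival_cohort(
    n_patients: int,
    signature_genes: int = 10,
    effect: float = 1.0,
    seed: int = 0,
    n_background_genes: int = 40,
    expression_separation: float = 2.0,
    baseline_hazard: float = 1.0 / 500.0,
    censor_horizon: float = 2000.0,
) -> tuple[ExpressionMatrix, list[SurvivalRecord], SurvivalTruth]:
    """Two latent patient groups with exponential survival, hazard ratio
    ``effect`` for group 2, independent uniform censoring on
    [0, censor_horizon], and signature genes mean-shifted between groups by
    ``expression_separation`` SD units.  Times are in days."""
    if n_patients < 20:
        raise ValidationError("n_patients must be >= 20")
    if effect <= 0:
        raise ValidationError("effect (hazard ratio) must be > 0")
    rng = np.random.default_rng(seed)
    patients = [f"P{i:03d}" for i in range(1, n_patients + 1)]
    group = np.zeros(n_patients, dtype=int)
    group[n_patients // 2:] = 1
    rng.shuffle(group)

    rates = baseline_hazard * np.where(group == 1, effect, 1.0)
    event_time = rng.exponential(1.0 / rates)
    censor_time = rng.uniform(0.0, censor_horizon, size=n_patients)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-9)  # time > 0 even for instantaneous events

    sig_ids = [f"SIG{i:03d}" for i in range(1, signature_genes + 1)]
    bg_ids = [f"BG{i:03d}" for i in range(1, n_background_genes + 1)]
    sig = rng.standard_normal((signature_genes, n_patients))
    sig += expression_separation * group[None, :]
    bg = rng.standard_normal((n_background_genes, n_patients))
    values = pd.DataFrame(
        np.vstack([sig, bg]), index=sig_ids + bg_ids, columns=patients
    )
    records = [
        SurvivalRecord(patient_id=p, time=float(t), event=int(e),
                       group=f"group{g + 1}")
        for p, t, e, g in zip(patients, time, event, group)
    ]
    truth = SurvivalTruth(
        groups={p: int(g) + 1 for p, g in zip(patients, group)},
        signature_genes=tuple(sig_ids),
    )
    return ExpressionMatrix(values, {"generator": "dnbkit.synthetic"}), records, truth


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def write_dataset(
    expr: StagedExpression, truth: GroundTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write the expression TSV, stage-design TSV and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "design": out / "stage_design.tsv",
        "truth": out / "ground_truth.json",
    }
    write_expression_table(expr, paths["expression"])
    write_stage_design(expr.design, paths["design"])
    paths["truth"].write_text(truth.to_json())
    return paths
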