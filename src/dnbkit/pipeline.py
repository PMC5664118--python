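"""End-to-end orchestration: simulate/load -> detect -> DEG -> enrich -> survival.

A run is described by a :class:`RunConfig` (every threshold the analysis
uses, with the documented defaults), executes each stage in order, writes
all tabular outputs plus a JSON run manifest, and is reproducible: the
manifest records the resolved configuration, input checksums and package
version, and re-running with the same config and inputs regenerates
identical deterministic outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .core import DNBConfig, detect_tipping_point, stage_scores_table
from .differential import pairwise_deg_counts, ttest_deg
from .errors import DNBError, ValidationError
from .io import (
    attach_stage_design,
    read_expression_table,
    read_stage_design,
    write_gene_set,
)
from .network import DEFAULT_MIN_SCORE, load_edge_list, neighborhood_enrichment, node_degrees
from .survival import (
    logrank_test,
    per_gene_survival_screen,
    read_clinical_table,
    stratify_by_signature,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters.

    The defaults carry the analysis' canonical thresholds: the top-0.05
    quantile of pairwise |PCC| defines "high correlation", the SD filter
    keeps genes above the 50th percentile, pairwise DEGs use FDR q < 0.05,
    the omnibus ANOVA screen uses unadjusted p < 0.01, and survival
    contrasts are called at log-rank p < 0.05.
    """

    expression: str | None = None
    design: str | None = None
    out_dir: str = "dnb_run"
    log2: bool = False
    # detection (DNBConfig)
    sd_percentile: float = 50.0     # SD filter: keep genes above the median
    pcc_quantile: float = 0.05      # top 5% of |PCC| pairs are "high"
    linkage: str = "average"
    min_module_size: int = 3
    pcc_scope: str = "filtered"
    # differential expression
    deg_alpha: float = 0.05         # FDR-adjusted q < 0.05
    anova_alpha: float = 0.01       # unadjusted omnibus p < 0.01
    # network enrichment
    network: str | None = None
    min_score: float = DEFAULT_MIN_SCORE
    # survival
    clinical: str | None = None
    survival_expression: str | None = None
    survival_alpha: float = 0.05    # log-rank p < 0.05
    seed: int = 0

    def dnb_config(self) -> DNBConfig:
        return DNBConfig(
            sd_percentile=self.sd_percentile,
            pcc_quantile=self.pcc_quantile,
            linkage=self.linkage,
            min_module_size=self.min_module_size,
            pcc_scope=self.pcc_scope,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunManifest:
    """Reproducibility record written alongside the outputs."""

    config: dict
    input_checksums: dict[str, str]
    version: str
    summary: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_full_pipeline(config: RunConfig) -> RunManifest:
    """Execute detection, flanking DEG analysis, optional enrichment and
    optional survival analysis; write outputs and the run manifest.

    On a stage failure the partial outputs are moved under ``failed/`` and
    the error is re-raised naming the stage.
    """
    if config.expression is None or config.design is None:
        raise ValidationError("config must set 'expression' and 'design' paths")
    for name in ("expression", "design", "network", "clinical", "survival_expression"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise ValidationError(f"{name} path does not exist: {p}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        input_checksums={
            name: _sha256(p)
            for name in ("expression", "design", "network", "clinical", "survival_expression")
            if (p := getattr(config, name)) is not None
        },
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )
    stage_name = "load"
    try:
        matrix = read_expression_table(config.expression)
        if config.log2:
            matrix = matrix.log2()
        design = read_stage_design(config.design)
        expr = attach_stage_design(matrix, design)

        stage_name = "detect"
        result = detect_tipping_point(expr, config.dnb_config())
        write_gene_set(result.dnb_genes, out / "dnb_genes.txt")
        stage_scores_table(result).to_csv(out / "stage_scores.tsv", sep="\t", index=False)
        (out / "modules.json").write_text(json.dumps(
            {s: [list(m) for m in mods] for s, mods in result.module_lists.items()},
            indent=2,
        ))
        manifest.summary["tipping_stage"] = result.tipping_stage
        manifest.summary["dnb_size"] = len(result.dnb_genes)
        manifest.summary["signal_contrast"] = result.signal_contrast
        manifest.summary["ci_scores"] = result.scores

        stage_name = "deg"
        counts = pairwise_deg_counts(expr, alpha=config.deg_alpha)
        counts.to_csv(out / "pairwise_deg_counts.tsv", sep="\t")
        stages = expr.stages
        t_idx = stages.index(result.tipping_stage)
        pre = stages[max(t_idx - 1, 0)]
        post = stages[min(t_idx + 1, len(stages) - 1)]
        deg_genes: list[str] = []
        if pre != post:
            deg_table = ttest_deg(expr, pre, post, alpha=config.deg_alpha)
            deg_table.to_csv(out / f"deg_{pre}_vs_{post}.tsv", sep="\t", index=False)
            deg_genes = deg_table.loc[deg_table["significant"], "gene"].tolist()
            manifest.summary["flanking_contrast"] = f"{pre}:{post}"
            manifest.summary["flanking_deg_count"] = len(deg_genes)
        manifest.summary["pairwise_deg_counts"] = {
            f"{a}:{b}": int(counts.loc[a, b])
            for i, a in enumerate(stages) for b in stages[i + 1:]
        }

        if config.network is not None:
            stage_name = "enrich"
            net = load_edge_list(config.network, min_score=config.min_score)
            universe = {g.upper() for g in expr.gene_ids} & set(net.graph.nodes)
            if deg_genes and universe:
                enr = neighborhood_enrichment(net, result.dnb_genes, deg_genes, universe)
                manifest.summary["enrichment"] = {
                    "N": enr.universe_size, "K": enr.success_size,
                    "n": enr.draw_size, "k": enr.overlap, "p": enr.p,
                }
            degrees = node_degrees(net, focus=result.dnb_genes)
            degrees.to_csv(out / "dnb_degrees.tsv", sep="\t", header=True)

        if config.clinical is not None:
            stage_name = "survival"
            records = read_clinical_table(config.clinical)
            surv_path = config.survival_expression or config.expression
            surv_matrix = read_expression_table(surv_path)
            sig = [g for g in result.dnb_genes if g in surv_matrix.values.index]
            if sig:
                labels = stratify_by_signature(surv_matrix.values.loc[sig], seed=config.seed)
                lab = {p: f"group{v}" for p, v in labels.items()}
                grouped = [dataclasses.replace(r, group=lab[r.patient_id])
                           for r in records if r.patient_id in lab]
                stat, p = logrank_test(grouped)
                manifest.summary["signature_logrank"] = {"statistic": stat, "p": p}
                screen = per_gene_survival_screen(
                    surv_matrix, records, genes=sig, alpha=config.survival_alpha
                )
                screen.to_csv(out / "per_gene_survival.tsv", sep="\t", index=False)
                manifest.summary["prognostic_genes"] = int(screen["significant"].sum())

        manifest.finished = datetime.now(timezone.utc).isoformat()
        manifest.write(out / "manifest.json")
        return manifest
    except DNBError:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        manifest.summary["failed_stage"] = stage_name
        manifest.write(failed / "manifest.json")
        logger.error("pipeline failed at stage %r", stage_name)
        raise


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    cfg = RunConfig.from_yaml(path) if path else RunConfig()
    for key, value in overrides.items():
        if value is not None:
            setattr(cfg, key, value)
    return cfg
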