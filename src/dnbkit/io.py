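"""Expression-matrix I/O, probe collapsing, and the staged data model.

The pipeline works on gene-by-sample matrices bound to an ordered stage
design (disease stages t = 1..T, a handful of samples per stage).  This
module reads and validates the standard tab/comma-separated tables, collapses
probe-level matrices to gene symbols, and attaches stage designs.

Conventions
-----------
* Expression tables: genes as rows, samples as columns, header row of sample
  ids, first column gene (or probe) ids.  ``.csv`` is comma-separated,
  anything else tab-separated.
* Stage designs: two columns, ``sample_id<TAB>stage``; stage order of first
  appearance defines the progression order unless an explicit order is given.
* Probe annotations: two columns, ``probe_id<TAB>symbol``; multi-symbol
  annotations use the Affymetrix ``" /// "`` convention or ``";"`` and the
  first listed symbol wins.  Empty or ``---`` symbols mean "unannotated".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: hard floor on samples per stage for correlation estimation
MIN_STAGE_SAMPLES = 3
#: below this the stage's correlations are usable but noisy; we warn
SMALL_STAGE_SAMPLES = 5

_MULTI_SYMBOL_SEPARATORS = (" /// ", ";")
_UNANNOTATED = {"", "---", "--", "NA", "nan"}


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A validated gene-by-sample matrix of finite expression values.

    ``values`` is a DataFrame with unique gene (row) and sample (column)
    identifiers.  ``metadata`` records provenance (file of origin, scale,
    whether values were log-transformed, ...) and is purely informational.
    """

    values: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Return a log2(x + pseudocount)-transformed copy."""
        if (self.values.to_numpy() + pseudocount <= 0).any():
            raise ValidationError("log2 transform requires values > -pseudocount")
        meta = dict(self.metadata, log2=True, pseudocount=pseudocount)
        return ExpressionMatrix(np.log2(self.values + pseudocount), meta)


@dataclass
class StageDesign:
    """An ordered list of stage labels and a sample -> stage assignment."""

    stages: list[str]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValidationError("duplicate stage labels in design")
        unknown = {s for s in self.assignment.values() if s not in self.stages}
        if unknown:
            raise ValidationError(f"assignment uses stages not in order: {sorted(unknown)}")
        for stage in self.stages:
            n = self.n_samples(stage)
            if n < MIN_STAGE_SAMPLES:
                raise ValidationError(
                    f"stage {stage!r} has {n} samples; minimum is {MIN_STAGE_SAMPLES}"
                )
            if n < SMALL_STAGE_SAMPLES:
                logger.warning(
                    "stage %r has only %d samples; correlation estimates will be noisy",
                    stage, n,
                )

    def samples_for(self, stage: str) -> list[str]:
        return [s for s, t in self.assignment.items() if t == stage]

    def n_samples(self, stage: str) -> int:
        return len(self.samples_for(stage))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment)


@dataclass
class StagedExpression:
    """An ExpressionMatrix whose samples are bound to an ordered stage design."""

    values: pd.DataFrame
    design: StageDesign
    metadata: dict = field(default_factory=dict)

    @property
    def stages(self) -> list[str]:
        return list(self.design.stages)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def stage_values(self, stage: str) -> pd.DataFrame:
        """Genes-by-samples sub-matrix for one stage."""
        if stage not in self.design.stages:
            raise ValidationError(f"unknown stage {stage!r}")
        return self.values[self.design.samples_for(stage)]


# ---------------------------------------------------------------------------
# table readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(path: str | Path, rows_are_genes: bool = True) -> ExpressionMatrix:
    """Read a rectangular expression table into an ExpressionMatrix.

    Duplicated identifiers, ragged rows and non-numeric cells are rejected
    with the offending row/column named.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    dup = [name for name in header if name in seen or seen.add(name)]
    if dup:
        raise ParseError(f"{path}: duplicated sample column(s) {sorted(set(dup))}")
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at row {raw.index[r]!r},"
            f" column {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at row {raw.index[r]!r}, column {raw.columns[c]!r}"
        )
    values = raw.astype(float)  # numpy's parser is correctly rounded
    if not rows_are_genes:
        values = values.T
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, metadata={"source": str(path)})


def write_expression_table(matrix: ExpressionMatrix | StagedExpression, path: str | Path) -> None:
    """Write genes-by-samples TSV/CSV (full float precision round-trips)."""
    path = Path(path)
    matrix.values.to_csv(path, sep=_sep_for(path), index_label="gene_id", float_format="%.17g")


def read_stage_design(path: str | Path, stage_order: Sequence[str] | None = None) -> StageDesign:
    """Read a two-column sample/stage table.

    Stage order defaults to order of first appearance in the file.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: expected columns sample_id, stage")
    samples = table.iloc[:, 0].astype(str)
    stages = table.iloc[:, 1].astype(str)
    if samples.duplicated().any():
        raise ParseError(f"{path}: duplicated sample id {samples[samples.duplicated()].iloc[0]!r}")
    order = list(stage_order) if stage_order is not None else list(dict.fromkeys(stages))
    return StageDesign(stages=order, assignment=dict(zip(samples, stages)))


def write_stage_design(design: StageDesign, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"sample_id": list(design.assignment), "stage": list(design.assignment.values())}
    ).to_csv(path, sep=_sep_for(path), index=False)


def read_gene_set(path: str | Path) -> list[str]:
    """One symbol per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_set(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


# ---------------------------------------------------------------------------
# probe annotation and collapsing
# ---------------------------------------------------------------------------

def read_probe_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column probe_id -> symbol table (probe ids unique)."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: expected columns probe_id, symbol")
    probes = table.iloc[:, 0].astype(str)
    if probes.duplicated().any():
        raise ParseError(f"{path}: duplicated probe id {probes[probes.duplicated()].iloc[0]!r}")
    return dict(zip(probes, table.iloc[:, 1].astype(str)))


def first_symbol(annotation: str) -> str | None:
    """Resolve a (possibly multi-symbol) annotation to its first symbol.

    Returns None for unannotated probes (empty / ``---`` placeholders).
    """
    text = annotation.strip()
    for sep in _MULTI_SYMBOL_SEPARATORS:
        if sep in text:
            text = text.split(sep)[0].strip()
            break
    return None if text in _UNANNOTATED else text


def collapse_probes(probe_matrix: ExpressionMatrix, annotation: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene symbol.

    Probes without a symbol are dropped; probes annotated to multiple symbols
    count only toward the first listed symbol; multiple probes for one gene
    are averaged (arithmetic mean per sample).  Idempotent when gene symbols
    are already the row ids and map to themselves.
    """
    symbols = {}
    for probe in probe_matrix.gene_ids:
        sym = first_symbol(str(annotation.get(probe, "")))
        if sym is not None:
            symbols[probe] = sym
    if not symbols:
        raise ValidationError("no probe maps to a gene symbol; nothing to collapse")
    dropped = probe_matrix.shape[0] - len(symbols)
    if dropped:
        logger.info("collapse_probes: dropped %d unannotated probe(s)", dropped)
    sub = probe_matrix.values.loc[list(symbols)]
    collapsed = sub.groupby(pd.Series(symbols), sort=True).mean()
    collapsed.index.name = probe_matrix.values.index.name
    meta = dict(probe_matrix.metadata, collapsed=True)
    return ExpressionMatrix(collapsed, meta)


# ---------------------------------------------------------------------------
# stage attachment
# ---------------------------------------------------------------------------

def attach_stage_design(matrix: ExpressionMatrix, design: StageDesign) -> StagedExpression:
    """Bind a matrix to a stage design, dropping samples outside the design."""
    missing = [s for s in design.assignment if s not in matrix.values.columns]
    if missing:
        raise ValidationError(f"design references unknown sample(s): {missing[:5]}")
    extra = [s for s in matrix.sample_ids if s not in design.assignment]
    if extra:
        logger.info("attach_stage_design: dropping %d sample(s) not in design", len(extra))
    ordered = [s for t in design.stages for s in design.samples_for(t)]
    return StagedExpression(matrix.values[ordered], design, dict(matrix.metadata))


# ---------------------------------------------------------------------------
# GEO series-matrix reader (for the optional microarray reproduction)
# ---------------------------------------------------------------------------

def read_series_matrix(path: str | Path) -> ExpressionMatrix:
    """Read the data block of a GEO series-matrix file (probe-level rows).

    Header lines are prefixed ``!``; the expression block sits between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines)
                     if ln.lower().startswith("!series_matrix_table_begin"))
        end = next(i for i, ln in enumerate(lines)
                   if ln.lower().startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ParseError(f"{path}: series-matrix table markers not found") from None
    block = lines[start + 1:end]
    if len(block) < 2:
        raise ParseError(f"{path}: empty series-matrix table")

    def split(line: str) -> list[str]:
        return [f.strip().strip('"') for f in line.split("\t")]

    header = split(block[0])
    sample_ids = header[1:]
    rows, probe_ids = [], []
    for i, line in enumerate(block[1:], start + 2):
        fields = split(line)
        if len(fields) != len(header):
            raise ParseError(f"{path}: line {i + 1}: expected {len(header)} fields, got {len(fields)}")
        probe_ids.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i + 1}: {exc}") from exc
    values = pd.DataFrame(rows, index=probe_ids, columns=sample_ids)
    return ExpressionMatrix(values, metadata={"source": str(path), "format": "series_matrix"})
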