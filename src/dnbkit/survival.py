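"""Kaplan-Meier estimation, log-rank testing, and patient stratification.

Two stratification schemes are supported: a two-group k-means clustering of
patients on a gene signature (the DNB gene set), and per-gene median splits
into low/high expression followed by a log-rank screen.  Estimation and
testing go through lifelines; this module adds the data model, degenerate-
case policies and the stratification logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.cluster import KMeans

from .errors import ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SurvivalRecord:
    """One patient's right-censored follow-up: time in days, event 1 = death
    observed, 0 = censored; optional group label."""

    patient_id: str
    time: float
    event: int
    group: str | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"patient {self.patient_id!r}: time must be >= 0")
        if self.event not in (0, 1):
            raise ValidationError(f"patient {self.patient_id!r}: event must be 0 or 1")


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    rows = [(r.patient_id, r.time, r.event, r.group) for r in records]
    return pd.DataFrame(rows, columns=["patient_id", "time", "event", "group"])


def read_clinical_table(path) -> list[SurvivalRecord]:
    """Read patient_id/time/event (+ optional group) TSV or CSV."""
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep)
    needed = {"patient_id", "time", "event"}
    if not needed.issubset(table.columns):
        raise ValidationError(f"clinical table must have columns {sorted(needed)}")
    has_group = "group" in table.columns
    return [
        SurvivalRecord(
            patient_id=str(row.patient_id), time=float(row.time),
            event=int(row.event),
            group=str(row.group) if has_group else None,
        )
        for row in table.itertuples()
    ]


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) after each distinct event time."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def probability_at(self, t: float) -> float:
        """S(t): survival just after time t."""
        past = self.event_times <= t
        return float(self.survival[past][-1]) if past.any() else 1.0


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit curve, events-before-censoring at ties."""
    if not records:
        raise ValidationError("km_estimate needs at least one record")
    frame = records_to_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(frame["time"], event_observed=frame["event"])
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(ev.index).to_numpy(dtype=float)
    return KMCurve(
        event_times=times,
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        n_events=ev["observed"].to_numpy(dtype=float),
        survival=surv,
    )


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic on 1 df, p-value).

    Records must carry exactly two distinct group labels.  With no events at
    all the test is undefined; returns (0.0, 1.0) with a warning.
    """
    frame = records_to_frame(records)
    groups = sorted(frame["group"].dropna().unique())
    if len(groups) != 2:
        raise ValidationError(f"logrank_test needs exactly 2 groups, got {groups}")
    a = frame[frame["group"] == groups[0]]
    b = frame[frame["group"] == groups[1]]
    if a.empty or b.empty:
        raise ValidationError("both groups must be non-empty")
    if frame["event"].sum() == 0:
        logger.warning("logrank_test: no events observed; returning p = 1")
        return 0.0, 1.0
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def stratify_by_signature(
    matrix: ExpressionMatrix | pd.DataFrame, seed: int = 0, n_init: int = 20
) -> pd.Series:
    """Two-group k-means over patients on per-gene standardized expression.

    Rows are signature genes, columns patients.  Returns a Series of labels
    in {1, 2}; group 1 is the cluster with the higher mean standardized
    signature level, so labels are stable across seeds up to clustering.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 2:
        raise ValidationError("need >= 2 patients to stratify")
    if values.shape[0] < 1:
        raise ValidationError("need >= 1 signature gene")
    arr = values.to_numpy(dtype=float)
    sds = arr.std(axis=1, ddof=0)
    keep = sds > 0
    if not keep.any():
        raise ValidationError("all patients identical on the signature")
    z = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sds[keep][:, None]
    X = z.T  # patients as observations
    if np.allclose(X, X[0]):
        raise ValidationError("all patients identical on the signature")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    mean_level = [X[raw == k].mean() for k in (0, 1)]
    high = int(np.argmax(mean_level))
    labels = np.where(raw == high, 1, 2)
    return pd.Series(labels, index=values.columns, name="group")


def per_gene_survival_screen(
    matrix: ExpressionMatrix | pd.DataFrame,
    records: Sequence[SurvivalRecord],
    genes: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Median-split each gene into low/high expression and log-rank the
    groups.  Values strictly above the median are "high", the rest "low".
    Genes whose median ties exceed half the cohort (split undefined) are
    skipped with a warning.  No multiplicity correction is applied; the
    ``significant`` flag is simply p < alpha."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    frame = records_to_frame(records).set_index("patient_id")
    patients = [p for p in values.columns if p in frame.index]
    if len(patients) < 4:
        raise ValidationError("need >= 4 patients with both expression and follow-up")
    frame = frame.loc[patients]
    gene_list = list(genes) if genes is not None else list(values.index)
    rows = []
    for gene in gene_list:
        if gene not in values.index:
            logger.warning("screen: gene %r absent from matrix; skipped", gene)
            continue
        x = values.loc[gene, patients].to_numpy(dtype=float)
        med = float(np.median(x))
        ties = (x == med).sum()
        high = x > med
        if ties > 0.5 * len(x) or high.all() or (~high).all():
            logger.warning("screen: gene %r median split undefined; skipped", gene)
            rows.append({"gene": gene, "statistic": np.nan, "p": np.nan,
                         "significant": False, "skipped": True})
            continue
        recs = [
            SurvivalRecord(p, float(frame.at[p, "time"]), int(frame.at[p, "event"]),
                           group="high" if h else "low")
            for p, h in zip(patients, high)
        ]
        stat, p = logrank_test(recs)
        rows.append({"gene": gene, "statistic": stat, "p": p,
                     "significant": bool(p < alpha), "skipped": False})
    return pd.DataFrame(rows)
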