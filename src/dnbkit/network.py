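"""Interaction-network context for a DNB gene set.

Loads a STRING-style weighted edge list into an undirected graph, reports
first-neighbor degrees, and tests whether a set of differentially expressed
genes is enriched in the DNB-associated subnetwork (the DNB members plus
their first neighbors) with an upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: STRING's conventional "high confidence" score cutoff
DEFAULT_MIN_SCORE = 0.7


@dataclass
class InteractionNetwork:
    """Undirected PPI graph; node names upper-cased, edges score-filtered."""

    graph: nx.Graph
    min_score: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors_of(self, genes: Iterable[str]) -> set[str]:
        """Union of first neighbors of ``genes`` (genes themselves excluded
        unless they neighbor each other)."""
        out: set[str] = set()
        for g in genes:
            g = g.upper()
            if g in self.graph:
                out.update(self.graph.neighbors(g))
        return out


def load_edge_list(path: str | Path, min_score: float = DEFAULT_MIN_SCORE) -> InteractionNetwork:
    """Read a (geneA, geneB[, score]) TSV into a deduplicated network.

    Self-loops are dropped; duplicate edges keep the maximal score; edges
    below ``min_score`` are discarded.  A missing score column means score 1.
    """
    path = Path(path)
    graph = nx.Graph()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {ln}: expected >= 2 columns")
            a, b = fields[0].strip().upper(), fields[1].strip().upper()
            if ln == 1 and len(fields) >= 3:
                try:
                    float(fields[2])
                except ValueError:
                    continue  # header row
            if len(fields) >= 3:
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {ln}: bad score {fields[2]!r}") from exc
            else:
                score = 1.0
            if a == b:
                continue
            if score < min_score:
                continue
            if graph.has_edge(a, b):
                graph[a][b]["score"] = max(graph[a][b]["score"], score)
            else:
                graph.add_edge(a, b, score=score)
    logger.info("loaded %d nodes / %d edges (min score %.2f) from %s",
                graph.number_of_nodes(), graph.number_of_edges(), min_score, path)
    return InteractionNetwork(graph=graph, min_score=min_score)


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    rows = [(a, b, d["score"]) for a, b, d in network.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["geneA", "geneB", "score"]).to_csv(
        path, sep="\t", index=False
    )


def node_degrees(network: InteractionNetwork, focus: Iterable[str] | None = None) -> pd.Series:
    """First-neighbor counts, sorted descending.

    ``focus`` restricts the report to those genes; genes absent from the
    network get degree 0.
    """
    if focus is None:
        deg = {g: d for g, d in network.graph.degree()}
    else:
        deg = {g: (network.graph.degree(g.upper()) if g.upper() in network.graph else 0)
               for g in focus}
    series = pd.Series(deg, dtype=int, name="degree")
    return series.sort_values(ascending=False, kind="stable")


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric test of DEG overlap with a gene set.

    Drawing ``n`` DEGs from a universe of ``N`` genes of which ``K`` lie in
    the DNB-associated set, ``p`` = P(X >= k) for the observed overlap k.
    """

    universe_size: int
    success_size: int
    draw_size: int
    overlap: int
    p: float
    success_set: tuple[str, ...] = ()


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); k = 0 gives 1 exactly."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError("need 0 <= K <= N and 0 <= n <= N")
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def neighborhood_enrichment(
    network: InteractionNetwork,
    dnb: Iterable[str],
    degs: Iterable[str],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Are the DEGs over-represented in the DNB-associated network?

    The success set is the DNB plus its first neighbors, intersected with
    the universe; genes outside the universe are dropped with a warning.
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValidationError("empty universe")
    dnb_set = {g.upper() for g in dnb}
    deg_set = {g.upper() for g in degs}
    if not deg_set:
        raise ValidationError("empty DEG set")
    for name, s in (("dnb", dnb_set), ("degs", deg_set)):
        outside = s - universe_set
        if outside:
            logger.warning("%d %s gene(s) outside the universe dropped", len(outside), name)
    dnb_set &= universe_set
    deg_set &= universe_set
    if not deg_set:
        raise ValidationError("no DEG remains inside the universe")
    success = (dnb_set | network.neighbors_of(dnb_set)) & universe_set
    N = len(universe_set)
    K = len(success)
    n = len(deg_set)
    k = len(deg_set & success)
    p = hypergeom_upper_tail(N, K, n, k)
    return EnrichmentResult(
        universe_size=N, success_size=K, draw_size=n, overlap=k, p=p,
        success_set=tuple(sorted(success)),
    )
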