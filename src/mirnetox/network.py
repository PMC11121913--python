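"""Anti-correlation miRNA-mRNA network inference and hub analysis.

For each candidate pair, the Pearson correlation of the two features'
expression — log2(CPM + 1) by default — is computed across the paired
samples of one treatment regimen (3 control + 3 treated replicates by
default).  BH-FDR is controlled across exactly the candidate pairs of
that regimen, and edges with r < 0 and FDR < alpha (both strict) form a
bipartite repression network.  miRNA nodes with at least ``min_degree``
retained connections are hubs.

``CorrelationNetworkModel`` is the statsmodels-style entry point:
construct from the two count matrices, the sample sheet, a regimen and
the candidate pairs; ``fit()`` returns ``CorrelationNetworkResults``
holding the edge table, the networkx graph and the hub report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust, cpm_normalize
from .io import CountMatrix, SampleSheet
from .targets import CandidateTargetPair

__all__ = [
    "pearson_r",
    "correlate_pairs",
    "filter_edges",
    "build_network",
    "find_hubs",
    "HubReport",
    "CorrelationNetworkModel",
    "CorrelationNetworkResults",
]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    dx, dy = x - x.mean(), y - y.mean()
    sx, sy = math.sqrt(float(dx @ dx)), math.sqrt(float(dy @ dy))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(dx @ dy) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_pairs(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    pairs: Sequence[CandidateTargetPair],
    samples: SampleSheet,
) -> pd.DataFrame:
    """Per-pair Pearson r/p/FDR across the sheet's paired samples.

    ``mirna_expr`` and ``mrna_expr`` are expression frames (features x
    libraries) already on the analysis scale; pairing of columns follows
    the sample sheet, never column order.  The BH family is exactly the
    supplied pair list.
    """
    if len(samples.records) < 3:
        raise ValueError("need at least 3 paired samples for correlation")
    mi_cols = samples.mirna_libraries()
    mr_cols = samples.mrna_libraries()
    rows = []
    for pair in pairs:
        x = mirna_expr.loc[pair.mirna, mi_cols].to_numpy(dtype=float)
        y = mrna_expr.loc[pair.gene, mr_cols].to_numpy(dtype=float)
        r, p = pearson_r(x, y)
        rows.append((pair.mirna, pair.gene, r, p))
    edges = pd.DataFrame(rows, columns=["mirna", "gene", "r", "p_value"])
    edges["fdr"] = bh_adjust(edges["p_value"]) if len(edges) else []
    return edges


def filter_edges(edges: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Retain anti-correlated significant edges: r < 0 and FDR < alpha."""
    return edges[(edges["r"] < 0) & (edges["fdr"] < alpha)].reset_index(drop=True)


def build_network(
    edges: pd.DataFrame,
    mirna_log2fc: Mapping[str, float] | None = None,
    gene_log2fc: Mapping[str, float] | None = None,
) -> nx.Graph:
    """Bipartite miRNA-mRNA graph from a retained edge table.

    Node attributes: ``role`` (miRNA/mRNA), ``log2fc`` when supplied,
    ``degree``.  Edge attributes: ``r``, ``fdr``.
    """
    mirnas = set(edges["mirna"])
    genes = set(edges["gene"])
    clash = mirnas & genes
    if clash:
        raise ValueError(f"node(s) on both sides of the bipartite graph: {sorted(clash)}")
    g = nx.Graph()
    for m in sorted(mirnas):
        g.add_node(m, role="miRNA", log2fc=float((mirna_log2fc or {}).get(m, 0.0)))
    for t in sorted(genes):
        g.add_node(t, role="mRNA", log2fc=float((gene_log2fc or {}).get(t, 0.0)))
    for row in edges.itertuples():
        g.add_edge(row.mirna, row.gene, r=float(row.r), fdr=float(row.fdr))
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    return g


@dataclass
class HubReport:
    """miRNA hubs (degree >= threshold) and their share of the network."""

    hubs: list[tuple[str, int]]  # (mirna, degree), descending degree then name
    hub_edge_count: int
    total_edge_count: int
    hub_target_count: int
    min_degree: int = 10

    @property
    def hub_edge_fraction(self) -> float:
        return self.hub_edge_count / self.total_edge_count if self.total_edge_count else 0.0


def find_hubs(graph: nx.Graph, min_degree: int = 10) -> HubReport:
    """Hub miRNAs and the bipartite edge/target tallies they account for."""
    mirna_nodes = [n for n, d in graph.nodes(data=True) if d.get("role") == "miRNA"]
    hubs = sorted(
        ((m, graph.degree(m)) for m in mirna_nodes if graph.degree(m) >= min_degree),
        key=lambda item: (-item[1], item[0]),
    )
    hub_names = {m for m, _ in hubs}
    # bipartite: edges incident to hub miRNAs are counted exactly once
    hub_edge_count = sum(d for _, d in hubs)
    targets = {v for m in hub_names for v in graph.neighbors(m)}
    return HubReport(
        hubs=hubs,
        hub_edge_count=hub_edge_count,
        total_edge_count=graph.number_of_edges(),
        hub_target_count=len(targets),
        min_degree=min_degree,
    )


class CorrelationNetworkModel:
    """Anti-correlation network of candidate pairs within one regimen.

    Parameters
    ----------
    mirna_counts, mrna_counts
        Raw count matrices covering (at least) the regimen's libraries.
    sheet
        Sample sheet; pairing between the two matrices comes from here.
    regimen
        ``"co"`` or ``"pre"``; selects the 6 paired samples (3 control +
        3 treated) whose expression the correlation uses.  ``None`` uses
        every sample in the sheet.
    pairs
        Candidate miRNA-mRNA pairs (the FDR family).
    scale
        ``"log2cpm"`` (default) correlates log2(CPM + 1); ``"cpm"`` raw CPM.
    """

    def __init__(
        self,
        mirna_counts: CountMatrix,
        mrna_counts: CountMatrix,
        sheet: SampleSheet,
        pairs: Sequence[CandidateTargetPair],
        regimen: str | None = None,
        scale: str = "log2cpm",
    ) -> None:
        if scale not in {"log2cpm", "cpm"}:
            raise ValueError(f"unknown scale {scale!r}")
        self.sheet = sheet.subset(regimen=regimen) if regimen else sheet
        if not self.sheet.records:
            raise ValueError(f"no samples for regimen {regimen!r}")
        sheet.validate_against(mirna_counts, mrna_counts)
        self.mirna_counts = mirna_counts
        self.mrna_counts = mrna_counts
        self.pairs = list(pairs)
        self.regimen = regimen
        self.scale = scale

    def _expression(self, matrix: CountMatrix) -> pd.DataFrame:
        cpm = cpm_normalize(matrix)
        return np.log2(cpm + 1.0) if self.scale == "log2cpm" else cpm

    def fit(
        self,
        alpha: float = 0.05,
        min_hub_degree: int = 10,
        mirna_log2fc: Mapping[str, float] | None = None,
        gene_log2fc: Mapping[str, float] | None = None,
    ) -> "CorrelationNetworkResults":
        edges = correlate_pairs(
            self._expression(self.mirna_counts),
            self._expression(self.mrna_counts),
            self.pairs,
            self.sheet,
        )
        retained = filter_edges(edges, alpha=alpha)
        graph = build_network(retained, mirna_log2fc, gene_log2fc)
        hubs = find_hubs(graph, min_degree=min_hub_degree)
        return CorrelationNetworkResults(self, edges, retained, graph, hubs, alpha)


class CorrelationNetworkResults:
    """Fitted network: full edge table, retained edges, graph, hubs."""

    def __init__(
        self,
        model: CorrelationNetworkModel,
        edges: pd.DataFrame,
        retained: pd.DataFrame,
        graph: nx.Graph,
        hub_report: HubReport,
        alpha: float,
    ) -> None:
        self.model = model
        self.edges = edges
        self.retained = retained
        self.graph = graph
        self.hub_report = hub_report
        self.alpha = alpha

    @property
    def n_mirnas(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["role"] == "miRNA")

    @property
    def n_genes(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["role"] == "mRNA")

    def summary(self) -> str:
        hr = self.hub_report
        lines = [
            "miRNA-mRNA anti-correlation network",
            "=" * 48,
            f"candidate pairs tested {len(self.edges):>8d}",
            f"retained edges         {len(self.retained):>8d}"
            f"   (r < 0, FDR < {self.alpha:g})",
            f"unique miRNAs / mRNAs  {self.n_mirnas:>5d} / {self.n_genes}",
            f"hubs (degree >= {hr.min_degree:>2d})    {len(hr.hubs):>8d}",
            f"hub edges              {hr.hub_edge_count:>8d}"
            f"   ({100 * hr.hub_edge_fraction:.1f}% of network)",
            f"hub targets            {hr.hub_target_count:>8d}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.retained.to_csv(path, sep="\t", index=False, float_format="%.6g")
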