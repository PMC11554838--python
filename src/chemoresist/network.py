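"""DEG-ranked gene selection and degree-filtered hub extraction.

From a differential-expression table the top-n genes by absolute log2
fold change among significant genes (padj below a cutoff) are selected.
Restricting a confidence-scored interaction edge list to those genes
and to edges at or above a confidence floor (default 0.9, the
"highest confidence" convention of interaction databases) yields a
subgraph whose high-degree nodes — strictly more than ``min_degree``
edges, default > 2 — are the hubs of the final interaction map.

Variance-based feature selection (top-n genes by sample variance) is
provided for ordination/heatmap inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import AnalyteMatrix, InvariantError

logger = logging.getLogger("chemoresist")


@dataclass
class EdgeList:
    """Undirected confidence-scored gene-pair interactions.

    Canonical form: ``gene_a < gene_b`` lexicographically, no
    self-loops, duplicate pairs collapsed keeping the maximum
    confidence, confidence in [0, 1].
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene_a", "gene_b", "confidence"}
        missing = need - set(self.edges.columns)
        if missing:
            raise InvariantError(f"edge list missing column(s): {sorted(missing)}")
        df = self.edges[["gene_a", "gene_b", "confidence"]].copy()
        df["gene_a"] = df["gene_a"].astype(str)
        df["gene_b"] = df["gene_b"].astype(str)
        df["confidence"] = df["confidence"].astype(float)
        loops = df["gene_a"] == df["gene_b"]
        if loops.any():
            raise InvariantError(f"self-loop edge(s): {sorted(set(df.loc[loops, 'gene_a']))}")
        if ((df["confidence"] < 0) | (df["confidence"] > 1)).any():
            raise InvariantError("edge confidence must lie in [0, 1]")
        a = df[["gene_a", "gene_b"]].min(axis=1)
        b = df[["gene_a", "gene_b"]].max(axis=1)
        df["gene_a"], df["gene_b"] = a, b
        n_before = len(df)
        df = (df.groupby(["gene_a", "gene_b"], as_index=False)["confidence"].max()
                .sort_values(["gene_a", "gene_b"]).reset_index(drop=True))
        if len(df) < n_before:
            logger.info("EdgeList: collapsed %d duplicate pair(s), keeping max confidence",
                        n_before - len(df))
        self.edges = df

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class HubNetwork:
    """Degree-filtered interaction map.

    ``degrees`` are computed on the confidence-filtered, gene-restricted
    subgraph; ``retained`` holds the genes whose degree exceeds the
    threshold, and ``edges`` the induced edges among them.
    """

    degrees: dict[str, int]
    retained: list[str]
    edges: pd.DataFrame


def select_top_deg(degs: pd.DataFrame, n: int, padj_max: float = 0.05) -> list[str]:
    """Top-n genes by |log2 fold change| among significant genes (padj < padj_max).

    Ties in |lfc| break by gene id for determinism. If fewer than n
    genes pass the significance filter, all survivors are returned
    (with a logged note).
    """
    if len(degs) == 0:
        raise InvariantError("empty DEG table")
    if n < 1:
        raise InvariantError(f"n must be >= 1, got {n}")
    sig = degs[degs["padj"] < padj_max].copy()
    sig["abs_lfc"] = sig["lfc"].abs()
    sig = sig.sort_values(["abs_lfc", "gene"], ascending=[False, True], kind="stable")
    if len(sig) < n:
        logger.info("select_top_deg: only %d/%d gene(s) pass padj < %g; returning all",
                    len(sig), n, padj_max)
    return sig["gene"].head(n).tolist()


def select_top_variance(m: AnalyteMatrix, n: int) -> list[str]:
    """Top-n analytes by across-sample variance (ddof=1), ties by id."""
    if n > len(m.values.index):
        raise InvariantError(f"n={n} exceeds the {len(m.values.index)} available analytes")
    if len(m.values.columns) < 2:
        raise InvariantError("variance undefined with a single sample")
    var = m.values.var(axis=1, ddof=1, skipna=True)
    ranked = (pd.DataFrame({"gene": var.index, "var": var.to_numpy()})
              .sort_values(["var", "gene"], ascending=[False, True], kind="stable"))
    return ranked["gene"].head(n).tolist()


def extract_hubs(edges: EdgeList, genes: Sequence[str] | Iterable[str],
                 conf_min: float = 0.9, min_degree_exclusive: int = 2) -> HubNetwork:
    """Hub genes of the confidence-filtered, gene-restricted interaction graph.

    Edges are kept when both endpoints are in ``genes`` and confidence
    >= ``conf_min``; degrees are counted on that simple subgraph and
    nodes with degree > ``min_degree_exclusive`` are retained together
    with their induced edges. An empty result is valid.
    """
    genes = list(genes)
    if not genes:
        raise InvariantError("gene list is empty")
    gene_set = set(genes)
    df = edges.edges
    kept = df[(df["confidence"] >= conf_min)
              & df["gene_a"].isin(gene_set) & df["gene_b"].isin(gene_set)]
    graph = nx.Graph()
    graph.add_nodes_from(gene_set)
    graph.add_edges_from(zip(kept["gene_a"], kept["gene_b"]))
    degrees = {g: int(d) for g, d in graph.degree()}
    retained = sorted(g for g, d in degrees.items() if d > min_degree_exclusive)
    retained_set = set(retained)
    induced = kept[kept["gene_a"].isin(retained_set) & kept["gene_b"].isin(retained_set)]
    induced = induced.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    logger.info("extract_hubs: %d/%d gene(s) retained at conf >= %g, degree > %d",
                len(retained), len(gene_set), conf_min, min_degree_exclusive)
    return HubNetwork(degrees, retained, induced)
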