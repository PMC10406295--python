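"""Correlation matrices and the thresholded group-level brain graph.

Per-subject functional connectivity is the Pearson correlation between
every pair of ROI time courses. Subject matrices are averaged elementwise
across the cohort, and the group-mean matrix is thresholded (default 0.1,
signed comparison, so negative correlations are dropped too): entries below
threshold are zeroed and the corresponding edges removed from the otherwise
complete graph. The surviving graph is undirected and unweighted; each
node's feature vector is its row of the thresholded mean-correlation
matrix with the diagonal zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import CohortTimeSeries

__all__ = [
    "CorrelationMatrix",
    "BrainGraph",
    "pearson_correlation",
    "subject_correlation_matrix",
    "group_mean_correlation",
    "cohort_mean_correlation",
    "build_graph",
    "complete_graph_edge_count",
    "write_graph",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    roi_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"correlation matrix must be square, got {v.shape}")
        if v.shape[0] != len(self.roi_ids):
            raise ValueError("roi_ids length must match matrix dimension")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1.0 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("correlation diagonal must be exactly 1")
        # snap tiny float excursions so invariants hold exactly
        v = np.clip((v + v.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class BrainGraph:
    """Undirected unweighted ROI graph with per-node feature rows."""

    n_nodes: int
    edges: set[tuple[int, int]]
    features: np.ndarray
    roi_ids: list[str]
    adjacency: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u}")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError(f"edge ({u}, {v}) out of range")
        if self.features.shape[0] != self.n_nodes:
            raise ValueError("feature row count must equal node count")
        if len(self.roi_ids) != self.n_nodes:
            raise ValueError("roi_ids length must equal node count")
        neigh: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            neigh[u].append(v)
            neigh[v].append(u)
        self.adjacency = [np.array(sorted(ns), dtype=np.int64) for ns in neigh]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node: int) -> np.ndarray:
        if not (0 <= node < self.n_nodes):
            raise KeyError(f"unknown node {node}")
        return self.adjacency[node]

    def degree(self, node: int) -> int:
        return len(self.neighbors(node))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation r_xy = sum((x - x̄)(y - ȳ)) / sqrt(Σ(x-x̄)² Σ(y-ȳ)²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series shapes differ or not 1-D: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.dot(xc, xc) * np.dot(yc, yc))
    if denom == 0.0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.clip(np.dot(xc, yc) / denom, -1.0, 1.0))


def subject_correlation_matrix(
    ts: np.ndarray, roi_ids: Sequence[str] | None = None
) -> CorrelationMatrix:
    """All-pairs ROI correlation for one subject's (time, roi) matrix."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time-series matrix must be 2-D (time x roi)")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    ids = list(roi_ids) if roi_ids is not None else [f"ROI{j:03d}" for j in range(ts.shape[1])]
    variances = np.var(ts, axis=0)
    if np.any(variances == 0.0):
        bad = int(np.flatnonzero(variances == 0.0)[0])
        raise ValueError(f"constant time series for ROI {ids[bad]!r}")
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(values=r, roi_ids=ids)


def group_mean_correlation(mats: Sequence[CorrelationMatrix]) -> CorrelationMatrix:
    """Elementwise arithmetic mean across subjects."""
    if len(mats) == 0:
        raise ValueError("need at least one correlation matrix")
    ref = mats[0].roi_ids
    for i, m in enumerate(mats):
        if m.roi_ids != ref:
            raise ValueError(f"ROI order of matrix {i} differs from the first")
    mean = np.mean([m.values for m in mats], axis=0)
    np.fill_diagonal(mean, 1.0)
    return CorrelationMatrix(values=mean, roi_ids=list(ref))


def cohort_mean_correlation(cohort: CohortTimeSeries) -> CorrelationMatrix:
    """Per-subject correlation matrices averaged across the cohort."""
    mats = [
        subject_correlation_matrix(mat, cohort.roi_ids) for mat in cohort.subjects
    ]
    return group_mean_correlation(mats)


def complete_graph_edge_count(n_nodes: int) -> int:
    """Edges of the complete graph on n nodes: n(n-1)/2."""
    if n_nodes < 0:
        raise ValueError("node count must be nonnegative")
    return n_nodes * (n_nodes - 1) // 2


def build_graph(mean_corr: CorrelationMatrix, threshold: float = 0.1) -> BrainGraph:
    """Threshold the group-mean matrix and build the node-attributed graph.

    Starting from the complete graph, edge (i, j) is kept iff
    mean_corr[i, j] >= threshold (signed comparison). Node features are the
    rows of the thresholded matrix with sub-threshold entries and the
    diagonal set to zero.
    """
    if not (-1.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (-1, 1), got {threshold}")
    v = mean_corr.values
    n = mean_corr.n_rois
    keep = v >= threshold
    features = np.where(keep, v, 0.0)
    np.fill_diagonal(features, 0.0)
    iu, ju = np.triu_indices(n, k=1)
    mask = keep[iu, ju]
    edges = {(int(i), int(j)) for i, j in zip(iu[mask], ju[mask])}
    graph = BrainGraph(
        n_nodes=n, edges=edges, features=features, roi_ids=list(mean_corr.roi_ids)
    )
    isolated = [graph.roi_ids[i] for i in range(n) if graph.degree(i) == 0]
    if isolated:
        logger.warning("graph has %d isolated node(s): %s", len(isolated), isolated)
    return graph


def write_graph(graph: BrainGraph, out_dir: str | Path) -> tuple[Path, Path]:
    """Edge list and feature matrix as TSV; returns (edges_path, features_path)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges_path = out / "edges.tsv"
    rows = sorted(graph.edges)
    pd.DataFrame(
        [(graph.roi_ids[u], graph.roi_ids[v]) for u, v in rows],
        columns=["roi_id_u", "roi_id_v"],
    ).to_csv(edges_path, sep="\t", index=False)
    features_path = out / "features.tsv"
    df = pd.DataFrame(graph.features, columns=graph.roi_ids)
    df.insert(0, "roi_id", graph.roi_ids)
    df.to_csv(features_path, sep="\t", index=False, float_format="%.9g")
    return edges_path, features_path
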