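"""End-to-end orchestration: cohort -> graph -> embeddings -> partition.

One global seed derives per-stage seeds by fixed offsets (cohort +0,
embedding +1, k-means +2), so any stage can be re-run in isolation and a
whole run is reproducible from its logged configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import build_graph, cohort_mean_correlation, write_graph
from .extraction import (
    evaluate_recovery,
    identify_network,
    kmeans_cluster,
    pca_reduce,
    write_partition,
)
from .sage import SageConfig, train_embeddings, write_embeddings
from .sbc import run_sbc, write_seed_map
from .synthetic import CohortTimeSeries, SyntheticConfig, simulate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "read_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)

_EMBED_SEED_OFFSET = 1
_KMEANS_SEED_OFFSET = 2


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    synthetic: SyntheticConfig | None = None
    manifest_path: str | None = None
    threshold: float = 0.1
    sage: SageConfig | None = None
    variance_target: float = 0.95
    k: int = 7
    reference_rois: list[str] | None = None
    sbc_seed_roi: str | None = None
    sbc_alpha: float = 0.0001
    sbc_fwer: bool = False
    run_sbc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.manifest_path is None):
            raise ValueError("exactly one of synthetic config or manifest_path required")


@dataclass
class PipelineResult:
    cohort: CohortTimeSeries
    graph: object
    embeddings: object
    reduced: object
    partition: object
    seed_map: object | None
    metrics: dict


def read_cohort(manifest_path: str | Path) -> CohortTimeSeries:
    """Load a cohort written by :func:`rsnsage.synthetic.write_cohort`.

    ROI order is taken from the first subject file and enforced on all.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    subjects = []
    roi_ids: list[str] | None = None
    for fname in manifest["subject_files"]:
        path = base / fname
        if not path.exists():
            raise FileNotFoundError(f"subject file missing: {path}")
        df = pd.read_csv(path, sep="\t")
        header = [str(c) for c in df.columns]
        if roi_ids is None:
            roi_ids = header
        elif header != roi_ids:
            raise ValueError(f"header of {path} does not match the first subject")
        subjects.append(df.to_numpy(dtype=float))
    labels = manifest.get("true_labels")
    return CohortTimeSeries(
        subjects=subjects,
        roi_ids=roi_ids or [],
        true_labels=None if labels is None else np.asarray(labels, dtype=np.int64),
    )


def _default_reference(cohort: CohortTimeSeries) -> list[str] | None:
    """Planted DMN block (true label 0) when ground truth is available."""
    if cohort.true_labels is None:
        return None
    return [r for r, l in zip(cohort.roi_ids, cohort.true_labels) if l == 0]


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Correlation -> graph -> embed -> PCA -> k-means -> identify -> SBC."""
    stage = "load-cohort"
    try:
        if config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            cohort = simulate_cohort(syn)
        else:
            cohort = read_cohort(config.manifest_path)

        stage = "connectivity-graph"
        mean_corr = cohort_mean_correlation(cohort)
        graph = build_graph(mean_corr, threshold=config.threshold)
        logger.info("graph: %d nodes, %d edges", graph.n_nodes, graph.n_edges)

        stage = "graphsage-embedding"
        sage_cfg = config.sage or SageConfig()
        sage_cfg = dataclasses.replace(sage_cfg, seed=config.seed + _EMBED_SEED_OFFSET)
        embeddings = train_embeddings(graph, sage_cfg)

        stage = "network-extraction"
        reduced = pca_reduce(embeddings, variance_target=config.variance_target)
        partition = kmeans_cluster(
            reduced, k=config.k, seed=config.seed + _KMEANS_SEED_OFFSET
        )
        reference = config.reference_rois or _default_reference(cohort)
        if reference:
            identify_network(partition, reference)
        metrics: dict = {
            "edge_count": graph.n_edges,
            "p": reduced.n_components,
            "inertia": partition.inertia,
            "dmn_cluster": partition.dmn_cluster,
            "seed": config.seed,
        }
        if cohort.true_labels is not None:
            metrics.update(evaluate_recovery(partition, cohort.true_labels))

        seed_map = None
        if config.run_sbc:
            stage = "sbc-baseline"
            seed_roi = config.sbc_seed_roi or (reference[0] if reference else None)
            if seed_roi is not None:
                seed_map = run_sbc(
                    cohort, seed_roi, alpha=config.sbc_alpha, fwer_mode=config.sbc_fwer
                )
                metrics["sbc_seed"] = seed_roi
                metrics["sbc_n_significant"] = int(np.sum(seed_map.significant))

        if out_dir is not None:
            stage = "write-outputs"
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_graph(graph, out)
            write_embeddings(embeddings, out)
            write_partition(partition, out, metrics=metrics)
            if seed_map is not None:
                write_seed_map(seed_map, out)
            run_log = {
                "config": {
                    "threshold": config.threshold,
                    "variance_target": config.variance_target,
                    "k": config.k,
                    "seed": config.seed,
                    "sage": dataclasses.asdict(sage_cfg),
                    "synthetic": (
                        None
                        if config.synthetic is None
                        else dataclasses.asdict(dataclasses.replace(
                            config.synthetic, seed=config.seed))
                    ),
                    "manifest_path": config.manifest_path,
                },
                "metrics": metrics,
            }
            (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return PipelineResult(
        cohort=cohort,
        graph=graph,
        embeddings=embeddings,
        reduced=reduced,
        partition=partition,
        seed_map=seed_map,
        metrics=metrics,
    )
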