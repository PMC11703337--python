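"""End-to-end pipeline: similarity -> LEN -> screens -> hierarchy -> metrics."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from . import __version__
from ._seeds import STAGE_OFFSETS
from .embedding import build_len
from .hierarchy import MSCConfig, run_msc
from .io import (
    read_input,
    read_labels_tsv,
    write_edge_list,
    write_json,
)
from .metrics import (
    ClusterCollection,
    coverage_rate,
    detection_accuracy,
    inclusion_rate,
)
from .screening import screen_graph
from .similarity import (
    ExpressionMatrix,
    SimilarityMatrix,
    euclidean_similarity,
    pearson_similarity,
    top_variance_mask,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "compute_similarity", "build_screened_len"]


@dataclass
class RunConfig:
    input_path: str
    input_format: str  # mtx_dir | tsv_dense | tsv_coords | tsv_similarity
    out_dir: str
    similarity: str = "pearson"  # pearson | euclidean
    feature_file: Optional[str] = None
    n_top_features: Optional[int] = None
    stall: int = 3
    k_max: Optional[int] = None
    skip_similarity_screen: bool = False
    contested_quantile: float = 0.25
    loess_span: float = 0.5
    min_cluster_size: int = 10
    min_split_size: int = 20
    gamma_step: float = 0.05
    gamma_max: float = 2.0
    n_perm: int = 100
    perm_frac: float = 0.10
    p_threshold: float = 0.05
    seed: int = 0
    truth_path: Optional[str] = None
    allow_negative: bool = False

    def config_hash(self) -> str:
        # identifies the analysis, not where it is written
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def compute_similarity(config: RunConfig):
    """Load the input and produce (SimilarityMatrix, ExpressionMatrix|None)."""
    obj = read_input(
        config.input_path,
        config.input_format,
        require_nonnegative=not config.allow_negative,
    )
    if config.input_format == "tsv_similarity":
        return obj, None
    if config.input_format == "tsv_coords":
        coords, ids = obj
        if config.similarity != "euclidean":
            raise ValueError("coordinate input requires --similarity euclidean")
        return euclidean_similarity(coords, ids), None
    expr: ExpressionMatrix = obj
    if config.feature_file:
        wanted = set(Path(config.feature_file).read_text().split())
        mask = np.array([g in wanted for g in expr.gene_ids])
        if not mask.any():
            raise ValueError("feature file matches no gene ids")
        expr.feature_mask = mask
    elif config.n_top_features:
        expr.feature_mask = top_variance_mask(expr, config.n_top_features)
    if config.similarity == "pearson":
        return pearson_similarity(expr), expr
    raise ValueError(
        "euclidean similarity requires a coordinate (tsv_coords) input"
    )


def build_screened_len(
    sim: SimilarityMatrix,
    expr: Optional[ExpressionMatrix],
    config: RunConfig,
) -> tuple[nx.Graph, nx.Graph, object]:
    """Raw LEN, screened LEN and the screen report."""
    raw = build_len(sim, stall=config.stall, k_max=config.k_max)
    final, report = screen_graph(
        raw,
        expr,
        contested_quantile=config.contested_quantile,
        span=config.loess_span,
        skip_similarity=config.skip_similarity_screen,
    )
    return raw, final, report


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the artifact files into ``out_dir``.

    Writes len.edges.tsv, screen_report.json, hierarchy.json,
    membership.tsv, metrics.json (when a truth file is given) and
    manifest.json.  Deterministic for a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "similarity"
    try:
        sim, expr = compute_similarity(config)
        stage = "len"
        raw, final, report = build_screened_len(sim, expr, config)
        write_edge_list(final, out / "len.edges.tsv")
        write_json(
            {"config_hash": config.config_hash(), **report.to_dict()},
            out / "screen_report.json",
        )
        logger.info(
            "LEN: %d raw edges, %d after screens, %d components",
            raw.number_of_edges(),
            final.number_of_edges(),
            report.n_components_out,
        )
        stage = "clustering"
        n_steps = int(round(config.gamma_max / config.gamma_step))
        grid = np.round(np.arange(1, n_steps + 1) * config.gamma_step, 10)
        msc_config = MSCConfig(
            min_cluster_size=config.min_cluster_size,
            min_split_size=config.min_split_size,
            gamma_grid=grid,
            n_perm=config.n_perm,
            perm_frac=config.perm_frac,
            p_threshold=config.p_threshold,
            seed=config.seed,
        )
        hierarchy = run_msc(final, msc_config)
        hier_dict = {"config_hash": config.config_hash(), **hierarchy.to_dict()}
        write_json(hier_dict, out / "hierarchy.json")
        rows = hierarchy.membership()
        (out / "membership.tsv").write_text(
            "cell_id\tnode_id\n"
            + "\n".join(f"{c}\t{n}" for c, n in rows)
            + "\n"
        )

        results = {
            "n_cells": sim.n_cells,
            "n_edges_raw": raw.number_of_edges(),
            "n_edges_final": final.number_of_edges(),
            "n_nodes_hierarchy": len(hierarchy.nodes),
            "n_roots": len(hierarchy.roots),
        }
        if config.truth_path:
            stage = "evaluation"
            truth = ClusterCollection.from_labels(read_labels_tsv(config.truth_path))
            result_clusters = ClusterCollection(hierarchy.cluster_sets())
            _, ir = inclusion_rate(result_clusters, truth)
            _, cr = coverage_rate(result_clusters, truth)
            _, da = detection_accuracy(result_clusters, truth)
            metrics = {"IR": ir, "CR": cr, "DA": da, "config_hash": config.config_hash()}
            write_json(metrics, out / "metrics.json")
            results.update(IR=ir, CR=cr, DA=da)

        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed_scheme": {
                "formula": "(seed + 7919*offset + counter) mod 2^31",
                "offsets": STAGE_OFFSETS,
            },
            "versions": _versions(),
            "stage_stats": results,
        }
        write_json(manifest, out / "manifest.json")
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _versions() -> dict:
    import igraph
    import leidenalg
    import networkx
    import numpy
    import pandas
    import scipy

    return {
        "msclust": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
        "igraph": igraph.__version__,
        "leidenalg": leidenalg.version,
    }
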