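"""Overlap-aware clustering agreement metrics and enrichment tests.

A hierarchy yields overlapping clusters (every cell belongs to each node on
its root-to-leaf path), so plain partition metrics do not apply.  The
inclusion rate (IR) is the size-weighted best precision of each result
cluster against the truth; the coverage rate (CR) is the size-weighted best
recall of each truth cluster; detection accuracy (DA) replaces recall with
the Jaccard index, penalizing both over- and under-segmentation.  ARI is
provided for strict partitions, and a Fisher-exact / BH workflow flags
cluster-condition enrichments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterCollection",
    "inclusion_rate",
    "coverage_rate",
    "detection_accuracy",
    "jaccard_index",
    "adjusted_rand_index",
    "group_enrichment",
    "EnrichmentTable",
]


@dataclass
class ClusterCollection:
    """Named cell-id sets; overlaps permitted."""

    clusters: dict[str, set]

    def __post_init__(self) -> None:
        for name, members in self.clusters.items():
            if not members:
                raise ValueError(f"cluster {name!r} is empty")

    @classmethod
    def from_labels(cls, labels: Mapping[str, str]) -> "ClusterCollection":
        out: dict[str, set] = {}
        for cell, lab in labels.items():
            out.setdefault(str(lab), set()).add(cell)
        return cls(out)

    @property
    def universe(self) -> set:
        return set().union(*self.clusters.values())

    def is_partition(self) -> bool:
        return sum(len(c) for c in self.clusters.values()) == len(self.universe)


def _as_collection(x) -> ClusterCollection:
    if isinstance(x, ClusterCollection):
        return x
    return ClusterCollection({str(k): set(v) for k, v in dict(x).items()})


def jaccard_index(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def inclusion_rate(result, truth) -> tuple[dict[str, float], float]:
    """Per-result-cluster IR (best precision) and size-weighted overall IR."""
    result, truth = _as_collection(result), _as_collection(truth)
    per = {
        name: max(len(r & t) / len(r) for t in truth.clusters.values())
        for name, r in result.clusters.items()
    }
    sizes = {name: len(r) for name, r in result.clusters.items()}
    overall = sum(per[n] * sizes[n] for n in per) / sum(sizes.values())
    return per, float(overall)


def coverage_rate(result, truth) -> tuple[dict[str, float], float]:
    """Per-truth-cluster CR (best recall) and size-weighted overall CR."""
    result, truth = _as_collection(result), _as_collection(truth)
    per = {
        name: max(len(r & t) / len(t) for r in result.clusters.values())
        for name, t in truth.clusters.items()
    }
    sizes = {name: len(t) for name, t in truth.clusters.items()}
    overall = sum(per[n] * sizes[n] for n in per) / sum(sizes.values())
    return per, float(overall)


def detection_accuracy(result, truth) -> tuple[dict[str, float], float]:
    """Per-truth-cluster DA (best Jaccard) and size-weighted overall DA."""
    result, truth = _as_collection(result), _as_collection(truth)
    per = {
        name: max(jaccard_index(r, t) for r in result.clusters.values())
        for name, t in truth.clusters.items()
    }
    sizes = {name: len(t) for name, t in truth.clusters.items()}
    overall = sum(per[n] * sizes[n] for n in per) / sum(sizes.values())
    return per, float(overall)


def adjusted_rand_index(partition_a, partition_b) -> float:
    """Permutation-model adjusted Rand index of two partitions.

    Raises when either input has overlapping clusters or the universes
    differ (ARI is only defined for partitions of the same items).
    """
    a, b = _as_collection(partition_a), _as_collection(partition_b)
    if not a.is_partition() or not b.is_partition():
        raise ValueError("ARI requires non-overlapping partitions")
    if a.universe != b.universe:
        raise ValueError("partitions must cover the same universe")
    items = sorted(a.universe)
    label_a = {c: name for name, members in a.clusters.items() for c in members}
    label_b = {c: name for name, members in b.clusters.items() for c in members}
    from sklearn.metrics import adjusted_rand_score

    return float(
        adjusted_rand_score(
            [label_a[i] for i in items], [label_b[i] for i in items]
        )
    )


@dataclass
class EnrichmentTable:
    """Per (cluster, sample) Fisher-exact enrichment plus condition labels."""

    table: pd.DataFrame  # cluster, sample, condition, odds_ratio, p, fdr, enriched
    condition_labels: pd.DataFrame  # cluster, condition, frac_enriched, labeled
    skipped_clusters: list[str]


def group_enrichment(
    membership: Sequence[tuple[str, str]],
    cell_to_sample: Mapping[str, str],
    sample_to_condition: Mapping[str, str],
    fdr_threshold: float = 0.05,
    condition_frac: float = 0.5,
) -> EnrichmentTable:
    """Cluster-sample Fisher enrichment with BH correction.

    ``membership`` holds (cell_id, cluster_id) rows (overlaps allowed).  For
    each (cluster, sample) pair a one-sided Fisher's exact test is run on
    the 2x2 table of cluster membership x sample origin; BH is applied over
    all tests jointly; a sample is enriched at FDR < ``fdr_threshold``; a
    cluster is labeled for a condition when at least ``condition_frac`` of
    that condition's samples are enriched.
    """
    memb = pd.DataFrame(membership, columns=["cell", "cluster"])
    missing = set(memb["cell"]) - set(cell_to_sample)
    if missing:
        raise ValueError(f"cells without a sample mapping: {sorted(missing)[:5]}")
    universe = list(cell_to_sample.keys())
    n_total = len(universe)
    sample_of = pd.Series(cell_to_sample)
    sample_counts = sample_of.value_counts()

    rows = []
    skipped = []
    for cluster, grp in memb.groupby("cluster"):
        cells = set(grp["cell"])
        samples_hit = sample_of.loc[sorted(cells)].unique()
        if len(samples_hit) == 0:
            skipped.append(str(cluster))
            continue
        for sample in sample_counts.index:
            in_both = sum(1 for c in cells if cell_to_sample[c] == sample)
            in_cluster_only = len(cells) - in_both
            in_sample_only = int(sample_counts[sample]) - in_both
            rest = n_total - in_both - in_cluster_only - in_sample_only
            odds, p = fisher_exact(
                [[in_both, in_cluster_only], [in_sample_only, rest]],
                alternative="greater",
            )
            rows.append(
                {
                    "cluster": str(cluster),
                    "sample": str(sample),
                    "condition": str(sample_to_condition[sample]),
                    "odds_ratio": float(odds),
                    "p": float(p),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
        table["enriched"] = table["fdr"] < fdr_threshold
    else:
        table["fdr"] = []
        table["enriched"] = []

    cond_samples = pd.Series(list(sample_to_condition.values())).value_counts()
    label_rows = []
    for cluster, grp in table.groupby("cluster"):
        for cond, cond_grp in grp.groupby("condition"):
            n_enriched = int(cond_grp["enriched"].sum())
            frac = n_enriched / int(cond_samples[cond])
            label_rows.append(
                {
                    "cluster": cluster,
                    "condition": cond,
                    "frac_enriched": frac,
                    "labeled": frac >= condition_frac,
                }
            )
    condition_labels = pd.DataFrame(label_rows)
    return EnrichmentTable(table=table, condition_labels=condition_labels, skipped_clusters=skipped)
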