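"""Most-variable-probe selection, hierarchical clustering and CpG-region
enrichment testing.

The unsupervised view of a methylation cohort: rank probes by across-sample
variability, cluster samples on the selected submatrix (Euclidean distance,
average linkage by default), and ask whether a selected probe set is
enriched for CpG-island probes relative to a universe (one-sided Fisher
exact test on the island vs non-island 2×2 table).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .containers import (
    REGION_CLASSES,
    BetaMatrix,
    ProbeAnnotation,
    ValidationError,
)


@dataclasses.dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of samples over a probe-restricted submatrix."""

    linkage_matrix: np.ndarray          # scipy (n-1) × 4 merge table
    sample_ids: tuple[str, ...]         # leaf IDs in input order
    sample_order: tuple[str, ...]       # dendrogram leaf order
    probe_order: tuple[str, ...]
    metric: str
    linkage_method: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels (1-based) for a maxclust cut of the tree."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=list(self.sample_ids), name="cluster")

    def to_newick(self) -> str:
        """Newick text of the sample dendrogram (heights as branch lengths)."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = max(0.0, parent_height - node.dist)
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.9g}"
            left = walk(node.get_left(), node.dist)
            right = walk(node.get_right(), node.dist)
            return f"({left},{right}):{length:.9g}"

        return walk(tree, tree.dist) + ";"


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    """Island-vs-rest enrichment of a selected probe set within a universe."""

    selected_counts: dict[str, int]
    universe_counts: dict[str, int]
    fold_enrichment: dict[str, float]
    odds_ratio: float
    p_value: float

    @property
    def island_fold(self) -> float:
        return self.fold_enrichment["island"]


def top_variable_probes(beta: BetaMatrix, k: int, ddof: int = 1) -> pd.Index:
    """The ``k`` probes with the largest across-sample standard deviation.

    Deterministic ordering: descending SD, ties broken by ascending probe
    ID. The matrix must be complete (run the completeness filter first).
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > beta.shape[0]:
        raise ValueError(f"k={k} exceeds probe count {beta.shape[0]}")
    beta.require_complete("top_variable_probes")
    sd = beta.df.std(axis=1, ddof=ddof)
    # stable two-key sort: probe ID ascending, then SD descending
    ordered = sd.sort_index().sort_values(ascending=False, kind="mergesort")
    return ordered.index[:k]


def hierarchical_cluster(
    beta: BetaMatrix,
    probes: pd.Index | list[str] | None = None,
    metric: str = "euclidean",
    linkage: str = "average",
) -> ClusterResult:
    """Cluster samples (columns) on the probe-restricted submatrix."""
    sub = beta if probes is None else beta.select(probes=list(probes))
    if bool(sub.df.isna().to_numpy().any()):
        raise ValidationError(
            "hierarchical_cluster requires complete values; filter or impute "
            "missing probes before clustering"
        )
    X = sub.df.to_numpy().T  # samples × probes
    if X.shape[0] < 2:
        raise ValidationError("need at least two samples to cluster")
    Z = hierarchy.linkage(X, method=linkage, metric=metric)
    order = hierarchy.leaves_list(Z)
    sample_ids = tuple(sub.sample_ids)
    return ClusterResult(
        linkage_matrix=Z,
        sample_ids=sample_ids,
        sample_order=tuple(sample_ids[i] for i in order),
        probe_order=tuple(sub.probe_ids),
        metric=metric,
        linkage_method=linkage,
    )


def region_enrichment(
    selected: pd.Index | list[str],
    annotation: ProbeAnnotation,
    universe: pd.Index | list[str],
) -> EnrichmentResult:
    """One-sided Fisher exact test for CpG-island enrichment.

    ``selected`` must be a nonempty subset of ``universe``. The test is on
    the 2×2 table (island vs non-island) × (selected vs not); per-region
    fold enrichment is the selected-fraction over the universe-fraction.
    """
    selected = pd.Index(selected)
    universe = pd.Index(universe)
    if len(selected) == 0:
        raise ValidationError("selected probe set is empty")
    stray = selected.difference(universe)
    if len(stray):
        raise ValidationError(f"selected probes outside universe: {stray[:5].tolist()}")

    sel_counts = annotation.region_counts(selected)
    uni_counts = annotation.region_counts(universe)

    sel_island = int(sel_counts["island"])
    uni_island = int(uni_counts["island"])
    table = [
        [sel_island, len(selected) - sel_island],
        [uni_island - sel_island, (len(universe) - uni_island) - (len(selected) - sel_island)],
    ]
    odds_ratio, p_value = stats.fisher_exact(table, alternative="greater")

    fold = {}
    for region in REGION_CLASSES:
        uni_frac = uni_counts[region] / len(universe)
        sel_frac = sel_counts[region] / len(selected)
        fold[region] = float(sel_frac / uni_frac) if uni_frac > 0 else float("nan")
    return EnrichmentResult(
        selected_counts={r: int(sel_counts[r]) for r in REGION_CLASSES},
        universe_counts={r: int(uni_counts[r]) for r in REGION_CLASSES},
        fold_enrichment=fold,
        odds_ratio=float(odds_ratio),
        p_value=float(p_value),
    )
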