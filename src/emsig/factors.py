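"""Correlation-based factor extraction per scale.

A "factor" here is a cluster of correlated Likert items interpreted as one
perception construct (e.g. COVID-19 "fear"). The procedure per scale:

1. pairwise Pearson correlation matrix of the (reverse-scored) items;
2. agglomerative clustering with Ward linkage on the dissimilarity
   d(i, j) = 1 - pcc(i, j);
3. cluster-count selection over k = 2..8 by a centroid silhouette floor
   plus a within-cluster PCC floor, minimizing the pooled variance of
   within-cluster pairwise correlations;
4. factor scores by aggregating each cluster's item responses.

Items are embedded for the silhouette as rows of the dissimilarity matrix,
so cluster centroids are ordinary coordinate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .schema import SurveyDataset

__all__ = [
    "CorrelationMatrix",
    "ClusterPartition",
    "ClusterQuality",
    "FactorSolution",
    "pcc_matrix",
    "ward_linkage",
    "ward_partition",
    "centroid_silhouette",
    "cluster_pcc_stats",
    "select_k",
    "compute_factor_scores",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric item x item Pearson correlation matrix with unit diagonal."""

    item_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.item_ids), len(self.item_ids)):
            raise ValueError("correlation matrix shape does not match item_ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.nanmax(np.abs(v)) > 1 + 1e-8:
            raise ValueError("correlation entries outside [-1, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def dissimilarity(self) -> np.ndarray:
        """Item dissimilarity d = 1 - pcc, in [0, 2], zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 2.0)


@dataclass(frozen=True)
class ClusterPartition:
    """Assignment of every item to exactly one of k contiguous clusters."""

    k: int
    assignment: dict[str, int]

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if labels != set(range(self.k)):
            raise ValueError(
                f"cluster indices must be contiguous 0..{self.k - 1}, got {sorted(labels)}"
            )

    def members(self, cluster: int) -> list[str]:
        return [i for i, c in self.assignment.items() if c == cluster]

    def labels_for(self, item_ids) -> np.ndarray:
        return np.array([self.assignment[i] for i in item_ids], dtype=int)


@dataclass
class ClusterQuality:
    """Silhouette and within-cluster PCC diagnostics for one candidate k."""

    k: int
    per_item_a: pd.Series
    per_item_b: pd.Series
    per_item_s: pd.Series
    sc: float
    per_cluster_pcc_mean: np.ndarray
    per_cluster_pcc_min: np.ndarray
    per_cluster_pcc_variance: np.ndarray
    pooled_pcc_variance: float
    has_singleton: bool
    admissible: bool = False


@dataclass
class FactorSolution:
    """Chosen partition for one scale plus the per-k quality table.

    ``chosen_k`` is ``None`` when no k in the examined range satisfied both
    the silhouette floor and the within-cluster PCC floor ("no admissible
    k"); the quality table is still populated so the caller can relax the
    thresholds.
    """

    scale_id: str
    chosen_k: int | None
    partition: ClusterPartition | None
    quality: dict[int, ClusterQuality]
    labels: dict[int, str] = field(default_factory=dict)
    prefix: str = ""

    @property
    def admissible_ks(self) -> list[int]:
        return [k for k, q in self.quality.items() if q.admissible]

    def factor_ids(self) -> list[str]:
        if self.partition is None:
            return []
        pre = self.prefix or self.scale_id[0].upper()
        return [
            self.labels.get(c, f"{pre}-c{c + 1}") for c in range(self.partition.k)
        ]

    def quality_table(self) -> pd.DataFrame:
        rows = []
        for k, q in sorted(self.quality.items()):
            rows.append(
                {
                    "k": k,
                    "sc": q.sc,
                    "pcc_mean_min": float(np.min(q.per_cluster_pcc_mean)),
                    "pcc_min_min": float(np.min(q.per_cluster_pcc_min)),
                    "pcc_pooled_variance": q.pooled_pcc_variance,
                    "has_singleton": q.has_singleton,
                    "admissible": q.admissible,
                    "chosen": k == self.chosen_k,
                }
            )
        return pd.DataFrame(rows)


def pcc_matrix(dataset: SurveyDataset, scale_id: str) -> CorrelationMatrix:
    """Pairwise Pearson correlations between a scale's items across respondents."""
    scale = dataset.scale(scale_id)
    if len(scale.item_ids) < 2:
        raise ValueError(f"scale {scale_id!r} needs >= 2 items for a PCC matrix")
    block = dataset.responses[list(scale.item_ids)].to_numpy(dtype=float)
    sd = block.std(axis=0)
    if np.any(sd == 0):
        bad = scale.item_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"item {bad!r} has zero variance; PCC undefined")
    corr = np.corrcoef(block, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(item_ids=scale.item_ids, values=np.clip(corr, -1, 1))


def ward_linkage(corr: CorrelationMatrix) -> np.ndarray:
    """Ward merge tree on the condensed dissimilarity d = 1 - pcc."""
    condensed = squareform(corr.dissimilarity(), checks=False)
    return linkage(condensed, method="ward")


def ward_partition(
    corr: CorrelationMatrix, k: int, merge_tree: np.ndarray | None = None
) -> ClusterPartition:
    """Cut the Ward merge tree at k clusters.

    Cluster indices are renumbered by first item appearance so the result is
    independent of scipy's internal label order.
    """
    n = corr.n_items
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if merge_tree is None:
        merge_tree = ward_linkage(corr)
    raw = fcluster(merge_tree, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for item, lab in zip(corr.item_ids, raw):
        if lab not in remap:
            remap[lab] = len(remap)
        assignment[item] = remap[lab]
    return ClusterPartition(k=len(remap), assignment=assignment)


def centroid_silhouette(
    partition: ClusterPartition,
    item_coords: pd.DataFrame,
) -> tuple[pd.Series, pd.Series, pd.Series, float]:
    """Centroid-based silhouette of an item partition.

    a'(i) is the Euclidean distance from item i to its own cluster centroid,
    b'(i) the smallest distance to another cluster's centroid, and
    s'(i) = (b'(i) - a'(i)) / max(a'(i), b'(i)). Returns per-item a', b',
    s' and their mean SC' in [-1, 1].

    ``item_coords`` holds one coordinate row per item (by default the rows
    of the dissimilarity matrix; see :func:`select_k`).
    """
    if partition.k < 2:
        raise ValueError("silhouette needs at least 2 clusters (b' undefined)")
    ids = list(item_coords.index)
    coords = item_coords.to_numpy(dtype=float)
    labels = partition.labels_for(ids)
    centroids = np.vstack(
        [coords[labels == c].mean(axis=0) for c in range(partition.k)]
    )
    dists = cdist(coords, centroids)
    a = dists[np.arange(len(ids)), labels]
    masked = dists.copy()
    masked[np.arange(len(ids)), labels] = np.inf
    b = masked.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    a_s = pd.Series(a, index=ids, name="a")
    b_s = pd.Series(b, index=ids, name="b")
    s_s = pd.Series(s, index=ids, name="s")
    return a_s, b_s, s_s, float(s.mean())


def cluster_pcc_stats(
    corr: CorrelationMatrix, partition: ClusterPartition
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    """Within-cluster pairwise-PCC mean, min and variance per cluster.

    Statistics are over off-diagonal within-cluster pairs only. Clusters
    with a single item carry NaN statistics (no pair evidence). The pooled
    variance is the variance of all within-cluster pair values across the
    partition.
    """
    idx = {item: j for j, item in enumerate(corr.item_ids)}
    means, mins, variances = [], [], []
    pooled: list[float] = []
    has_singleton = False
    for c in range(partition.k):
        members = [idx[i] for i in partition.members(c)]
        if len(members) < 2:
            has_singleton = True
            means.append(np.nan)
            mins.append(np.nan)
            variances.append(np.nan)
            continue
        sub = corr.values[np.ix_(members, members)]
        pairs = sub[np.triu_indices(len(members), k=1)]
        pooled.extend(pairs.tolist())
        means.append(float(pairs.mean()))
        mins.append(float(pairs.min()))
        variances.append(float(pairs.var()))
    pooled_var = float(np.var(pooled)) if pooled else np.nan
    return (
        np.array(means),
        np.array(mins),
        np.array(variances),
        pooled_var,
        has_singleton,
    )


def _quality_for_k(
    corr: CorrelationMatrix,
    partition: ClusterPartition,
    coords: pd.DataFrame,
) -> ClusterQuality:
    a, b, s, sc = centroid_silhouette(partition, coords)
    means, mins, variances, pooled, singleton = cluster_pcc_stats(corr, partition)
    return ClusterQuality(
        k=partition.k,
        per_item_a=a,
        per_item_b=b,
        per_item_s=s,
        sc=sc,
        per_cluster_pcc_mean=means,
        per_cluster_pcc_min=mins,
        per_cluster_pcc_variance=variances,
        pooled_pcc_variance=pooled,
        has_singleton=singleton,
    )


def select_k(
    corr: CorrelationMatrix,
    *,
    k_range=range(2, 9),
    sc_min: float = 0.25,
    pcc_floor: float = 0.5,
    use_min_pcc: bool = False,
    scale_id: str = "",
    prefix: str = "",
    labels: dict[int, str] | None = None,
) -> FactorSolution:
    """Choose the cluster count for one scale's correlation matrix.

    A candidate k is admissible when the centroid silhouette SC' >= sc_min
    and every cluster's within-cluster PCC statistic (mean by default, the
    minimum pairwise value with ``use_min_pcc``) reaches ``pcc_floor``.
    Partitions containing singleton clusters are inadmissible, since a
    one-item cluster offers no internal-correlation evidence.

    Among admissible k the mean silhouette SC' is maximized (ties go to the
    smaller k); the pooled within-cluster PCC variance is reported per k as
    the cohesion-dispersion diagnostic. The variance is not used as the
    objective because for nested Ward cuts it decreases monotonically in k
    — each further split removes the least-correlated pairs — so its argmin
    always sits at the top of the examined range rather than at the planted
    structure, while SC' peaks at it.
    """
    coords = pd.DataFrame(
        corr.dissimilarity(), index=list(corr.item_ids), columns=list(corr.item_ids)
    )
    merge_tree = ward_linkage(corr)
    quality: dict[int, ClusterQuality] = {}
    partitions: dict[int, ClusterPartition] = {}
    for k in k_range:
        if k < 2 or k > corr.n_items:
            continue
        part = ward_partition(corr, k, merge_tree)
        if part.k != k:  # duplicate heights collapsed the cut
            continue
        q = _quality_for_k(corr, part, coords)
        floor_stat = q.per_cluster_pcc_min if use_min_pcc else q.per_cluster_pcc_mean
        q.admissible = (
            q.sc >= sc_min
            and not q.has_singleton
            and bool(np.all(floor_stat >= pcc_floor))
        )
        quality[k] = q
        partitions[k] = part

    admissible = [k for k in sorted(quality) if quality[k].admissible]
    chosen: int | None = None
    if admissible:
        best_sc = max(quality[k].sc for k in admissible)
        chosen = min(k for k in admissible if quality[k].sc >= best_sc - 1e-12)
    return FactorSolution(
        scale_id=scale_id or "scale",
        chosen_k=chosen,
        partition=partitions.get(chosen) if chosen is not None else None,
        quality=quality,
        labels=dict(labels or {}),
        prefix=prefix,
    )


def compute_factor_scores(
    dataset: SurveyDataset,
    solutions: dict[str, FactorSolution],
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Respondents x factors score matrix.

    The score of a respondent on a factor is the mean (default) or sum of
    the respondent's reverse-scored responses over the factor's items.
    Factor columns follow the scale-prefix convention, e.g. ``C-c1`` for
    the first CoVaH cluster. Scales whose solution has no admissible k are
    skipped.
    """
    if aggregator not in ("mean", "sum"):
        raise ValueError("aggregator must be 'mean' or 'sum'")
    if not dataset.reverse_applied:
        raise ValueError(
            "factor scores require reverse scoring; call reverse_score first"
        )
    columns: dict[str, pd.Series] = {}
    for scale_id, sol in solutions.items():
        if sol.partition is None:
            continue
        fids = sol.factor_ids()
        for c in range(sol.partition.k):
            block = dataset.responses[sol.partition.members(c)]
            agg = block.mean(axis=1) if aggregator == "mean" else block.sum(axis=1)
            columns[fids[c]] = agg.astype(float)
    scores = pd.DataFrame(columns, index=dataset.respondent_ids)
    if scores.isna().any().any() or not np.isfinite(scores.to_numpy()).all():
        raise ValueError("non-finite factor scores")
    return scores
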