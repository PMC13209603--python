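"""Cohort-level statistics over dysregulation calls and feature profiles.

Covers the four cohort stages: prevalence ranking of dysregulated
features with binomial confidence intervals, Ward clustering of scaled
feature profiles validated by silhouette / Calinski-Harabasz / Dunn
indices, PERMANOVA on the cluster separation, and per-feature Wilcoxon
rank-sum contrasts with Benjamini-Hochberg FDR control.

Two binomial CI methods are provided.  ``modified_wald`` is the
Agresti-Coull add-two-successes-and-failures interval,
``p~ = (x+2)/(n+4)`` with the usual normal half-width over ``n+4``;
``wald`` is the plain normal approximation.  Both are clamped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "binomial_ci",
    "prevalence_ranking",
    "ClusterResult",
    "cluster_heatmap",
    "dunn_index",
    "permanova",
    "feature_wilcoxon_bh",
]

DYSREGULATED_LABELS = frozenset({"moderate", "high"})


def binomial_ci(
    x: int, n: int, method: str = "wald", confidence: float = 0.95
) -> tuple[float, float]:
    """Binomial proportion confidence interval, clamped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    z = float(stats.norm.ppf(1 - (1 - confidence) / 2))
    if method == "wald":
        p = x / n
        half = z * np.sqrt(p * (1 - p) / n)
    elif method == "modified_wald":
        p = (x + 2) / (n + 4)
        half = z * np.sqrt(p * (1 - p) / (n + 4))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return (max(0.0, p - half), min(1.0, p + half))


def prevalence_ranking(
    calls: pd.DataFrame,
    n: int | None = None,
    ci_method: str = "wald",
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-feature prevalence of dysregulation (moderate or high),
    ranked by proportion descending, ties broken alphabetically.

    ``calls`` needs columns ``sample_id``, ``feature_name``, ``label``
    and must cover every sample x feature pair.
    """
    required = {"sample_id", "feature_name", "label"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls frame needs columns {sorted(required)}")
    samples = calls["sample_id"].unique()
    features = calls["feature_name"].unique()
    counts = calls.groupby("feature_name")["sample_id"].nunique()
    gaps = [
        f"{f}: {len(samples) - counts.get(f, 0)} samples missing"
        for f in features
        if counts.get(f, 0) != len(samples)
    ]
    if gaps:
        raise ValueError("incomplete calls: " + "; ".join(gaps))
    n = n if n is not None else len(samples)
    records = []
    for feature, group in calls.groupby("feature_name"):
        x = int(group["label"].isin(DYSREGULATED_LABELS).sum())
        low, high = binomial_ci(x, n, method=ci_method, confidence=confidence)
        records.append(
            {
                "feature_name": feature,
                "n": n,
                "x_dysregulated": x,
                "proportion": x / n,
                "ci_low": low,
                "ci_high": high,
                "ci_method": ci_method,
            }
        )
    out = pd.DataFrame(records).sort_values(
        ["proportion", "feature_name"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


@dataclass
class ClusterResult:
    assignments: pd.Series  # sample -> cluster id (1-based)
    k: int
    linkage: str
    distance: str
    silhouette: float
    calinski_harabasz: float
    dunn: float
    permanova_F: float
    permanova_R2: float
    permanova_p: float
    row_order: list
    col_order: list
    scaled: pd.DataFrame
    candidate_scores: dict


def dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-cluster distance over maximum cluster diameter."""
    uniq = np.unique(labels)
    min_between = np.inf
    max_diameter = 0.0
    for i, a in enumerate(uniq):
        ia = labels == a
        da = dist[np.ix_(ia, ia)]
        if da.size:
            max_diameter = max(max_diameter, float(da.max()))
        for b in uniq[i + 1 :]:
            ib = labels == b
            min_between = min(min_between, float(dist[np.ix_(ia, ib)].min()))
    if max_diameter == 0.0:
        raise ValueError("all points in every cluster identical")
    return min_between / max_diameter


def cluster_heatmap(
    profiles: pd.DataFrame,
    k_candidates=(2, 3, 4, 5, 6),
    n_permutations: int = 999,
    seed: int | None = None,
) -> ClusterResult:
    """Ward clustering of column-standardized feature profiles.

    Columns are z-scored (constant columns dropped with a warning),
    Ward linkage is computed on Euclidean distances, and among the
    candidate cluster counts the one maximizing the silhouette is kept;
    Calinski-Harabasz and Dunn are reported alongside and disagreements
    logged.  Cluster separation is then tested with PERMANOVA on the
    same scaled matrix.
    """
    if len(profiles) < 4:
        raise ValueError("clustering needs at least 4 samples")
    X = profiles.replace([np.inf, -np.inf], np.nan)
    X = X.dropna(axis=1, how="any")
    sd = X.std(axis=0, ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        logger.warning("dropping constant feature columns before scaling: %s", constant)
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValueError("no variable feature columns remain")
    scaled = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    mat = scaled.to_numpy()
    condensed = pdist(mat, metric="euclidean")
    if not np.any(condensed > 0):
        raise ValueError("all samples identical: no distance structure to cluster")
    Z = hierarchy.linkage(mat, method="ward")
    dist = squareform(condensed)
    candidate_scores = {}
    best_k, best_sil, best_labels = None, -np.inf, None
    for k in sorted(set(int(k) for k in k_candidates)):
        if not 2 <= k <= len(profiles) - 1:
            continue
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
        candidate_scores[k] = {
            "silhouette": sil,
            "calinski_harabasz": float(calinski_harabasz_score(mat, labels)),
            "dunn": float(dunn_index(dist, labels)),
        }
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    if best_k is None:
        raise ValueError("no valid clustering among the candidate k values")
    ch_best = max(candidate_scores, key=lambda k: candidate_scores[k]["calinski_harabasz"])
    dunn_best = max(candidate_scores, key=lambda k: candidate_scores[k]["dunn"])
    if len({best_k, ch_best, dunn_best}) > 1:
        logger.info(
            "validity indices disagree: silhouette->k=%d, CH->k=%d, Dunn->k=%d "
            "(silhouette arbitrates)",
            best_k,
            ch_best,
            dunn_best,
        )
    F, R2, p = permanova(
        pd.DataFrame(dist, index=scaled.index, columns=scaled.index),
        best_labels,
        n_permutations=n_permutations,
        seed=seed,
    )
    col_Z = hierarchy.linkage(mat.T, method="ward")
    return ClusterResult(
        assignments=pd.Series(best_labels, index=scaled.index, name="cluster"),
        k=best_k,
        linkage="ward",
        distance="euclidean",
        silhouette=best_sil,
        calinski_harabasz=candidate_scores[best_k]["calinski_harabasz"],
        dunn=candidate_scores[best_k]["dunn"],
        permanova_F=F,
        permanova_R2=R2,
        permanova_p=p,
        row_order=list(scaled.index[hierarchy.leaves_list(Z)]),
        col_order=list(scaled.columns[hierarchy.leaves_list(col_Z)]),
        scaled=scaled,
        candidate_scores=candidate_scores,
    )


def _distance_ss_partition(dist: np.ndarray, labels: np.ndarray):
    """Among/within sum-of-squares partition of a distance matrix."""
    n = len(dist)
    d2 = dist**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total - ss_within, ss_within, ss_total


def permanova(
    dist: pd.DataFrame | np.ndarray,
    group_labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Permutational MANOVA on a distance matrix.

    Returns (pseudo-F, R², p).  The p-value uses the add-one convention
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` and is therefore
    never below ``1/(1+n_permutations)``.
    """
    labels = np.asarray(group_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        singles = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"singleton groups not allowed: {singles}")
    arr = dist.to_numpy() if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    ss_among, ss_within, ss_total = _distance_ss_partition(arr, labels)
    if ss_total <= 0 or ss_within <= 0:
        raise ValueError("degenerate distance structure: pseudo-F undefined")
    n, k = len(labels), len(uniq)
    F = (ss_among / (k - 1)) / (ss_within / (n - k))
    R2 = ss_among / ss_total
    ids = [str(i) for i in range(n)]
    result = _skbio_permanova(
        DistanceMatrix(arr, ids=ids),
        grouping=[str(g) for g in labels],
        permutations=n_permutations,
        seed=seed,
    )
    skbio_F = float(result["test statistic"])
    if not np.isclose(skbio_F, F, rtol=1e-8):  # pragma: no cover - sanity guard
        raise AssertionError(f"pseudo-F mismatch: {skbio_F} vs {F}")
    return F, R2, float(result["p-value"])


def feature_wilcoxon_bh(
    profiles: pd.DataFrame, assignments, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum between two clusters,
    BH-adjusted across features; ``enriched_cluster`` is the cluster
    with the greater median."""
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 clusters required, got {len(uniq)}")
    a, b = uniq
    rows = []
    for feature in profiles.columns:
        va = profiles.loc[labels == a, feature].to_numpy(dtype=float)
        vb = profiles.loc[labels == b, feature].to_numpy(dtype=float)
        if np.ptp(np.concatenate([va, vb])) == 0:
            stat, p = np.nan, 1.0
        else:
            stat, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        med_a, med_b = np.median(va), np.median(vb)
        enriched = a if med_a > med_b else (b if med_b > med_a else a)
        rows.append(
            {
                "feature_name": feature,
                "statistic": float(stat) if np.isfinite(stat) else np.nan,
                "raw_p": float(p),
                "enriched_cluster": enriched,
            }
        )
    out = pd.DataFrame(rows)
    reject, adj, _, _ = multipletests(out["raw_p"], alpha=alpha, method="fdr_bh")
    out["adjusted_p"] = adj
    out["significant"] = reject
    return out
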