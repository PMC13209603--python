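"""Paired before/after diversity analysis.

Alpha diversity: Chao1 richness (classic and bias-corrected) and the
Shannon index, with paired Wilcoxon signed-rank testing of the deltas
and the share of pairs that increased.  Beta diversity: Bray-Curtis
dissimilarities, classical PCoA, PERMANOVA on batch labels, and PERMDISP
for homogeneity of dispersions (spatial medians).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permdisp as _skbio_permdisp
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .abundance import GenusAbundanceTable
from .features import shannon_index

logger = logging.getLogger(__name__)

__all__ = [
    "chao1",
    "PairedDiversityResult",
    "paired_change",
    "bray_curtis_matrix",
    "pcoa",
    "permdisp",
]


def chao1(counts, bias_corrected: bool = False) -> float:
    """Chao1 richness estimate from a single sample's counts.

    Classic form ``S_obs + F1^2 / (2 F2)`` using singleton (F1) and
    doubleton (F2) counts; the bias-corrected form
    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` is used when requested or
    when no doubletons exist (where the classic form is undefined).
    """
    c = np.asarray(counts)
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("Chao1 of an empty sample is undefined")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(c, np.rint(c)):
        raise ValueError("Chao1 requires integer counts")
    c = np.rint(c).astype(np.int64)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 * f1 / (2.0 * f2)


@dataclass
class PairedDiversityResult:
    metric: str
    per_pair: pd.DataFrame  # columns: before, after, delta
    mean_before: float
    mean_after: float
    prop_increased: float
    p_value: float
    test_used: str


def _metric_values(table: GenusAbundanceTable, metric: str, depth: int | None) -> pd.Series:
    if metric == "chao1":
        data = table.data
        if table.mode == "relative":
            if depth is None:
                raise ValueError(
                    "Chao1 needs counts; pass depth= to rescale relative abundances"
                )
            logger.warning(
                "rescaling relative abundances to depth %d for Chao1; "
                "rare-taxon counts are approximate",
                depth,
            )
            data = (data * depth).round()
        return pd.Series(
            [chao1(row) for row in data.to_numpy()], index=data.index
        )
    if metric == "shannon":
        return pd.Series(
            [shannon_index(row) for row in table.data.to_numpy()],
            index=table.data.index,
        )
    raise ValueError(f"unknown metric {metric!r}")


def paired_change(
    before: GenusAbundanceTable,
    after: GenusAbundanceTable,
    metric: str = "chao1",
    test: str = "wilcoxon",
    depth: int | None = None,
) -> PairedDiversityResult:
    """Per-pair diversity change with a two-sided paired test.

    Pairs are matched by sample id.  Zero deltas are excluded by the
    signed-rank convention; if every delta is zero the test is
    degenerate and p is reported as 1.
    """
    ids_b, ids_a = set(before.sample_ids), set(after.sample_ids)
    if ids_b != ids_a:
        missing = sorted(ids_b ^ ids_a)
        raise ValueError(f"unmatched sample ids between batches: {missing}")
    order = before.sample_ids
    vb = _metric_values(before, metric, depth)
    va = _metric_values(after, metric, depth).reindex(order)
    vb = vb.reindex(order)
    delta = va - vb
    n_pairs = len(order)
    if n_pairs < 5:
        warnings.warn("fewer than 5 pairs: paired test is unreliable", stacklevel=2)
    if test == "wilcoxon":
        nonzero = delta[delta != 0]
        if len(nonzero) == 0:
            p = 1.0
        else:
            p = float(
                stats.wilcoxon(nonzero, alternative="two-sided").pvalue
            )
    elif test == "t":
        if delta.std(ddof=1) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_rel(va, vb).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    per_pair = pd.DataFrame({"before": vb, "after": va, "delta": delta})
    return PairedDiversityResult(
        metric=metric,
        per_pair=per_pair,
        mean_before=float(vb.mean()),
        mean_after=float(va.mean()),
        prop_increased=float((delta > 0).mean()),
        p_value=p,
        test_used=test,
    )


def bray_curtis_matrix(table: GenusAbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities,
    ``BC(x, y) = sum |x_i - y_i| / sum (x_i + y_i)``, in [0, 1]."""
    data = table.data if isinstance(table, GenusAbundanceTable) else table
    arr = data.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    zero_rows = list(data.index[arr.sum(axis=1) == 0])
    if len(zero_rows) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero samples: {zero_rows}"
        )
    dist = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(dist, index=data.index, columns=data.index)


def pcoa(
    dist: pd.DataFrame, n_axes: int = 2
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Returns (coordinates, explained-variance fractions, number of
    negative eigenvalues).  Axes are restricted to positive eigenvalues;
    a request beyond those is truncated with a warning.
    """
    dm = DistanceMatrix(dist.to_numpy(), ids=[str(i) for i in dist.index])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    n_negative = int((eig < -1e-10).sum())
    positive = int((eig > 1e-10).sum())
    if n_axes > positive:
        warnings.warn(
            f"only {positive} positive eigenvalues; truncating to {positive} axes",
            stacklevel=2,
        )
        n_axes = positive
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.index = dist.index
    explained = res.proportion_explained.to_numpy()[:n_axes]
    return coords, explained, n_negative


def permdisp(
    dist: pd.DataFrame,
    group_labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Homogeneity of multivariate dispersions (PERMDISP).

    Member distances to each group's spatial median in PCoA space,
    compared by a permutation F test.  Returns (F, p).
    """
    labels = np.asarray(group_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMDISP needs at least 2 groups")
    if (counts < 2).any():
        singles = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"singleton groups not allowed: {singles}")
    dm = DistanceMatrix(dist.to_numpy(), ids=[str(i) for i in range(len(dist))])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_permdisp(
            dm,
            grouping=[str(g) for g in labels],
            test="median",
            permutations=n_permutations,
            seed=seed,
        )
    return float(res["test statistic"]), float(res["p-value"])
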