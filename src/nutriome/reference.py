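"""Reference-population percentile classification of feature values.

Each functional feature is compared against its distribution in a healthy
reference cohort.  The percentile of the individual's value determines a
three-level dysregulation call:

* ``neutral`` — reference-like values;
* ``moderate`` — percentile in [2.5, 25] for beneficial (low-tail)
  features or [75, 97.5] for prejudicial (high-tail) features;
* ``high`` — percentile below 2.5 (beneficial) or above 97.5
  (prejudicial).

Interval endpoints are assigned to the *less* extreme of the printed
bands they separate inward (2.5, 25, 75 and 97.5 are all ``moderate``),
a fixed convention pinned by tests.  References are fitted per feature:
a normal law when Shapiro-Wilk does not reject normality at 0.05, the
empirical CDF otherwise (methane-like zero-inflated features always fall
back to empirical).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .features import FeatureSet, compute_profiles

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceDistribution",
    "DysregulationCall",
    "ReferenceFitError",
    "OutlierRemovalError",
    "remove_reference_outliers",
    "fit_reference",
    "classify_dysregulation",
    "DysregulationClassifier",
    "calls_to_frame",
]

LABELS = ("neutral", "moderate", "high")
MIN_REFERENCE_N = 20


class ReferenceFitError(ValueError):
    """Raised when a reference distribution cannot be fitted."""


class OutlierRemovalError(ValueError):
    """Raised when PCA outlier screening would discard too many samples."""


@dataclass
class ReferenceDistribution:
    """A fitted per-feature reference law.

    ``model == "normal"`` uses the fitted mean/sd and the Gaussian CDF;
    ``model == "empirical"`` uses the midpoint-rank percentile
    ``100 * (#below + 0.5 * #equal) / n``, which avoids saturating at
    0/100 for in-range values.
    """

    feature_name: str
    model: str
    reference_values: np.ndarray
    fitted_mean: float | None = None
    fitted_sd: float | None = None
    normality_p: float = float("nan")

    @property
    def n(self) -> int:
        return int(len(self.reference_values))

    def percentile_of(self, x: float) -> float:
        if self.model == "normal":
            z = (x - self.fitted_mean) / self.fitted_sd
            return float(100.0 * stats.norm.cdf(z))
        v = self.reference_values
        below = int(np.sum(v < x))
        equal = int(np.sum(v == x))
        return float(100.0 * (below + 0.5 * equal) / len(v))

    def to_json(self) -> str:
        payload = {
            "feature_name": self.feature_name,
            "model": self.model,
            "n": self.n,
            "fitted_mean": self.fitted_mean,
            "fitted_sd": self.fitted_sd,
            "normality_p": self.normality_p,
            "reference_values": [float(v) for v in self.reference_values],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceDistribution":
        d = json.loads(text)
        return cls(
            feature_name=d["feature_name"],
            model=d["model"],
            reference_values=np.asarray(d["reference_values"], dtype=float),
            fitted_mean=d["fitted_mean"],
            fitted_sd=d["fitted_sd"],
            normality_p=d["normality_p"],
        )


@dataclass(frozen=True)
class DysregulationCall:
    sample_id: str
    feature_name: str
    percentile: float
    label: str
    direction_used: str


def calls_to_frame(calls: list[DysregulationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "feature_name": c.feature_name,
                "percentile": c.percentile,
                "label": c.label,
                "direction_used": c.direction_used,
            }
            for c in calls
        ]
    )


def remove_reference_outliers(
    reference: pd.DataFrame,
    k_sd: float = 3.0,
    allow_large_removal: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop reference samples that are PCA outliers.

    Samples whose score distance from the centroid in the first two
    principal components (each component standardized by its own SD)
    exceeds ``k_sd`` are removed.  Removing more than 20% of the cohort
    raises unless explicitly overridden — a screen that aggressive points
    at a batch problem, not individual outliers.
    """
    if len(reference) < 10:
        raise ValueError("outlier screening needs at least 10 reference samples")
    if math.isinf(k_sd):
        return reference.copy(), []
    X = reference.to_numpy(dtype=float)
    scores = PCA(n_components=2).fit_transform(X)
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    dist = np.sqrt(((scores / sd) ** 2).sum(axis=1))
    mask = dist > k_sd
    removed = [str(s) for s in reference.index[mask]]
    if len(removed) > 0.2 * len(reference) and not allow_large_removal:
        raise OutlierRemovalError(
            f"outlier screen would remove {len(removed)}/{len(reference)} samples "
            "(>20%); pass allow_large_removal=True to override"
        )
    if removed:
        logger.warning("removed %d PCA outliers: %s", len(removed), removed)
    return reference.loc[~mask], removed


def fit_reference(
    values,
    feature_name: str = "",
    force_model: str | None = None,
    alpha: float = 0.05,
) -> ReferenceDistribution:
    """Fit a per-feature reference law from cohort values.

    Non-finite values (e.g. flagged infinite phylum ratios) are excluded.
    Normality is assessed with Shapiro-Wilk; the normal model is used
    when not rejected at ``alpha``, else the empirical CDF.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < MIN_REFERENCE_N:
        raise ReferenceFitError(
            f"{feature_name or 'feature'}: need >= {MIN_REFERENCE_N} finite "
            f"reference values, got {len(v)} (percentiles unstable)"
        )
    if np.ptp(v) == 0:
        raise ReferenceFitError(
            f"{feature_name or 'feature'}: constant reference values (sd = 0)"
        )
    with np.errstate(all="ignore"):
        normality_p = float(stats.shapiro(v).pvalue)
    if force_model is not None:
        if force_model not in ("normal", "empirical"):
            raise ValueError(f"unknown model {force_model!r}")
        model = force_model
    else:
        model = "normal" if normality_p >= alpha else "empirical"
    mean = sd = None
    if model == "normal":
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1))
        if sd <= 0:
            raise ReferenceFitError(f"{feature_name}: zero SD under normal model")
    return ReferenceDistribution(
        feature_name=feature_name,
        model=model,
        reference_values=np.sort(v),
        fitted_mean=mean,
        fitted_sd=sd,
        normality_p=normality_p,
    )


def classify_dysregulation(percentile: float, tail_policy: str) -> str:
    """Map a percentile to neutral / moderate / high under a tail policy.

    Beneficial features flag the low tail, prejudicial the high tail;
    ``both`` flags either extreme, ``none`` never flags.  Shared interval
    endpoints (2.5, 25, 75, 97.5) belong to the moderate band.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile {percentile} outside [0, 100]")
    if tail_policy == "none":
        return "neutral"
    low_label = "neutral"
    if tail_policy in ("low", "both"):
        if percentile < 2.5:
            low_label = "high"
        elif percentile <= 25.0:
            low_label = "moderate"
    high_label = "neutral"
    if tail_policy in ("high", "both"):
        if percentile > 97.5:
            high_label = "high"
        elif percentile >= 75.0:
            high_label = "moderate"
    if tail_policy == "low":
        return low_label
    if tail_policy == "high":
        return high_label
    if tail_policy == "both":
        order = {"neutral": 0, "moderate": 1, "high": 2}
        return low_label if order[low_label] >= order[high_label] else high_label
    raise ValueError(f"unknown tail policy {tail_policy!r}")


class DysregulationClassifier:
    """Fit per-feature reference distributions; classify individuals.

    Parameters
    ----------
    feature_set:
        The active :class:`~nutriome.features.FeatureSet`.
    k_sd:
        PCA outlier cutoff applied to the reference profile matrix
        before fitting (``math.inf`` disables screening).
    force_models:
        Optional feature -> {"normal", "empirical"} overrides.
    """

    def __init__(
        self,
        feature_set: FeatureSet,
        k_sd: float = 3.0,
        force_models: dict[str, str] | None = None,
        phylum_of: dict[str, str] | None = None,
    ):
        self.feature_set = feature_set
        self.k_sd = k_sd
        self.force_models = dict(force_models or {})
        self.phylum_of = phylum_of
        self.references: dict[str, ReferenceDistribution] = {}
        self.removed_outliers: list[str] = []

    def fit(self, reference_table) -> "DysregulationClassifier":
        """Fit from a reference :class:`GenusAbundanceTable` or a
        precomputed profile DataFrame (samples x features)."""
        profiles = self._as_profiles(reference_table)
        if math.isinf(self.k_sd):
            self.removed_outliers = []
        else:
            # flagged infinities (phylum ratios) must not dominate the PCA
            finite = profiles.replace([np.inf, -np.inf], np.nan)
            finite = finite.fillna(finite.median(numeric_only=True))
            _, self.removed_outliers = remove_reference_outliers(finite, k_sd=self.k_sd)
            profiles = profiles.drop(index=self.removed_outliers)
        self.reference_profiles_ = profiles
        self.references = {}
        for definition in self.feature_set:
            if definition.tail_policy == "none":
                continue
            self.references[definition.name] = fit_reference(
                profiles[definition.name].to_numpy(),
                feature_name=definition.name,
                force_model=self.force_models.get(definition.name),
            )
        return self

    def _as_profiles(self, table) -> pd.DataFrame:
        if isinstance(table, pd.DataFrame):
            return table
        return compute_profiles(table, self.feature_set, self.phylum_of)

    def classify(self, table) -> list[DysregulationCall]:
        """Dysregulation calls for every sample x classified feature."""
        if not self.references:
            raise RuntimeError("classifier is not fitted")
        profiles = self._as_profiles(table)
        calls = []
        for sample_id, row in profiles.iterrows():
            for definition in self.feature_set:
                if definition.name not in self.references:
                    continue
                ref = self.references[definition.name]
                value = float(row[definition.name])
                if not math.isfinite(value):
                    # flagged descriptor (e.g. infinite phylum ratio):
                    # out past every reference value on the high side
                    pct = 100.0
                else:
                    pct = ref.percentile_of(value)
                label = classify_dysregulation(pct, definition.tail_policy)
                calls.append(
                    DysregulationCall(
                        sample_id=str(sample_id),
                        feature_name=definition.name,
                        percentile=pct,
                        label=label,
                        direction_used=definition.tail_policy,
                    )
                )
        return calls
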