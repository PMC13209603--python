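"""Map genus abundances to functional microbiome features.

A feature is either the summed relative abundance of a declared set of
member genera (e.g. the methane feature sums the six methanogen genera),
or a whole-community descriptor (Shannon diversity, a phylum ratio).
Membership is declarative configuration, not inference: the shipped YAML
roster carries 32 features of which only the methane and pathogen sets
are authoritative; the rest are editable placeholders.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .abundance import GenusAbundanceTable, to_relative

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureDefinition",
    "FeatureSet",
    "load_feature_sets",
    "default_feature_set",
    "compute_feature_value",
    "compute_profiles",
    "shannon_index",
    "phylum_ratio",
    "pathogen_screen",
    "METHANE_GENERA",
    "PATHOGEN_GENERA",
]

# Published, fixed genus sets.
METHANE_GENERA = (
    "Methanosphaera",
    "Methanobrevibacter",
    "Methanobacterium",
    "Methanosarcina",
    "Methanococcus",
    "Methanospirillum",
)
PATHOGEN_GENERA = (
    "Clostridioides",
    "Enterococcus",
    "Klebsiella",
    "Morganella",
    "Salmonella",
    "Shigella",
)

_DIRECTIONS = ("beneficial", "prejudicial", "informational")
_TAIL_POLICIES = ("low", "high", "both", "none")
_KINDS = ("abundance", "shannon", "phylum_ratio")


@dataclass(frozen=True)
class FeatureDefinition:
    """One functional feature: a genus set plus its flagging semantics."""

    name: str
    direction: str
    tail_policy: str
    recommendation_key: str
    member_genera: tuple[str, ...] = ()
    kind: str = "abundance"
    numerator_phylum: str | None = None
    denominator_phylum: str | None = None
    shannon_base: float = 2.0

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"{self.name}: bad direction {self.direction!r}")
        if self.tail_policy not in _TAIL_POLICIES:
            raise ValueError(f"{self.name}: bad tail_policy {self.tail_policy!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"{self.name}: bad kind {self.kind!r}")
        if self.direction == "informational" and self.tail_policy != "none":
            raise ValueError(
                f"{self.name}: informational features must have tail_policy 'none'"
            )
        if self.kind == "abundance":
            if not self.member_genera:
                raise ValueError(f"{self.name}: abundance feature needs member genera")
            lowered = [g.lower() for g in self.member_genera]
            if len(set(lowered)) != len(lowered):
                raise ValueError(f"{self.name}: duplicate member genera")
        if self.kind == "phylum_ratio" and not (
            self.numerator_phylum and self.denominator_phylum
        ):
            raise ValueError(f"{self.name}: phylum_ratio needs both phyla")


class FeatureSet:
    """Ordered collection of :class:`FeatureDefinition`, unique by name."""

    def __init__(self, definitions: list[FeatureDefinition]):
        names = [d.name for d in definitions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        self._defs = list(definitions)
        self._by_name = {d.name: d for d in definitions}

    def __iter__(self):
        return iter(self._defs)

    def __len__(self) -> int:
        return len(self._defs)

    def __getitem__(self, name: str) -> FeatureDefinition:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [d.name for d in self._defs]

    def all_member_genera(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self._defs:
            for g in d.member_genera:
                seen.setdefault(g, None)
        return list(seen)


def load_feature_sets(path) -> tuple[FeatureSet, dict[str, str]]:
    """Load a feature-definition YAML; returns (features, genus->phylum)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    defs = []
    for entry in doc["features"]:
        defs.append(
            FeatureDefinition(
                name=entry["name"],
                direction=entry["direction"],
                tail_policy=entry["tail_policy"],
                recommendation_key=entry.get("recommendation_key", entry["name"]),
                member_genera=tuple(entry.get("member_genera", ())),
                kind=entry.get("kind", "abundance"),
                numerator_phylum=entry.get("numerator_phylum"),
                denominator_phylum=entry.get("denominator_phylum"),
            )
        )
    return FeatureSet(defs), dict(doc.get("phyla", {}))


def default_feature_set() -> tuple[FeatureSet, dict[str, str]]:
    """The packaged 32-feature roster and its genus->phylum map."""
    with resources.as_file(
        resources.files("nutriome.data").joinpath("features.yaml")
    ) as p:
        return load_feature_sets(p)


_warned_missing: set[tuple[str, str]] = set()


def _genus_lookup(index) -> dict[str, str]:
    return {str(g).lower(): g for g in index}


def compute_feature_value(sample: pd.Series, definition: FeatureDefinition) -> float:
    """Summed relative abundance of the feature's member genera.

    Genus matching is case-insensitive and exact; a member genus absent
    from the table contributes 0 and is warned about once per process.
    """
    if definition.kind != "abundance":
        raise ValueError(f"{definition.name} is a descriptor, not an abundance feature")
    lookup = _genus_lookup(sample.index)
    total = 0.0
    for genus in definition.member_genera:
        col = lookup.get(genus.lower())
        if col is None:
            key = (definition.name, genus)
            if key not in _warned_missing:
                _warned_missing.add(key)
                logger.warning(
                    "feature %s: member genus %s absent from table, contributes 0",
                    definition.name,
                    genus,
                )
            continue
        total += float(sample[col])
    return total


def shannon_index(sample: pd.Series | np.ndarray, log_base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log(p_i), zero entries skipped.

    Base 2 by default (the upstream amplicon toolchain convention);
    natural log available via ``log_base=math.e``.
    """
    p = np.asarray(sample, dtype=float)
    if p.size == 0 or p.sum() <= 0:
        raise ValueError("Shannon index of an empty sample is undefined")
    p = p / p.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(log_base))


def phylum_ratio(
    sample: pd.Series,
    numerator_phylum: str,
    denominator_phylum: str,
    phylum_of: dict[str, str],
) -> float:
    """Summed numerator-phylum abundance over summed denominator-phylum
    abundance; an absent denominator yields +inf (flagged, excluded from
    reference fitting), never a crash."""
    num = 0.0
    den = 0.0
    for genus, value in sample.items():
        phylum = phylum_of.get(str(genus))
        if phylum == numerator_phylum:
            num += float(value)
        elif phylum == denominator_phylum:
            den += float(value)
    if den == 0.0:
        return math.inf
    return num / den


def pathogen_screen(
    sample: pd.Series,
    pathogen_genera: tuple[str, ...] = PATHOGEN_GENERA,
    detection_threshold: float = 0.0,
) -> dict[str, bool]:
    """Presence call per pathogen genus: present iff abundance > threshold."""
    lookup = _genus_lookup(sample.index)
    out = {}
    for genus in pathogen_genera:
        col = lookup.get(genus.lower())
        out[genus] = bool(col is not None and float(sample[col]) > detection_threshold)
    return out


def compute_profiles(
    table: GenusAbundanceTable,
    feature_set: FeatureSet,
    phylum_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample feature profile matrix (samples x features).

    Counts tables are converted to relative abundances first.  Descriptor
    features (Shannon, phylum ratios) are computed on the same rows.
    """
    rel = table if table.mode == "relative" else to_relative(table)
    phylum_of = phylum_of if phylum_of is not None else (table.phylum_of or {})
    values = np.empty((rel.n_samples, len(feature_set)))
    for j, definition in enumerate(feature_set):
        if definition.kind == "abundance":
            lookup = _genus_lookup(rel.data.columns)
            cols = [
                lookup[g.lower()] for g in definition.member_genera if g.lower() in lookup
            ]
            for g in definition.member_genera:
                if g.lower() not in lookup:
                    compute_feature_value(rel.data.iloc[0], definition)  # warn path
                    break
            values[:, j] = (
                rel.data[cols].sum(axis=1).to_numpy() if cols else 0.0
            )
        elif definition.kind == "shannon":
            values[:, j] = [
                shannon_index(row, definition.shannon_base)
                for _, row in rel.data.iterrows()
            ]
        else:  # phylum_ratio
            values[:, j] = [
                phylum_ratio(
                    row,
                    definition.numerator_phylum,
                    definition.denominator_phylum,
                    phylum_of,
                )
                for _, row in rel.data.iterrows()
            ]
    return pd.DataFrame(values, index=rel.data.index, columns=feature_set.names)
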