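"""Biomarker classification, recommendations, and report rendering.

Blood biomarkers are classified against reference ranges into optimal /
borderline / critical, with "borderline" defined by a configurable
margin fraction of the range width (default 0.1) since no numeric
convention is published.  Per-individual results — dysregulation calls,
nutrigenetic risk labels, biomarkers, and the recommendation texts they
trigger — are assembled into a :class:`ReportBundle` and rendered
deterministically to Markdown or JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .reference import DysregulationCall

logger = logging.getLogger(__name__)

__all__ = [
    "BiomarkerRecord",
    "classify_biomarker",
    "classify_biomarker_table",
    "load_biomarker_ranges",
    "default_biomarker_ranges",
    "cohort_in_range_summary",
    "adherence_aggregate",
    "Recommendations",
    "default_recommendations",
    "ReportBundle",
    "ReportError",
    "render_report",
]

STATUSES = ("optimal", "borderline", "critical")
ADHERENCE_BANDS = ("0-25", "25-50", "50-75", "75-100")


class ReportError(KeyError):
    """Raised when a report cannot be rendered completely."""


@dataclass(frozen=True)
class BiomarkerRecord:
    analyte: str
    value: float
    unit: str
    range_low: float
    range_high: float
    status: str
    borderline_margin: float


def classify_biomarker(
    value: float, range_low: float, range_high: float, margin: float = 0.1
) -> str:
    """Optimal inside the range; borderline within ``margin * width``
    outside it; critical beyond that."""
    if not range_low < range_high:
        raise ValueError(f"inverted range [{range_low}, {range_high}]")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if range_low <= value <= range_high:
        return "optimal"
    width = range_high - range_low
    excess = (range_low - value) if value < range_low else (value - range_high)
    return "borderline" if excess <= margin * width else "critical"


def load_biomarker_ranges(path) -> tuple[dict, float]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return dict(doc["analytes"]), float(doc.get("borderline_margin", 0.1))


def default_biomarker_ranges() -> tuple[dict, float]:
    with resources.as_file(
        resources.files("nutriome.data").joinpath("biomarker_ranges.yaml")
    ) as p:
        return load_biomarker_ranges(p)


def classify_biomarker_table(
    values: pd.DataFrame,
    ranges: dict | None = None,
    margin: float | None = None,
) -> list[BiomarkerRecord]:
    """Classify a frame with columns ``analyte``, ``value`` (and
    optionally ``unit``) against the configured reference ranges."""
    if ranges is None:
        ranges, default_margin = default_biomarker_ranges()
        margin = default_margin if margin is None else margin
    margin = 0.1 if margin is None else margin
    records = []
    for _, row in values.iterrows():
        analyte = str(row["analyte"])
        if analyte not in ranges:
            raise KeyError(f"no reference range configured for {analyte!r}")
        spec = ranges[analyte]
        status = classify_biomarker(
            float(row["value"]), spec["range_low"], spec["range_high"], margin
        )
        records.append(
            BiomarkerRecord(
                analyte=analyte,
                value=float(row["value"]),
                unit=str(row.get("unit", spec.get("unit", ""))),
                range_low=float(spec["range_low"]),
                range_high=float(spec["range_high"]),
                status=status,
                borderline_margin=margin,
            )
        )
    return records


def cohort_in_range_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte percentage in range (optimal) vs out of range
    (borderline + critical); the two shares sum to 100 per analyte."""
    if not {"analyte", "status"}.issubset(records.columns):
        raise ValueError("need columns 'analyte' and 'status'")
    bad = set(records["status"]) - set(STATUSES)
    if bad:
        raise ValueError(f"unknown statuses: {sorted(bad)}")
    rows = []
    for analyte, group in records.groupby("analyte"):
        if len(group) == 0:  # pragma: no cover - groupby yields no empty groups
            logger.warning("analyte %s has no records; excluded", analyte)
            continue
        in_pct = 100.0 * (group["status"] == "optimal").mean()
        rows.append(
            {
                "analyte": analyte,
                "n": len(group),
                "in_range_pct": in_pct,
                "out_of_range_pct": 100.0 - in_pct,
            }
        )
    return pd.DataFrame(rows)


def adherence_aggregate(band_percentages: dict[str, float]) -> float:
    """Percent of participants following at least 25% of recommendations:
    the sum of the 25-50, 50-75 and 75-100 bands."""
    missing = [b for b in ADHERENCE_BANDS if b not in band_percentages]
    if missing:
        raise ValueError(f"missing adherence bands: {missing}")
    total = sum(float(band_percentages[b]) for b in ADHERENCE_BANDS)
    if abs(total - 100.0) > 0.5:
        raise ValueError(f"band percentages sum to {total}, not 100 +/- 0.5")
    return float(sum(float(band_percentages[b]) for b in ADHERENCE_BANDS[1:]))


class Recommendations:
    """(key, label) -> text lookup with per-section default templates."""

    def __init__(self, features: dict, genetics: dict):
        self._sections = {"features": dict(features), "genetics": dict(genetics)}

    @classmethod
    def from_yaml(cls, path) -> "Recommendations":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(features=doc.get("features", {}), genetics=doc.get("genetics", {}))

    def resolve(self, section: str, key: str, label: str) -> str:
        table = self._sections[section]
        entry = table.get(key, {})
        if label in entry:
            return str(entry[label])
        default = table.get("default", {})
        if label in default:
            return str(default[label])
        raise ReportError(
            f"no recommendation text for {section} key {key!r}, label {label!r}"
        )


def default_recommendations() -> Recommendations:
    with resources.as_file(
        resources.files("nutriome.data").joinpath("recommendations.yaml")
    ) as p:
        return Recommendations.from_yaml(p)


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything needed to render one individual's report."""

    sample_id: str
    dysregulation_calls: list[DysregulationCall] = field(default_factory=list)
    risk_labels: list[dict] = field(default_factory=list)
    biomarkers: list[BiomarkerRecord] = field(default_factory=list)
    recommendation_keys: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.provenance.setdefault("bundle_digest", "")
        payload = {
            "sample_id": self.sample_id,
            "calls": [vars(c) | {} for c in self.dysregulation_calls],
            "risk_labels": self.risk_labels,
            "biomarkers": [vars(b) | {} for b in self.biomarkers],
        }
        self.provenance["bundle_digest"] = _digest(payload)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "dysregulation_calls": [
                {
                    "feature_name": c.feature_name,
                    "percentile": c.percentile,
                    "label": c.label,
                    "direction_used": c.direction_used,
                }
                for c in self.dysregulation_calls
            ],
            "risk_labels": self.risk_labels,
            "biomarkers": [
                {
                    "analyte": b.analyte,
                    "value": b.value,
                    "unit": b.unit,
                    "range_low": b.range_low,
                    "range_high": b.range_high,
                    "status": b.status,
                    "borderline_margin": b.borderline_margin,
                }
                for b in self.biomarkers
            ],
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def render_report(
    bundle: ReportBundle,
    recommendations: Recommendations | None = None,
    format: str = "markdown",
) -> str:
    """Render a bundle deterministically.

    Every non-neutral dysregulation call and every informative genetic
    risk label carries its recommendation text; an unresolvable key is
    an error, never a silent omission.  An all-neutral bundle renders an
    explicit all-clear section.
    """
    recommendations = recommendations or default_recommendations()
    flagged = [c for c in bundle.dysregulation_calls if c.label != "neutral"]
    texts: list[tuple[str, str, str]] = []
    for call in flagged:
        key = bundle.recommendation_keys.get(call.feature_name, call.feature_name)
        texts.append(
            (call.feature_name, call.label, recommendations.resolve("features", key, call.label))
        )
    genetic_texts: list[tuple[str, str, str]] = []
    for lab in bundle.risk_labels:
        genetic_texts.append(
            (
                lab["subcategory"],
                lab["label"],
                recommendations.resolve("genetics", lab["subcategory"], lab["label"]),
            )
        )
    if format == "json":
        doc = bundle.to_dict()
        doc["recommendations"] = {
            "microbiome": [
                {"feature": f, "label": l, "text": t} for f, l, t in texts
            ],
            "genetics": [
                {"subcategory": s, "label": l, "text": t} for s, l, t in genetic_texts
            ],
        }
        return json.dumps(doc, sort_keys=True, indent=2)
    if format != "markdown":
        raise ValueError(f"unknown format {format!r}")

    lines = [f"# Personalized nutrition report — {bundle.sample_id}", ""]
    if bundle.dysregulation_calls:
        lines += ["## Gut microbiome features", ""]
        lines += ["| feature | percentile | status |", "|---|---|---|"]
        for c in bundle.dysregulation_calls:
            lines.append(f"| {c.feature_name} | {c.percentile:.1f} | {c.label} |")
        lines.append("")
        if texts:
            lines += ["### Recommendations", ""]
            for feature, label, text in texts:
                lines.append(f"- **{feature}** ({label}): {text}")
            lines.append("")
        else:
            lines += [
                "### All clear",
                "",
                "All assessed microbiome features are within the reference "
                "range; no microbiome recommendation applies.",
                "",
            ]
    if bundle.risk_labels:
        lines += ["## Nutrigenetic risk labels", ""]
        lines += ["| subcategory | label | score |", "|---|---|---|"]
        for lab in bundle.risk_labels:
            score = lab.get("score")
            score_str = "-" if score is None or score != score else f"{score:.2f}"
            lines.append(f"| {lab['subcategory']} | {lab['label']} | {score_str} |")
        lines.append("")
        for subcategory, label, text in genetic_texts:
            lines.append(f"- **{subcategory}** ({label}): {text}")
        lines.append("")
    if bundle.biomarkers:
        lines += ["## Blood biomarkers", ""]
        lines += [
            "| analyte | value | reference range | status |",
            "|---|---|---|---|",
        ]
        for b in bundle.biomarkers:
            lines.append(
                f"| {b.analyte} | {b.value:g} {b.unit} | "
                f"[{b.range_low:g}, {b.range_high:g}] | {b.status} |"
            )
        lines += [
            "",
            f"Borderline margin: {bundle.biomarkers[0].borderline_margin:g} "
            "of the reference-range width.",
            "",
        ]
    lines += [
        "---",
        f"Provenance: {json.dumps(bundle.provenance, sort_keys=True)}",
        "",
    ]
    return "\n".join(lines)
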