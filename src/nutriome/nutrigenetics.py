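"""Nutrigenetic panel: genotype extraction, risk labels, frequency QC.

A panel of up to 300 variants in 7 categories / 39 subcategories is read
from YAML.  Per sample and subcategory, an additive weighted risk-allele
dosage score (normalized to [0, 1]) is mapped through configurable
thresholds to one of the study's nine labels: the risk-graded set
(no risk / low risk / medium risk / moderate risk / high risk), the
valence set (favorable / neutral / unfavorable), plus ``non-informative``
when too many genotype calls are missing.  Cohort allele frequencies are
compared against a reference population with per-variant Fisher exact
tests and Benjamini-Hochberg FDR control.

The published report does not disclose its label-assignment rules; the
additive score with per-subcategory thresholds is this package's rule
engine, shipped with a demonstration rule file, and every label cites
the rule version that produced it.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PanelVariant",
    "Panel",
    "SubcategoryRule",
    "RiskLabel",
    "load_panel",
    "load_rules",
    "default_panel",
    "default_rules",
    "demo_panel",
    "extract_panel_genotypes",
    "subcategory_label",
    "label_cohort",
    "allele_frequency_comparison",
]

CATEGORIES = (
    "Vitamins and minerals",
    "Food intolerance",
    "Dietary habits",
    "Response to diet",
    "Metabolic diseases",
    "Response to physical exercise",
    "Methylation profile",
)
RISK_GRADED_LABELS = ("no risk", "low risk", "medium risk", "moderate risk", "high risk")
VALENCE_LABELS = ("favorable", "neutral", "unfavorable")
NON_INFORMATIVE = "non-informative"
MAX_PANEL_VARIANTS = 300
MAX_SUBCATEGORIES = 39


@dataclass(frozen=True)
class PanelVariant:
    variant_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    risk_allele: str
    category: str
    subcategory: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"{self.variant_id}: unknown category {self.category!r}"
            )
        if self.weight <= 0:
            raise ValueError(f"{self.variant_id}: weight must be positive")
        if self.risk_allele not in (self.ref, self.alt):
            raise ValueError(
                f"{self.variant_id}: risk allele {self.risk_allele!r} is neither "
                f"REF {self.ref!r} nor ALT {self.alt!r}"
            )


class Panel:
    """Ordered panel of variants, unique by id, one subcategory each."""

    def __init__(self, variants: list[PanelVariant]):
        ids = [v.variant_id for v in variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in panel")
        if len(variants) > MAX_PANEL_VARIANTS:
            raise ValueError(f"panel exceeds {MAX_PANEL_VARIANTS} variants")
        subcats = {v.subcategory for v in variants}
        if len(subcats) > MAX_SUBCATEGORIES:
            raise ValueError(f"panel exceeds {MAX_SUBCATEGORIES} subcategories")
        self._variants = list(variants)
        self._by_id = {v.variant_id: v for v in variants}

    def __iter__(self):
        return iter(self._variants)

    def __len__(self) -> int:
        return len(self._variants)

    def __getitem__(self, variant_id: str) -> PanelVariant:
        return self._by_id[variant_id]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._by_id

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self._variants]

    @property
    def subcategories(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self._variants:
            seen.setdefault(v.subcategory, None)
        return list(seen)

    def by_subcategory(self, subcategory: str) -> list[PanelVariant]:
        out = [v for v in self._variants if v.subcategory == subcategory]
        if not out:
            raise ValueError(f"empty subcategory panel: {subcategory!r}")
        return out


@dataclass(frozen=True)
class SubcategoryRule:
    """Threshold rule mapping a normalized score to a label set."""

    subcategory: str
    label_set: str  # "risk-graded" | "valence"
    score_thresholds: tuple[float, ...]
    max_missing_fraction: float = 0.34
    version: str = "demo-1"

    def __post_init__(self) -> None:
        labels = self.labels
        if len(self.score_thresholds) != len(labels) - 1:
            raise ValueError(
                f"{self.subcategory}: need {len(labels) - 1} thresholds for "
                f"{self.label_set}"
            )
        if any(
            b <= a for a, b in zip(self.score_thresholds, self.score_thresholds[1:])
        ):
            raise ValueError(f"{self.subcategory}: thresholds must strictly increase")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.label_set == "risk-graded":
            return RISK_GRADED_LABELS
        if self.label_set == "valence":
            return VALENCE_LABELS
        raise ValueError(f"unknown label set {self.label_set!r}")

    def label_for_score(self, score: float) -> str:
        return self.labels[bisect_right(self.score_thresholds, score)]


@dataclass(frozen=True)
class RiskLabel:
    sample_id: str
    subcategory: str
    label: str
    score: float
    n_informative: int
    rule_version: str


def load_panel(path) -> Panel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return Panel(
        [
            PanelVariant(
                variant_id=e["variant_id"],
                gene=e["gene"],
                chrom=str(e["chrom"]),
                pos=int(e["pos"]),
                ref=e["ref"],
                alt=e["alt"],
                risk_allele=e.get("risk_allele", e["alt"]),
                category=e["category"],
                subcategory=e["subcategory"],
                weight=float(e.get("weight", 1.0)),
            )
            for e in doc["panel"]
        ]
    )


def load_rules(path) -> dict[str, SubcategoryRule]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    version = str(doc.get("version", "demo-1"))
    defaults = doc.get("defaults", {})
    rules = {}
    for e in doc["rules"]:
        rules[e["subcategory"]] = SubcategoryRule(
            subcategory=e["subcategory"],
            label_set=e.get("label_set", defaults.get("label_set", "risk-graded")),
            score_thresholds=tuple(
                e.get("score_thresholds", defaults.get("score_thresholds"))
            ),
            max_missing_fraction=float(
                e.get(
                    "max_missing_fraction", defaults.get("max_missing_fraction", 0.34)
                )
            ),
            version=version,
        )
    return rules


def default_panel() -> Panel:
    with resources.as_file(resources.files("nutriome.data").joinpath("panel.yaml")) as p:
        return load_panel(p)


def default_rules() -> dict[str, SubcategoryRule]:
    with resources.as_file(resources.files("nutriome.data").joinpath("rules.yaml")) as p:
        return load_rules(p)


_BASES = ("A", "C", "G", "T")


def demo_panel(n_variants: int = MAX_PANEL_VARIANTS, seed: int = 0) -> Panel:
    """A schematic full-size panel: ``n_variants`` synthetic rsIDs spread
    over the 7 categories and 39 subcategories (the published variant
    list is not in scope; this stands in for pipeline-scale runs)."""
    if not 1 <= n_variants <= MAX_PANEL_VARIANTS:
        raise ValueError(f"n_variants must be in [1, {MAX_PANEL_VARIANTS}]")
    rng = np.random.default_rng(seed)
    subcats = [
        (CATEGORIES[i % len(CATEGORIES)], f"subcategory_{i + 1:02d}")
        for i in range(MAX_SUBCATEGORIES)
    ]
    variants = []
    for j in range(n_variants):
        category, subcategory = subcats[j % len(subcats)]
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        variants.append(
            PanelVariant(
                variant_id=f"rs9{j + 1:06d}",
                gene=f"GENE{j % 160 + 1:03d}",
                chrom=str(j % 22 + 1),
                pos=100_000 + 1_000 * j,
                ref=_BASES[ref],
                alt=_BASES[alt],
                risk_allele=_BASES[alt],
                category=category,
                subcategory=subcategory,
            )
        )
    return Panel(variants)


def extract_panel_genotypes(
    vcf_path, panel: Panel
) -> tuple[pd.DataFrame, list[dict]]:
    """Risk-allele dosage matrix (samples x panel variants) from a VCF.

    Matching is by rsID first, then by chromosome:position.  Dosage is
    the count of risk alleles in the called genotype (0/1/2); uncalled
    or partially called genotypes are missing (NaN).  Records whose
    alleles cannot represent the configured risk allele are reported in
    the mismatch list and left missing — never silently flipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    by_id = {v.variant_id: v for v in panel}
    by_pos = {(v.chrom, v.pos): v for v in panel}
    matrix = pd.DataFrame(
        np.nan, index=samples, columns=panel.variant_ids, dtype=float
    )
    mismatches: list[dict] = []
    seen: set[str] = set()
    for record in vcf:
        variant = by_id.get(record.ID) or by_pos.get((str(record.CHROM), record.POS))
        if variant is None:
            continue
        seen.add(variant.variant_id)
        alleles = [record.REF] + list(record.ALT)
        if variant.risk_allele not in alleles:
            mismatches.append(
                {
                    "variant_id": variant.variant_id,
                    "reason": "risk allele not among record alleles",
                    "record_alleles": alleles,
                    "risk_allele": variant.risk_allele,
                }
            )
            continue
        risk_index = alleles.index(variant.risk_allele)
        dosages = np.full(len(samples), np.nan)
        for i, gt in enumerate(record.genotypes):
            pair = gt[:-1]  # last element is the phasing flag
            if any(a is None or a < 0 for a in pair) or len(pair) < 2:
                continue
            dosages[i] = sum(1 for a in pair if a == risk_index)
        matrix[variant.variant_id] = dosages
    unseen = [vid for vid in panel.variant_ids if vid not in seen]
    if unseen:
        logger.warning(
            "%d panel variants absent from VCF (left missing): %s",
            len(unseen),
            unseen[:10],
        )
    return matrix, mismatches


def subcategory_label(
    dosages: pd.Series,
    rule: SubcategoryRule,
    variants: list[PanelVariant],
    sample_id: str = "",
) -> RiskLabel:
    """Label one sample's subcategory from its variant dosages.

    Score = sum(weight * dosage) over informative variants, normalized
    by sum(2 * weight) over the same variants, so it lies in [0, 1].
    The label is ``non-informative`` when the missing-call fraction
    exceeds the rule's tolerance (or nothing is informative).
    """
    if not variants:
        raise ValueError("empty subcategory panel")
    weights = np.array([v.weight for v in variants])
    values = np.array(
        [dosages.get(v.variant_id, np.nan) for v in variants], dtype=float
    )
    informative = np.isfinite(values)
    n_info = int(informative.sum())
    missing_fraction = 1.0 - n_info / len(variants)
    if n_info == 0 or missing_fraction > rule.max_missing_fraction:
        return RiskLabel(
            sample_id=sample_id,
            subcategory=rule.subcategory,
            label=NON_INFORMATIVE,
            score=float("nan"),
            n_informative=n_info,
            rule_version=rule.version,
        )
    score = float(
        (weights[informative] * values[informative]).sum()
        / (2.0 * weights[informative].sum())
    )
    return RiskLabel(
        sample_id=sample_id,
        subcategory=rule.subcategory,
        label=rule.label_for_score(score),
        score=score,
        n_informative=n_info,
        rule_version=rule.version,
    )


def label_cohort(
    dosage_matrix: pd.DataFrame,
    panel: Panel,
    rules: dict[str, SubcategoryRule],
) -> pd.DataFrame:
    """Risk labels for every sample x subcategory in the panel."""
    rows = []
    for subcategory in panel.subcategories:
        if subcategory not in rules:
            raise ValueError(f"no rule configured for subcategory {subcategory!r}")
        variants = panel.by_subcategory(subcategory)
        rule = rules[subcategory]
        for sample_id, dosages in dosage_matrix.iterrows():
            lab = subcategory_label(dosages, rule, variants, sample_id=str(sample_id))
            rows.append(
                {
                    "sample_id": lab.sample_id,
                    "subcategory": lab.subcategory,
                    "label": lab.label,
                    "score": lab.score,
                    "n_informative": lab.n_informative,
                    "rule_version": lab.rule_version,
                }
            )
    return pd.DataFrame(rows)


def allele_frequency_comparison(
    dosage_matrix: pd.DataFrame,
    reference: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cohort vs reference allele-frequency comparison per variant.

    ``reference`` is indexed by variant id with columns ``ref_freq``
    (risk-allele frequency) and ``n_chromosomes``.  Each variant gets a
    two-sided Fisher exact test on the 2x2 allele-count table, then
    Benjamini-Hochberg adjustment across all tested variants;
    ``significant`` means adjusted p < alpha.
    """
    if len(dosage_matrix) < 10:
        raise ValueError("allele-frequency comparison needs a cohort of >= 10")
    rows = []
    for vid in dosage_matrix.columns:
        if vid not in reference.index:
            raise ValueError(f"reference does not cover variant {vid!r}")
        col = dosage_matrix[vid]
        called = col.notna()
        n1 = 2 * int(called.sum())
        if n1 == 0:
            logger.warning("variant %s has zero called alleles; excluded", vid)
            continue
        x1 = int(col[called].sum())
        n2 = int(reference.loc[vid, "n_chromosomes"])
        x2 = int(round(float(reference.loc[vid, "ref_freq"]) * n2))
        _, p = stats.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])
        rows.append(
            {
                "variant_id": vid,
                "cohort_freq": x1 / n1,
                "ref_freq": float(reference.loc[vid, "ref_freq"]),
                "cohort_alleles": n1,
                "ref_alleles": n2,
                "raw_p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no testable variants")
    reject, adj, _, _ = multipletests(out["raw_p"], alpha=alpha, method="fdr_bh")
    out["adjusted_p"] = adj
    out["significant"] = reject
    return out
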