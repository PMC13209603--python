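"""Synthetic inputs for every pipeline stage.

Nothing in the pipeline's real data setting is deposited publicly, so the
package generates its own test substrate:

* reference cohorts of genus counts (log-normal intensities normalized to
  the simplex, multinomially sampled at a random sequencing depth) — the
  stand-in for the 194-individual European reference;
* individual samples planted at a chosen feature percentile, so the
  percentile classifier's calls can be checked against ground truth;
* paired before/after cohorts with planted richness gains in a chosen
  fraction of pairs, emulating a one-month follow-up design;
* panel genotypes drawn under Hardy-Weinberg equilibrium, written as
  minimal VCF v4.2.

All randomness flows through one explicitly seeded
:class:`numpy.random.Generator`; identical specs and seeds yield
byte-identical outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import GenusAbundanceTable, to_relative
from .features import FeatureSet, compute_profiles

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticCohortSpec",
    "PlantedEffect",
    "PairedEffectSpec",
    "demo_genus_names",
    "generate_reference_cohort",
    "plant_feature_percentile",
    "generate_paired_cohort",
    "generate_genotypes",
    "hwe_chi_square_p",
]

_ABUNDANCE_LAWS = ("lognormal-dirichlet", "uniform")


def demo_genus_names(n: int, feature_set: FeatureSet | None = None) -> list[str]:
    """``n`` genus names; the genera referenced by ``feature_set`` come
    first so every configured feature is computable, padded with
    placeholder names."""
    names: list[str] = []
    if feature_set is not None:
        names = feature_set.all_member_genera()[:n]
    names += [f"Genus_{i:04d}" for i in range(len(names), n)]
    return names[:n]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Conditions for one synthetic genus-count cohort.

    Defaults mirror the reference-cohort setting the pipeline targets:
    194 samples, heavy-tailed (log-normal) genus abundances, amplicon
    depths in the tens of thousands.
    """

    n_samples: int = 194
    n_genera: int = 120
    abundance_law: str = "lognormal-dirichlet"
    law_params: dict = field(
        default_factory=lambda: {"mu_spread": 1.5, "sigma": 0.6}
    )
    sequencing_depth_range: tuple[int, int] = (30_000, 50_000)
    seed: int = 0
    genus_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")
        if self.abundance_law not in _ABUNDANCE_LAWS:
            raise ValueError(f"unknown abundance law {self.abundance_law!r}")
        lo, hi = self.sequencing_depth_range
        if not (0 < lo <= hi):
            raise ValueError("sequencing depth range must satisfy 0 < low <= high")
        if self.genus_names is not None and len(self.genus_names) != self.n_genera:
            raise ValueError("genus_names length must equal n_genera")


@dataclass(frozen=True)
class PlantedEffect:
    """Plant one new sample at a target feature percentile."""

    feature_name: str
    target_percentile: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_percentile <= 100.0:
            raise ValueError("target_percentile must be in [0, 100]")


@dataclass(frozen=True)
class PairedEffectSpec:
    """Before/after design with planted richness gains.

    ``fraction_increasing`` of the pairs receive ``species_added`` novel
    genera (as singleton reads) in the after sample; the remaining pairs
    change only by evenness noise and resampling.
    """

    n_pairs: int = 97
    fraction_increasing: float = 0.66
    species_added: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not 0.0 <= self.fraction_increasing <= 1.0:
            raise ValueError("fraction_increasing must be in [0, 1]")
        if self.species_added < 0:
            raise ValueError("species_added must be >= 0")


def _compositions(spec: SyntheticCohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-sample compositions (rows on the simplex) under the spec's law."""
    if spec.abundance_law == "uniform":
        return rng.dirichlet(np.ones(spec.n_genera), size=spec.n_samples)
    mu_spread = float(spec.law_params.get("mu_spread", 1.5))
    sigma = float(spec.law_params.get("sigma", 0.6))
    mu = rng.normal(0.0, mu_spread, size=spec.n_genera)
    logs = mu[None, :] + sigma * rng.standard_normal((spec.n_samples, spec.n_genera))
    intensity = np.exp(logs - logs.max(axis=1, keepdims=True))
    return intensity / intensity.sum(axis=1, keepdims=True)


def generate_reference_cohort(spec: SyntheticCohortSpec) -> GenusAbundanceTable:
    """Draw a counts-mode cohort: composition per sample, then a
    multinomial read draw at a depth uniform in the configured range."""
    rng = np.random.default_rng(spec.seed)
    comps = _compositions(spec, rng)
    lo, hi = spec.sequencing_depth_range
    depths = rng.integers(lo, hi + 1, size=spec.n_samples)
    counts = np.vstack(
        [rng.multinomial(int(d), p) for d, p in zip(depths, comps)]
    )
    genera = (
        list(spec.genus_names)
        if spec.genus_names is not None
        else [f"Genus_{i:04d}" for i in range(spec.n_genera)]
    )
    ids = [f"ref_{i + 1:04d}" for i in range(spec.n_samples)]
    df = pd.DataFrame(counts, index=ids, columns=genera)
    return GenusAbundanceTable(data=df, mode="counts")


def plant_feature_percentile(
    reference: GenusAbundanceTable,
    effect: PlantedEffect,
    feature_set: FeatureSet,
    phylum_of: dict[str, str] | None = None,
) -> GenusAbundanceTable:
    """Append one sample whose feature value sits at the requested
    empirical percentile of the reference.

    The member genera of the target feature are rescaled multiplicatively
    in a template sample (the reference sample nearest the feature
    median) and the row renormalized, which moves the feature value
    exactly to the target quantile; leakage into other features through
    renormalization is accepted.  Returns a relative-mode table with the
    planted sample appended.  If the achieved empirical percentile
    differs from the target by more than one percentile point (ties at
    the extremes), a warning reports the nearest achievable value.
    """
    definition = feature_set[effect.feature_name]
    if definition.kind != "abundance":
        raise ValueError("percentile planting is defined for abundance features only")
    rel = reference if reference.mode == "relative" else to_relative(reference)
    profiles = compute_profiles(rel, feature_set, phylum_of)
    ref_values = profiles[effect.feature_name].to_numpy()
    target_value = float(
        np.quantile(ref_values, effect.target_percentile / 100.0)
    )
    template_idx = int(np.argmin(np.abs(ref_values - np.median(ref_values))))
    row = rel.data.iloc[template_idx].to_numpy(dtype=float).copy()
    lookup = {g.lower(): j for j, g in enumerate(rel.data.columns)}
    member_idx = [
        lookup[g.lower()] for g in definition.member_genera if g.lower() in lookup
    ]
    if not member_idx:
        raise ValueError(
            f"feature {definition.name} has no member genus in the table"
        )
    m = row[member_idx].sum()
    if m <= 0:
        row[member_idx] = 1e-6
        row /= row.sum()
        m = row[member_idx].sum()
    v = min(max(target_value, 0.0), 1.0 - 1e-12)
    if m >= 1.0:
        raise ValueError("template sample consists only of member genera")
    alpha = v * (1.0 - m) / (m * (1.0 - v)) if v > 0 else 0.0
    row[member_idx] *= alpha
    row /= row.sum()
    new_id = effect.sample_id or (
        f"planted_{definition.name}_{effect.target_percentile:g}"
    )
    new = pd.DataFrame([row], index=[new_id], columns=rel.data.columns)
    out = GenusAbundanceTable(
        data=pd.concat([rel.data, new]), mode="relative", phylum_of=rel.phylum_of
    )
    achieved_value = compute_profiles(
        GenusAbundanceTable(data=new, mode="relative"), feature_set, phylum_of
    ).iloc[0][definition.name]
    below = np.sum(ref_values < achieved_value)
    equal = np.sum(ref_values == achieved_value)
    achieved_pct = 100.0 * (below + 0.5 * equal) / len(ref_values)
    if abs(achieved_pct - effect.target_percentile) > 1.0:
        warnings.warn(
            f"target percentile {effect.target_percentile} unreachable for "
            f"{definition.name}; nearest achievable is {achieved_pct:.2f}",
            stacklevel=2,
        )
    return out


def generate_paired_cohort(
    spec: PairedEffectSpec,
    base: SyntheticCohortSpec,
    evenness_noise_sd: float = 0.6,
    abundance_floor: float = 0.25,
) -> tuple[GenusAbundanceTable, GenusAbundanceTable]:
    """Matched before/after counts tables.

    The genus pool splits into a core block, occupied by every sample,
    and a reserve of ``species_added`` novel genera that appear (as
    singleton reads) only in the after samples of the planted fraction.
    Core compositions mix the heavy-tailed law with a uniform floor
    (``abundance_floor``) so that at the simulated depths every core
    genus is always detected: unplanted pairs therefore tie on richness,
    while per-genus log-normal evenness noise (``evenness_noise_sd``)
    keeps evenness-sensitive metrics fluctuating between collections.
    """
    if spec.n_pairs > base.n_samples:
        raise ValueError("n_pairs exceeds base.n_samples")
    if spec.species_added >= base.n_genera:
        raise ValueError("species_added exceeds the available genus pool")
    rng = np.random.default_rng(spec.seed)
    n_core = base.n_genera - spec.species_added
    core_spec = SyntheticCohortSpec(
        n_samples=max(spec.n_pairs, 2),
        n_genera=n_core,
        abundance_law=base.abundance_law,
        law_params=base.law_params,
        sequencing_depth_range=base.sequencing_depth_range,
        seed=base.seed,
        genus_names=None,
    )
    comps = _compositions(core_spec, rng)[: spec.n_pairs]
    uniform = np.full(n_core, 1.0 / n_core)
    lo, hi = base.sequencing_depth_range
    n_increasing = int(round(spec.fraction_increasing * spec.n_pairs))
    increasing = np.zeros(spec.n_pairs, dtype=bool)
    increasing[rng.permutation(spec.n_pairs)[:n_increasing]] = True

    genera = (
        list(base.genus_names)
        if base.genus_names is not None
        else [f"Genus_{i:04d}" for i in range(n_core)]
        + [f"Novel_{i:04d}" for i in range(spec.species_added)]
    )
    before = np.zeros((spec.n_pairs, base.n_genera), dtype=np.int64)
    after = np.zeros_like(before)
    for i in range(spec.n_pairs):
        # both collections perturb the same base composition, so evenness
        # deltas are exchangeable (no systematic Shannon drift)
        for arr in (before, after):
            noise = np.exp(evenness_noise_sd * rng.standard_normal(n_core))
            perturbed = comps[i] * noise
            perturbed /= perturbed.sum()
            p = (1 - abundance_floor) * perturbed + abundance_floor * uniform
            arr[i, :n_core] = rng.multinomial(int(rng.integers(lo, hi + 1)), p)
        if increasing[i] and spec.species_added:
            # novel rare genera: singleton/doubleton mix keeps the Chao1
            # correction term modest
            after[i, n_core:] = 1 + rng.poisson(1.0, size=spec.species_added)
    ids = [f"pair_{i + 1:04d}" for i in range(spec.n_pairs)]
    tb = GenusAbundanceTable(
        data=pd.DataFrame(before, index=ids, columns=genera), mode="counts"
    )
    ta = GenusAbundanceTable(
        data=pd.DataFrame(after, index=ids, columns=genera), mode="counts"
    )
    return tb, ta


def generate_genotypes(
    panel,
    allele_freqs,
    n: int,
    seed: int = 0,
) -> str:
    """Minimal VCF v4.2 with one record per panel variant.

    Genotypes are drawn under Hardy-Weinberg equilibrium: each sample's
    risk-allele dosage is Binomial(2, f).  The risk allele is written as
    ALT, so dosage equals the ALT allele count.
    """
    variants = list(panel)
    freqs = np.asarray(allele_freqs, dtype=float)
    if len(freqs) != len(variants):
        raise ValueError("need exactly one allele frequency per panel variant")
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n)]
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        "##source=nutriome-synthetic",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in sorted({str(v.chrom) for v in variants}, key=str):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    order = sorted(range(len(variants)), key=lambda j: (str(variants[j].chrom), variants[j].pos))
    for j in order:
        v = variants[j]
        dosages = rng.binomial(2, freqs[j], size=n)
        gts = "\t".join(gt_strings[int(d)] for d in dosages)
        ref = v.ref
        alt = v.risk_allele if v.risk_allele != v.ref else v.alt
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    return "\n".join(lines) + "\n"


def hwe_chi_square_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-degree-of-freedom chi-square test of Hardy-Weinberg
    proportions from genotype counts."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_hom_alt + n_het) / (2 * n)
    q = 1 - p
    expected = np.array([q * q * n, 2 * p * q * n, p * p * n])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if (expected == 0).any():
        return 1.0
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))
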