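import numpy as np
import pandas as pd
import pytest

from nutriome.nutrigenetics import (
    NON_INFORMATIVE,
    Panel,
    PanelVariant,
    SubcategoryRule,
    allele_frequency_comparison,
    default_panel,
    default_rules,
    demo_panel,
    extract_panel_genotypes,
    label_cohort,
    subcategory_label,
)
from nutriome.synthetic import generate_genotypes


def _variant(vid="rs1", risk="A", ref="G", alt="A", sub="overweight", weight=1.0):
    return PanelVariant(
        variant_id=vid,
        gene="GENE",
        chrom="1",
        pos=1000,
        ref=ref,
        alt=alt,
        risk_allele=risk,
        category="Metabolic diseases",
        subcategory=sub,
        weight=weight,
    )


RULE = SubcategoryRule("overweight", "risk-graded", (0.125, 0.375, 0.625, 0.875))


class TestExtraction:
    def test_dosages_roundtrip_through_vcf(self, tmp_path):
        panel = demo_panel(10, seed=0)
        text = generate_genotypes(panel, [0.5] * 10, n=30, seed=3)
        path = tmp_path / "g.vcf"
        path.write_text(text)
        dosages, mismatches = extract_panel_genotypes(path, panel)
        assert dosages.shape == (30, 10)
        assert mismatches == []
        assert dosages.notna().all().all()
        assert set(np.unique(dosages.to_numpy())) <= {0.0, 1.0, 2.0}

    def test_missing_genotype_is_nan(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        )
        body = "1\t1000\trs1\tG\tA\t.\tPASS\t.\tGT\t1/1\t./.\n"
        path = tmp_path / "m.vcf"
        path.write_text(header + body)
        panel = Panel([_variant()])
        dosages, _ = extract_panel_genotypes(path, panel)
        assert dosages.loc["S1", "rs1"] == 2.0
        assert np.isnan(dosages.loc["S2", "rs1"])

    def test_allele_mismatch_reported_not_flipped(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        )
        body = "1\t1000\trs1\tG\tC\t.\tPASS\t.\tGT\t0/1\n"  # alt C, risk A
        path = tmp_path / "mm.vcf"
        path.write_text(header + body)
        dosages, mismatches = extract_panel_genotypes(path, Panel([_variant()]))
        assert len(mismatches) == 1
        assert mismatches[0]["variant_id"] == "rs1"
        assert dosages["rs1"].isna().all()

    def test_absent_panel_variant_left_missing(self, tmp_path):
        panel = demo_panel(3, seed=0)
        text = generate_genotypes(demo_panel(2, seed=0), [0.5, 0.5], n=5, seed=0)
        path = tmp_path / "a.vcf"
        path.write_text(text)
        dosages, _ = extract_panel_genotypes(path, panel)
        assert dosages[panel.variant_ids[2]].isna().all()


class TestLabels:
    def test_floor_and_ceiling(self):
        variants = [_variant(f"rs{i}") for i in range(4)]
        zeros = pd.Series({v.variant_id: 0.0 for v in variants})
        twos = pd.Series({v.variant_id: 2.0 for v in variants})
        assert subcategory_label(zeros, RULE, variants).label == "no risk"
        assert subcategory_label(twos, RULE, variants).label == "high risk"

    def test_valence_floor(self):
        rule = SubcategoryRule("overweight", "valence", (0.34, 0.67))
        variants = [_variant("rs1")]
        lab = subcategory_label(pd.Series({"rs1": 0.0}), rule, variants)
        assert lab.label == "favorable"

    def test_all_missing_non_informative(self):
        variants = [_variant(f"rs{i}") for i in range(3)]
        missing = pd.Series({v.variant_id: np.nan for v in variants})
        lab = subcategory_label(missing, RULE, variants)
        assert lab.label == NON_INFORMATIVE
        assert lab.n_informative == 0

    def test_missing_fraction_threshold(self):
        variants = [_variant(f"rs{i}") for i in range(4)]
        half = pd.Series({"rs0": 1.0, "rs1": 1.0, "rs2": np.nan, "rs3": np.nan})
        rule_strict = SubcategoryRule(
            "overweight", "risk-graded", (0.125, 0.375, 0.625, 0.875),
            max_missing_fraction=0.4,
        )
        assert subcategory_label(half, rule_strict, variants).label == NON_INFORMATIVE
        rule_lax = SubcategoryRule(
            "overweight", "risk-graded", (0.125, 0.375, 0.625, 0.875),
            max_missing_fraction=0.5,
        )
        assert subcategory_label(half, rule_lax, variants).label == "medium risk"

    def test_score_invariant_to_split_weights(self):
        base = [_variant("rs1", weight=1.0)]
        split = [_variant("rs1a", weight=0.5), _variant("rs1b", weight=0.5)]
        s1 = subcategory_label(pd.Series({"rs1": 2.0}), RULE, base).score
        s2 = subcategory_label(
            pd.Series({"rs1a": 2.0, "rs1b": 2.0}), RULE, split
        ).score
        assert s1 == s2 == 1.0

    def test_severity_monotone_in_score(self):
        variants = [_variant(f"rs{i}") for i in range(2)]
        order = []
        for dosage in [0, 1, 2]:
            d = pd.Series({"rs0": dosage, "rs1": dosage})
            order.append(subcategory_label(d, RULE, variants).label)
        severity = ["no risk", "low risk", "medium risk", "moderate risk", "high risk"]
        ranks = [severity.index(l) for l in order]
        assert ranks == sorted(ranks)

    def test_packaged_panel_and_rules_cover_each_other(self):
        panel = default_panel()
        rules = default_rules()
        assert set(panel.subcategories) <= set(rules)
        dosages = pd.DataFrame(
            0.0, index=["s1", "s2"], columns=panel.variant_ids
        )
        labels = label_cohort(dosages, panel, rules)
        assert set(labels["label"]) <= {"no risk", "favorable"}


class TestFrequencyComparison:
    def _reference(self, panel, freqs, chroms=214):
        return pd.DataFrame(
            {"ref_freq": freqs, "n_chromosomes": chroms}, index=panel.variant_ids
        )

    def test_identical_counts_give_p_one(self):
        panel = demo_panel(5, seed=0)
        # cohort of 107 with dosage sum = ref count exactly
        rng = np.random.default_rng(0)
        dmat = pd.DataFrame(
            rng.binomial(2, 0.5, size=(107, 5)), columns=panel.variant_ids
        )
        freqs = dmat.sum() / 214
        comp = allele_frequency_comparison(dmat, self._reference(panel, freqs.to_numpy()))
        assert (comp["raw_p"] == 1.0).all()

    def test_null_cohort_rarely_flags(self):
        panel = demo_panel(50, seed=1)
        rng = np.random.default_rng(2)
        freqs = rng.uniform(0.1, 0.9, 50)
        dmat = pd.DataFrame(
            rng.binomial(2, freqs, size=(357, 50)), columns=panel.variant_ids
        )
        comp = allele_frequency_comparison(dmat, self._reference(panel, freqs))
        assert comp["significant"].sum() == 0

    def test_planted_shift_detected_exactly(self):
        panel = demo_panel(100, seed=3)
        rng = np.random.default_rng(4)
        freqs = rng.uniform(0.15, 0.7, 100)
        shifted = freqs.copy()
        shifted[:2] += 0.25
        dmat = pd.DataFrame(
            rng.binomial(2, shifted, size=(357, 100)), columns=panel.variant_ids
        )
        comp = allele_frequency_comparison(dmat, self._reference(panel, freqs))
        hits = set(comp.loc[comp["significant"], "variant_id"])
        assert hits == set(panel.variant_ids[:2])

    def test_small_cohort_rejected(self):
        panel = demo_panel(2, seed=0)
        dmat = pd.DataFrame(np.zeros((5, 2)), columns=panel.variant_ids)
        with pytest.raises(ValueError, match=">= 10"):
            allele_frequency_comparison(dmat, self._reference(panel, [0.5, 0.5]))


class TestPanelValidation:
    def test_risk_allele_must_be_ref_or_alt(self):
        with pytest.raises(ValueError, match="risk allele"):
            _variant(risk="T", ref="G", alt="A")

    def test_panel_size_capped(self):
        with pytest.raises(ValueError):
            demo_panel(301)

    def test_demo_panel_structure(self):
        panel = demo_panel(300, seed=0)
        assert len(panel) == 300
        assert len(panel.subcategories) == 39
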