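import pytest

from hrdscreen.annotation import (
    HR_GENE_PANEL,
    PREDICTORS,
    AnnotatedMutation,
    MethylationEvidence,
    MutationCall,
    annotate_loh,
    assign_group,
    call_brca1_methylation_ccle,
    call_brca1_methylation_clp,
    comparison_groups,
    filter_deleterious_ccle,
    filter_deleterious_clp,
)
from hrdscreen.config import load_defaults


def call(gene="BRCA1", sample="S1", variant_class="other", annotation="",
         predictors=None, minor_cn=None):
    return MutationCall(
        sample_id=sample,
        gene=gene,
        variant_class=variant_class,
        dataset_annotation=annotation,
        predictor_calls=predictors or {},
        minor_cn_at_locus=minor_cn,
    )


class TestDeleteriousFilters:
    def test_dataset_annotation_filter_keeps_damaging_only(self):
        kept = filter_deleterious_ccle(
            [call(annotation="damaging"), call(annotation="silent"),
             call(annotation="Damaging")]  # case-sensitive
        )
        assert [m.dataset_annotation for m in kept] == ["damaging"]

    def test_empty_input_passes_through(self):
        assert filter_deleterious_ccle([]) == []
        assert filter_deleterious_clp([]) == []

    def test_truncating_kept_without_predictor_support(self):
        kept = filter_deleterious_clp([call(variant_class="truncating")])
        assert len(kept) == 1

    def test_missense_requires_unanimous_predictors(self):
        unanimous = {p: "damaging" for p in PREDICTORS}
        nearly = dict(unanimous, SIFT="tolerated")
        kept = filter_deleterious_clp(
            [call(variant_class="missense", predictors=unanimous),
             call(variant_class="missense", predictors=nearly)]
        )
        assert len(kept) == 1
        assert kept[0].predictor_calls["SIFT"] == "damaging"

    def test_missense_with_missing_predictor_dropped(self):
        nine = {p: "deleterious" for p in list(PREDICTORS)[:9]}
        assert filter_deleterious_clp([call(variant_class="missense",
                                            predictors=nine)]) == []

    def test_other_variant_classes_dropped(self):
        assert filter_deleterious_clp([call(variant_class="other")]) == []


class TestLohAnnotation:
    def test_minor_cn_zero_is_loh(self):
        assert annotate_loh(call(minor_cn=0)) == "LOH_present"

    def test_minor_cn_positive_is_no_loh(self):
        assert annotate_loh(call(minor_cn=2)) == "LOH_absent"

    def test_fallback_dataset_resolves_unknown(self):
        assert annotate_loh(call(minor_cn=None), call(minor_cn=0)) == "LOH_present"
        assert annotate_loh(call(minor_cn=None), call(minor_cn=1)) == "LOH_absent"

    def test_still_unknown_without_fallback(self):
        assert annotate_loh(call(minor_cn=None)) == "unknown"
        assert annotate_loh(call(minor_cn=None), call(minor_cn=None)) == "unknown"


class TestMethylationCalls:
    def evidence(self, betas, pct, gene="BRCA1"):
        probes = {f"p{i}": b for i, b in enumerate(betas)}
        return MethylationEvidence("S1", gene, probes, pct)

    def test_two_region_rule(self):
        assert call_brca1_methylation_ccle(self.evidence([0.8, 0.7], 2)) is True
        assert call_brca1_methylation_ccle(self.evidence([0.8, 0.1], 2)) is False
        assert call_brca1_methylation_ccle(self.evidence([0.8, 0.7], 50)) is False

    def test_boundary_beta_not_methylated(self):
        assert call_brca1_methylation_ccle(self.evidence([0.3, 0.3], 2)) is False

    def test_missing_region_gives_unknown(self):
        assert call_brca1_methylation_ccle(self.evidence([0.8], 2)) is None

    def test_probe_array_rule_threshold_count(self):
        all17 = call_brca1_methylation_clp(self.evidence([0.9] * 17, 5))
        fifteen = call_brca1_methylation_clp(
            self.evidence([0.9] * 15 + [0.1] * 2, 5)
        )
        fourteen = call_brca1_methylation_clp(
            self.evidence([0.9] * 14 + [0.1] * 3, 5)
        )
        assert (all17, fifteen, fourteen) == (True, True, False)

    def test_probe_array_rule_needs_low_expression(self):
        assert call_brca1_methylation_clp(self.evidence([0.9] * 17, 60)) is False

    def test_too_few_probes_gives_unknown(self):
        assert call_brca1_methylation_clp(self.evidence([0.9] * 10, 5)) is None

    def test_beta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            self.evidence([1.2, 0.5], 5)


class TestGrouping:
    def annotated(self, gene, minor_cn, sample="S1"):
        c = call(gene=gene, sample=sample, variant_class="truncating",
                 annotation="damaging", minor_cn=minor_cn)
        return AnnotatedMutation(call=c, loh=annotate_loh(c))

    def test_brca2_with_loh_is_brca_altered(self):
        a = assign_group("S1", [self.annotated("BRCA2", 0)], False)
        assert a.group == "BRCA_altered"

    def test_methylation_alone_is_brca_altered(self):
        assert assign_group("S1", [], True).group == "BRCA_altered"

    def test_no_panel_mutation_is_wild_type(self):
        assert assign_group("S1", [], False).group == "WT"
        non_panel = self.annotated("TP53", 0)
        assert assign_group("S1", [non_panel], False).group == "WT"

    def test_other_panel_gene_with_and_without_loh(self):
        with_loh = assign_group("S1", [self.annotated("ATM", 0)], False)
        without = assign_group("S1", [self.annotated("ATM", 1)], False)
        assert with_loh.group == "HRR_LOH_pos"
        assert without.group == "HRR_LOH_neg"

    def test_unknown_loh_excludes_sample(self):
        a = assign_group("S1", [self.annotated("ATM", None)], False)
        assert a.group == "excluded"

    def test_gene_symbols_matched_case_insensitively(self):
        a = assign_group("S1", [self.annotated(" brca1 ", 0)], False)
        assert a.group == "BRCA_altered"

    def test_grouping_is_deterministic(self):
        muts = [self.annotated("ATM", 0), self.annotated("BRCA1", 1)]
        groups = {assign_group("S1", muts, False).group for _ in range(5)}
        assert len(groups) == 1

    def test_comparison_schemes_nest(self):
        annotations = [
            assign_group("A", [self.annotated("BRCA2", 0, "A")], False),
            assign_group("B", [self.annotated("ATM", 0, "B")], False),
            assign_group("C", [self.annotated("ATM", 1, "C")], False),
            assign_group("D", [], False),
        ]
        brca_altered, wt_brca = comparison_groups(annotations, "brca_vs_wt")
        hrr_altered, wt_hrr = comparison_groups(annotations, "hrr_vs_wt")
        assert brca_altered == {"A"}
        assert hrr_altered == {"A", "B"}
        assert brca_altered <= hrr_altered
        assert wt_brca == wt_hrr == {"D"}
        loose, _ = comparison_groups(annotations, "hrr_vs_wt",
                                     include_loh_negative=True)
        assert loose == {"A", "B", "C"}


class TestShippedConstants:
    """The pipeline constants shipped in the package configuration."""

    def test_gene_panel_is_the_29_gene_set(self):
        cfg = load_defaults()
        expected = {
            "ATM", "ATR", "BARD1", "BLM", "BRCA1", "BRCA2", "BRIP1", "CDK12",
            "CHEK1", "CHEK2", "FANCA", "FANCC", "FANCD2", "FANCE", "FANCF",
            "FANCI", "FANCL", "FANCM", "MRE11", "NBN", "PALB2", "RAD50",
            "RAD51", "RAD51B", "RAD51C", "RAD51D", "RAD52", "RAD54L", "RPA1",
        }
        assert set(cfg["hr_gene_panel"]) == expected
        assert len(cfg["hr_gene_panel"]) == 29
        assert HR_GENE_PANEL == frozenset(expected)

    def test_predictor_list(self):
        cfg = load_defaults()
        assert cfg["predictors"] == [
            "SIFT", "Polyphen2", "LRT", "MutationTaster", "MutationAssessor",
            "FATHMM", "PROVEAN", "MetaSVM", "MetaLR", "M-CAP",
        ]
        assert len(PREDICTORS) == 10

    def test_24_drug_categories(self):
        cfg = load_defaults()
        assert len(cfg["drug_categories"]) == 24
        for expected in ("Platinum", "PARP inhibitor", "Topoisomerase inhibitor",
                         "Genome integrity", "Others"):
            assert expected in cfg["drug_categories"]

    def test_methylation_and_association_thresholds(self):
        cfg = load_defaults()
        assert cfg["methylation"]["ccle"]["beta_threshold"] == 0.3
        assert cfg["methylation"]["ccle"]["expression_percentile"] == 10.0
        assert cfg["methylation"]["clp"]["beta_threshold"] == 0.2
        assert cfg["methylation"]["clp"]["expression_percentile"] == 30.0
        assert cfg["methylation"]["clp"]["min_probes"] == 15
        assert cfg["methylation"]["clp"]["n_probes"] == 17
        assert cfg["association"]["min_altered"] == 10
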