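"""Knowledge-base loading and alteration-pattern matching."""

import pytest

from escvar.actionability import (
    ActionabilityRule,
    actionable_patients,
    load_knowledge_base,
    match_alterations,
)
from escvar.cnv import CopyNumberSegment
from escvar.datasets import reported_actionable_alterations
from escvar.model import VariantClass

from .conftest import make_variant


@pytest.fixture(scope="module")
def kb():
    return load_knowledge_base("default")


class TestDefaultKnowledgeBase:
    def test_covers_nine_genes_with_at_least_14_rules(self, kb):
        assert len(kb) >= 14
        assert {r.gene for r in kb} == {
            "AKT1", "CREBBP", "HNF1A", "IDH1", "MET", "NF1", "PIK3CA", "PTEN", "TP53",
        }

    def test_pik3ca_hotspot_rule(self, kb):
        rule = next(
            r for r in kb
            if r.gene == "PIK3CA" and r.pattern_type == "exact_protein_change"
            and r.pattern_value == "p.E545K"
        )
        assert "PI3K/AKT/mTOR" in rule.therapy

    def test_met_amplification_rule(self, kb):
        rule = next(r for r in kb if r.gene == "MET")
        assert rule.pattern_type == "amplification"
        assert "c-MET" in rule.therapy

    def test_missing_gene_field_rejected(self, tmp_path):
        p = tmp_path / "kb.tsv"
        p.write_text("gene\tpattern_type\tpattern_value\ttherapy\n"
                     "\tamplification\t\tdrug\n")
        with pytest.raises(ValueError, match="index 0"):
            load_knowledge_base(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "kb.tsv"
        p.write_text("gene\ttherapy\nTP53\tdrug\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_knowledge_base(p)

    def test_bad_pattern_type_rejected(self):
        with pytest.raises(ValueError, match="pattern type"):
            ActionabilityRule("TP53", "fusion", "", "drug")


class TestMatching:
    def test_tp53_frameshift_matches_class_rule(self, kb):
        v = make_variant(patient_id="12", gene="TP53", ref="CT", alt="C",
                         variant_class=VariantClass.frameshift_indel)
        matches = match_alterations([v], [], kb)
        assert {m.rule.pattern_value for m in matches} == {"frameshift"}
        assert actionable_patients(matches) == {"12"}

    def test_idh1_hotspot_matches_pan_idh(self, kb):
        v = make_variant(patient_id="8", gene="IDH1", protein_change="p.R132H")
        (m,) = match_alterations([v], [], kb)
        assert "pan-IDH" in m.therapy

    def test_unlisted_tp53_missense_no_match(self, kb):
        v = make_variant(patient_id="1", gene="TP53", protein_change="p.P72R")
        assert match_alterations([v], [], kb) == []

    def test_protein_notation_with_stray_space_matches(self, kb):
        v = make_variant(patient_id="2", gene="PIK3CA", protein_change="p.M1043 V")
        assert len(match_alterations([v], [], kb)) == 1

    def test_splice_disruption_matches_cdna(self, kb):
        v = make_variant(patient_id="6", gene="NF1",
                         variant_class=VariantClass.splice,
                         cdna_change="c.A3975-2 T")
        (m,) = match_alterations([v], [], kb)
        assert "MEK" in m.therapy

    def test_amplification_matches_cnv_gain_only(self, kb):
        gain = CopyNumberSegment("7", "chr7", 0, 100, log2_ratio=1.0, gene="MET")
        neutral = CopyNumberSegment("8", "chr7", 0, 100, log2_ratio=0.1, gene="MET")
        matches = match_alterations([], [gain, neutral], kb)
        assert actionable_patients(matches) == {"7"}

    def test_adding_rules_never_removes_matches(self, kb):
        variants, cnvs = reported_actionable_alterations()
        base = match_alterations(variants, cnvs, kb)
        extended = match_alterations(
            variants, cnvs,
            kb + [ActionabilityRule("EP300", "truncation_class", "nonsense", "HDACi")],
        )
        assert set(map(id_tuple, base)) <= set(map(id_tuple, extended))

    def test_matches_reproducible_by_pair_scan(self, kb):
        variants, cnvs = reported_actionable_alterations()
        got = {id_tuple(m) for m in match_alterations(variants, cnvs, kb)}
        oracle = set()
        for rule in kb:
            for v in variants:
                if rule.matches_variant(v):
                    oracle.add((v.patient_id, rule.gene, rule.pattern_type,
                                rule.pattern_value))
            for s in cnvs:
                if rule.matches_cnv(s):
                    oracle.add((s.patient_id, rule.gene, rule.pattern_type,
                                rule.pattern_value))
        assert got == oracle

    def test_duplicated_matches_count_patient_once(self, kb):
        v1 = make_variant(patient_id="9", gene="TP53", protein_change="p.R273C")
        v2 = make_variant(patient_id="9", gene="TP53", pos=2000, ref="GA", alt="G",
                          variant_class=VariantClass.frameshift_indel)
        matches = match_alterations([v1, v2], [], kb)
        assert len(matches) == 2
        assert actionable_patients(matches) == {"9"}

    def test_empty_matches_empty_set(self):
        assert actionable_patients([]) == set()


def id_tuple(m):
    return (m.patient_id, m.gene, m.rule.pattern_type, m.rule.pattern_value)


class TestReportedCohort:
    def test_nine_actionable_patients(self, kb):
        variants, cnvs = reported_actionable_alterations()
        matches = match_alterations(variants, cnvs, kb)
        assert actionable_patients(matches) == {"2", "3", "5", "6", "7", "8", "9",
                                                "12", "13"}
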