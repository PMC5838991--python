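"""Cohort matrix, frequencies, exclusivity, MMR triage, Fisher comparison."""

import math
import random

import pytest
from scipy import stats as sps

from escvar.cnv import CopyNumberSegment
from escvar.cohort import (
    build_matrix,
    clinvar_pathogenic,
    compare_to_reference,
    gene_frequency,
    mutual_exclusivity_overlap,
    pathway_frequency,
    triage_mmr_variants,
)
from escvar.datasets import reported_mmr_lesions
from escvar.model import ClinicalRecord, GeneGroupCatalog, VariantClass

from .conftest import make_variant


def clinical(n=15):
    return [
        ClinicalRecord(patient_id=str(i + 1), sex="male", age=60, stage="II",
                       site="mid", macroscopic_type="polypoid")
        for i in range(n)
    ]


def gain(gene, pid):
    return CopyNumberSegment(pid, "chr1", 0, 100, log2_ratio=1.0, gene=gene)


def loss(gene, pid):
    return CopyNumberSegment(pid, "chr1", 0, 100, log2_ratio=-1.0, gene=gene)


class TestBuildMatrix:
    def test_missense_cell(self):
        m = build_matrix([make_variant(patient_id="9", gene="TP53")], [], clinical())
        assert m.cell("TP53", "9") == {"missense"}

    def test_cnv_gain_maps_to_amplification(self):
        m = build_matrix([], [gain("PIK3CA", "13")], clinical())
        assert "amplification" in m.cell("PIK3CA", "13")

    def test_truncating_mapping(self):
        kept = [
            make_variant(patient_id="1", gene="TP53",
                         variant_class=VariantClass.stopgain),
            make_variant(patient_id="1", gene="TP53", pos=2000, ref="CT", alt="C",
                         variant_class=VariantClass.frameshift_indel),
        ]
        m = build_matrix(kept, [loss("RB1", "2")], clinical())
        assert m.cell("TP53", "1") == {"truncating"}
        assert m.cell("RB1", "2") == {"loss"}

    def test_no_calls_all_cells_empty(self):
        m = build_matrix([], [], clinical())
        assert all(not m.cell(g, p) for g in m.genes for p in m.patients)
        assert len(m.patients) == 15  # column per patient even with no alterations

    def test_unknown_patient_listed(self):
        with pytest.raises(ValueError, match="P99"):
            build_matrix([make_variant(patient_id="P99")], [], clinical())

    def test_permutation_invariance(self):
        kept = [
            make_variant(patient_id=str(i + 1), gene=g, pos=1000 + i)
            for i, g in enumerate(["TP53", "RB1", "MET", "TP53"])
        ]
        cnvs = [gain("PIK3CA", "3"), loss("CDKN2A", "5")]
        a = build_matrix(kept, cnvs, clinical())
        rnd = random.Random(3)
        kept2, cnvs2 = list(kept), list(cnvs)
        rnd.shuffle(kept2)
        rnd.shuffle(cnvs2)
        b = build_matrix(kept2, cnvs2, clinical())
        assert a.cells == b.cells and a.genes == b.genes


class TestFrequencies:
    def _matrix(self):
        kept = [make_variant(patient_id=str(p), gene="PIK3CA") for p in (1, 2, 3)]
        kept += [make_variant(patient_id=str(p), gene="TP53") for p in range(1, 16)]
        cnvs = [gain("PIK3CA", "7"), gain("PIK3CA", "13")]
        return build_matrix(kept, cnvs, clinical())

    def test_gene_altered_in_5_of_15_is_33pc(self):
        m = self._matrix()
        frac, count = gene_frequency(m, "PIK3CA")  # 3 SNVs + 2 amplifications
        assert count == 5
        assert round(100 * frac) == 33

    def test_gene_altered_in_all_is_100pc(self):
        frac, count = gene_frequency(self._matrix(), "TP53")
        assert (frac, count) == (1.0, 15)

    def test_unaltered_catalog_gene_is_0pc(self):
        frac, count = gene_frequency(self._matrix(), "NOTCH1")
        assert (frac, count) == (0.0, 0)

    def test_unknown_gene_errors(self):
        with pytest.raises(KeyError):
            gene_frequency(self._matrix(), "TTN")

    def test_pathway_counts_patient_once(self):
        kept = [
            make_variant(patient_id="1", gene="MSH2"),
            make_variant(patient_id="1", gene="POLE", pos=2000),
            make_variant(patient_id="2", gene="MLH1"),
        ]
        m = build_matrix(kept, [], clinical())
        frac, count = pathway_frequency(m, "MMR_proofreading")
        assert count == 2

    def test_singleton_group_equals_gene_frequency(self):
        groups = GeneGroupCatalog({"just_tp53": ["TP53"], "RTK": ["MET"]})
        kept = [make_variant(patient_id=str(p), gene="TP53") for p in (1, 4)]
        m = build_matrix(kept, [], clinical(), groups=groups)
        assert pathway_frequency(m, "just_tp53") == gene_frequency(m, "TP53")

    def test_empty_group_counts_zero(self):
        groups = GeneGroupCatalog({"empty": []})
        m = build_matrix([make_variant(patient_id="1")], [], clinical(), groups=groups)
        assert pathway_frequency(m, "empty") == (0.0, 0)

    def test_unknown_group_errors(self):
        with pytest.raises(KeyError):
            pathway_frequency(self._matrix(), "no_such_pathway")

    def test_per_gene_counts_bound_any_alteration_count(self):
        m = self._matrix()
        total = sum(gene_frequency(m, g)[1] for g in m.genes)
        any_altered = sum(1 for p in m.patients if m.altered_genes(p))
        assert total >= any_altered


class TestMutualExclusivity:
    RTK = ["MET", "CSF1R", "FLT3", "ERBB2"]

    def test_perfectly_exclusive_is_zero(self):
        kept = [make_variant(patient_id=str(i + 1), gene=g)
                for i, g in enumerate(self.RTK)]
        m = build_matrix(kept, [], clinical())
        assert mutual_exclusivity_overlap(m, self.RTK) == 0

    def test_one_double_hit_patient(self):
        kept = [
            make_variant(patient_id="1", gene="MET"),
            make_variant(patient_id="1", gene="ERBB2", pos=2000),
            make_variant(patient_id="2", gene="FLT3"),
        ]
        m = build_matrix(kept, [], clinical())
        assert mutual_exclusivity_overlap(m, self.RTK) == 1

    def test_random_matrix_matches_enumeration(self):
        rnd = random.Random(11)
        kept = [
            make_variant(patient_id=str(rnd.randint(1, 15)),
                         gene=rnd.choice(self.RTK), pos=1000 + i)
            for i in range(40)
        ]
        m = build_matrix(kept, [], clinical())
        oracle = sum(
            1
            for p in m.patients
            if sum(1 for g in self.RTK if m.cell(g, p)) >= 2
        )
        assert mutual_exclusivity_overlap(m, self.RTK) == oracle


class TestMmrTriage:
    def test_reported_lesions_pathogenic_row(self):
        table = triage_mmr_variants(reported_mmr_lesions())
        row = table[table["protein_change"] == "p.R929X"]
        assert len(row) == 1
        assert row.iloc[0]["gene"] == "MSH2"
        assert "Pathogenic" in row.iloc[0]["clinvar_sig"]

    def test_exactly_one_pathogenic_assertion(self):
        table = triage_mmr_variants(reported_mmr_lesions())
        assert int(table["pathogenic"].sum()) == 1

    def test_empty_input(self):
        assert triage_mmr_variants([]).empty

    def test_non_mmr_genes_excluded(self):
        table = triage_mmr_variants([make_variant(gene="TP53")])
        assert table.empty

    @pytest.mark.parametrize(
        "sig,expected",
        [
            (["Pathogenic"], True),
            (["Likely_pathogenic"], True),
            (["Likely_benign", "pathogenic"], False),  # conflicting assertion
            (["Benign"], False),
            ([], False),
        ],
    )
    def test_pathogenic_semantics(self, sig, expected):
        assert clinvar_pathogenic(sig) is expected


def hypergeom_two_sided(a, b, c, d):
    """Exhaustive enumeration of all 2x2 tables with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = sps.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = sps.hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisherComparison:
    def test_identical_proportions_p_one(self):
        assert compare_to_reference(3, 10, 3, 10) == pytest.approx(1.0)

    def test_total_separation_tiny_p(self):
        assert compare_to_reference(15, 15, 0, 15) < 1e-6

    @pytest.mark.parametrize(
        "count,n,ref_count,ref_n",
        [(5, 10, 0, 10), (5, 15, 5, 100), (1, 8, 7, 9), (0, 5, 5, 5), (12, 30, 3, 30)],
    )
    def test_matches_hypergeometric_enumeration(self, count, n, ref_count, ref_n):
        p = compare_to_reference(count, n, ref_count, ref_n)
        oracle = hypergeom_two_sided(count, n - count, ref_count, ref_n - ref_count)
        assert p == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("bad", [(0.5, 10, 1, 10), (5, 3, 1, 10), (-1, 5, 1, 5)])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            compare_to_reference(*bad)
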