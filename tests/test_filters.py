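"""Filter-cascade predicates: boundary semantics, order-freedom, idempotence."""

import itertools
import random

import pytest

from escvar.blacklist import Blacklist
from escvar.filters import (
    CascadeConfig,
    filter_blacklist,
    filter_evidence_tier,
    filter_functional_class,
    filter_population_frequency,
    filter_repeat_regions,
    run_cascade,
)
from escvar.model import RegionSet, VariantClass

from .conftest import make_variant

EMPTY_BL = Blacklist(n_normals=10, detection_counts={})
EMPTY_REPEATS = RegionSet([("chr9", 0, 1)])


class TestFunctionalClass:
    @pytest.mark.parametrize(
        "vclass,expected",
        [
            (VariantClass.missense, True),
            (VariantClass.stopgain, True),
            (VariantClass.frameshift_indel, True),
            (VariantClass.nonframeshift_indel, True),
            (VariantClass.synonymous, False),
            (VariantClass.splice, False),  # absent from the keep-list by default
            (VariantClass.other, False),
        ],
    )
    def test_keep_list(self, vclass, expected):
        assert filter_functional_class(make_variant(variant_class=vclass)) is expected

    def test_keep_splice_switch(self):
        v = make_variant(variant_class=VariantClass.splice)
        assert filter_functional_class(v, CascadeConfig(keep_splice=True))
        assert not filter_functional_class(v, CascadeConfig(keep_splice=False))


class TestPopulationFrequency:
    def test_exac_above_threshold_removed(self):
        assert not filter_population_frequency(make_variant(popfreq_exac=0.02))

    def test_missing_frequencies_kept(self):
        assert filter_population_frequency(
            make_variant(popfreq_1000g=None, popfreq_exac=None)
        )

    def test_exactly_one_percent_kept(self):
        assert filter_population_frequency(make_variant(popfreq_1000g=0.01))

    def test_either_database_suffices(self):
        assert not filter_population_frequency(
            make_variant(popfreq_1000g=0.05, popfreq_exac=0.001)
        )


class TestBlacklistFilter:
    BL = Blacklist(n_normals=10, detection_counts={("1", 1000, "C", "T"): 9})

    def test_blacklisted_key_removed(self):
        assert not filter_blacklist(make_variant(), self.BL)

    def test_absent_key_kept(self):
        assert filter_blacklist(make_variant(pos=2000), self.BL)

    def test_different_alt_allele_kept(self):
        assert filter_blacklist(make_variant(alt="G"), self.BL)


class TestRepeatRegions:
    REPEATS = RegionSet([("chr1", 100, 200)])

    def test_inside_removed(self):
        assert not filter_repeat_regions(make_variant(pos=150), self.REPEATS)

    def test_boundary_half_open(self):
        # 1-based 201 -> 0-based 200, outside [100, 200)
        assert filter_repeat_regions(make_variant(pos=201), self.REPEATS)
        # 1-based 101 -> 0-based 100, the first base inside
        assert not filter_repeat_regions(make_variant(pos=101), self.REPEATS)

    def test_empty_repeat_set_keeps(self):
        assert filter_repeat_regions(make_variant(pos=150), EMPTY_REPEATS)


class TestEvidenceTier:
    @pytest.mark.parametrize(
        "cosmic,vaf,alt_reads,expected",
        [
            (True, 0.015, 6, True),
            (False, 0.015, 20, False),  # VAF not above 2% for non-catalogued
            (True, 0.05, 4, False),     # read minimum binds regardless of VAF
            (False, 0.03, 8, True),
            (False, 0.02, 100, False),  # strict: exactly 2% fails
            (True, 0.01, 50, False),    # strict: exactly 1% fails
        ],
    )
    def test_examples(self, cosmic, vaf, alt_reads, expected):
        v = make_variant(cosmic=cosmic, vaf=vaf, alt_reads=alt_reads, depth=10_000)
        assert filter_evidence_tier(v) is expected

    def test_exhaustive_boundary_table(self):
        """Every (vaf, alt_reads, cosmic) grid point matches the stated rule."""
        for vaf, alt, cosmic in itertools.product(
            [0.0099, 0.01, 0.0101, 0.02, 0.0201], [4, 5, 7, 8], [True, False]
        ):
            v = make_variant(cosmic=cosmic, vaf=vaf, alt_reads=alt, depth=10_000)
            if cosmic:
                expected = vaf > 0.01 and alt >= 5
            else:
                expected = vaf > 0.02 and alt >= 8
            assert filter_evidence_tier(v) is expected, (vaf, alt, cosmic)


def _mixed_variants():
    """A batch exercising every predicate at least once."""
    out = []
    rnd = random.Random(7)
    classes = list(VariantClass)
    for i in range(60):
        depth = rnd.randrange(100, 500)
        alt = rnd.randrange(0, 30)
        out.append(
            make_variant(
                pos=rnd.choice([150, 999, 1000, 2500]),
                variant_class=rnd.choice(classes),
                cosmic=rnd.random() < 0.4,
                vaf=alt / depth,
                alt_reads=alt,
                depth=depth,
                popfreq_exac=rnd.choice([None, 0.001, 0.02]),
                popfreq_1000g=rnd.choice([None, 0.009, 0.5]),
            )
        )
    return out


BL = Blacklist(n_normals=10, detection_counts={("1", 1000, "C", "T"): 9})
REPEATS = RegionSet([("chr1", 100, 200)])


class TestCascade:
    def test_failing_popfreq_recorded_in_trace(self):
        v = make_variant(popfreq_exac=0.02)
        kept, (trace,) = run_cascade([v], EMPTY_BL, EMPTY_REPEATS)
        assert kept == [] and not trace.final_kept
        failed = [name for name, passed, _ in trace.decisions if not passed]
        assert failed == ["population_frequency"]

    def test_trace_lists_each_filter_once(self):
        _, (trace,) = run_cascade([make_variant()], BL, REPEATS)
        names = [name for name, _, _ in trace.decisions]
        assert names == ["functional_class", "population_frequency", "blacklist",
                         "repeat_regions", "evidence_tier"]
        assert trace.final_kept == all(p for _, p, _ in trace.decisions)

    def test_empty_input(self):
        assert run_cascade([], BL, REPEATS) == ([], [])

    def test_kept_equals_brute_force_intersection(self):
        variants = _mixed_variants()
        kept, _ = run_cascade(variants, BL, REPEATS)
        cfg = CascadeConfig()
        expected = [
            v
            for v in variants
            if filter_functional_class(v, cfg)
            and filter_population_frequency(v, cfg)
            and filter_blacklist(v, BL)
            and filter_repeat_regions(v, REPEATS)
            and filter_evidence_tier(v, cfg)
        ]
        assert kept == expected

    def test_order_invariance(self):
        """The kept set is identical under every permutation of the filters."""
        variants = _mixed_variants()
        cfg = CascadeConfig()
        predicates = {
            "functional_class": lambda v: filter_functional_class(v, cfg),
            "population_frequency": lambda v: filter_population_frequency(v, cfg),
            "blacklist": lambda v: filter_blacklist(v, BL),
            "repeat_regions": lambda v: filter_repeat_regions(v, REPEATS),
            "evidence_tier": lambda v: filter_evidence_tier(v, cfg),
        }
        kept_ref, _ = run_cascade(variants, BL, REPEATS)
        for order in itertools.permutations(predicates):
            survivors = list(variants)
            for name in order:
                survivors = [v for v in survivors if predicates[name](v)]
            assert survivors == kept_ref

    def test_idempotence(self):
        variants = _mixed_variants()
        kept, _ = run_cascade(variants, BL, REPEATS)
        kept_again, _ = run_cascade(kept, BL, REPEATS)
        assert kept_again == kept

    def test_min_depth_prefilter_off_by_default(self):
        v = make_variant(vaf=0.5, alt_reads=5, depth=10, cosmic=True)
        kept, _ = run_cascade([v], EMPTY_BL, EMPTY_REPEATS)
        assert kept == [v]
        kept, (trace,) = run_cascade([v], EMPTY_BL, EMPTY_REPEATS,
                                     CascadeConfig(min_depth=20))
        assert kept == [] and trace.first_failed == "min_depth"
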