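"""Ordered tumor-only somatic filtering cascade.

Five independent predicates, applied conjunctively:

1. functional class — keep only missense, stopgain, frameshift indel and
   non-frameshift indel calls (splice retained only if configured);
2. population frequency — drop anything above 1% in 1000 Genomes or ExAC
   (missing frequency counts as 0, i.e. presumed rare);
3. panel-of-normals blacklist — drop recurrent-artifact keys;
4. repeat-masked regions — drop calls inside repeat intervals;
5. evidence tier — catalogued (COSMIC) mutations need VAF > 1% and >= 5
   mutant reads; non-catalogued need VAF > 2% and >= 8 mutant reads.

Because each predicate looks only at the variant itself, the kept set is
invariant under any permutation of filter order; the printed order above is
kept for trace readability and for attributing removals to a first failing
filter in run manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .blacklist import Blacklist
from .model import RegionSet, VariantCall, VariantClass

__all__ = [
    "CascadeConfig",
    "FilterTrace",
    "FILTER_ORDER",
    "filter_functional_class",
    "filter_population_frequency",
    "filter_blacklist",
    "filter_repeat_regions",
    "filter_evidence_tier",
    "run_cascade",
]

KEEP_CLASSES = frozenset(
    {
        VariantClass.missense,
        VariantClass.stopgain,
        VariantClass.frameshift_indel,
        VariantClass.nonframeshift_indel,
    }
)

FILTER_ORDER = (
    "functional_class",
    "population_frequency",
    "blacklist",
    "repeat_regions",
    "evidence_tier",
)


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds of the cascade; defaults are the published values.

    ``keep_splice`` widens the functional keep-list to splice calls (off by
    default).  ``min_depth`` is an optional pre-filter mirroring the primary
    caller's depth requirement; it is disabled (0) by default because depth
    filtering belongs to upstream calling, not interpretation.
    """

    popfreq_max: float = 0.01
    cosmic_min_vaf: float = 0.01
    cosmic_min_reads: int = 5
    noncosmic_min_vaf: float = 0.02
    noncosmic_min_reads: int = 8
    keep_splice: bool = False
    min_depth: int = 0


@dataclass
class FilterTrace:
    """Per-variant decision trail: every configured filter exactly once."""

    variant: VariantCall
    decisions: list[tuple[str, bool, str]] = field(default_factory=list)

    @property
    def final_kept(self) -> bool:
        return all(passed for _, passed, _ in self.decisions)

    @property
    def first_failed(self) -> Optional[str]:
        for name, passed, _ in self.decisions:
            if not passed:
                return name
        return None


def filter_functional_class(v: VariantCall, config: CascadeConfig = CascadeConfig()) -> bool:
    """Keep only protein-altering classes (missense/stopgain/indels)."""
    if v.variant_class in KEEP_CLASSES:
        return True
    return config.keep_splice and v.variant_class is VariantClass.splice


def filter_population_frequency(v: VariantCall, config: CascadeConfig = CascadeConfig()) -> bool:
    """Drop presumed germline: > 1% frequency in either population database.

    Missing frequencies are treated as 0 (variant presumed rare); the bound
    is strict, so exactly 1% is kept.
    """
    g1000 = v.popfreq_1000g if v.popfreq_1000g is not None else 0.0
    exac = v.popfreq_exac if v.popfreq_exac is not None else 0.0
    return not (g1000 > config.popfreq_max or exac > config.popfreq_max)


def filter_blacklist(v: VariantCall, bl: Blacklist) -> bool:
    """Drop variants whose normalized key is a recurrent-artifact key."""
    return not bl.contains_variant(v)


def filter_repeat_regions(v: VariantCall, repeats: RegionSet) -> bool:
    """Drop variants whose position falls inside a repeat-masked interval."""
    return not repeats.contains_variant(v)


def filter_evidence_tier(v: VariantCall, config: CascadeConfig = CascadeConfig()) -> bool:
    """Tiered evidence rule: catalogued hotspots get the laxer threshold.

    VAF bounds are strict ("above 1%/2%"); read minimums are inclusive
    ("a minimum of 5/8 mutant reads").
    """
    if v.cosmic:
        return v.vaf > config.cosmic_min_vaf and v.alt_reads >= config.cosmic_min_reads
    return v.vaf > config.noncosmic_min_vaf and v.alt_reads >= config.noncosmic_min_reads


def _decisions(
    v: VariantCall, bl: Blacklist, repeats: RegionSet, config: CascadeConfig
) -> list[tuple[str, bool, str]]:
    out = []
    if config.min_depth > 0:
        ok = v.depth >= config.min_depth
        out.append(("min_depth", ok, f"depth={v.depth} (min {config.min_depth})"))
    ok = filter_functional_class(v, config)
    out.append(("functional_class", ok, f"class={v.variant_class.value}"))
    ok = filter_population_frequency(v, config)
    out.append(
        ("population_frequency", ok,
         f"1000g={v.popfreq_1000g} exac={v.popfreq_exac} (max {config.popfreq_max})")
    )
    ok = filter_blacklist(v, bl)
    out.append(("blacklist", ok, f"key={v.key}"))
    ok = filter_repeat_regions(v, repeats)
    out.append(("repeat_regions", ok, f"pos0={v.pos - 1}"))
    ok = filter_evidence_tier(v, config)
    tier = "cosmic" if v.cosmic else "non-cosmic"
    out.append(("evidence_tier", ok, f"{tier} vaf={v.vaf:.4g} alt={v.alt_reads}"))
    return out


def run_cascade(
    variants: list[VariantCall],
    bl: Blacklist,
    repeats: RegionSet,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[VariantCall], list[FilterTrace]]:
    """Apply the full cascade; return kept variants and one trace per input."""
    kept: list[VariantCall] = []
    traces: list[FilterTrace] = []
    for v in variants:
        tr = FilterTrace(variant=v, decisions=_decisions(v, bl, repeats, config))
        traces.append(tr)
        if tr.final_kept:
            kept.append(v)
    return kept, traces
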