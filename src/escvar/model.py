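"""Domain types for tumor-only panel variant interpretation.

Conventions used throughout the package:

* variants are 1-based (VCF convention);
* genomic regions are 0-based half-open (BED convention);
* conversion between the two happens only where a variant is intersected
  with a region set;
* chromosome names are compared after stripping an optional ``chr`` prefix,
  so mixed-reference inputs (``chr17`` vs ``17``) interoperate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

__all__ = [
    "VariantClass",
    "Sift",
    "VariantCall",
    "RegionSet",
    "ClinicalRecord",
    "GeneGroupCatalog",
    "normalize_chrom",
    "variant_key",
    "normalize_protein_change",
    "DEFAULT_GENE_GROUPS",
]


class VariantClass(str, enum.Enum):
    """Functional consequence class of a small variant."""

    missense = "missense"
    stopgain = "stopgain"
    frameshift_indel = "frameshift_indel"
    nonframeshift_indel = "nonframeshift_indel"
    splice = "splice"
    synonymous = "synonymous"
    other = "other"


class Sift(str, enum.Enum):
    """SIFT functional prediction; ``missing`` when not annotated."""

    deleterious = "deleterious"
    neutral = "neutral"
    missing = "missing"


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr``/``Chr`` prefix so references interoperate."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        return c[3:]
    return c


def normalize_protein_change(p: Optional[str]) -> str:
    """Canonical protein-notation key: drop ``p.`` prefix, spaces, case.

    Published tables mix notations such as ``p.M1043 V`` (stray space) and
    ``p.288 fs``; both normalize to the same key as ``p.M1043V`` / ``p.288fs``.
    """
    if not p:
        return ""
    s = "".join(p.split())
    if s.lower().startswith("p."):
        s = s[2:]
    return s.upper()


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    # shared suffix first, then shared prefix; keep at least one base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Normalized identity key ``(chrom, pos, ref, alt)`` for cross-sample matching.

    Shared ref/alt prefixes and suffixes are trimmed (suffix first) and the
    position adjusted, so equivalent indel spellings from different callers
    collapse to one key.  Chromosome names lose any ``chr`` prefix.
    """
    pos, ref, alt = _trim_alleles(pos, ref.upper(), alt.upper())
    return (normalize_chrom(chrom), pos, ref, alt)


@dataclass
class VariantCall:
    """One annotated variant observation in a tumor or normal sample.

    ``vaf`` is the variant allele frequency (mutant reads / depth) on [0, 1];
    ``cosmic`` flags catalogue membership, which relaxes the evidence tier;
    population frequencies and SIFT/ClinVar annotations are consumed as
    provided by upstream annotation, never computed here.
    """

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_class: VariantClass
    vaf: float
    alt_reads: int
    depth: int
    cosmic: bool = False
    protein_change: Optional[str] = None
    cdna_change: Optional[str] = None
    popfreq_1000g: Optional[float] = None
    popfreq_exac: Optional[float] = None
    sift: Sift = Sift.missing
    clinvar_sig: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variant_class = VariantClass(self.variant_class)
        self.sift = Sift(self.sift)
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf must lie in [0,1], got {self.vaf!r}")
        if self.alt_reads < 0 or self.depth < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})"
            )
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref!r})")
        for f in (self.popfreq_1000g, self.popfreq_exac):
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValueError(f"population frequency outside [0,1]: {f!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


class RegionSet:
    """A set of genomic intervals (0-based half-open), merged on construction.

    ``total_bases`` is the length of the union, so it is invariant under
    interval reordering, splitting and overlap.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]], label: str = ""):
        self.label = label
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"interval start >= end: ({chrom}, {start}, {end})")
            trees.setdefault(normalize_chrom(chrom), IntervalTree()).addi(start, end)
        for t in trees.values():
            t.merge_overlaps(strict=False)  # also merges adjacent
        self._trees = trees

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    @property
    def total_bases(self) -> int:
        return sum(iv.end - iv.begin for t in self._trees.values() for iv in t)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        t = self._trees.get(normalize_chrom(chrom))
        return bool(t is not None and t.overlaps_point(pos0))

    def contains_variant(self, v: VariantCall) -> bool:
        """Membership of a variant's 1-based position (converted to 0-based)."""
        return self.contains(v.chrom, v.pos - 1)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegionSet({self.label!r}, n={len(self)}, bases={self.total_bases})"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Stage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"


class TumorSite(str, enum.Enum):
    upper = "upper"
    mid = "mid"
    lower = "lower"


class MacroType(str, enum.Enum):
    polypoid = "polypoid"
    ulcerating = "ulcerating"
    infiltrative = "infiltrative"


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates (descriptive only; no survival model)."""

    patient_id: str
    sex: Sex
    age: int
    stage: Stage
    site: TumorSite
    macroscopic_type: MacroType
    smoker: Optional[bool] = None
    overall_survival_months: Optional[float] = None
    alive: Optional[bool] = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.stage = Stage(self.stage)
        self.site = TumorSite(self.site)
        self.macroscopic_type = MacroType(self.macroscopic_type)
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")


# Functional gene groups used for pathway-level profiling. A gene may belong
# to more than one group.
DEFAULT_GENE_GROUPS: dict[str, frozenset[str]] = {
    "RTK": frozenset({"MET", "CSF1R", "FLT3", "FLT1", "ERBB2", "FGFR4", "PDGFRB"}),
    "RAS_PI3K": frozenset({"PIK3CA", "AKT1", "PTEN", "NF1"}),
    "histone_modification": frozenset({"EP300", "CREBBP", "KMT2A", "KMT2B", "KDM5A"}),
    "cell_cycle_dna_repair": frozenset({"TP53", "RB1", "CCND1", "CDKN2A"}),
    "NOTCH": frozenset({"NOTCH1", "FBXW7"}),
    "MMR_proofreading": frozenset({"MSH2", "MLH1", "PMS1", "PMS2", "POLE"}),
}


class GeneGroupCatalog:
    """Mapping of functional group name -> set of gene symbols."""

    def __init__(self, groups: Optional[dict[str, Iterable[str]]] = None):
        source = groups if groups is not None else DEFAULT_GENE_GROUPS
        self._groups: dict[str, frozenset[str]] = {}
        for name, genes in source.items():
            gs = frozenset(g.strip() for g in genes)
            if any(not g for g in gs):
                raise ValueError(f"empty gene symbol in group {name!r}")
            self._groups[name] = gs

    def __getitem__(self, name: str) -> frozenset[str]:
        if name not in self._groups:
            raise KeyError(f"unknown gene group {name!r}")
        return self._groups[name]

    def __contains__(self, name: str) -> bool:
        return name in self._groups

    @property
    def names(self) -> list[str]:
        return list(self._groups)

    def items(self):
        return self._groups.items()
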