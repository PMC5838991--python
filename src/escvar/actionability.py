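"""Clinical-actionability matching.

Kept alterations (small variants and copy-number calls) are matched against
a knowledge base of gene + alteration-pattern rules, each tied to a therapy
with reported sensitivity in clinical practice or active trials.  The
shipped default knowledge base encodes the actionable alterations reported
for the 15-tumor esophageal sarcomatoid carcinoma cohort this package
analyses (AKT1/MET/PIK3CA amplifications, PIK3CA/IDH1/TP53 hotspot changes,
TP53 truncations, CREBBP/HNF1A/PTEN lesions and an NF1 splice disruption).

Pattern kinds:

``amplification``
    matches a CNV gain call on the gene;
``exact_protein_change``
    matches the normalized protein notation (``p.`` prefix, spaces and case
    are ignored, so ``p.M1043 V`` matches ``p.M1043V``);
``truncation_class``
    value ``nonsense`` matches stopgain calls, ``frameshift`` matches
    frameshift indels;
``splice_disruption``
    matches a variant whose cDNA notation carries an intronic offset
    (e.g. ``c.A3975-2T``), or any splice-class call; an optional value
    restricts to one exact cDNA change;
``any_deleterious``
    matches any SIFT-deleterious call on the gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd

from .cnv import CnvCall, CopyNumberSegment
from .model import VariantCall, VariantClass, normalize_protein_change

__all__ = [
    "PATTERN_TYPES",
    "ActionabilityRule",
    "ActionabilityMatch",
    "load_knowledge_base",
    "match_alterations",
    "actionable_patients",
]

PATTERN_TYPES = frozenset(
    {"amplification", "exact_protein_change", "truncation_class",
     "splice_disruption", "any_deleterious"}
)

# intronic offset in HGVS-like cDNA notation, e.g. c.A3975-2T or c.1234+5G>A
_SPLICE_NOTATION = re.compile(r"C\.[A-Z]*\d+[+-]\d+")


def _normalize_cdna(c: str) -> str:
    return "".join(c.split()).upper()


def has_splice_notation(cdna_change: str | None) -> bool:
    if not cdna_change:
        return False
    return bool(_SPLICE_NOTATION.search(_normalize_cdna(cdna_change)))


@dataclass(frozen=True)
class ActionabilityRule:
    gene: str
    pattern_type: str
    pattern_value: str
    therapy: str
    evidence_note: str = ""
    citation_tag: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("rule missing gene symbol")
        if self.pattern_type not in PATTERN_TYPES:
            raise ValueError(f"unknown pattern type {self.pattern_type!r}")
        if self.pattern_type == "exact_protein_change" and not self.pattern_value:
            raise ValueError("exact_protein_change rule needs a protein notation")
        if self.pattern_type == "truncation_class" and self.pattern_value not in (
            "nonsense", "frameshift",
        ):
            raise ValueError(
                f"truncation_class value must be nonsense|frameshift, "
                f"got {self.pattern_value!r}"
            )

    def matches_variant(self, v: VariantCall) -> bool:
        if v.gene != self.gene:
            return False
        if self.pattern_type == "exact_protein_change":
            return (
                normalize_protein_change(v.protein_change)
                == normalize_protein_change(self.pattern_value)
            )
        if self.pattern_type == "truncation_class":
            target = (
                VariantClass.stopgain
                if self.pattern_value == "nonsense"
                else VariantClass.frameshift_indel
            )
            return v.variant_class is target
        if self.pattern_type == "splice_disruption":
            if self.pattern_value:
                return bool(
                    v.cdna_change
                    and _normalize_cdna(v.cdna_change) == _normalize_cdna(self.pattern_value)
                )
            return has_splice_notation(v.cdna_change) or v.variant_class is VariantClass.splice
        if self.pattern_type == "any_deleterious":
            return v.sift.value == "deleterious"
        return False  # amplification never matches a small variant

    def matches_cnv(self, s: CopyNumberSegment) -> bool:
        return (
            self.pattern_type == "amplification"
            and s.gene == self.gene
            and s.call is CnvCall.gain
        )


@dataclass(frozen=True)
class ActionabilityMatch:
    patient_id: str
    gene: str
    alteration: str
    rule: ActionabilityRule
    therapy: str


_KB_COLUMNS = ["gene", "pattern_type", "pattern_value", "therapy",
               "evidence_note", "citation_tag"]


def load_knowledge_base(path: Union[str, Path] = "default") -> list[ActionabilityRule]:
    """Load actionability rules from a TSV, or the shipped default KB."""
    if str(path) == "default":
        source = resources.files("escvar.data").joinpath("actionability_kb.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_KB_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"knowledge base missing columns {sorted(missing)}")
    rules = []
    for i, row in df.iterrows():
        try:
            rules.append(
                ActionabilityRule(
                    gene=row["gene"].strip(),
                    pattern_type=row["pattern_type"].strip(),
                    pattern_value=row.get("pattern_value", "").strip(),
                    therapy=row["therapy"].strip(),
                    evidence_note=str(row.get("evidence_note", "")).strip(),
                    citation_tag=str(row.get("citation_tag", "")).strip(),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed knowledge-base rule at index {i}: {exc}") from exc
    return rules


def match_alterations(
    kept: list[VariantCall],
    cnvs: list[CopyNumberSegment],
    rules: list[ActionabilityRule],
) -> list[ActionabilityMatch]:
    """All (patient, rule, alteration) matches; adding rules only adds matches."""
    matches: list[ActionabilityMatch] = []
    for rule in rules:
        for v in kept:
            if rule.matches_variant(v):
                desc = v.protein_change or v.cdna_change or v.variant_class.value
                matches.append(
                    ActionabilityMatch(
                        patient_id=v.patient_id, gene=v.gene,
                        alteration=desc, rule=rule, therapy=rule.therapy,
                    )
                )
        for s in cnvs:
            if rule.matches_cnv(s):
                matches.append(
                    ActionabilityMatch(
                        patient_id=s.patient_id, gene=s.gene or "",
                        alteration="amplification", rule=rule, therapy=rule.therapy,
                    )
                )
    return matches


def actionable_patients(matches: list[ActionabilityMatch]) -> set[str]:
    """Distinct patients with at least one actionability match."""
    return {m.patient_id for m in matches}


def matches_to_frame(matches: list[ActionabilityMatch]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": m.patient_id,
            "gene": m.gene,
            "alteration": m.alteration,
            "pattern_type": m.rule.pattern_type,
            "pattern_value": m.rule.pattern_value,
            "therapy": m.therapy,
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows,
        columns=["patient_id", "gene", "alteration", "pattern_type",
                 "pattern_value", "therapy"],
    )
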