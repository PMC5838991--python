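"""Cohort-level mutation profiling.

Builds the gene x patient alteration matrix behind an oncoprint-style
summary: per-gene and per-pathway alteration frequencies, mutual-exclusivity
counts among gene sets (e.g. receptor tyrosine kinases), a triage table for
mismatch-repair / proofreading lesions carrying SIFT and ClinVar columns,
and a Fisher-exact comparison of an observed alteration frequency against a
reference cohort.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from scipy import stats

from .cnv import CnvCall, CopyNumberSegment
from .model import ClinicalRecord, GeneGroupCatalog, VariantCall, VariantClass

__all__ = [
    "CohortMatrix",
    "build_matrix",
    "gene_frequency",
    "pathway_frequency",
    "mutual_exclusivity_overlap",
    "triage_mmr_variants",
    "clinvar_pathogenic",
    "compare_to_reference",
]

# alteration categories a matrix cell may carry
CATEGORIES = frozenset(
    {"missense", "truncating", "nonframeshift_indel", "splice",
     "amplification", "loss", "structural"}
)

_CLASS_TO_CATEGORY = {
    VariantClass.missense: "missense",
    VariantClass.stopgain: "truncating",
    VariantClass.frameshift_indel: "truncating",
    VariantClass.nonframeshift_indel: "nonframeshift_indel",
    VariantClass.splice: "splice",
}


class CohortMatrix:
    """Gene x patient alteration-category matrix with pathway groupings."""

    def __init__(
        self,
        patients: list[str],
        genes: list[str],
        cells: dict[tuple[str, str], set[str]],
        groups: Optional[GeneGroupCatalog] = None,
    ):
        self.patients = list(patients)
        self.genes = list(genes)
        self.cells = cells
        self.groups = groups if groups is not None else GeneGroupCatalog()
        bad = CATEGORIES.union(*cells.values()) - CATEGORIES if cells else set()
        if bad:
            raise ValueError(f"unknown alteration categories: {sorted(bad)}")

    def cell(self, gene: str, patient: str) -> set[str]:
        return self.cells.get((gene, patient), set())

    def altered_genes(self, patient: str) -> set[str]:
        return {g for g in self.genes if self.cell(g, patient)}

    def to_frame(self) -> pd.DataFrame:
        """Genes x patients frame, cells semicolon-joined category sets."""
        data = {
            p: [";".join(sorted(self.cell(g, p))) for g in self.genes]
            for p in self.patients
        }
        return pd.DataFrame(data, index=self.genes, columns=self.patients)


def build_matrix(
    kept: list[VariantCall],
    cnvs: list[CopyNumberSegment],
    clinical: list[ClinicalRecord],
    groups: Optional[GeneGroupCatalog] = None,
) -> CohortMatrix:
    """Assemble the matrix from kept small variants and non-neutral CNVs.

    Stopgain and frameshift calls map to the ``truncating`` category, CNV
    gains to ``amplification`` and CNV losses to ``loss``.  Every clinical
    patient gets a column, altered or not; variant/CNV patient ids absent
    from the clinical table are an error.  Rows cover the observed genes
    plus every catalog gene, so an unaltered catalog gene reports a
    frequency of 0 rather than being absent.
    """
    patients = [c.patient_id for c in clinical]
    known = set(patients)
    offenders = sorted(
        {v.patient_id for v in kept if v.patient_id not in known}
        | {s.patient_id for s in cnvs if s.patient_id not in known}
    )
    if offenders:
        raise ValueError(f"patient ids missing from clinical table: {offenders}")

    cells: dict[tuple[str, str], set[str]] = {}
    genes: list[str] = []

    def add(gene: str, patient: str, category: str) -> None:
        if gene not in genes:
            genes.append(gene)
        cells.setdefault((gene, patient), set()).add(category)

    for v in kept:
        category = _CLASS_TO_CATEGORY.get(v.variant_class)
        if category is not None and v.gene:
            add(v.gene, v.patient_id, category)
    for s in cnvs:
        if s.gene is None:
            continue
        if s.call is CnvCall.gain:
            add(s.gene, s.patient_id, "amplification")
        elif s.call is CnvCall.loss:
            add(s.gene, s.patient_id, "loss")

    catalog = groups if groups is not None else GeneGroupCatalog()
    all_genes = set(genes).union(*(gs for _, gs in catalog.items()))
    return CohortMatrix(patients=patients, genes=sorted(all_genes), cells=cells,
                        groups=catalog)


def gene_frequency(m: CohortMatrix, gene: str) -> tuple[float, int]:
    """(fraction, count) of patients with any alteration in ``gene``."""
    if gene not in m.genes:
        raise KeyError(f"gene {gene!r} not in matrix")
    count = sum(1 for p in m.patients if m.cell(gene, p))
    return count / len(m.patients), count


def pathway_frequency(m: CohortMatrix, group_name: str) -> tuple[float, int]:
    """(fraction, count) of patients altered in >= 1 gene of the group."""
    genes = m.groups[group_name]
    count = sum(
        1 for p in m.patients if any(m.cell(g, p) for g in genes if g in m.genes)
    )
    return count / len(m.patients), count


def mutual_exclusivity_overlap(m: CohortMatrix, genes: Iterable[str]) -> int:
    """Number of patients altered in >= 2 of the listed genes (0 = exclusive)."""
    gene_set = set(genes)
    unknown = gene_set - set(m.genes)
    if unknown:
        raise KeyError(f"genes not in matrix: {sorted(unknown)}")
    return sum(
        1
        for p in m.patients
        if sum(1 for g in gene_set if m.cell(g, p)) >= 2
    )


def clinvar_pathogenic(clinvar_sig: list[str]) -> bool:
    """Whether a ClinVar annotation amounts to a pathogenic assertion.

    Requires a pathogenic/likely-pathogenic term and the absence of any
    benign-class term, so conflicting annotations such as
    ``Likely_benign;pathogenic`` do not count as pathogenic.
    """
    terms = [t.strip().lower() for t in clinvar_sig]
    has_path = any(t in ("pathogenic", "likely_pathogenic") for t in terms)
    has_benign = any("benign" in t for t in terms)
    return has_path and not has_benign


def triage_mmr_variants(
    kept: list[VariantCall],
    group: Optional[Iterable[str]] = None,
    groups: Optional[GeneGroupCatalog] = None,
) -> pd.DataFrame:
    """Table of kept lesions in MMR / proofreading genes with annotations.

    One row per kept SNV/indel in the gene set, carrying SIFT and ClinVar
    columns verbatim plus a derived ``pathogenic`` flag per
    :func:`clinvar_pathogenic`.
    """
    if group is None:
        catalog = groups if groups is not None else GeneGroupCatalog()
        group = catalog["MMR_proofreading"]
    gene_set = set(group)
    rows = [
        {
            "patient_id": v.patient_id,
            "gene": v.gene,
            "protein_change": v.protein_change or "",
            "cdna_change": v.cdna_change or "",
            "sift": v.sift.value,
            "clinvar_sig": ";".join(v.clinvar_sig),
            "pathogenic": clinvar_pathogenic(v.clinvar_sig),
        }
        for v in kept
        if v.gene in gene_set
    ]
    return pd.DataFrame(
        rows,
        columns=["patient_id", "gene", "protein_change", "cdna_change",
                 "sift", "clinvar_sig", "pathogenic"],
    )


def compare_to_reference(count: int, n: int, ref_count: int, ref_n: int) -> float:
    """Two-sided Fisher exact p-value comparing cohort vs reference frequency."""
    import numbers

    vals = (count, n, ref_count, ref_n)
    if any(not isinstance(x, numbers.Integral) or isinstance(x, bool) for x in vals):
        raise ValueError(f"counts must be integers, got {vals!r}")
    if any(x < 0 for x in vals) or count > n or ref_count > ref_n:
        raise ValueError(f"invalid 2x2 margins: {vals!r}")
    table = [[count, n - count], [ref_count, ref_n - ref_count]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def write_matrix(m: CohortMatrix, path: Union[str, Path]) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene")


def frequency_table(m: CohortMatrix) -> pd.DataFrame:
    """Per-gene alteration counts/fractions plus per-group pathway rows."""
    rows = []
    for g in m.genes:
        frac, count = gene_frequency(m, g)
        rows.append({"name": g, "kind": "gene", "count": count,
                     "fraction": round(frac, 4)})
    for name in m.groups.names:
        frac, count = pathway_frequency(m, name)
        rows.append({"name": name, "kind": "pathway", "count": count,
                     "fraction": round(frac, 4)})
    return pd.DataFrame(rows, columns=["name", "kind", "count", "fraction"])
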