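"""Loaders for the small curated tables shipped with the package.

These encode the alterations reported for the published 15-tumor esophageal
sarcomatoid carcinoma cohort this package re-analyses: the clinically
actionable alteration set (small variants plus amplifications) and the
mismatch-repair / proofreading lesion table with SIFT and ClinVar
annotations.  Genomic coordinates for class-level entries the source tables
report without a specific change are synthetic placeholders; gene, patient,
protein/cDNA notation and annotation columns follow the published tables.
"""

from __future__ import annotations

from importlib import resources

from .cnv import CopyNumberSegment, read_segments
from .io import read_variant_table
from .model import VariantCall

__all__ = ["reported_actionable_alterations", "reported_mmr_lesions"]


def _data_path(name: str):
    return resources.as_file(resources.files("escvar.data").joinpath(name))


def reported_actionable_alterations() -> tuple[list[VariantCall], list[CopyNumberSegment]]:
    """The cohort's reported actionable alterations: (small variants, CNV gains)."""
    with _data_path("actionable_cohort_variants.tsv") as p:
        variants = read_variant_table(p, dialect="tsv")
    with _data_path("actionable_cohort_cnv.tsv") as p:
        cnvs = read_segments(p)
    return variants, cnvs


def reported_mmr_lesions() -> list[VariantCall]:
    """The cohort's reported MMR / proofreading lesions with annotations."""
    with _data_path("mmr_cohort_variants.tsv") as p:
        return read_variant_table(p, dialect="tsv")
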