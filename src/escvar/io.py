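"""Readers and writers for the file formats the pipeline touches.

Variant tables travel as MAF-like TSVs with the canonical columns listed in
``VARIANT_COLUMNS`` (documented in the README), or as VCFs whose per-sample
``AD``/``DP`` FORMAT fields supply the evidence counts and whose INFO fields
carry the annotations.  Regions are plain BED (0-based half-open); coverage
tables and the clinical table are TSVs.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import (
    ClinicalRecord,
    RegionSet,
    Sift,
    VariantCall,
    VariantClass,
)

__all__ = [
    "VARIANT_COLUMNS",
    "read_variant_table",
    "write_variant_table",
    "read_bed",
    "read_gene_bed",
    "read_coverage",
    "write_coverage",
    "read_clinical_table",
    "write_clinical_table",
]

VARIANT_COLUMNS = [
    "patient_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "variant_class",
    "protein_change",
    "cdna_change",
    "vaf",
    "alt_reads",
    "depth",
    "cosmic",
    "popfreq_1000g",
    "popfreq_exac",
    "sift",
    "clinvar_sig",
]

# INFO keys consulted when reading a VCF; absent keys become missing values.
_VCF_INFO_KEYS = {
    "gene": "GENE",
    "variant_class": "VARIANT_CLASS",
    "protein_change": "PROTEIN_CHANGE",
    "cdna_change": "CDNA_CHANGE",
    "cosmic": "COSMIC",
    "popfreq_1000g": "POPFREQ_1000G",
    "popfreq_exac": "POPFREQ_EXAC",
    "sift": "SIFT",
    "clinvar_sig": "CLNSIG",
}


def _opt_float(cell) -> Optional[float]:
    if cell is None:
        return None
    if isinstance(cell, float) and math.isnan(cell):
        return None
    s = str(cell).strip()
    if s in ("", ".", "NA", "nan"):
        return None
    return float(s)


def _opt_str(cell) -> Optional[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    return s or None


def _parse_bool(cell) -> bool:
    s = str(cell).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f", "", "nan", "."):
        return False
    raise ValueError(f"cannot interpret boolean cell {cell!r}")


def _row_to_variant(row: pd.Series, line_no: int) -> VariantCall:
    try:
        clinvar_raw = _opt_str(row.get("clinvar_sig"))
        clinvar = [t for t in clinvar_raw.split(";") if t] if clinvar_raw else []
        sift_raw = _opt_str(row.get("sift"))
        return VariantCall(
            patient_id=str(row["patient_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]).strip(),
            alt=str(row["alt"]).strip(),
            gene=str(row["gene"]).strip(),
            variant_class=VariantClass(str(row["variant_class"]).strip()),
            protein_change=_opt_str(row.get("protein_change")),
            cdna_change=_opt_str(row.get("cdna_change")),
            vaf=float(row["vaf"]),
            alt_reads=int(row["alt_reads"]),
            depth=int(row["depth"]),
            cosmic=_parse_bool(row.get("cosmic")),
            popfreq_1000g=_opt_float(row.get("popfreq_1000g")),
            popfreq_exac=_opt_float(row.get("popfreq_exac")),
            sift=Sift(sift_raw.lower()) if sift_raw else Sift.missing,
            clinvar_sig=clinvar,
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"malformed variant row at line {line_no}: {exc}") from exc


def _read_variant_tsv(path: Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"patient_id", "chrom", "pos", "ref", "alt", "gene", "variant_class",
               "vaf", "alt_reads", "depth"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    variants = []
    for i, row in df.iterrows():
        # +2: header line plus 1-based numbering
        variants.append(_row_to_variant(row, line_no=int(i) + 2))
    return variants


def _read_variant_vcf(path: Path) -> list[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantCall] = []
    for rec in vcf:
        info = {k: rec.INFO.get(v) for k, v in _VCF_INFO_KEYS.items()}
        vclass = VariantClass(str(info["variant_class"] or "other"))
        sift_raw = _opt_str(info["sift"])
        clinvar_raw = _opt_str(info["clinvar_sig"])
        clinvar = [t for t in clinvar_raw.split(";") if t] if clinvar_raw else []
        for si, sample in enumerate(samples):
            ad = rec.format("AD")
            dp = rec.format("DP")
            alt_reads = int(ad[si][1])
            depth = int(dp[si][0]) if dp is not None else int(ad[si].sum())
            if depth == 0:
                continue
            variants.append(
                VariantCall(
                    patient_id=sample,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0],
                    gene=str(info["gene"] or ""),
                    variant_class=vclass,
                    protein_change=_opt_str(info["protein_change"]),
                    cdna_change=_opt_str(info["cdna_change"]),
                    vaf=alt_reads / depth,
                    alt_reads=alt_reads,
                    depth=depth,
                    cosmic=bool(info["cosmic"]),
                    popfreq_1000g=_opt_float(info["popfreq_1000g"]),
                    popfreq_exac=_opt_float(info["popfreq_exac"]),
                    sift=Sift(sift_raw.lower()) if sift_raw else Sift.missing,
                    clinvar_sig=clinvar,
                )
            )
    return variants


def read_variant_table(path: Union[str, Path], dialect: str = "tsv") -> list[VariantCall]:
    """Read annotated variant calls from a TSV (canonical columns) or a VCF.

    For VCF input, VAF is recomputed as ``AD[alt] / DP`` per sample rather
    than trusting an AF field.  Every row must satisfy the
    :class:`~escvar.model.VariantCall` invariants; a violation raises
    ``ValueError`` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def variants_to_frame(variants: list[VariantCall]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "patient_id": v.patient_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "variant_class": v.variant_class.value,
                "protein_change": v.protein_change or "",
                "cdna_change": v.cdna_change or "",
                "vaf": repr(v.vaf),
                "alt_reads": v.alt_reads,
                "depth": v.depth,
                "cosmic": str(v.cosmic),
                "popfreq_1000g": "" if v.popfreq_1000g is None else repr(v.popfreq_1000g),
                "popfreq_exac": "" if v.popfreq_exac is None else repr(v.popfreq_exac),
                "sift": "" if v.sift is Sift.missing else v.sift.value,
                "clinvar_sig": ";".join(v.clinvar_sig),
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variant_table(variants: list[VariantCall], path: Union[str, Path]) -> None:
    """Write variants as a canonical TSV; a read-back reproduces every field.

    Floats are written with ``repr`` so the round trip is exact, and missing
    annotation cells stay empty rather than being zero-filled.
    """
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_bed(path: Union[str, Path], label: str = "") -> RegionSet:
    """Read a 3+ column BED into a merged :class:`RegionSet`."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            intervals.append((chrom, start, end))
    return RegionSet(intervals, label=label or Path(path).stem)


def read_gene_bed(path: Union[str, Path]) -> list[tuple[str, int, int, str]]:
    """Read a 4-column BED of named (gene) intervals, without merging."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns (chrom start end name)")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            out.append((parts[0], start, end, parts[3]))
    return out


def read_coverage(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-bin coverage TSV (chrom, start, end, mean_coverage[, gene])."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "mean_coverage"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: coverage table needs columns {sorted(required)}")
    return df


def write_coverage(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)


_CLINICAL_COLUMNS = [
    "patient_id", "sex", "age", "stage", "site", "macroscopic_type",
    "smoker", "overall_survival_months", "alive",
]


def read_clinical_table(path: Union[str, Path]) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    seen = set()
    for i, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in seen:
            raise ValueError(f"{path}: duplicate patient_id {pid!r} at line {int(i) + 2}")
        seen.add(pid)
        smoker = _opt_str(row.get("smoker"))
        alive = _opt_str(row.get("alive"))
        os_m = _opt_float(row.get("overall_survival_months"))
        records.append(
            ClinicalRecord(
                patient_id=pid,
                sex=row["sex"],
                age=int(row["age"]),
                stage=row["stage"],
                site=row["site"],
                macroscopic_type=row["macroscopic_type"],
                smoker=None if smoker is None else _parse_bool(smoker),
                overall_survival_months=os_m,
                alive=None if alive is None else _parse_bool(alive),
            )
        )
    return records


def write_clinical_table(records: list[ClinicalRecord], path: Union[str, Path]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "sex": r.sex.value,
                "age": r.age,
                "stage": r.stage.value,
                "site": r.site.value,
                "macroscopic_type": r.macroscopic_type.value,
                "smoker": "" if r.smoker is None else str(r.smoker),
                "overall_survival_months": (
                    "" if r.overall_survival_months is None else repr(r.overall_survival_months)
                ),
                "alive": "" if r.alive is None else str(r.alive),
            }
        )
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)
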