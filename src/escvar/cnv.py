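"""Binned log2 tumor/reference coverage ratios and gain/loss classification.

Per bin the statistic is ``log2((T_i / median(T)) / (R_i / median(R)))``
where medians are genome-wide per-sample medians — median normalization
removes library-size differences without modeling GC content.  Contiguous
bins of one gene are averaged into a single per-gene segment, and a segment
is called a gain when its mean log2 ratio is >= +0.6 and a loss when
<= -0.6 (the cutoff corresponds to roughly 1.5-fold gain / 0.66-fold loss).
The cutoff boundary is inclusive.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "CnvCall",
    "CopyNumberSegment",
    "LOG2_CUTOFF",
    "classify_segment",
    "log2_to_fold",
    "compute_log2_ratios",
    "read_segments",
    "write_segments",
]

LOG2_CUTOFF = 0.6


class CnvCall(str, enum.Enum):
    gain = "gain"
    loss = "loss"
    neutral = "neutral"


def classify_segment(log2_ratio: float, cutoff: float = LOG2_CUTOFF) -> CnvCall:
    """Gain iff log2 >= +cutoff, loss iff <= -cutoff, else neutral."""
    if not math.isfinite(log2_ratio):
        raise ValueError(f"non-finite log2 ratio: {log2_ratio!r}")
    if log2_ratio >= cutoff:
        return CnvCall.gain
    if log2_ratio <= -cutoff:
        return CnvCall.loss
    return CnvCall.neutral


def log2_to_fold(log2_ratio: float) -> float:
    """Fold change 2**log2; the +-0.6 cutoff maps to 1.52x / 0.66x."""
    return float(2.0 ** log2_ratio)


@dataclass
class CopyNumberSegment:
    """A genomic interval with its mean log2 ratio and gain/loss call."""

    patient_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    gene: Optional[str] = None
    call: CnvCall = None  # type: ignore[assignment]
    cutoff: float = LOG2_CUTOFF

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start >= end: {self.start} >= {self.end}")
        derived = classify_segment(self.log2_ratio, self.cutoff)
        if self.call is None:
            self.call = derived
        else:
            self.call = CnvCall(self.call)
            if self.call is not derived:
                raise ValueError(
                    f"call {self.call.value!r} inconsistent with log2 "
                    f"{self.log2_ratio:.3f} at cutoff {self.cutoff}"
                )


def _merged_bins(tumor_cov: pd.DataFrame, ref_cov: pd.DataFrame) -> pd.DataFrame:
    t = tumor_cov.copy()
    r = ref_cov.copy()
    for df in (t, r):
        df["chrom"] = df["chrom"].map(normalize_chrom)
    merged = t.merge(
        r[["chrom", "start", "end", "mean_coverage"]],
        on=["chrom", "start", "end"],
        how="inner",
        suffixes=("_tumor", "_ref"),
    )
    if len(merged) != len(t) or len(merged) != len(r):
        raise ValueError(
            f"tumor and reference coverage bins differ "
            f"({len(t)} vs {len(r)} bins, {len(merged)} shared)"
        )
    return merged


def compute_log2_ratios(
    tumor_cov: pd.DataFrame,
    ref_cov: pd.DataFrame,
    patient_id: str = "",
    cutoff: float = LOG2_CUTOFF,
) -> list[CopyNumberSegment]:
    """Per-gene segments of median-normalized log2 tumor/reference ratios.

    Both tables need columns ``chrom, start, end, mean_coverage`` over the
    same bins; a ``gene`` column (on either table) groups bins into per-gene
    segments, otherwise each bin becomes its own segment.  Bins with zero or
    missing reference (or tumor) coverage are dropped with a warning.
    """
    merged = _merged_bins(tumor_cov, ref_cov)
    if "gene" not in merged.columns:
        merged["gene"] = None

    bad = (
        (merged["mean_coverage_ref"] <= 0)
        | (merged["mean_coverage_tumor"] <= 0)
        | merged["mean_coverage_ref"].isna()
        | merged["mean_coverage_tumor"].isna()
    )
    if bad.any():
        logger.warning(
            "dropping %d/%d bins with zero or missing coverage", int(bad.sum()), len(merged)
        )
        merged = merged[~bad]
    if merged.empty:
        raise ValueError("no usable bins after dropping zero-coverage bins")

    t_med = float(merged["mean_coverage_tumor"].median())
    r_med = float(merged["mean_coverage_ref"].median())
    merged = merged.assign(
        log2_ratio=np.log2(
            (merged["mean_coverage_tumor"] / t_med) / (merged["mean_coverage_ref"] / r_med)
        )
    )

    segments: list[CopyNumberSegment] = []
    if merged["gene"].notna().any():
        for (chrom, gene), grp in merged.groupby(["chrom", "gene"], sort=True, dropna=False):
            segments.append(
                CopyNumberSegment(
                    patient_id=patient_id,
                    chrom=str(chrom),
                    start=int(grp["start"].min()),
                    end=int(grp["end"].max()),
                    log2_ratio=float(grp["log2_ratio"].mean()),
                    gene=None if pd.isna(gene) else str(gene),
                    cutoff=cutoff,
                )
            )
    else:
        for row in merged.itertuples():
            segments.append(
                CopyNumberSegment(
                    patient_id=patient_id,
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    log2_ratio=float(row.log2_ratio),
                    gene=None,
                    cutoff=cutoff,
                )
            )
    return segments


_SEGMENT_COLUMNS = ["patient_id", "chrom", "start", "end", "gene", "log2_ratio", "call"]


def write_segments(segments: list[CopyNumberSegment], path: Union[str, Path]) -> None:
    rows = [
        {
            "patient_id": s.patient_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "gene": s.gene or "",
            "log2_ratio": repr(s.log2_ratio),
            "call": s.call.value,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments(path: Union[str, Path]) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "gene": str},
                     keep_default_na=False, float_precision="round_trip")
    out = []
    for row in df.itertuples():
        out.append(
            CopyNumberSegment(
                patient_id=str(row.patient_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                log2_ratio=float(row.log2_ratio),
                gene=str(row.gene) or None,
                call=CnvCall(row.call),
            )
        )
    return out
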