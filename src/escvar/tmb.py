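"""Tumor mutation burden: non-synonymous and indel mutations per megabase.

The numerator counts kept variants whose functional class is missense,
stopgain, frameshift indel or non-frameshift indel (the cascade keep-list,
so stopgain counts as non-synonymous while synonymous and splice calls do
not); copy-number events are excluded.  The denominator is the merged
unique target footprint of the panel in Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .filters import KEEP_CLASSES
from .model import RegionSet, VariantCall

__all__ = ["TMBResult", "compute_tmb"]


@dataclass(frozen=True)
class TMBResult:
    patient_id: str
    eligible_count: int
    panel_mb: float
    tmb: float


def compute_tmb(
    kept: list[VariantCall],
    panel: RegionSet,
    patients: Optional[Iterable[str]] = None,
) -> dict[str, TMBResult]:
    """Per-patient TMB over the panel footprint.

    ``patients`` may supply the full cohort so that patients with zero
    eligible mutations still receive a TMB of 0; otherwise only patients
    present in ``kept`` are reported.
    """
    if panel.total_bases <= 0:
        raise ValueError("panel footprint is empty")
    panel_mb = panel.total_bases / 1e6
    counts: dict[str, int] = {}
    if patients is not None:
        counts = {str(p): 0 for p in patients}
    for v in kept:
        if v.variant_class in KEEP_CLASSES:
            counts[v.patient_id] = counts.get(v.patient_id, 0) + 1
    return {
        pid: TMBResult(patient_id=pid, eligible_count=c, panel_mb=panel_mb,
                       tmb=c / panel_mb)
        for pid, c in counts.items()
    }


def write_tmb(results: dict[str, TMBResult], path: Union[str, Path]) -> None:
    rows = [
        {"patient_id": r.patient_id, "eligible_count": r.eligible_count,
         "panel_mb": repr(r.panel_mb), "tmb": repr(r.tmb)}
        for r in sorted(results.values(), key=lambda r: r.patient_id)
    ]
    pd.DataFrame(rows, columns=["patient_id", "eligible_count", "panel_mb", "tmb"]
                 ).to_csv(path, sep="\t", index=False)
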