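"""Panel-of-normals blacklist of recurrent sequencing artifacts.

Tumor-only calling cannot subtract a matched normal, so recurrent technical
artifacts are identified from a cohort of normal samples sequenced on the
same platform: a variant counts as *detected* in a normal when it has at
least 3 mutant reads and a VAF strictly above 1%, and a variant key detected
in strictly more than 20% of the normals is blacklisted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .model import VariantCall

__all__ = ["Blacklist", "detected_in_normal", "build_blacklist",
           "read_blacklist", "write_blacklist"]

DETECTION_MIN_READS = 3
DETECTION_MIN_VAF = 0.01
DEFAULT_RECURRENCE_FRACTION = 0.20

Key = tuple[str, int, str, str]


def detected_in_normal(
    v: VariantCall,
    min_reads: int = DETECTION_MIN_READS,
    min_vaf: float = DETECTION_MIN_VAF,
) -> bool:
    """True iff the variant is considered detected in a normal sample.

    The read-count bound is inclusive (>= 3) and the VAF bound strict
    (> 1%); exactly 1% VAF is *not* a detection.
    """
    return v.alt_reads >= min_reads and v.vaf > min_vaf


@dataclass
class Blacklist:
    """Recurrence counts across normals and the derived blacklisted key set."""

    n_normals: int
    detection_counts: dict[Key, int] = field(default_factory=dict)
    recurrence_fraction: float = DEFAULT_RECURRENCE_FRACTION

    def __post_init__(self) -> None:
        if self.n_normals <= 0:
            raise ValueError("n_normals must be positive")
        bad = {k: c for k, c in self.detection_counts.items() if c > self.n_normals}
        if bad:
            raise ValueError(f"detection counts exceed cohort size: {bad}")

    @property
    def blacklisted_keys(self) -> set[Key]:
        thr = self.recurrence_fraction * self.n_normals
        return {k for k, c in self.detection_counts.items() if c > thr}

    def __contains__(self, key: Key) -> bool:
        return key in self.blacklisted_keys

    def contains_variant(self, v: VariantCall) -> bool:
        return v.key in self.blacklisted_keys


def build_blacklist(
    normal_tables: Iterable[list[VariantCall]],
    recurrence_fraction: float = DEFAULT_RECURRENCE_FRACTION,
    min_reads: int = DETECTION_MIN_READS,
    min_vaf: float = DETECTION_MIN_VAF,
) -> Blacklist:
    """Count per-key detections across normal samples and derive the blacklist.

    A key appearing several times within one normal's table counts once:
    recurrence is across samples.  The recurrence test is strict
    (``count / n > fraction``), so e.g. 11 of 53 normals (20.8%) blacklists
    a key while 10 of 53 (18.9%) does not.
    """
    counts: dict[Key, int] = {}
    n = 0
    for table in normal_tables:
        n += 1
        detected_keys = {v.key for v in table
                         if detected_in_normal(v, min_reads=min_reads, min_vaf=min_vaf)}
        for k in detected_keys:
            counts[k] = counts.get(k, 0) + 1
    if n == 0:
        raise ValueError("normal cohort is empty")
    return Blacklist(n_normals=n, detection_counts=counts,
                     recurrence_fraction=recurrence_fraction)


def write_blacklist(bl: Blacklist, path: Union[str, Path]) -> None:
    """Persist as an auditable TSV of (chrom, pos, ref, alt, n_detected, n_normals)."""
    rows = [
        {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
         "n_detected": c, "n_normals": bl.n_normals}
        for k, c in sorted(bl.detection_counts.items())
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "n_detected", "n_normals"])
    with open(path, "w") as fh:
        fh.write(f"# recurrence_fraction={bl.recurrence_fraction} "
                 f"n_normals={bl.n_normals}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_blacklist(path: Union[str, Path]) -> Blacklist:
    recurrence = DEFAULT_RECURRENCE_FRACTION
    n_normals = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].strip().split():
                key, _, val = token.partition("=")
                if key == "recurrence_fraction":
                    recurrence = float(val)
                elif key == "n_normals":
                    n_normals = int(val)
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    if n_normals is None:
        if df.empty:
            raise ValueError(f"{path}: cannot infer cohort size from empty table")
        n_normals = int(df["n_normals"].iloc[0])
    counts = {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): int(r.n_detected)
        for r in df.itertuples()
    }
    return Blacklist(n_normals=n_normals,
                     detection_counts=counts,
                     recurrence_fraction=recurrence)
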